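# Methods

This note documents the models and numerical choices behind `ahquant`: what
each stage computes, which parameters matter, what the synthetic-data
generator does and does not emulate, and where the design was genuinely
open.

## In silico digestion

Trypsin specificity is the [KR/P] rule: the peptide bond after K or R is
cleaved unless the next residue is P. Peptides are *fully tryptic* — both
termini are cleavage sites or protein termini — and a peptide's missed
cleavages are the internal K/R sites left uncut. The digest enumerates all
boundary pairs with at most `max_missed` internal sites and a length within
`[min_len, max_len]`; positions are 1-based inclusive. Two presets matter
downstream: observable peptides for the iBAQ denominator (0 missed
cleavages, length 6–30) and targeted-validation candidates (≤2 missed
cleavages, length 8–25).

Decisions:

* Protein termini count as valid peptide termini. This is the standard
  convention and is required for proteins without any K/R to yield their
  single spanning peptide.
* Ambiguity codes (B, J, O, U, X, Z) pass through digestion as non-cleaving
  residues, because cleavage logic does not need their chemistry; mass
  computation refuses them with the offending positions listed, because
  their mass is undefined. Fail loudly where chemistry is undefined,
  proceed where only cleavage logic is needed.
* The initiator methionine is kept by default; `remove_initiator_met`
  strips it (positions then refer to the stripped sequence).
* Molecular weights use average residue masses (plus one water), the
  convention for molecular-weight weighting of abundances; monoisotopic
  masses are available behind `average=False`. Residue masses come from
  pyteomics.

The digest is verified against an independent brute-force oracle
(enumerate all substrings, keep those with valid boundaries and internal
missed-cleavage count within the allowance) on 1,000 random sequences per
run of the acceptance suite, and cross-checked against pyteomics' cleave
machinery given the same [KR/P] regex.

## iBAQ quantification, ranking and tiers

Protein intensity is the sum of its peptide intensities (absent
observations contribute nothing, identical to zero-imputation);
iBAQ = intensity / observable-peptide count; riBAQ normalises iBAQ to sum
to one over quantified proteins; estimated abundance = riBAQ × molecular
weight; the percentage column and ranking derive from estimated abundance.
The percentage interpretation matters: published top-10 tables order
proteins differently from raw iBAQ (a 254 kDa protein outranks albumin at
one third of its iBAQ), and only the mass-weighted reading reproduces the
printed ratios — this is asserted as a test, not assumed.

Tiers walk ranks in descending-percentage order, accumulating percentage:
a protein is *high* when the cumulative fraction before it is < 0.95,
*medium* when < 0.99, else *low* (the "cumulative-before" rule; the
"cumulative-after ≤ cut" alternative is available via `boundary="after"`).
The rule was chosen because published tier counts come without a stated
boundary convention. Ties in percentage break by accession, so ranking is
deterministic. Proteins with zero total intensity or zero observable
peptides are excluded from normalisation (they would be rank-unstable at
zero or undefined, respectively) with a logged warning. A `min_peptides`
option (default 1) optionally drops proteins observed with fewer distinct
peptides.

Dynamic range is log10(max/min) of positive relative abundances, reported
both as the float and its nearest integer, since "orders of magnitude" in
reports is ambiguous between floor/round/ceiling.

## DIA roll-up, normalization and differential analysis

Roll-up sums fragment peak areas to peptide intensities and peptide
intensities to protein intensities per run; totals are conserved exactly.
Identifications can be filtered at q ≤ 0.01 (closed boundary); when
q-values are absent the filter is skipped with an explicit warning, never
silently.

Cross-run normalization assumes most peptides are not regulated across
runs and removes one multiplicative factor per run. The factor estimator
is the per-run median of *row-centered* log intensities over rows observed
in every run: row-centering cancels the per-row abundance term exactly, so
the estimate does not depend on the shape of the intensity distribution
(a raw per-run median has error ∝ 1/(2·f(median)·√n), which is large when
intensities spread over seven decades) and is robust to regulation that is
roughly balanced between up and down. Factors are anchored so the
least-biased run has factor 1; pure multiplicative bias is inverted
exactly and the operation is idempotent. When no row is complete in all
runs, pairwise-median factors against the first run are used, with a
warning. An `rt_local` mode applies the same computation within
retention-time bins and interpolates log-factors between bin centers, for
peptide-level matrices carrying an RT column. The pipeline estimates
factors on the peptide-level matrix (many rows) and applies them to the
protein matrix.

Fold change uses geometric group means: FC = 2^(mean log2 after − mean
log2 before). Geometric means match the multiplicative error model and are
robust to skew; the arithmetic-mean ratio is available behind
`method="arithmetic"` for sensitivity analysis. Zeros are replaced by half
the smallest positive value in the matrix (a documented pseudocount) only
when both groups have signal; proteins unobserved in one group are flagged
`insufficient` rather than dropped. DEP calling is strict:
up if FC > θ, down if FC < 1/θ, else null, with θ > 1 enforced
(default 1.5).

The validation statistic is a two-sided Welch t-test on log2 intensities
per protein — a documented stand-in, since published per-protein p-values
of this kind rarely name their test. Degenerate rows (zero variance in
both groups, or fewer than two observations per group) return p = 1 with a
flag.

### OPLS-DA

Runs × proteins log2 intensities (per-protein median imputation of missing
runs) are mean-centered (unit-variance scaling optional) and decomposed
against the ±1 group vector: `n_orthogonal` y-orthogonal components are
stripped NIPALS-style, then one predictive component is fit. The
separation statistic is the between-group distance of predictive scores
divided by the pooled within-group spread. Significance comes from
relabelling runs: p = (1 + #{stat_perm ≥ stat_obs}) / (1 + n_perm), the
add-one estimator, so p ≥ 1/(n_perm + 1) and p = 0 is impossible. When the
design admits no more than the requested number of distinct relabelings —
always the case at 3 vs 3, which has 9 distinct non-observed partitions —
the test is exact: all distinct partitions are enumerated (the statistic
is symmetric under a global label swap, so mirrored assignments are
counted once) and `n_permutations` in the result is the count actually
compared. The attainable floor at 3 vs 3 is therefore exactly 0.1; small
designs simply cannot certify stronger significance by permutation, and a
commercial CV-ANOVA p-value is not comparable to this number. Score signs
are indeterminate, as in any latent-variable model.

### DIA window design

Variable-width isolation windows equalise precursor counts: in-range
precursor m/z values are sorted and split into `n_windows` nearly equal
chunks (sizes differ by ≤1); boundaries sit midway between adjacent chunk
extremes, with the first/last boundary pinned to the configured range, so
windows are contiguous and cover the range exactly.

## PPI network analysis

STRING-style edge lists (two identifiers plus a combined score) are read
with dialect auto-detection (any score > 1 ⇒ integer 0–999 scale, divided
by 1000). The score filter is closed (≥ min, default 0.4). Self-loops are
dropped; duplicate undirected pairs collapse to their maximum score, which
makes loading independent of row order. Degree is the only hub statistic;
ranking breaks ties lexicographically. Induced subnetworks keep edges with
both endpoints in the subset and count isolated subset members separately.
Identifiers are opaque strings; accession↔symbol mapping is the caller's
lookup table, not a service call.

## Synthetic data generator

The generator emulates a label-free body-fluid study with a two-group
before/after design. The intensity of peptide j of protein i in run r is

    I_ijr = A_i · d_ij · b_r · f_i(group(r)) · ε_ijr

* `A_i` — true abundance, log-uniformly spaced so that
  log10(max/min) equals `abundance_decades` (default 7) *exactly*; the
  exactness makes the dynamic-range recovery a clean invariant.
* `d_ij` — per-peptide detectability, log-normal with natural-log SD
  `detectability_sigma` (default 0.4, ≈ 50% spread), constant across runs:
  within a study, a peptide's response is reproducible; the chosen scale
  keeps the quantification chain's recovery of the constructed span within
  ±0.3 decades, which is the regime the generative model is meant to
  represent.
* `b_r` — per-run multiplicative bias, uniform on `run_bias_range`
  (default [0.5, 2]).
* `f_i` — spiked fold change (default 4) applied to the "after" group of
  the `n_de_proteins` regulated proteins, split evenly up/down (extra one
  up); all other proteins have fold change exactly 1.
* `ε_ijr` — mean-one log-normal noise with CV `peptide_cv` (default 0.2).

Intensities go missing completely at random at `missing_rate`
(default 5%). Defaults mirror the targeted study design: 3 runs per group,
7 decades, fold change 4, 20% CV. Fragment tables split each peptide's
intensity by per-peptide Dirichlet proportions reused across runs, so
fragment sums reconstruct peptide intensities exactly. PPI simulation
plants `n_hubs` nodes of exact degree `hub_degree` over a sparse
background whose node degrees are capped below the hub degree, so planted
hubs are recoverable whenever `hub_degree > background_degree + n_hubs`.
All outputs are deterministic given the seed.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: spectrum-level structure (m/z, retention time,
peaks, charge states), intensity-dependent missingness (missingness is
completely at random), correlated peptide interference, protein-inference
ambiguity (each peptide maps to one protein), and identification-error
q-value structure (q-values are consumed as given, not generated).

## Bundled reference data

`ah_top10_abundance.tsv` is the published ten-most-abundant-protein table
(accession, gene, iBAQ, percentage). `standin_sequences.fasta` contains
*synthetic stand-in* sequences for PTPRZ1 (P23471), ALB (P02768) and TF
(P02787): random 20-letter sequences constructed so their average
molecular mass matches the published value for those UniProt entries
(254,087 / 69,367 / 77,064 Da) to < 0.1 Da. The consistency checks use
only the molecular weight, so the stand-ins are a faithful substitute for
that purpose and nothing else; they are labelled synthetic in the file and
its loader.

## Pipeline and determinism

`run_pipeline` wires the stages under a single validated configuration
(unknown keys rejected; the effective configuration is echoed to
`config.json`). All stage seeds derive deterministically from one root
seed; reruns with the same configuration are byte-identical, and
`summary.json` contains no paths or timestamps so it is comparable across
output directories. A stage failure aborts the run with the failing stage
named. Problem sizes in the examples, tests and acceptance script
(40–200 proteins, 60–300 residue proteins, up to 20 simulation replicates)
were chosen so each property is measured with comfortable statistical
margin while the whole suite stays lightweight.

## Known limitations

* The Welch t stand-in and the permutation OPLS-DA p are analogues, not
  reimplementations, of the commercial statistics that typically accompany
  published DEP tables; their values are not comparable one-to-one.
* Median-based normalization assumes roughly balanced regulation; strongly
  one-sided regulation biases the factors (the row-centered estimator
  mitigates but cannot eliminate this).
* Tier counts depend on the boundary convention when a protein straddles a
  cut; both conventions are implemented, but only one can match any given
  published count.
* Catalog comparisons key on bare accessions with isoform suffixes
  stripped by default; merging catalogs that mix identifier namespaces
  (e.g. gene symbols vs accessions) requires caller-side mapping.
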