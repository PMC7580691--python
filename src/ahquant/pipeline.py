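"""Configuration-driven orchestration of the full analysis on synthetic data.

``run_pipeline`` wires the stages end to end: simulate → digest → quantify
(iBAQ, tiers, dynamic range) → differential (roll-up, normalization, fold
change, DEP calling, OPLS-DA) → isolation-window design → PPI network →
catalog comparison. Every stage writes its TSV outputs under ``outdir`` and
contributes to a summary report; all randomness derives deterministically
from one root seed, so reruns with the same configuration are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from pyteomics import mass as _pyteomics_mass

from . import catalogs as cat
from . import differential as diff
from . import ibaq
from . import network as net
from . import synthetic as syn
from .digestion import count_observable_peptides, protein_mass, write_fasta

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate",
    "digest",
    "quantify",
    "diff",
    "windows",
    "network",
    "compare",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str | Path = "pipeline_out"
    stages: tuple[str, ...] = ALL_STAGES
    simulation: syn.SimulationConfig = field(default_factory=syn.SimulationConfig)
    min_peptides: int = 1
    tier_thresholds: ibaq.TierThresholds = field(default_factory=ibaq.TierThresholds)
    q_cutoff: float = 0.01
    normalize_mode: str = "global_median"
    fc_threshold: float = 1.5
    fc_method: str = "geometric"
    n_permutations: int = 199
    n_orthogonal: int = 1
    n_windows: int = 38
    mz_range: tuple[float, float] = (400.0, 900.0)
    min_interaction_score: float = 0.4
    ppi_n_hubs: int = 3
    ppi_hub_degree: int = 20
    ppi_background_degree: int = 2
    top_k_hubs: int = 10

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        """Build from a (possibly nested) plain dict, rejecting unknown keys."""
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if isinstance(raw.get("simulation"), dict):
            sim_known = {f.name for f in dataclasses.fields(syn.SimulationConfig)}
            sim_unknown = set(raw["simulation"]) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown simulation keys: {sorted(sim_unknown)}")
            sim = dict(raw["simulation"])
            for key in ("seq_length_range", "run_bias_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            raw["simulation"] = syn.SimulationConfig(**sim)
        if isinstance(raw.get("tier_thresholds"), dict):
            raw["tier_thresholds"] = ibaq.TierThresholds(**raw["tier_thresholds"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "mz_range" in raw:
            raw["mz_range"] = tuple(raw["mz_range"])
        return cls(**raw)

    def echo(self) -> dict[str, Any]:
        """The effective configuration as plain JSON-serialisable data."""
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        return d


def _stage_seeds(root: int) -> dict[str, int]:
    ss = np.random.SeedSequence(root)
    vals = ss.generate_state(3).astype(np.int64) % (2**31)
    return {"simulate": int(vals[0]), "ppi": int(vals[1]), "oplsda": int(vals[2])}


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the configured stages and write outputs under ``outdir``.

    Returns the summary report (also written as ``summary.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    with open(outdir / "config.json", "w") as fh:
        json.dump(config.echo(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    report: dict[str, Any] = {"seed": config.seed}
    stages = set(config.stages)

    def _fail(stage: str, err: Exception) -> None:
        raise PipelineError(f"stage {stage!r} failed: {err}") from err

    # ---- simulate -------------------------------------------------------
    try:
        sim_cfg = replace(config.simulation, seed=seeds["simulate"])
        records = syn.generate_protein_fasta(sim_cfg)
        peptide_table, truth = syn.simulate_peptide_table(records, sim_cfg)
        fragment_table = syn.simulate_fragment_table(peptide_table, sim_cfg)
        if "simulate" in stages:
            write_fasta(records, outdir / "proteins.fasta")
            syn.write_table(peptide_table, outdir / "peptides.tsv")
            syn.write_table(fragment_table, outdir / "fragments.tsv")
            syn.write_ground_truth(truth, outdir)
        report["simulate"] = {
            "n_proteins": len(records),
            "n_peptide_rows": int(len(peptide_table)),
        }
    except PipelineError:
        raise
    except Exception as err:  # noqa: BLE001 - stage boundary
        _fail("simulate", err)

    # ---- digest ---------------------------------------------------------
    try:
        n_theoretical = {r.accession: count_observable_peptides(r) for r in records}
        masses = {r.accession: protein_mass(r) for r in records}
        if "digest" in stages:
            pd.DataFrame(
                {
                    "accession": list(n_theoretical),
                    "n_observable_peptides": list(n_theoretical.values()),
                    "average_mass_da": [masses[a] for a in n_theoretical],
                }
            ).to_csv(outdir / "digest_summary.tsv", sep="\t", index=False)
        report["digest"] = {
            "n_proteins": len(n_theoretical),
            "median_observable_peptides": float(np.median(list(n_theoretical.values()))),
        }
    except PipelineError:
        raise
    except Exception as err:  # noqa: BLE001
        _fail("digest", err)

    # ---- quantify -------------------------------------------------------
    abundance_table = None
    if "quantify" in stages:
        try:
            abundance_table, tier_counts, (span, span_int) = ibaq.quantify(
                peptide_table,
                n_theoretical,
                masses,
                thresholds=config.tier_thresholds,
                min_peptides=config.min_peptides,
            )
            abundance_table.to_csv(outdir / "abundance.tsv", sep="\t", index=False)
            report["quantify"] = {
                "n_quantified": int(len(abundance_table)),
                "tier_counts": tier_counts,
                "dynamic_range_decades": span,
                "dynamic_range_rounded": span_int,
            }
        except PipelineError:
            raise
        except Exception as err:  # noqa: BLE001
            _fail("quantify", err)

    # ---- differential ---------------------------------------------------
    dep_table = None
    if "diff" in stages:
        try:
            matrix = diff.rollup(fragment_table)
            matrix = diff.qvalue_filter(matrix, config.q_cutoff)
            # factors estimated on peptide-level rows (many more of them)
            peptide_matrix = diff.rollup(fragment_table, level="peptide")
            matrix, factors = diff.cross_run_normalize(
                matrix, mode=config.normalize_mode, factor_source=peptide_matrix
            )
            diff.write_run_matrix(matrix, outdir / "normalized_matrix.tsv")
            fc = diff.fold_change(matrix, method=config.fc_method)
            dep_table, dep_counts = diff.select_deps(fc, threshold=config.fc_threshold)
            pvals = diff.validation_test(matrix)
            dep_table = dep_table.merge(pvals, on="accession")
            dep_table.to_csv(outdir / "deps.tsv", sep="\t", index=False)
            opls = diff.oplsda(
                matrix,
                n_orthogonal=config.n_orthogonal,
                n_permutations=config.n_permutations,
                seed=seeds["oplsda"],
            )
            scores = pd.DataFrame(
                {
                    "run_id": opls.predictive_scores.index,
                    "group": [matrix.groups[r] for r in opls.predictive_scores.index],
                    "predictive": opls.predictive_scores.to_numpy(),
                }
            )
            for c in opls.orthogonal_scores.columns:
                scores[c] = opls.orthogonal_scores[c].to_numpy()
            scores.to_csv(outdir / "oplsda_scores.tsv", sep="\t", index=False)
            report["diff"] = {
                "n_proteins": int(matrix.data.shape[0]),
                "normalization_factors": {k: float(v) for k, v in factors.items()},
                "dep_counts": dep_counts,
                "oplsda_permutation_p": opls.permutation_p,
                "oplsda_separation": opls.separation,
            }
        except PipelineError:
            raise
        except Exception as err:  # noqa: BLE001
            _fail("diff", err)

    # ---- DIA window design ---------------------------------------------
    if "windows" in stages:
        try:
            proton = 1.00728
            mzs = []
            for pep in peptide_table["peptide_sequence"].unique():
                m = _pyteomics_mass.fast_mass(pep, charge=0)
                mzs.append((m + 2 * proton) / 2.0)
            windows = diff.design_dia_windows(
                mzs, n_windows=config.n_windows, mz_range=config.mz_range
            )
            diff.windows_to_frame(windows).to_csv(
                outdir / "dia_windows.tsv", sep="\t", index=False
            )
            counts = [w.precursor_count for w in windows]
            report["windows"] = {
                "n_windows": len(windows),
                "max_count_difference": int(max(counts) - min(counts)),
            }
        except PipelineError:
            raise
        except Exception as err:  # noqa: BLE001
            _fail("windows", err)

    # ---- PPI network ----------------------------------------------------
    if "network" in stages:
        try:
            if dep_table is not None:
                dep_accs = sorted(
                    dep_table.loc[dep_table.direction != "null", "accession"]
                )
            else:
                dep_accs = sorted(truth.de_accessions)
            if len(dep_accs) < 2:
                raise ValueError("too few DEPs for a network")
            hub_degree = min(config.ppi_hub_degree, len(dep_accs) - 1)
            edge_df = syn.simulate_ppi_edges(
                dep_accs,
                n_hubs=min(config.ppi_n_hubs, len(dep_accs)),
                hub_degree=hub_degree,
                background_degree=config.ppi_background_degree,
                seed=seeds["ppi"],
                score_range=(0.3, 1.0),
            )
            edge_df.to_csv(outdir / "ppi_edges_raw.tsv", sep="\t", index=False)
            edges = net.load_edges(edge_df, min_score=config.min_interaction_score)
            summary, kept = net.induced_subnetwork(
                edges, dep_accs, top_k=config.top_k_hubs
            )
            net.write_network_outputs(kept, summary, outdir)
            hubs = net.hub_ranking(kept, top_k=config.top_k_hubs)
            report["network"] = {
                "n_nodes": summary.n_nodes,
                "n_edges": summary.n_edges,
                "top_hubs": [{"node": n, "degree": d} for n, d in hubs],
            }
        except PipelineError:
            raise
        except Exception as err:  # noqa: BLE001
            _fail("network", err)

    # ---- catalog comparison --------------------------------------------
    if "compare" in stages:
        try:
            quantified = cat.Catalog.from_iterable(
                "quantified",
                abundance_table["accession"] if abundance_table is not None else truth.proteins.accession,
                abundance=(
                    dict(zip(abundance_table.accession, abundance_table.percentage))
                    if abundance_table is not None
                    else None
                ),
            )
            true_de = cat.Catalog.from_iterable("true_de", truth.de_accessions)
            stats = None
            if dep_table is not None:
                detected = cat.Catalog.from_iterable(
                    "detected_de",
                    dep_table.loc[dep_table.direction != "null", "accession"],
                )
                stats = cat.overlap_stats(detected, true_de)
                cat.overlap_report(detected, true_de).to_csv(
                    outdir / "catalog_overlap.tsv", sep="\t", index=False
                )
            regions = cat.venn_counts([quantified, true_de])
            weighted = None
            if quantified.abundance and abundance_table is not None:
                high = cat.Catalog.from_iterable(
                    "high_tier",
                    abundance_table.loc[abundance_table.tier == "high", "accession"],
                )
                weighted = cat.abundance_weighted_overlap(quantified, high)
            report["compare"] = {
                "venn_regions": {"+".join(k): v for k, v in regions.items()},
                "detected_vs_true_de": (
                    {kk: vv for kk, vv in stats.items() if isinstance(vv, (int, float))}
                    if stats
                    else None
                ),
                "high_tier_abundance_share_pct": weighted,
            }
        except PipelineError:
            raise
        except Exception as err:  # noqa: BLE001
            _fail("compare", err)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
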