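import numpy as np
import pandas as pd
import pytest

from ahquant.datasets import load_standin_records, load_top10_abundance
from ahquant.digestion import count_observable_peptides, protein_mass
from ahquant.ibaq import (
    TierThresholds,
    classify_tiers,
    compute_ibaq,
    dynamic_range,
    estimated_abundance_table,
    quantify,
    sum_protein_intensity,
)


def _peptable(rows):
    return pd.DataFrame(rows, columns=["protein_accession", "peptide_sequence", "run_id", "group", "intensity"])


class TestSumProteinIntensity:
    def test_simple_sum(self):
        t = _peptable(
            [
                ("P1", "AAAAAK", "r1", "before", 1e6),
                ("P1", "CCCCCK", "r1", "before", 2e6),
                ("P1", "DDDDDK", "r2", "after", 3e6),
            ]
        )
        assert sum_protein_intensity(t)["P1"] == pytest.approx(6e6)

    def test_protein_without_peptides_omitted(self):
        t = _peptable([("P1", "AAAAAK", "r1", "before", 1e6)])
        sums = sum_protein_intensity(t, known_accessions={"P1", "P2"})
        assert "P2" not in sums.index

    def test_unknown_accession_rejected(self):
        t = _peptable([("P9", "AAAAAK", "r1", "before", 1.0)])
        with pytest.raises(KeyError, match="P9"):
            sum_protein_intensity(t, known_accessions={"P1"})

    def test_negative_intensity_rejected(self):
        t = _peptable([("P1", "AAAAAK", "r1", "before", -1.0)])
        with pytest.raises(ValueError):
            sum_protein_intensity(t)


class TestComputeIbaq:
    def test_division(self):
        out = compute_ibaq({"P1": 1e6}, {"P1": 2})
        assert out["P1"] == pytest.approx(5e5)

    def test_zero_intensity(self):
        assert compute_ibaq({"P1": 0.0}, {"P1": 5})["P1"] == 0.0

    def test_unquantifiable_protein_excluded(self, caplog):
        out = compute_ibaq({"P1": 1.0, "P2": 1.0}, {"P1": 1, "P2": 0})
        assert list(out.index) == ["P1"]

    def test_linearity_under_global_scaling(self):
        base = compute_ibaq({"P1": 10.0, "P2": 30.0}, {"P1": 2, "P2": 3})
        scaled = compute_ibaq({"P1": 70.0, "P2": 210.0}, {"P1": 2, "P2": 3})
        assert np.allclose(scaled.to_numpy(), 7 * base.to_numpy())


class TestEstimatedAbundance:
    def test_single_protein(self):
        df = estimated_abundance_table({"P1": 5.0}, {"P1": 50000.0})
        assert df.rel_ibaq.iloc[0] == 1.0
        assert df.percentage.iloc[0] == pytest.approx(100.0)

    def test_normalization_invariants(self):
        df = estimated_abundance_table(
            {"P1": 5.0, "P2": 1.0, "P3": 14.0},
            {"P1": 1e4, "P2": 5e4, "P3": 2e4},
        )
        assert df.rel_ibaq.sum() == pytest.approx(1.0, abs=1e-9)
        assert df.percentage.sum() == pytest.approx(100.0, abs=1e-6)
        assert sorted(df["rank"]) == [1, 2, 3]

    def test_percentages_invariant_under_ibaq_rescaling(self):
        masses = {"P1": 1e4, "P2": 5e4}
        a = estimated_abundance_table({"P1": 5.0, "P2": 1.0}, masses)
        b = estimated_abundance_table({"P1": 500.0, "P2": 100.0}, masses)
        assert np.allclose(a.percentage.to_numpy(), b.percentage.to_numpy())

    def test_missing_mass_raises(self):
        with pytest.raises(KeyError, match="P2"):
            estimated_abundance_table({"P1": 1.0, "P2": 1.0}, {"P1": 1e4})

    def test_published_share_ratio_reproduced_with_mass_weighting(self):
        """MW-weighted shares reproduce the published percentage ratios and
        the rank inversion (PTPRZ1 above ALB despite a lower iBAQ)."""
        tab = load_top10_abundance().set_index("accession")
        masses = {a: protein_mass(r) for a, r in load_standin_records().items()}
        ib = {a: tab.loc[a, "ibaq"] for a in ("P23471", "P02768")}
        df = estimated_abundance_table(ib, masses).set_index("accession")
        got = df.percentage["P23471"] / df.percentage["P02768"]
        assert got == pytest.approx(29.60 / 27.34, rel=0.02)
        assert df["rank"]["P23471"] == 1  # despite 6.79e7 < 2.30e8 iBAQ


class TestTierClassification:
    def test_boundary_rule_worked_example(self):
        df = pd.DataFrame({"accession": ["A", "B", "C"], "percentage": [96.0, 3.0, 1.0]})
        out, counts = classify_tiers(df)
        assert list(out.tier) == ["high", "medium", "low"]
        assert counts == {"high": 1, "medium": 1, "low": 1}

    def test_uniform_percentages_cumulative_walk(self):
        df = pd.DataFrame(
            {"accession": [f"P{i:03d}" for i in range(100)], "percentage": [1.0] * 100}
        )
        _, counts = classify_tiers(df)
        assert counts == {"high": 95, "medium": 4, "low": 1}

    def test_counts_partition_quantified_proteins(self, small_study):
        records, peptides, _, _ = small_study
        n_theo = {r.accession: count_observable_peptides(r) for r in records}
        masses = {r.accession: protein_mass(r) for r in records}
        table, counts, _ = quantify(peptides, n_theo, masses)
        assert sum(counts.values()) == len(table)
        # tiers consistent with rank: no low above a high
        order = table.sort_values("rank").tier.map({"high": 0, "medium": 1, "low": 2})
        assert (order.diff().dropna() >= 0).all()

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            TierThresholds(high_cut=0.99, medium_cut=0.95)


class TestDynamicRange:
    def test_seven_decades(self):
        span, rounded = dynamic_range({"a": 1.0, "b": 1e7})
        assert span == pytest.approx(7.0)
        assert rounded == 7

    def test_invariant_under_rescaling(self):
        v = {"a": 2.0, "b": 5e3, "c": 7e6}
        assert dynamic_range(v)[0] == pytest.approx(
            dynamic_range({k: 13.7 * x for k, x in v.items()})[0]
        )

    def test_nonpositive_excluded(self):
        span, _ = dynamic_range({"a": 0.0, "b": 1.0, "c": 100.0})
        assert span == pytest.approx(2.0)


class TestPipelineRecovery:
    def test_noise_free_equal_detectability_recovers_truth(self):
        """With equal detectabilities and no noise, iBAQ is proportional to
        the true abundance up to one global constant."""
        from ahquant.synthetic import SimulationConfig, generate_protein_fasta, simulate_peptide_table

        cfg = SimulationConfig(
            n_proteins=25,
            seq_length_range=(60, 200),
            n_de_proteins=0,
            true_fc=1.0,
            peptide_cv=0.0,
            run_bias_range=(1.0, 1.0),
            missing_rate=0.0,
            detectability_sigma=0.0,
            seed=11,
        )
        records = generate_protein_fasta(cfg)
        peptides, truth = simulate_peptide_table(records, cfg)
        n_theo = {r.accession: count_observable_peptides(r) for r in records}
        sums = sum_protein_intensity(peptides)
        ibaq = compute_ibaq(sums, n_theo)
        true_a = truth.proteins.set_index("accession").true_abundance.loc[ibaq.index]
        ratio = (ibaq / true_a).to_numpy()
        assert np.max(np.abs(ratio / ratio[0] - 1.0)) < 1e-6

    def test_synthetic_dynamic_range_near_seven_decades(self):
        """Catalog-style quantification (pooled design: no treatment
        contrast) recovers the constructed 7-decade abundance span; only
        per-protein detectability averaging perturbs it."""
        from ahquant.synthetic import SimulationConfig, generate_protein_fasta, simulate_peptide_table

        cfg = SimulationConfig(
            n_proteins=30,
            seq_length_range=(60, 200),
            n_de_proteins=0,
            true_fc=1.0,
            peptide_cv=0.0,
            run_bias_range=(1.0, 1.0),
            missing_rate=0.0,
            seed=7,
        )
        records = generate_protein_fasta(cfg)
        peptides, _ = simulate_peptide_table(records, cfg)
        n_theo = {r.accession: count_observable_peptides(r) for r in records}
        masses = {r.accession: protein_mass(r) for r in records}
        table, _, (span, _) = quantify(peptides, n_theo, masses)
        assert span == pytest.approx(7.0, abs=0.3)
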