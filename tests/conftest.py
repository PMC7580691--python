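import numpy as np
import pandas as pd
import pytest

from ahquant.synthetic import (
    SimulationConfig,
    generate_protein_fasta,
    simulate_fragment_table,
    simulate_peptide_table,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Small but fully featured synthetic study."""
    return SimulationConfig(
        n_proteins=40,
        seq_length_range=(60, 200),
        n_de_proteins=10,
        seed=42,
    )


@pytest.fixture(scope="session")
def noise_free_config() -> SimulationConfig:
    """Deterministic generative limit: no noise, no bias, no missingness."""
    return SimulationConfig(
        n_proteins=30,
        seq_length_range=(60, 200),
        n_de_proteins=8,
        true_fc=4.0,
        peptide_cv=0.0,
        run_bias_range=(1.0, 1.0),
        missing_rate=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    records = generate_protein_fasta(small_config)
    peptides, truth = simulate_peptide_table(records, small_config)
    fragments = simulate_fragment_table(peptides, small_config)
    return records, peptides, fragments, truth


@pytest.fixture(scope="session")
def noise_free_study(noise_free_config):
    records = generate_protein_fasta(noise_free_config)
    peptides, truth = simulate_peptide_table(records, noise_free_config)
    return records, peptides, truth


def brute_force_digest(seq: str, max_missed: int, min_len: int, max_len: int):
    """Independent digestion oracle: enumerate all substrings and keep those
    whose boundaries are valid tryptic cleavage points (or protein termini)
    and whose internal uncut-site count is within the allowance.

    Returns a set of (start, end) 1-based inclusive coordinates.
    """
    n = len(seq)
    # boundary b sits between seq[b-1] and seq[b]
    def boundary_ok(b: int) -> bool:
        if b == 0 or b == n:
            return True
        return seq[b - 1] in "KR" and seq[b] != "P"

    def cleavable(b: int) -> bool:
        return 0 < b < n and seq[b - 1] in "KR" and seq[b] != "P"

    out = set()
    for s in range(n):
        if not boundary_ok(s):
            continue
        for e in range(s + 1, min(s + max_len, n) + 1):
            if not boundary_ok(e):
                continue
            if e - s < min_len:
                continue
            missed = sum(1 for b in range(s + 1, e) if cleavable(b))
            if missed <= max_missed:
                out.add((s + 1, e))
    return out
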