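"""Intensity-based absolute quantification (iBAQ) and abundance ranking.

iBAQ divides a protein's summed peptide intensity by its number of
theoretically observable tryptic peptides, removing the trivial dependence
of summed intensity on protein length. Relative iBAQ (riBAQ) normalises to
the sum over all quantified proteins; multiplying riBAQ by the protein's
molecular weight yields a mass-weighted estimated abundance whose share of
the total is the "percentage" used for ranking and tier classification
(high = top 95% of cumulative abundance, medium = 95–99%, low = rest).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ABUNDANCE_COLUMNS = [
    "accession",
    "protein_intensity",
    "n_theoretical",
    "ibaq",
    "rel_ibaq",
    "est_abundance",
    "percentage",
    "rank",
    "tier",
]


@dataclass(frozen=True)
class TierThresholds:
    """Cumulative-abundance cut points separating high/medium/low tiers."""

    high_cut: float = 0.95
    medium_cut: float = 0.99

    def __post_init__(self) -> None:
        if not (0 < self.high_cut < self.medium_cut < 1):
            raise ValueError("need 0 < high_cut < medium_cut < 1")


def sum_protein_intensity(
    peptide_table: pd.DataFrame,
    known_accessions: set[str] | None = None,
    per_run: bool = False,
) -> pd.Series | pd.DataFrame:
    """Summed peptide intensity per protein (over all runs, or per run).

    Missing values are simply absent rows; they contribute nothing to the
    sum, which is identical to zero-imputing them.
    """
    if (peptide_table["intensity"] < 0).any():
        raise ValueError("negative peptide intensities")
    if known_accessions is not None:
        unknown = sorted(set(peptide_table["protein_accession"]) - known_accessions)
        if unknown:
            raise KeyError(f"peptides mapped to unknown accessions: {unknown}")
    if per_run:
        return peptide_table.pivot_table(
            index="protein_accession",
            columns="run_id",
            values="intensity",
            aggfunc="sum",
        )
    return peptide_table.groupby("protein_accession")["intensity"].sum()


def compute_ibaq(
    intensity: Mapping[str, float] | pd.Series, n_theoretical: Mapping[str, int]
) -> pd.Series:
    """iBAQ = summed intensity / number of observable tryptic peptides.

    Proteins with zero theoretical peptides are unquantifiable; they are
    excluded with a warning rather than propagating an infinity.
    """
    intensity = pd.Series(dict(intensity) if not isinstance(intensity, pd.Series) else intensity)
    out = {}
    dropped = []
    for acc, val in intensity.items():
        n = n_theoretical.get(acc) if hasattr(n_theoretical, "get") else n_theoretical[acc]
        if n is None or n < 1:
            dropped.append(acc)
            continue
        out[acc] = val / n
    if dropped:
        logger.warning(
            "%d protein(s) with no observable peptide excluded from iBAQ: %s",
            len(dropped),
            dropped[:10],
        )
    return pd.Series(out, name="ibaq")


def estimated_abundance_table(
    ibaq_map: Mapping[str, float] | pd.Series,
    mass_map: Mapping[str, float],
    intensity_map: Mapping[str, float] | None = None,
    n_theoretical: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Relative iBAQ, MW-weighted estimated abundance, percentage and rank.

    rel_ibaq = ibaq / Σ ibaq; est_abundance = rel_ibaq × MW;
    percentage = 100 × est_abundance / Σ est_abundance. Records are sorted
    by descending percentage (ties broken by accession) and ranked from 1.
    Proteins with zero intensity are excluded from the normalisation.
    """
    ibaq = pd.Series(dict(ibaq_map) if not isinstance(ibaq_map, pd.Series) else ibaq_map, dtype=float)
    ibaq = ibaq[ibaq > 0]
    if ibaq.empty:
        raise ValueError("no protein with positive iBAQ")
    missing_mass = sorted(a for a in ibaq.index if a not in mass_map)
    if missing_mass:
        raise KeyError(f"no molecular mass for accessions: {missing_mass}")
    mass = pd.Series({a: float(mass_map[a]) for a in ibaq.index})

    rel = ibaq / ibaq.sum()
    est = rel * mass
    pct = 100.0 * est / est.sum()

    df = pd.DataFrame(
        {
            "accession": ibaq.index,
            "ibaq": ibaq.to_numpy(),
            "rel_ibaq": rel.to_numpy(),
            "est_abundance": est.to_numpy(),
            "percentage": pct.to_numpy(),
        }
    )
    if intensity_map is not None:
        df["protein_intensity"] = [intensity_map.get(a, np.nan) for a in df.accession]
    if n_theoretical is not None:
        df["n_theoretical"] = [n_theoretical.get(a, np.nan) for a in df.accession]
    df = df.sort_values(
        ["percentage", "accession"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def classify_tiers(
    records: pd.DataFrame,
    thresholds: TierThresholds = TierThresholds(),
    boundary: str = "before",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assign abundance tiers by walking ranks in descending-percentage order.

    With the default ``boundary="before"`` rule a protein is *high* when the
    cumulative fraction before adding it is below ``high_cut``, *medium*
    when below ``medium_cut``, else *low*. The alternative
    ``boundary="after"`` rule compares the cumulative fraction including the
    protein (≤ cut). Returns the annotated table and per-tier counts.
    """
    if boundary not in {"before", "after"}:
        raise ValueError("boundary must be 'before' or 'after'")
    df = records.sort_values(
        ["percentage", "accession"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    if "rank" not in df.columns:
        df["rank"] = np.arange(1, len(df) + 1)
    frac = df["percentage"].to_numpy() / df["percentage"].sum()
    cum_after = np.cumsum(frac)
    cum_before = cum_after - frac
    basis = cum_before if boundary == "before" else cum_after
    op = np.less if boundary == "before" else np.less_equal
    tier = np.where(
        op(basis, thresholds.high_cut),
        "high",
        np.where(op(basis, thresholds.medium_cut), "medium", "low"),
    )
    df["tier"] = tier
    counts = {t: int((tier == t).sum()) for t in ("high", "medium", "low")}
    return df, counts


def dynamic_range(values: Mapping[str, float] | pd.Series) -> tuple[float, int]:
    """Decimal decades spanned by the positive abundances: log10(max/min).

    Returns the float and its nearest-integer rounding. Non-positive values
    are excluded with a warning.
    """
    v = pd.Series(dict(values) if not isinstance(values, pd.Series) else values, dtype=float)
    pos = v[v > 0]
    if len(pos) < len(v):
        logger.warning("%d non-positive abundance(s) excluded", len(v) - len(pos))
    if len(pos) < 2:
        raise ValueError("need at least two positive abundances")
    span = math.log10(pos.max() / pos.min())
    return span, int(round(span))


def quantify(
    peptide_table: pd.DataFrame,
    n_theoretical: Mapping[str, int],
    mass_map: Mapping[str, float],
    thresholds: TierThresholds = TierThresholds(),
    min_peptides: int = 1,
) -> tuple[pd.DataFrame, dict[str, int], tuple[float, int]]:
    """End-to-end iBAQ chain: sum → iBAQ → shares/ranks → tiers → range.

    ``min_peptides`` drops proteins observed with fewer distinct peptide
    sequences than the cutoff before quantification.
    """
    if min_peptides > 1:
        npep = peptide_table.groupby("protein_accession")["peptide_sequence"].nunique()
        keep = set(npep[npep >= min_peptides].index)
        peptide_table = peptide_table[peptide_table.protein_accession.isin(keep)]
    intensity = sum_protein_intensity(peptide_table)
    ibaq = compute_ibaq(intensity, n_theoretical)
    table = estimated_abundance_table(
        ibaq, mass_map, intensity_map=intensity.to_dict(), n_theoretical=dict(n_theoretical)
    )
    table, counts = classify_tiers(table, thresholds)
    span = dynamic_range(table.set_index("accession")["rel_ibaq"])
    return table, counts, span
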