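"""Set and abundance-weighted comparison of proteome catalogs.

A catalog is a named set of protein accessions (optionally with per-protein
abundances). Typical uses: merging this study's identifications with
previous body-fluid catalogs, computing the overlap with the plasma
proteome, and counting Venn regions for up to three catalogs. Percentages
are rounded half-up to one decimal, the convention of proteomics reports.
Isoform suffixes (``P12345-2`` → ``P12345``) are stripped by default, since
cross-study catalogs mix conventions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

_ISOFORM = re.compile(r"-\d+$")


def round_pct(value: float, digits: int = 1) -> float:
    """Round half-up, as percentages are reported."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def normalize_accession(acc: str, strip_isoforms: bool = True) -> str:
    acc = acc.strip()
    if strip_isoforms and _ISOFORM.search(acc):
        base = _ISOFORM.sub("", acc)
        logger.debug("isoform suffix stripped: %s -> %s", acc, base)
        return base
    return acc


@dataclass
class Catalog:
    """A named proteome catalog: accession set plus optional abundances."""

    name: str
    accessions: frozenset[str]
    abundance: dict[str, float] | None = None

    @classmethod
    def from_iterable(
        cls,
        name: str,
        accessions: Iterable[str],
        abundance: Mapping[str, float] | None = None,
        strip_isoforms: bool = True,
    ) -> "Catalog":
        accs = frozenset(normalize_accession(a, strip_isoforms) for a in accessions)
        ab = None
        if abundance is not None:
            ab = {}
            for a, v in abundance.items():
                key = normalize_accession(a, strip_isoforms)
                ab[key] = ab.get(key, 0.0) + float(v)
        return cls(name=name, accessions=accs, abundance=ab)

    @classmethod
    def from_file(cls, name: str, path: str | Path, strip_isoforms: bool = True) -> "Catalog":
        """One accession per line, or TSV with accession and abundance columns."""
        path = Path(path)
        first = path.read_text().splitlines()
        if not first:
            return cls(name=name, accessions=frozenset())
        if "\t" in first[0]:
            df = pd.read_csv(path, sep="\t")
            acc_col, ab_col = df.columns[0], df.columns[1]
            return cls.from_iterable(
                name,
                df[acc_col].astype(str),
                abundance=dict(zip(df[acc_col].astype(str), df[ab_col])),
                strip_isoforms=strip_isoforms,
            )
        return cls.from_iterable(
            name, (l for l in first if l.strip()), strip_isoforms=strip_isoforms
        )

    def __len__(self) -> int:
        return len(self.accessions)


def merge_catalogs(catalogs: Sequence[Catalog], name: str = "merged") -> tuple[Catalog, dict[str, set[str]]]:
    """Union with deduplication; returns the merged catalog and, per
    accession, the set of source catalogs that contained it."""
    if not catalogs:
        raise ValueError("need at least one catalog")
    provenance: dict[str, set[str]] = {}
    for cat in catalogs:
        for acc in cat.accessions:
            provenance.setdefault(acc, set()).add(cat.name)
    return Catalog(name=name, accessions=frozenset(provenance)), provenance


def overlap_stats(catalog_a: Catalog, catalog_b: Catalog) -> dict:
    """Intersection/complement counts and percentages relative to |A|."""
    if not catalog_a.accessions:
        raise ValueError("catalog_a is empty")
    common = catalog_a.accessions & catalog_b.accessions
    specific = catalog_a.accessions - catalog_b.accessions
    n_a = len(catalog_a.accessions)
    return {
        "n_a": n_a,
        "n_b": len(catalog_b.accessions),
        "n_common": len(common),
        "n_a_specific": len(specific),
        "pct_common": round_pct(100.0 * len(common) / n_a),
        "pct_a_specific": round_pct(100.0 * len(specific) / n_a),
        "common": common,
        "a_specific": specific,
    }


def abundance_weighted_overlap(catalog_a: Catalog, catalog_b: Catalog) -> float:
    """Share of catalog A's total abundance carried by proteins also in B."""
    if not catalog_a.abundance:
        raise ValueError(f"catalog {catalog_a.name!r} has no abundances")
    total = sum(catalog_a.abundance.values())
    if total <= 0:
        raise ValueError("total abundance is not positive")
    common = sum(
        v for a, v in catalog_a.abundance.items() if a in catalog_b.accessions
    )
    return round_pct(100.0 * common / total)


def venn_counts(catalogs: Sequence[Catalog]) -> dict[tuple[str, ...], int]:
    """Disjoint region counts for 2 or 3 catalogs.

    Keys are tuples of the catalog names a region belongs to; every element
    of every catalog falls in exactly one region, so region sums reconcile
    with catalog sizes.
    """
    if len(catalogs) not in (2, 3):
        raise ValueError("venn_counts supports exactly 2 or 3 catalogs")
    names = [c.name for c in catalogs]
    if len(set(names)) != len(names):
        raise ValueError("catalog names must be distinct")
    sets = {c.name: c.accessions for c in catalogs}
    universe = set().union(*sets.values())
    regions: dict[tuple[str, ...], int] = {}
    for acc in universe:
        key = tuple(n for n in names if acc in sets[n])
        regions[key] = regions.get(key, 0) + 1
    # make all possible regions explicit
    from itertools import combinations

    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions.setdefault(combo, 0)
    return regions


def overlap_report(catalog_a: Catalog, catalog_b: Catalog) -> pd.DataFrame:
    s = overlap_stats(catalog_a, catalog_b)
    return pd.DataFrame(
        [
            {
                "catalog_a": catalog_a.name,
                "catalog_b": catalog_b.name,
                "n_a": s["n_a"],
                "n_b": s["n_b"],
                "n_common": s["n_common"],
                "n_a_specific": s["n_a_specific"],
                "pct_common": s["pct_common"],
                "pct_a_specific": s["pct_a_specific"],
            }
        ]
    )
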