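"""In silico tryptic proteolysis and protein molecular weight.

Trypsin cleaves C-terminal to lysine (K) and arginine (R) except when the
next residue is proline — the ``[KR/P]`` rule. A peptide is *fully tryptic*
when both of its termini are cleavage sites or protein termini, and its
*missed cleavages* are the internal K/R sites left uncut.

Two digest presets matter downstream:

* observable peptides for iBAQ: fully tryptic, 0 missed cleavages,
  length 6–30 residues;
* targeted-MS (PRM) candidates: fully tryptic, up to 2 missed cleavages,
  length 8–25 residues.

Positions are 1-based inclusive, the convention of proteomics reports.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mass as _pyteomics_mass

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
#: residues with undefined chemistry (ambiguity codes and rare letters);
#: digestion passes them through as non-cleaving, mass computation refuses them
AMBIGUOUS_AA = set("BJOUXZ")
VALID_AA = STANDARD_AA | AMBIGUOUS_AA

WATER_AVERAGE_DA = 18.015


class InvalidSequenceError(ValueError):
    """Sequence contains characters outside the accepted amino-acid alphabet."""


class UndefinedMassError(ValueError):
    """Mass is requested for a sequence containing ambiguous residues."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein as the unit of digestion and quantification."""

    accession: str
    sequence: str
    description: str = ""
    gene: str | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise InvalidSequenceError(f"{self.accession}: empty sequence")
        bad = sorted({c for c in seq if c not in VALID_AA})
        if bad:
            raise InvalidSequenceError(
                f"{self.accession}: invalid residues {bad!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideEntry:
    """A fully tryptic peptide with 1-based inclusive coordinates."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int

    def __post_init__(self) -> None:
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("peptide coordinates inconsistent with sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DigestRule:
    """Protease specificity and peptide filters.

    Defaults encode trypsin [KR/P] with no length filter.
    """

    cleave_after: frozenset[str] = frozenset("KR")
    block_next: frozenset[str] = frozenset("P")
    max_missed: int = 0
    min_len: int = 1
    max_len: int = 10**9

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")
        object.__setattr__(self, "cleave_after", frozenset(self.cleave_after))
        object.__setattr__(self, "block_next", frozenset(self.block_next))


#: preset used for the theoretically observable peptide count behind iBAQ
OBSERVABLE_RULE = DigestRule(max_missed=0, min_len=6, max_len=30)
#: preset for targeted-validation candidate peptides
PRM_RULE = DigestRule(max_missed=2, min_len=8, max_len=25)


def cleavage_sites(sequence: str, rule: DigestRule = DigestRule()) -> list[int]:
    """0-based indices i such that the bond after ``sequence[i]`` is cut.

    The protein C-terminus is never listed (it is a boundary regardless).
    """
    n = len(sequence)
    sites = []
    for i in range(n - 1):
        if sequence[i] in rule.cleave_after and sequence[i + 1] not in rule.block_next:
            sites.append(i)
    return sites


def tryptic_digest(
    record: ProteinRecord | str,
    rule: DigestRule = DigestRule(),
    remove_initiator_met: bool = False,
) -> list[PeptideEntry]:
    """Enumerate fully tryptic peptides of ``record`` under ``rule``.

    Protein N- and C-termini count as valid peptide termini. With
    ``remove_initiator_met`` a leading methionine is stripped first and
    positions refer to the stripped sequence.
    Output is sorted by (start, end).
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else str(record)
    if not isinstance(record, ProteinRecord):
        # validate free-standing sequences through the record contract
        ProteinRecord(accession="_", sequence=seq)
        seq = seq.upper()
    if remove_initiator_met and seq.startswith("M") and len(seq) > 1:
        seq = seq[1:]
    # boundaries are cut positions expressed as "number of residues before the cut"
    bounds = [0] + [i + 1 for i in cleavage_sites(seq, rule)] + [len(seq)]
    bounds = sorted(set(bounds))
    peptides: list[PeptideEntry] = []
    for j in range(len(bounds) - 1):
        for k in range(j + 1, len(bounds)):
            missed = k - j - 1
            if missed > rule.max_missed:
                break
            start, end = bounds[j], bounds[k]
            length = end - start
            if rule.min_len <= length <= rule.max_len:
                peptides.append(
                    PeptideEntry(
                        sequence=seq[start:end],
                        start=start + 1,
                        end=end,
                        missed_cleavages=missed,
                    )
                )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def count_observable_peptides(
    record: ProteinRecord | str, rule: DigestRule = OBSERVABLE_RULE
) -> int:
    """Number of theoretically observable tryptic peptides (length 6–30,
    fully tryptic, no missed cleavages) — the iBAQ denominator."""
    return len(tryptic_digest(record, rule))


def select_prm_peptides(record: ProteinRecord | str) -> list[PeptideEntry]:
    """Candidate peptides for targeted (PRM) validation: tryptic [KR/P],
    length 8–25, at most 2 missed cleavages."""
    return tryptic_digest(record, PRM_RULE)


def protein_mass(
    record: ProteinRecord | str,
    average: bool = True,
    remove_initiator_met: bool = False,
) -> float:
    """Molecular mass in Da of the intact protein.

    Average mass by default (the convention for molecular-weight weighting
    of abundances); monoisotopic with ``average=False``. Raises
    :class:`UndefinedMassError` on ambiguous residues, listing positions.
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else str(record).upper()
    if not seq:
        raise InvalidSequenceError("empty sequence has no mass")
    if remove_initiator_met and seq.startswith("M") and len(seq) > 1:
        seq = seq[1:]
    offenders = [(i + 1, c) for i, c in enumerate(seq) if c in AMBIGUOUS_AA]
    if offenders:
        raise UndefinedMassError(
            f"mass undefined for ambiguous residues at positions {offenders}"
        )
    bad = sorted({c for c in seq if c not in STANDARD_AA})
    if bad:
        raise InvalidSequenceError(f"invalid residues {bad!r}")
    return _pyteomics_mass.calculate_mass(sequence=seq, average=average)


# ---------------------------------------------------------------------------
# FASTA I/O

_UNIPROT_HEADER = re.compile(r"^(?:sp|tr)\|(?P<acc>[^|]+)\|(?P<name>\S+)")
_GENE_TOKEN = re.compile(r"\bGN=(\S+)")


def _parse_header(seq_record: SeqRecord) -> tuple[str, str, str | None]:
    """Extract (accession, description, gene) tolerating UniProt headers."""
    header = seq_record.description
    m = _UNIPROT_HEADER.match(seq_record.id)
    accession = m.group("acc") if m else seq_record.id
    g = _GENE_TOKEN.search(header)
    gene = g.group(1) if g else None
    return accession, header, gene


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from FASTA, extracting the accession from
    UniProt-style ``sp|ACC|NAME`` ids and the gene from a ``GN=`` token."""
    records = []
    for sr in SeqIO.parse(str(path), "fasta"):
        accession, description, gene = _parse_header(sr)
        records.append(
            ProteinRecord(
                accession=accession,
                sequence=str(sr.seq),
                description=description,
                gene=gene,
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as standard 60-column-wrapped FASTA."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.description)
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def digest_to_rows(
    records: Iterable[ProteinRecord], rule: DigestRule = DigestRule()
) -> Iterator[dict]:
    """Long-format digest rows for TSV export."""
    for rec in records:
        for p in tryptic_digest(rec, rule):
            yield {
                "accession": rec.accession,
                "peptide": p.sequence,
                "start": p.start,
                "end": p.end,
                "missed_cleavages": p.missed_cleavages,
            }
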