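"""Bundled reference data.

Two small text assets ship with the package:

* ``ah_top10_abundance.tsv`` — the published ten most abundant aqueous
  humor proteins with their reported iBAQ intensities and abundance
  percentages; used as a worked example and as the input of the
  internal-consistency checks of the abundance arithmetic.
* ``standin_sequences.fasta`` — synthetic stand-in sequences for the three
  reference proteins whose molecular weights those checks need (PTPRZ1,
  ALB, TF). Each stand-in is a random 20-letter sequence constructed to
  match the published average molecular weight of the corresponding
  UniProt entry (the only property the checks use); they are *not* the
  biological sequences.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .digestion import ProteinRecord, read_fasta

#: maps stand-in ids to the UniProt accession they substitute for
STANDIN_FOR = {
    "STANDIN-PTPRZ1": "P23471",
    "STANDIN-ALB": "P02768",
    "STANDIN-TF": "P02787",
}


def _data_path(name: str):
    return resources.files("ahquant") / "data" / name


def load_top10_abundance() -> pd.DataFrame:
    """Published top-10 abundance table (accession, description, gene,
    ibaq, percentage)."""
    with resources.as_file(_data_path("ah_top10_abundance.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    df["ibaq"] = df["ibaq"].astype(float)
    return df


def load_standin_records(keyed_by_target: bool = True) -> dict[str, ProteinRecord]:
    """Synthetic mass-matched stand-in sequences, keyed by the UniProt
    accession they stand in for (or by their own ids)."""
    with resources.as_file(_data_path("standin_sequences.fasta")) as p:
        records = read_fasta(p)
    if keyed_by_target:
        return {STANDIN_FOR[r.accession]: r for r in records}
    return {r.accession: r for r in records}
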