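"""In silico tryptic digestion and observable-peptide counting.

Digests a short demo protein with the [KR/P] rule, counts the peptides
usable for iBAQ (fully tryptic, length 6-30, no missed cleavages), and
lists candidate peptides for targeted (PRM) validation (length 8-25, up to
2 missed cleavages).
"""

from ahquant import (
    DigestRule,
    ProteinRecord,
    count_observable_peptides,
    protein_mass,
    select_prm_peptides,
    tryptic_digest,
)

record = ProteinRecord(
    accession="DEMO1",
    sequence="MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVK",
    description="demo protein",
)

print(f"{record.accession}: {len(record)} residues, "
      f"average mass {protein_mass(record):,.1f} Da")

peptides = tryptic_digest(record, DigestRule(min_len=1, max_len=10**9))
print(f"\nfull tryptic digest ({len(peptides)} peptides, 0 missed cleavages):")
for p in peptides:
    print(f"  {p.start:>3}-{p.end:<3} {p.sequence}")

n_obs = count_observable_peptides(record)
print(f"\nobservable peptides (length 6-30) for the iBAQ denominator: {n_obs}")

prm = select_prm_peptides(record)
print(f"\nPRM candidates (8-25 residues, <=2 missed cleavages): {len(prm)}")
for p in prm[:5]:
    print(f"  {p.sequence}  (missed={p.missed_cleavages})")
print("...\nEach candidate is a targeted-MS assay surrogate for this protein.")
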