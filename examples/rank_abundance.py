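"""iBAQ abundance ranking on the bundled published top-10 table.

Recomputes molecular-weight-weighted abundance shares from the published
iBAQ intensities of the three proteins whose (mass-matched stand-in)
sequences ship with the package, demonstrating why PTPRZ1 outranks serum
albumin despite a ~3.4x lower iBAQ: its molecular weight is ~3.7x higher.
"""

from ahquant.datasets import load_standin_records, load_top10_abundance
from ahquant.digestion import protein_mass
from ahquant.ibaq import estimated_abundance_table

table = load_top10_abundance().set_index("accession")
masses = {acc: protein_mass(rec) for acc, rec in load_standin_records().items()}

ibaq = {acc: float(table.loc[acc, "ibaq"]) for acc in masses}
shares = estimated_abundance_table(ibaq, masses)

print("published iBAQ -> mass-weighted abundance share (3-protein subsystem):")
for row in shares.itertuples():
    gene = table.loc[row.accession, "gene"]
    print(
        f"  rank {row.rank}: {gene:8s} iBAQ {row.ibaq:.3g}  "
        f"MW {masses[row.accession]/1000:6.1f} kDa  share {row.percentage:5.2f}%"
    )

r = shares.set_index("accession").percentage
print(
    f"\nPTPRZ1/ALB share ratio: {r['P23471']/r['P02768']:.4f} "
    f"(published percentages give {29.60/27.34:.4f})"
)
print("The mass weighting reproduces the published ordering and ratios.")
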