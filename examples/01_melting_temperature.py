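"""Predict the melting temperature of a PBS against its target strand.

The PBS of a pegRNA anneals the nicked non-target DNA strand as an RNA:DNA
hybrid; its Tm relative to the editing temperature is the design criterion.
"""

from pegtherm import NucleicSeq, ThermoParams, DuplexTable, tm_nearest_neighbor, tm_wallace

pbs = NucleicSeq("AUCUACGG", "RNA", name="PBS8")

res = tm_nearest_neighbor(pbs, ThermoParams(table=DuplexTable.RNA_DNA_HYBRID))
print(f"PBS {pbs.bases} ({len(pbs)} nt)")
print(f"  nearest-neighbor Tm = {res.tm_celsius:.1f} C "
      f"(dH {res.dH:.1f} kcal/mol, dS {res.dS:.1f} cal/mol/K, dG37 {res.dG37:.2f} kcal/mol)")
# A Tm near 37 C means the PBS:target duplex forms readily at mammalian
# culture temperature without over-stabilizing the auto-inhibitory fold-back.

wal = tm_wallace(pbs)
print(f"  Wallace rule        = {wal.tm_celsius:.1f} C "
      f"(base-composition only; coarser than the nearest-neighbor model)")

rna_rna = tm_nearest_neighbor(pbs, ThermoParams(table=DuplexTable.RNA_RNA))
print(f"  same pairing as RNA:RNA duplex: Tm = {rna_rna.tm_celsius:.1f} C")
print("  The RNA:RNA duplex is typically the more stable one - the physical basis")
print("  of the spacer:PBS auto-inhibition inside the pegRNA.")
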