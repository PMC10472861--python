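"""Negative-mode exact-mass annotation of the reference iridoids.

For each molecular formula the calculated deprotonated ion [M - H]- is the
neutral monoisotopic mass minus one hydrogen atom; the ppm error measures
how far the detected ion sits from that calculation.  The fragment cascade
of the lead compound (loss of the glucose residue, then 114 Da ring
cleavage) and the 3:1 chlorine isotope cluster test are shown too.
"""

from inhibikit import msannot, ufscreen

table = ufscreen.load_reference_table()
print(f"{'formula':<12} {'detected':>9} {'calculated':>10} {'ppm':>6}")
for row in table.itertuples():
    ion = msannot.annotate_ion(row.detected_mz, row.formula)
    print(f"{row.formula:<12} {ion.detected_mz:>9.4f} {ion.calculated_mz_4dp:>10.4f} {ion.ppm_1dp:>6.1f}")

print("\nFragment cascade of the lead glycoside (parent m/z 497.1292):")
for parent, frag in ((497.1292, 335.0784), (335.0784, 221.0456)):
    ann = msannot.annotate_neutral_losses(parent, [frag])[0]
    label = ann.label or "unassigned"
    print(f"  {parent:.4f} -> {frag:.4f}: loss {ann.nominal_loss} Da ({label})")

print("\nChlorine check (M vs M+2 intensity 300:100):",
      "3:1 cluster" if msannot.chlorine_cluster_flag(300, 100) else "no Cl signature")
print("A |ppm| below ~10 supports the formula assignment; the -162 loss marks a glucoside.")
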