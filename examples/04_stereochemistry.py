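"""Stereochemistry assignment: Z/E bonds, pentadienyl labels, prochiral
hydrogens and the antarafacial/S relationship.

Shows the full stereo tool-chain on generator output: the all-Z hexaene,
the plane-angle criterion that decides whether the radical planarizes to
ZE (maresin-competent) or ZZ, and the pro-R/pro-S labeling of the C12
methylene hydrogens.
"""

from loxtraj import stereo
from loxtraj import synthetic as syn

frag = syn.build_polyene_fragment(plane_angles={"C12": 75.0, "C9": 115.0})
fr = frag.frame()
print("double-bond configurations of the built chain:")
for b in syn.DHA_DOUBLE_BONDS:
    bond = (frag.index_of(f"C{b}"), frag.index_of(f"C{b+1}"))
    subs = (frag.index_of(f"C{b-1}"), frag.index_of(f"C{b+2}"))
    label, tor = stereo.bond_config(fr, bond, subs)
    print(f"  delta-{b:2d}: {label} (torsion {tor:6.1f} deg)")

print("\npro-R/pro-S at the C12 bis-allylic methylene (priority C13 > C11):")
h1, h2 = frag.info["hydrogens"]["C12"]
labels = stereo.prochiral_labels(
    fr, frag.index_of("C12"), (frag.index_of("C13"), frag.index_of("C11")), (h1, h2)
)
for h, lab in labels.items():
    print(f"  {frag.topology.atom_names[h]}: {lab}")

print("\npentadienyl label after abstraction, as a function of the")
print("C10C11C12/C12C13C14 plane angle of the parent frame:")
for theta in (40.0, 75.0, 110.0, 150.0):
    rad = syn.abstraction_fragment(theta)
    rfr = rad.frame()
    span = [rad.index_of(f"C{i}") for i in range(10, 15)]
    flanks = (rad.index_of("C9"), rad.index_of("C15"))
    res = stereo.pentadienyl_label(rfr, span, flanks)
    print(f"  plane angle {theta:5.1f} deg -> {res.label}"
          f"  (planarity {res.planarity:.1e} A)")
print("Angles below 90 deg give ZE - the 10Z,12E pattern required for the")
print("14S-hydroperoxide that feeds maresin biosynthesis; above 90, ZZ.")
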