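"""Pore descriptors of a toy framework vs their closed forms.

A cubic cell with one corner atom has analytic pore metrics: the largest
cavity diameter is the body-center inscribed sphere, sqrt(3)a - 2r, and
the pore-limiting diameter is the face-center bottleneck, sqrt(2)a - 2r.
"""

from mofscreen import (
    compute_pore_descriptors,
    corner_lattice_lcd,
    corner_lattice_pld,
    make_cubic_framework,
)
from mofscreen.elements import vdw_radius

a = 12.0
structure = make_cubic_framework(a, "C")
r = vdw_radius("C")

d = compute_pore_descriptors(structure, spacing=0.2, probe_radius=1.0, seed=0)
print(f"corner-atom cubic cell, a = {a} A, vdW radius r = {r} A")
print(f"  LCD computed {d.lcd:6.2f} A   closed form {corner_lattice_lcd(a, r):6.2f} A")
print(f"  PLD computed {d.pld:6.2f} A   closed form {corner_lattice_pld(a, r):6.2f} A")
print(f"  accessible volume {d.accessible_volume:8.2f} cm^3/g at probe 1.0 A")
print(f"  void fraction {d.void_fraction:.3f}, porous: {d.porous}")
print()
print("LCD is the largest sphere that fits anywhere in the void;")
print("PLD is the largest sphere that can percolate through it —")
print("the 'pore opening' that decides whether a drug can enter.")
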