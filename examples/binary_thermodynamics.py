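"""Activities and vapor pressures of water-ethanol beverages.

Builds the composition of four typical beverages (beer, wine, vodka and
rum strengths), evaluates their water and ethanol activities at 35 degC
and the theoretical headspace pressure (no air) at 50 degC.
"""

from bottlesim import thermo

print("abv    x_e     a_w     a_e")
for abv in (0.08, 0.15, 0.40, 0.70):
    comp = thermo.composition_from_abv(abv)
    a_w, a_e, _, _ = thermo.activities(35.0, abv)
    print(f"{abv:4.2f}  {comp.x_e:5.3f}  {a_w:6.3f}  {a_e:6.3f}")

_, _, p_total = thermo.partial_pressures(50.0, 0.70)
print(f"\ntotal vapor pressure of a liquor (abv 0.70) at 50 degC: "
      f"{p_total / 1e3:.1f} kPa")
print("a_w sets the water driving force against the storage RH; a_e drives")
print("ethanol loss (the outside air holds no ethanol).")
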