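"""Weight-minimizing design: wall thickness and shape trade-offs.

For a 160 mL parametric bottle (150 mL capacity, vodka-type beverage at
25 degC), finds the minimal body wall thickness granting 180 days of
shelf-life for a few (W, D) shapes, and extracts the Pareto front of a
small design sweep (a 3x3 grid here; enlarge for real studies).
"""

from bottlesim import DesignSpec, design_sweep, pareto_front, solve_wall_thickness

spec = DesignSpec()  # 160 mL / 150 mL, abv 0.4, 180 d at 25 degC, 50 % RH

print("single designs (W x D -> optimized wall):")
for w_mm, d_mm in ((40, 40), (60, 60), (100, 50)):
    p = solve_wall_thickness(spec, w_mm * 1e-3, d_mm * 1e-3, confirm=False)
    print(f"  {w_mm:3d} x {d_mm:3d} mm: H = {p.height * 1e3:5.1f} mm, "
          f"l_wall = {p.l_wall * 1e6:6.0f} um, mass = {p.mass * 1e3:5.1f} g, "
          f"binding: {p.meta['binding']}")

points = design_sweep((40e-3, 100e-3), (40e-3, 100e-3), 3, 3, spec)
front = pareto_front(points)
feasible = [p for p in points if p.feasible]
masses = sorted(p.mass * 1e3 for p in feasible)
print(f"\n3x3 sweep: {len(feasible)} feasible designs, "
      f"masses {masses[0]:.1f}-{masses[-1]:.1f} g "
      f"(ratio {masses[-1] / masses[0]:.2f})")
print(f"Pareto front ({len(front)} designs, mass down / shelf-life up):")
for p in front:
    print(f"  W={p.width * 1e3:5.1f} D={p.depth * 1e3:5.1f} mm  "
          f"mass={p.mass * 1e3:5.1f} g  shelf-life={p.shelf_life_days:6.1f} d")
print("\nNear-square sections minimize surface-to-volume and hence weight;")
print("flat shapes need thick walls and are the heavy family.")
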