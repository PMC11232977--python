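"""Boundary sensitivity grid and Monte-Carlo error propagation.

Evaluates the geometry + density chain at the seven canonical boundary
sizes (near-boundary mean, +-1 and +-2 sd, minimum resolvable and
unresolvable sizes), then propagates the near-boundary normal
N(34.4, 10.5 px) through the chain with 1000 positive draws.
"""

import preyfield as pf

MEAN_COUNT = 3563 / 124  # countable objects per image from the annotated set

grid = pf.boundary_grid(34.4, 10.5, min_res_px=14.9, min_unres_px=9.9,
                        mean_count_per_image=MEAN_COUNT)
cols = ["label", "boundary_px", "range_mm", "volume_m3", "mean_density_krill_per_m3"]
print(grid.rows[cols].round(2).to_string(index=False))
print()
print("Volume scales as the inverse cube of the boundary size: moving the")
print("boundary by 2 sd changes the imaged volume by two orders of magnitude.")
print()

prop = pf.propagate(34.4, 10.5, n=1000, seed=0, mean_count_per_image=MEAN_COUNT)
for q, unit, scale in (("range_mm", "m", 1e-3), ("volume_m3", "m^3", 1.0),
                       ("density_krill_per_m3", "krill/m^3", 1.0)):
    s = prop.summaries[q]
    print(f"{q:22s} median {s['median']*scale:6.2f} {unit}, "
          f"IQR [{s['q25']*scale:.2f}, {s['q75']*scale:.2f}]")
print()
print("Medians sit near the deterministic chain values; the long right tails")
print("(means above medians) reflect the inverse-cube nonlinearity.")
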