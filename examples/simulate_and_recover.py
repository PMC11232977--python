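"""Forward-simulate a swarm imaging survey and run the estimator on it.

Generates annotation sets with known true density and resolvable range,
then shows what the estimation pipeline recovers.  With the frustum
fully annotated far beyond the true resolvable range, the fitted
logistic boundary sits above the median-orientation calibration point
and density is overestimated — a characterised limitation discussed in
docs/methods.md.
"""

import numpy as np

import preyfield as pf

TRUE_DENSITY = 48.0
TRUE_RANGE_MM = 1949.0

ratios = []
for seed in range(5):
    cfg = pf.SimulationConfig(
        true_density_per_m3=TRUE_DENSITY,
        n_images=60,
        true_r_res_mm=TRUE_RANGE_MM,
        max_range_factor=3.0,
        seed=seed,
    )
    aset, truth = pf.generate_dataset(cfg)
    bundle = pf.estimate_density(aset)
    ratios.append(bundle.density.mean / TRUE_DENSITY)
    if seed == 0:
        print(f"true density {TRUE_DENSITY} krill/m^3, true range {TRUE_RANGE_MM/1000:.2f} m")
        print(f"seed {seed}: fitted boundary {bundle.boundary.L_boundary_px:.1f} px, "
              f"estimated range {bundle.volume.resolvable_range_mm/1000:.2f} m, "
              f"estimated density {bundle.density.mean:.1f} krill/m^3")

print(f"density estimate / truth over 5 seeds: "
      f"{np.mean(ratios):.2f} +- {np.std(ratios):.2f}")
print()
print("A median-length animal at 45 degrees at the true range images at "
      f"{42 * pf.MEDIAN_PROJECTION * pf.CameraModel().focal_px / TRUE_RANGE_MM:.1f} px;")
print("the fitted boundary lands higher because distant small objects dominate")
print("the fully annotated far field, so range is under- and density over-estimated.")
print("Real annotation sets are sparser in the far field, which moves the")
print("boundary toward the calibration point.")
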