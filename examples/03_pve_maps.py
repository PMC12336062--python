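"""Fit the three coupling GLMs and recover known variance fractions.

Builds one synthetic subject whose voxels carry designed variance fractions,
fits the joint / cardiac-only / respiratory-only models, and compares the
estimated percent variance explained (PVE) against the ground truth.
"""

import numpy as np

import boldphysio as bp

scenario = bp.SimScenario(seed=5, n_vols=404, tr_s=1.4, grid_shape=(5, 5, 4))
tcs = bp.simulate_timecourses(scenario, "young01")
levels = np.repeat([0.0, 0.1, 0.3, 0.5], 25).reshape(scenario.grid_shape)
bold, truth = bp.simulate_bold(scenario, tcs, "young01", true_pve=levels)

maps = bp.run_three_models(bold, tcs)

print("model        mean PVE (all voxels)")
for tag, pmap in maps.items():
    print(f"{tag:<12} {np.nanmean(pmap.values):.3f}")

print("\ntrue fraction   mean estimated PVE (joint)")
for lvl in (0.0, 0.1, 0.3, 0.5):
    est = maps["joint"].values[levels == lvl]
    print(f"{lvl:>12.1f}   {est.mean():.3f}")

err = np.abs(maps["joint"].values - levels).mean()
print(f"\nmean absolute recovery error: {err:.3f}")
print(
    "\nPVE is the share of drift-removed voxel variance captured by the\n"
    "physiological regressors; the joint model always explains at least as\n"
    "much as either single-signal model, and estimates track the designed\n"
    "fractions to within a few percent at this scan length."
)
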