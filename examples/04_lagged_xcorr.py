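"""Model-free lag mapping: where and when physiology leads the BOLD signal.

Builds voxels coupled to heart rate at known latencies, cross-correlates
without any response-function assumption, and reads the peak lag off the
correlation curve — then shows tissue-level curves with 0.2 s upsampling.
"""

import numpy as np

import boldphysio as bp
from boldphysio.xcorr import LagGrid

scenario = bp.SimScenario(seed=8, n_vols=404, tr_s=1.4)
tcs = bp.simulate_timecourses(scenario, "young01")
hr = tcs["hr_bpm"]

grid = LagGrid.from_trs(1.4, -2, 15)  # -2.8 .. 21.0 s in TR steps
true_lags = [0.0, 2.8, 5.6]
vox = bp.simulate_lagged_voxels(hr, true_lags, seed=8)

print("true lag (s)   estimated peak-|r| lag (s)   peak r")
for i, L in enumerate(true_lags):
    r = bp.xcorr_at_lags(hr.values, vox[i], 1.4, grid)
    k = int(np.nanargmax(np.abs(r)))
    print(f"{L:>10.1f}     {grid.lags_s[k]:>10.1f}              {r[k]:.2f}")

bold, _ = bp.simulate_bold(scenario, tcs, "young01")
tx = bp.tissue_xcorr(bold, hr, grid, upsample_dt_s=0.2)
print("\ntissue        peak lag (s, 0.2 s grid)   peak r")
for tissue in ("gray", "white", "ventricles"):
    curve = tx.r[tissue]
    print(f"{tissue:<12}  {tx.peak_lag(tissue):>8.1f}               "
          f"{np.nanmax(curve):.2f}")
print(
    "\nPositive lag means the physiological signal leads the BOLD response.\n"
    "Voxel peaks land on the grid lag nearest the injected latency; the\n"
    "convolved cohort BOLD peaks a few seconds later because the cardiac\n"
    "impulse response itself delays the signal."
)
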