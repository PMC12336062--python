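# boldphysio

Cardiac and respiratory fluctuations leave a large, spatially structured
imprint on resting-state BOLD fMRI. Slow changes in heart rate, breathing
depth, and arterial CO₂ drive vascular responses that can masquerade as — or
obscure — neural signal, and their strength and timing change with age.
`boldphysio` quantifies this physiological component of the BOLD signal, for
researchers studying physiological noise, cerebrovascular coupling, or
autonomic interventions:

1. **Physiological preprocessing** — PPG beat detection (0.5–2 Hz band-pass,
   IQR-scaled peak threshold), artifact-interpolated inter-beat intervals,
   TR-locked heart rate (median IBI in 6 s windows), respiratory variation
   (windowed SD of the belt trace, normalized to ±1), end-tidal CO₂ from
   aligned capnograph peaks, breathing rate, and HRV summaries (RMSSD, LF
   0.04–0.15 Hz and HF 0.15–0.4 Hz band power, reported on the natural-log
   scale).
2. **Coupling GLMs** — heart rate convolved with the canonical cardiac
   response function CRF(t) = 0.6 t²·⁷e^(−t/1.6) − (16/√(18π))e^(−(t−12)²/18),
   respiration with the respiratory response function
   RRF(t) = 0.6 t²·¹e^(−t/1.6) − 0.0023 t³·⁵⁴e^(−t/4.25) (each with temporal
   and dispersive derivative bases), or PETCO₂ with a configurable
   double-gamma response. Three voxelwise models (joint, cardiac-only,
   respiratory-only) yield **percent-variance-explained (PVE)** maps:
   the share of drift-removed voxel variance captured by the physiological
   regressors.
3. **Lagged cross-correlation** — model-free Pearson correlation of each
   voxel (or tissue-averaged) BOLD series with raw HR/RV/PETCO₂ across a lag
   grid (positive lag = physiology leads), optionally upsampled to 0.2 s at
   the tissue level.
4. **Group inference** — pooled two-sample t maps, threshold-free cluster
   enhancement (TFCE, E=0.5, H=2), and label-shuffling permutation tests with
   familywise-corrected p-values; Bonferroni-corrected lag-wise tissue tests;
   Welch/paired t tables for cohort physiological summaries.
5. **Synthetic cohorts** — a generator producing PPG/respiration/capnograph
   waveforms and coupled 4D BOLD (NIfTI + BIDS-style physio TSV) with exact,
   known ground truth, so every stage above is validated by parameter
   recovery.

## Worked example

```python
import numpy as np
import boldphysio as bp

scenario = bp.SimScenario(seed=5, n_vols=404, tr_s=1.4, grid_shape=(5, 5, 4))
tcs = bp.simulate_timecourses(scenario, "young01")
levels = np.repeat([0.0, 0.1, 0.3, 0.5], 25).reshape(scenario.grid_shape)
bold, truth = bp.simulate_bold(scenario, tcs, "young01", true_pve=levels)
maps = bp.run_three_models(bold, tcs)
for lvl in (0.0, 0.1, 0.3, 0.5):
    print(lvl, round(maps["joint"].values[levels == lvl].mean(), 3))
```

prints

```
0.0 0.022
0.1 0.118
0.3 0.303
0.5 0.513
```

— voxels built to carry 0/10/30/50% of their (drift-free) variance in
physiological coupling are recovered to within a few percent at a 404-volume
scan; the small offset at 0 is the expected null-R² inflation of a 6-regressor
fit. The scripts in `examples/` walk through each capability the same way
(cohort generation, physio metrics, PVE maps, lag maps, TFCE group tests).

A thin CLI mirrors the pipeline stages for shell use:

```bash
boldphysio simulate --outdir cohort --subjects-per-group 2 --n-vols 64
boldphysio physio --manifest cohort/manifest.csv --outdir run
boldphysio pve --manifest cohort/manifest.csv --outdir run
boldphysio xcorr --manifest cohort/manifest.csv --outdir run
boldphysio group --manifest cohort/manifest.csv --outdir run
boldphysio report --outdir run
```

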