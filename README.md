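# mebold — multi-echo EPI BOLD toolkit

BOLD fMRI of regions near air–tissue interfaces (orbitofrontal cortex,
entorhinal and piriform cortex — the olfactory system) is plagued by two
problems: susceptibility-induced signal dropout, which shortens T2\* so much
that a conventional single-echo acquisition at TE ≈ 22 ms is far from any
voxel's optimal echo time, and respiratory artifacts that are time-locked to
sniff cues and therefore masquerade as task activation.  Multi-echo EPI
(ME-EPI) acquires several echoes per excitation and lets each voxel be
reconstructed at an effective echo time matched to its own T2\*.

`mebold` implements that pipeline end to end, for methods researchers who
want to study it quantitatively on data with known ground truth:

* **Decay models** — the monoexponential gradient-echo signal
  `S(TE) = S0·e^(−TE/T2*)` and its magnitude-image extension with a thermal
  noise floor, `S(TE) = sqrt((S0·e^(−TE/T2*))² + x0²)`.  The floor `x0` is
  the rectified-noise offset of magnitude images; ignoring it biases naive
  fits toward long T2\* exactly where dropout is worst.
* **T2\*/S0/x0 mapping** — log-linear initialisation, bounded
  trust-region nonlinear least squares, and a noise-floor-aware fit that
  minimises signal-weighted residuals `r_i = (S_i/Σ_j S_j)(Ŝ_i − S_i)` over
  every (echo, volume) observation in the scan.
* **T2\*-weighted echo combination** ("optimal combination", ME-WC) with
  per-voxel weights `W_TE = TE·e^(−TE/T2*) / Σ_n TE_n·e^(−TE_n/T2*)`,
  which peak at the echo time of maximal BOLD contrast-to-noise, TE = T2\*.
* **A synthetic multi-echo task-fMRI phantom** with short-T2\* "olfactory"
  regions, HRF-convolved task-evoked ΔR2\*, sniff-locked TE-independent
  S0 breathing artifacts, and two-channel Gaussian noise whose magnitude
  realises the Rician floor — all reproducible bit-for-bit from a seed.
* **The statistical battery** — respiration preprocessing, framewise
  displacement, 24-parameter motion expansion with 6-SD spike censoring,
  discrete-cosine high-pass (1/128 Hz), GLM with global AR(1) prewhitening,
  contrast Z maps, voxel-wise Levene variance comparison between pipelines,
  Benjamini–Hochberg FDR, and exact noncentral-t sample-size estimation.

## Worked example

Fitting, combining and analysing the default phantom (24×24×12 voxels,
5 echoes at 10.60/22.92/35.24/47.56/59.88 ms, 200 volumes, TR 2.041 s):

```python
import numpy as np
import mebold as mb

ph = mb.generate_phantom(mb.PhantomSpec(seed=42))
fit = mb.fit_parameter_maps(ph.series, method="noisefloor",
                            use_all_volumes=False, mask=ph.truth.tissue_mask)
print(fit.summary())
```

```
T2* fit results
========================================
method:            noisefloor
voxels in mask:    864
failed voxels:     0
obs per voxel:     5
T2* (ms) median:   34.95
T2* (ms) IQR:      [26.99, 41.32]
x0 median:         5.164
```

The phantom's tissue spans T2\* = 18–45 ms and its true noise floor is
`x0 = 5·sqrt(π/2) ≈ 6.27`; the per-voxel estimates bracket both.  Combining
the echoes and running the task GLM:

```python
combined = mb.combine_series(ph.series, mb.compute_weight_map(fit))
trace = mb.RespiratoryTrace(ph.resp_samples, ph.resp_fs_hz)
breathing = mb.preprocess_respiration(trace, ph.series.tr_s, ph.series.n_volumes)
design = mb.build_design_matrix(ph.series.n_volumes, ph.series.tr_s,
                                events=ph.events,
                                conditions=["lemon", "benzaldehyde", "control"],
                                breathing=breathing)
glm = mb.fit_glm_ar1(combined.data, design, mask=ph.truth.tissue_mask)
con = glm.contrast("odor>control")
for lab, m in ph.truth.roi_masks.items():
    print(f"{lab:9s} mean Z = {np.nanmean(con.z[m]):5.2f}")
```

```
ofc       mean Z =  6.00
piriform  mean Z =  7.66
cortex    mean Z =  8.41
white     mean Z = -0.04
```

The three active regions light up and the inactive white-matter block stays
at Z ≈ 0.  Running the same GLM on the second echo alone (TE = 22.92 ms,
the single-echo surrogate) gives a mean Z of 3.65 in the short-T2\* "ofc"
region — the T2\*-weighted combination nearly doubles the detection
statistic there, which is the point of the method.

## Command line

```bash
mebold simulate --config spec.yaml --out data/ --seed 1
mebold fit --echos data/echo-1_bold.nii.gz ... --out maps/ --fast
mebold combine --echos ... --t2star maps/t2star.nii.gz --out mewc.nii.gz
mebold analyze --bold mewc.nii.gz --events data/events.tsv \
    --physio data/physio.tsv --motion data/motion.tsv \
    --contrast "odor>control" --out stats/
mebold power --d 0.5           # -> n = 34
```

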