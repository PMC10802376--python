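# ms2quant

Quantification of nascent-transcription dynamics from MS2-MCP imaging in
dense 3D tissue, and stochastic modelling of auto-repressive
transcriptional bursting.

## The problem

The MS2-MCP system tags nascent mRNA so that active transcription sites
appear as diffraction-limited fluorescent spots whose intensity tracks
the number of engaged RNA polymerases. In a vertebrate embryo — the
motivating case is the zebrafish segmentation clock gene *her1*, an
auto-repressive oscillator with a ~30 min period — these spots must be
found and quantified inside thousands of moving nuclei, against a
strong, spatially structured MCP background, across hours of light-sheet
imaging. This package provides the image-analysis side of that
measurement and the modelling side of its interpretation:

- **Detection**: per-z-slice Difference-of-Gaussians filtering,
  thresholding, 3D connected components, bright-region masking.
- **Classification**: a small 3D CNN (two conv layers of four 3×3×3
  kernels, dense-512, dropout, sigmoid) that rejects false candidates in
  9×11×11 px voxels; probability threshold 0.7.
- **Quantification**: sub-pixel localization (Gaussian fitting or the
  radial-center method, both on DoG-prefiltered voxels), shell
  background estimation (inner/outer widths 4/6 px), and
  background-subtracted integration over a 4×4×4 px ellipsoid.
- **Traces**: assignment of spots to tracked nuclei (externally produced
  label movies), iterative gap-filling, spatial filters, and per-point
  uncertainties combining background fluctuations with empirical
  detection error rates (fp = 0.04, fn = 0.08):

  σ = √(σ_I²/(1−fp) + I²·fp/(1−fp))  for I > 0,  σ = Ī·fn/(1−fn) for I = 0

- **Dynamics**: protein prediction through the linear model
  dm/dt = r_m x − γ_m m, dp/dt = r_p m − γ_p p (γ ≈ 0.23 min⁻¹), burst
  calling by moving-average thresholding, bursts-per-oscillation and
  period statistics.
- **Tissue scale**: spline anterior–posterior axes, kymographs (100 AP
  bins × time), and tissue-period measurement with bootstrap errors.
- **Burst model**: exact delayed-Gillespie simulation of a two-state
  promoter with auto-repressive feedback on transcription rate
  (amplitude), k_on (frequency), k_off (duration) or both, plus an MS2
  measurement model (polymerase memory kernel w = 0.29, multiplicative
  noise, detection threshold) and interval/regularity statistics.
- **Synthetic data**: Gaussian-PSF spots on exponential-gradient
  backgrounds (decay 10 px) with Poisson noise, spot libraries with
  known ground truth, and full two-channel embryo movies with labeled,
  moving nuclei — the validation substrate for everything above.

## Worked example

Simulate the frequency-regulation bursting model, synthesize an MS2
measurement, and look at its burst interval statistics:

```python
import numpy as np
from ms2quant import burstmodel as bm

traj = bm.simulate_feedback_bursting(bm.PRESETS["frequency"], T=6000, seed=51)
sig = bm.synthesize_ms2_signal(traj.promoter, traj.rate,
                               bm.MS2SynthParams(), seed=52)
active, inactive = bm.extract_intervals(sig, binarize_threshold=1.0, kernel=3)
print(f"{len(active)} bursts; mean ON {active.mean():.1f} min, "
      f"mean OFF {inactive.mean():.1f} min")
print(f"active exponential-like: p = {bm.exponentiality_pvalue(active):.2f}; "
      f"inactive: p = {bm.exponentiality_pvalue(inactive):.1e}")
```

prints

```
192 bursts; mean ON 17.5 min, mean OFF 13.8 min
active exponential-like: p = 0.17; inactive: p = 5.5e-17
```

With only the burst frequency under feedback control the ON durations
stay exponential (set by the constant k_off) while the OFF durations are
peaked — bursts recur quasi-periodically. Amplitude or combined
frequency+duration regulation peaks both distributions; this fingerprint
is what lets interval statistics discriminate regulatory mechanisms.

The same analysis is scriptable from the shell:

```sh
ms2quant simulate --mode frequency --T 3000 --seed 1 --out sim/
ms2quant synth movie --out movie/ --n-nuclei 5 --n-timepoints 40
ms2quant run --mcp movie/mcp.zarr --labels movie/labels.zarr --out run/
```

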