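# sisifus

Single-sample image-fusion upsampling of fluorescence lifetime images.

Fluorescence lifetime imaging microscopy (FLIM) maps the nanosecond decay
time of fluorescence per pixel — an intensity-independent reporter of
metabolism, microenvironment, and molecular interactions.  Time-resolved
detectors pay for that timing with resolution: SPAD arrays have low pixel
counts and fill factors, and scanning TCSPC systems need long dwell times.
A plain camera, meanwhile, captures the same field of view at high
resolution — intensity only — almost for free.

`sisifus` fuses the two measurements of *one* sample: a low-resolution
lifetime image τ_LR ∈ ℝ^{m×n} (or the raw time-resolved datacube it is
fitted from) and a high-resolution intensity image I ∈ ℝ^{M×N}, with
M = λm, N = λn for an integer upsampling factor λ ∈ {2, 4, 8, 16}.  The
forward model is point decimation, τ_LR = A τ_HR, and the fused estimate
minimises

    C(τ̂) = ‖A τ̂ − τ_LR‖₂² + γ‖(τ̂ − τ̂_LP)·m_LP‖₂² + β‖(τ̂ − τ̂_GP)·m_GP‖₂²
         + α‖D τ̂‖₁          subject to τ̂ ≥ 0,

solved by ADMM with monotone-FISTA primal updates (γ = 0.1; β = 0.02 for
λ ≤ 4 and 0.5 for λ ≥ 8; D is the anisotropic total-variation gradient).
The two priors are built from the sample itself — no external training
data, hence no out-of-distribution hallucination:

- **Local prior (LP)** — in each 5×5 window of lifetime samples, a 1-D
  intensity→lifetime function (linear interpolation by default) is fitted
  and evaluated at the window's unsampled intensity pixels.
- **Global prior (GP)** — a small convolutional network (3 conv + 3 fully
  connected layers, pure numpy) is trained from scratch on 13×13
  intensity patches centred on the lifetime samples — augmented 8× by
  rotation/mirroring and up to 72× with neighbour labelling — and then
  predicts the lifetime of every unsampled patch centre.

The package also ships mono-exponential lifetime fitting (Pearson-weighted
least squares, optional IRF deconvolution), four-point perspective
co-registration, PSNR/SSIM evaluation, a bilinear-interpolation baseline,
and a physics-grounded phantom generator (quantum-yield intensity model
with an absorbance confounder, Poisson photon noise) so the whole pipeline
is testable without microscope data.  See `docs/methods.md` for the model
details and design choices.

## Worked example

Reconstruct an 8× upsampling benchmark end to end — a synthetic scene of
vesicles (τ = 2 ns) and membrane ridges (τ = 4 ns), equally bright so only
morphology separates them, on a dim 3 ns background, decimated 8× with
full Poisson noise:

```python
from sisifus import GlobalPriorConfig, PipelineConfig, run_pipeline
from sisifus.phantom import make_fixture

bundle = make_fixture("two_class_8x", seed=1)
cfg = PipelineConfig(factor=8, gp=GlobalPriorConfig.desk_scale(seed=1))
result = run_pipeline(bundle["intensity_hr"], cfg,
                      cube=bundle["cube"], tau_gt=bundle["tau_hr_gt"])

cm = bundle["class_map"]
for k, cls in enumerate(bundle["spec"].classes):
    if cls.morphology != "background":
        sel = (cm == k) & result.gp.valid
        print(f"{cls.morphology}: true {cls.tau_ns} ns, "
              f"fused {result.tau_hr.tau[sel].mean():.3f} ns")
for r in result.metrics:
    print(f"{r.method_label}: SSIM {r.ssim:.3f}, PSNR {r.psnr:.1f} dB")
```

Output (a few minutes on one core):

```
ridge: true 4.0 ns, fused 3.717 ns
blob: true 2.0 ns, fused 2.253 ns
sisifus: SSIM 0.596, PSNR 16.2 dB
bilinear: SSIM 0.392, PSNR 13.4 dB
```

Both class lifetimes are recovered to well within 0.3 ns, and the fusion
clearly beats bilinear interpolation on structural similarity — the
bilinear image blurs every structure narrower than the 8-pixel sampling
pitch, while the fused image recovers them from the intensity guide.

The same stages are available from the shell:

```bash
sisifus simulate --fixture two_class_8x --seed 1 --out-dir fx/
sisifus fit --cube fx/cube.tif --meta fx/cube.json \
            --out-tau tau_lr.tif --out-intensity int_lr.tif
sisifus run --cube fx/cube.tif --meta fx/cube.json \
            --intensity fx/int_hr.tif --gt fx/tau_gt.tif \
            --factor 8 --seed 1 --out-dir out/
```

`sisifus run` writes the fused image, priors, baseline, metrics CSV, and
a manifest with input/output hashes for reproducibility.

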