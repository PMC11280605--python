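# cestrecon

Joint *k*–ω image reconstruction and Z-spectrum fitting for chemical
exchange saturation transfer (CEST) MRI.

CEST MRI images low-concentration metabolites by saturating exchangeable
protons at a set of RF offset frequencies ω and reading out the attenuated
water signal. The per-pixel **Z-spectrum** Z(x, ω) = S<sub>sat</sub>(x, ω)/S₀(x)
shows a broad direct-water-saturation dip at the water line plus small dips
at each solute pool's resonance; the CEST effect is quantified by the MTR
asymmetry MTR<sub>asym</sub>(ω) = [S<sub>sat</sub>(−ω) − S<sub>sat</sub>(ω)]/S₀.
Acquiring many offsets makes scans long, so noise tolerance and robustness
to sparse frequency schedules matter.

The conventional pipeline reconstructs each offset's image independently
(inverse FFT of its k-space) and only then fits the Z-spectrum pixel by
pixel, so each image sees only its own noisy data. This package implements
a joint alternative for users who want to exploit the redundancy across
offsets: all amplitude images f(x, ω) are reconstructed simultaneously by

```
min_{f,A,Z}  ½ Σ_ω ‖F A(x,ω) f(x,ω) − g(ω)‖² + R[f, λ]
subject to   f(x,ω) = f(x,ω₀) · Z(x,ω),
```

where g(ω) is the measured complex k-space, F the (centered, orthonormal)
2-D DFT, A = e<sup>iφ</sup> a smooth phase factor, ω₀ the unsaturated
reference offset, and Z constrained to a multi-pool spectral model — a
Lorentzian line for direct water saturation and Gaussian lines for the CEST
pools (amplitudes a, Γ, bᵢ, σᵢ; pool centers known from the experiment):

```
Z(ω) = 1 − a/((ω−ω₁)² + Γ) − Σᵢ bᵢ exp(−(ω−ωᵢ)²/σᵢ²)
```

The problem is solved by ADMM with splitting variables v (a denoised image
copy, handled plug-and-play by a patch-based denoiser) and T (a spectrum
copy): CGLS solves the quadratic image sub-problems — the reference-image
update couples every offset, which is how information flows across the
spectrum — pixel-wise bounded least squares projects spectra onto the model
family, the T update is closed-form, and the duals ascend. The package also
ships the conventional baseline, a phantom/acquisition simulator (forward
model, smooth phase, complex Gaussian k-space noise scaled to the mean
reference k-space magnitude, offset subsampling) and SNR / MTR-asymmetry /
uncertainty metrics.

## Worked example

```python
import numpy as np
from cestrecon import (preset_spec, build_phantom, grid_from_spec,
                       synthesize_series, phase_series, encode_kspace,
                       add_noise, conventional_reconstruct, joint_reconstruct,
                       averaged_snr, mtr_asymmetry_map, ReconConfig)

spec  = preset_spec("simulated_brain", (64, 64))   # CEST pool at 450 Hz
scene = build_phantom(spec)
grid  = grid_from_spec(spec)                       # −1250..1250 Hz, step 50
truth = synthesize_series(scene, grid)
ks    = add_noise(encode_kspace(truth, phase_series(scene, grid)),
                  level=0.105, seed=7)             # 10.5% k-space noise

conv  = conventional_reconstruct(ks, centers=[450.0])
joint = joint_reconstruct(ks, centers=[450.0], cfg=ReconConfig(max_outer_iters=10))

roi, bg = scene.roi_masks["insert"], scene.roi_masks["background"]
for name, res in [("conventional", conv), ("joint", joint)]:
    snr = averaged_snr(res.images, roi, bg)
    mm  = mtr_asymmetry_map(res.images, 450.0)
    print(f"{name}: averaged SNR {snr:.1f} dB, "
          f"MTRasym insert {np.nanmean(mm[roi]):.4f} ± {np.nanstd(mm[roi]):.4f}")
```

Output:

```
conventional: averaged SNR 35.3 dB, MTRasym insert 0.1187 ± 0.0212
joint: averaged SNR 62.6 dB, MTRasym insert 0.1199 ± 0.0019
```

The joint reconstruction raises the frequency-averaged SNR (mean ROI signal
over background std, in dB, averaged over all offsets) and tightens the MTR
asymmetry estimate around the simulated ground truth of 0.12 — the spectral
constraint suppresses noise that the per-offset FFT baseline passes through.

The same pipeline is available as a CLI:

```sh
cestrecon simulate --spec preset:simulated_brain --shape 64 --noise 0.105 --seed 7 --out sim/
cestrecon reconstruct --in sim/kspace.h5 --method both --out rec/
cestrecon evaluate --recon rec/ --truth sim/ --out eval/
```

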