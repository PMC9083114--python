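# tensorsr

Single-volume 3D super-resolution for medical images (MRI, CT) that
combines a **nonlocal patch-group Tucker prior with folded-concave (MCP)
penalties** and a **weighted 3D total-variation** term, solved by ADMM.

Clinical scanners trade resolution against time and dose, so the acquired
volume is often a blurred, downsampled version of the anatomy of interest.
`tensorsr` estimates the high-resolution volume `X` from a single
low-resolution observation `Y = D S X + ε` (Gaussian blur `S`, decimation
`D`, noise `ε`) by minimizing

```
‖DSX − Y‖²_F + λ_tv‖X‖_3DTV + λ₁ Σ_{k,n} ‖U_k⁽ⁿ⁾‖_{P_λ} + λ₂ Σ_k ‖G_k‖²_F
s.t.  P_X^k = G_k ×₁ U_k⁽¹⁾ ×₂ … ×₄ U_k⁽⁴⁾   for every patch group k
```

where `P_X^k` stacks each key patch with its `d−1` most similar patches
into a 4th-order tensor (nonlocal self-similarity), the Tucker constraint
with MCP-penalized factor spectra `‖·‖_{P_λ}` captures the low multilinear
rank of those stacks without the downward bias of a nuclear norm, and the
weighted 3D TV preserves piecewise smoothness both in-plane and across
slices.  Defaults follow the reference setting λ_tv = 10, λ₁ = 5, λ₂ = 20,
d = 15, 1-voxel blur, factor-2 decimation.

The intended audience is researchers in medical image reconstruction who
want a complete, deterministic, test-covered implementation of this model —
including the multilinear algebra, the exact operator adjoints, all six
closed-form ADMM updates, a structured phantom generator, and PSNR/SSIM
evaluation — with every parameter exposed in one configuration object.

## Worked example

Simulate a 64×64×16 phantom with repeated texture motifs and a
piecewise-constant polyhedral background, degrade it (blur σ=1, factor 2,
noise σ=0.01), then reconstruct:

```bash
$ tensorsr simulate --out-gt gt.nii --out-lr lr.nii --seed 0
wrote GT (64, 64, 16) -> gt.nii; LR (32, 32, 8) -> lr.nii

$ tensorsr baseline --input lr.nii --output nn.nii --factor 2
$ tensorsr evaluate --a nn.nii --b gt.nii
PSNR 20.1695 dB  SSIM 0.7216

$ tensorsr superresolve --input lr.nii --output hr.nii --gt gt.nii --seed 0
reconstructed (64, 64, 16) in 41 iterations (675 groups, ranks (2, 2, 2, 4))
PSNR 22.2232 dB  SSIM 0.7494
```

The reconstruction recovers about 2 dB PSNR over nearest-neighbour
upsampling and improves SSIM; `ranks (2, 2, 2, 4)` is the shared Tucker
rank tuple selected from the 99%-energy spectra of the 675 matched patch
groups.  `--metrics-csv slices.csv` additionally writes per-slice PSNR/SSIM
curves.  The same pipeline is available as a library:

```python
from tensorsr import (PhantomSpec, DegradationSpec, SolverConfig,
                      generate_phantom, degrade, superresolve, psnr)

gt = generate_phantom(PhantomSpec(seed=0))
lr = degrade(gt, DegradationSpec(), noise_sigma=0.01, seed=0)
result = superresolve(lr, SolverConfig())
print(psnr(result.x.clip(0, 1), gt))   # 24.16 dB (NN baseline: 22.11 dB)
```

(The CLI numbers differ from the library numbers because file I/O
normalizes each volume by its own intensity range; the ordering and margins
are the same.)

Solver configuration is a flat YAML file mapping 1:1 onto `SolverConfig`
(`lam_tv`, `lam1`, `lam2`, `patch_size`, `stride`, `n_similar`,
`blur_sigma`, `down_factor`, ADMM penalties `w1..w4`, …); see
`tensorsr.cli.config_from_dict` for the schema and `docs/methods.md` for
what each parameter does and how the defaults were chosen.

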