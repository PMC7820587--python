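# lambold

Laminar gradient-echo BOLD analysis: cortical-depth activation profiles,
multi-echo R2\* relaxometry, functional contrast-to-noise ratio, and the
incremental-ROI (Weisskoff) characterisation of the physiological-noise
regime — with a synthetic multi-echo generator that reproduces the signal
and noise structure the analysis assumes.

## The problem

Layer-resolved fMRI needs sub-millimetre voxels, and at that resolution
single voxels are dominated by thermal noise.  The standard remedy is to
integrate the signal of all voxels sampled at a given cortical depth over a
patch of cortex.  Integration helps only while the noise is incoherent
across voxels: once spatially shared *physiological* fluctuations dominate,
adding voxels no longer reduces the temporal noise.  Whether — and after
how many voxels — a depth-integrated signal enters this physiological-noise
regime determines how well laminar GE-BOLD works at a given field strength
and echo time.  `lambold` implements the complete analysis for multi-echo
FLASH-style acquisitions at 1.5 T, 3 T and 7 T:

* **Depth profiles.** Voxels are averaged per depth bin (15 bins: 2 white
  matter, 11 cortical, 2 CSF), per echo and volume.  From a block paradigm
  the signal change ΔS = S_active − S_rest, its normalised form
  ΔS / ⟨ΔS⟩_(cortex×TE), the resting temporal SD σ, the CNR = ΔS/σ, a Welch
  t statistic, and the grey-matter-to-pial ratio ΔS(mid-cortex)/ΔS(pial)
  are computed per (depth, TE).
* **Relaxometry.** Mono-exponential fits S(TE) = S₀·exp(−TE·R2\*) per depth
  and volume give resting and activation R2\* profiles and
  ΔR2\* = R2\*_rest − R2\*_active, plus the Lorentzian linewidth
  Δf = 1/(π·T2\*).
* **Weisskoff test.** Voxels are accumulated in seeded random order; the
  temporal SD of the running i-voxel mean, normalised by the mean resting
  signal at the reference echo (TE ≈ T2\*_GM),

      σ_n(i, TE) = std_t[ mean_{v≤i} S ] / avg(S_{N, T2*_GM})

  falls as 1/√i under thermal noise and plateaus when shared physiological
  noise dominates.  The package detects the plateau entry point n_phys
  automatically and classifies the dominant physiological component as
  BOLD-like (rate fluctuations, footprint ∝ TE·S(TE)) or non-BOLD-like
  (multiplicative, footprint ∝ S(TE)) from the TE-dependence of the
  plateau.
* **Synthetic data.** A two-compartment (tissue + venous blood) forward
  model with per-field echo grids, depth-dependent T2\* and ΔR2\* ramps and
  the three-component noise model (independent thermal, shared BOLD-like,
  shared multiplicative) generates fully controlled test data, written as
  NIfTI or TSV.

## Worked example

```python
from lambold.io import RunConfig
from lambold.pipeline import run_pipeline

cfg = RunConfig(
    out_dir="out",
    simulate={"field": 7.0, "n_voxels": 400, "n_volumes": 60},
    seed=1,
)
report = run_pipeline(cfg)
print(report.t2s_gm_ms, report.n_phys, report.classification)
```

prints (values from this exact run):

```
27.433724592189105 227 BOLD-like dominated
```

and `out/summary.txt` contains

```
lambold run 1a46cc2e130e (seed 1)
voxels used: 400 (thickness-removed: 0)
t2s_gm_ms: 27.433724592189105
n_phys: 227 at plateau 0.004346102626105484
noise regime: BOLD-like dominated
gm/pial ratio per TE: [0.7517014406870133, 0.6031742133559566, ...]
```

Reading the numbers: the fitted mid-cortex resting T2\* (27.4 ms) sits just
below the generator's tissue value of 27.9 ms because the fitted decay also
contains a small fast-relaxing venous compartment.  The Weisskoff curve at
the reference echo leaves the 1/√i regime after ~227 of 400 voxels, i.e.
the depth-integrated signal is physiological-noise dominated for this noise
mix; the plateau level is flat across echoes rather than tracking S(TE), so
the shared noise is classified BOLD-like.  The GM/pial ratio is below 1 at
every echo — the activation profile ascends toward the pial surface, the
signature of draining-vein weighting in GE-BOLD.

The same stages are available from the shell:

```bash
lambold simulate --field 7 --n-voxels 400 --seed 1 --out data/
lambold weisskoff --echoes data/echo-01.nii.gz ... --depth-labels data/depth_labels.nii.gz \
    --mask data/mask.nii.gz --protocol data/protocol.json --out out/wk.tsv
lambold run --config config.yaml
```

## Layout

```
src/lambold/
  protocol.py     # per-field acquisition presets (echo grids, TR, paradigm)
  simulate.py     # tissue/noise parameters, voxel grids, forward model
  relaxometry.py  # mono-exponential fitting, ΔR2*, linewidth
  profiles.py     # depth integration, ΔS, CNR, t, normalisation, GM/pial
  weisskoff.py    # σ_n(i, TE) curves, plateau detection, noise regime
  io.py           # NIfTI/TSV/JSON/YAML formats, run configuration
  pipeline.py     # staged end-to-end run
  cli.py          # simulate / profile / relax / weisskoff / run
docs/methods.md   # model, assumptions, parameter choices, limitations
```
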