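# Methods

This note documents the models implemented in `lambold`, the default
parameter values and why they were chosen, the numerical conventions, and
what the synthetic-data pathway can and cannot establish about real data.

## Acquisition model

A run is described by an `AcquisitionProtocol`: field strength, a strictly
increasing echo grid (ms), the volume acquisition time volTR (s), the
number of volumes, a per-volume rest/active paradigm and the isotropic
voxel size.  The per-field presets follow published multi-echo FLASH
protocols for laminar imaging:

| field | TE₁ … TE₁₀ (ms)   | volTR (s) | volumes | voxel |
|------:|-------------------|----------:|--------:|------:|
| 1.5 T | 7.3 … 102.6       | 160       | 10      | 0.75 mm |
| 3 T   | 5.9 … 79.0        | 130       | 12      | 0.75 mm |
| 7 T   | 4.8 … 56.1        | 97        | 18      | 0.75 mm |

Ten echoes are evenly spaced between the printed first and last echo
(`linspace`), which honours both endpoints; the implied spacings
(10.59/8.12/5.70 ms) differ from the nominal 10.6/8.1/5.7 ms by at most
0.03 ms, within the print precision of the endpoints.  The stimulus block
equals one volume, so the paradigm alternates rest/active volume by
volume — the task sits at the Nyquist frequency of the volume sampling.

## Depth axis

Fifteen sampling points span the cortical ribbon: bins 1–2 white matter,
bins 3–13 the eleven cortical layers (numbered WM → pial), bins 14–15 CSF.
"Middle of the cortex" is cortical layer 6 (overall bin 8); the "pial
surface" is cortical layer 11 (bin 13).  Depth labels arrive as an integer
volume already in functional space (surface generation and registration
are out of scope); sampling is nearest-neighbour, with label 0 meaning
outside the ribbon.  Voxels whose local cortical thickness exceeds 2.5 mm
(default) are discarded as likely segmentation errors.

## Synthetic forward model

Each voxel carries a two-compartment decay

    S(TE) = S0(d) · [ (1−v(d)) · exp(−TE · R2*_t(d, s)) + v(d) · exp(−TE · R2*_v(s)) ]

with depth bin d and paradigm state s.  Activation *decreases* the tissue
rate: R2\*_t(d, active) = R2\*_t(d, rest) − ΔR2\*(d), with ΔR2\*(d) ≥ 0 —
the sign convention is fixed here once and used by the fitting module in
reverse (ΔR2\* = R2\*_rest − R2\*_active, positive).

Default depth dependence (all overridable; the venous/CSF numbers are
literature-style plausibility constants, not fitted to any dataset, and
are never used as test oracles):

* **Tissue T2\* at rest** — mid-cortex values 68.8 / 55.2 / 27.9 ms at
  1.5 / 3 / 7 T; a linear ±8% ramp across the cortical layers makes T2\*
  lengthen toward the pial surface (R2\* falls from WM to pial); WM bins
  sit at 0.85× the mid-cortex value; CSF at 300 / 250 / 120 ms.
* **ΔR2\*** — ramps linearly from 10% of its pial maximum at the WM
  boundary to the maximum at the pial layer (0.35 / 0.7 / 1.4 s⁻¹ at
  1.5 / 3 / 7 T, an approximately field-proportional activation effect).
  Together with the venous ramp this produces the ascending ΔS(depth)
  profile characteristic of GE-BOLD at every echo.
* **Venous compartment** — volume fraction ramps 0.01 → 0.05 across
  cortex (0.005 in WM, 0.05 in CSF); venous T2\* at rest ≈ 0.35× the
  tissue T2\* (24 / 19 / 10 ms), lengthening by 25% upon activation.
* **S0** — flat 1000 a.u. across depth (no coil-profile or proton-density
  gradient).

## Noise model

Three components, each removed exactly by setting its SD to zero:

* **Thermal**: additive Gaussian, independent per (voxel, echo, volume);
  SD `sigma_thermal` in signal units.  Default 10 a.u. = 1% of S0, which
  keeps single voxels thermal-dominated.
* **BOLD-like physiological**: one shared rate fluctuation δr(t) ~
  N(0, `sigma_delta_r2s`) per volume, applied inside the exponent scaled
  by a per-depth weight (default ∝ venous fraction, normalised to mean 1
  over cortex).  Its signal footprint is ≈ −TE·S·δr, i.e. it follows the
  BOLD TE-weighting.  Default 0.15 s⁻¹.
* **Non-BOLD-like physiological**: one shared multiplicative fluctuation
  g(t) ~ N(0, `sigma_nonbold`) per volume; footprint ∝ S(TE), the
  cardiac/respiratory-style term.  Default 5×10⁻⁴, a factor of a few
  below the BOLD-like footprint even at the shortest echo, so the default
  mix realises the BOLD-like-dominated regime that depth-integrated
  grey-matter signal shows in vivo.

All draws come from one `numpy` generator seeded once; the shared
trajectories are drawn before the per-voxel noise, so enlarging the voxel
population does not perturb them.  Negative magnitudes are clipped at zero
and counted; a clip fraction above 1% warns that the noise settings are
implausible for the chosen S0.  Rician magnitude bias is deliberately not
modelled — at the SNRs of interest (≥ 100 for integrated signal) it is
negligible, and the Gaussian model keeps every estimator's ground truth
exact.

## Relaxometry

`fit_monoexponential` performs nonlinear least squares of S₀·exp(−TE·R2\*)
in the original signal domain (non-negativity bounds on both parameters),
initialised from the log-linear regression of log S on TE.  Non-positive
samples are excluded from the initialisation but kept in the nonlinear
objective; fewer than 3 positive samples is an error.  A solver failure is
flagged and the log-linear estimate is carried instead of dropping the
cell.  The fit is exact (≥ 6 significant digits) on noiseless
single-compartment input and scale-equivariant.  On two-compartment
decays the fitted T2\* lies between the compartment values, which is why
mixed pial voxels over-estimate activation-induced relaxation changes.

`relaxometry_profile` integrates ROI voxels per depth bin, fits every
(depth, volume) decay, averages fitted R2\* within each paradigm state and
forms ΔR2\* per depth; the per-volume fits operate on depth-integrated
signal (not per voxel), matching the integration-first philosophy of the
rest of the analysis.  T2\*_GM is the resting value at the mid-cortex bin.

## Activation metrics

From the depth-integrated array s(depth, TE, volume): state means, ΔS
(active − rest, with a percent variant), the temporal SD over resting
volumes, CNR = ΔS/σ_rest (flagged NaN where σ_rest = 0, never infinite),
and a Welch two-sample t between active and rest per-volume means.  The
Welch t is a deliberate surrogate for a GLM t-map: with one-volume blocks
the GLM design matrix degenerates to a two-sample comparison, and the
surrogate preserves the monotonicities of interest (t grows ≈ √n_volumes
at fixed CNR).  Profile normalisation divides the whole ΔS surface by its
single grand mean over the cortical bins and all echoes — one value per
dataset — making profiles comparable across subjects and fields
(scale-invariant and idempotent by construction).  The GM/pial ratio is
ΔS(bin 8)/ΔS(bin 13) per echo; for between-field comparison the echo axis
is expressed as TE/T2\*_GM.

## Temporal high-pass

`highpass_cutoff` implements f_c = 1/(2.1·volTR); `highpass_filter`
regresses out discrete-cosine drift regressors with frequencies strictly
below f_c, preserving the mean.  Note a structural caveat: with
one-volume stimulus blocks the task frequency 1/(2·volTR) lies *just
above* this cutoff, so for runs of 10–18 volumes the sub-cutoff cosine
basis is nearly complete and filtering would remove almost all temporal
structure, task response included.  The operation therefore warns when the
basis approaches completeness, and the pipeline applies the filter only
when the configuration asks for it (`highpass: true`; default off).  For
long synthetic runs, where the basis is a small fraction of the temporal
degrees of freedom, the filter behaves conventionally: constants and
on-grid components above the cutoff pass unchanged, slow drift is removed.

## Weisskoff analysis

`weisskoff_curve` draws one uniform random permutation of the ROI voxels
per run (seeded; stored in the result), forms the running mean of the
first i voxels per volume, and takes the temporal SD over resting volumes
for every i = 1..N and every echo.  All curves share a single
denominator: the mean resting signal of the full ROI at the reference
echo, the acquired TE nearest the fitted mid-decay T2\* (a reference
further than 25% from that T2\* warns and falls back to the nearest
echo).  σ_n(N) is permutation-invariant; intermediate values vary with
the seed, and multi-seed summaries stabilise the detection point.

**Plateau detection** is automated (the original procedure was visual):
the plateau level is the median of the last `tail_fraction` (default 0.2)
of the curve, and n_phys is the smallest i from which the entire
remaining curve stays within (1+ε) of that level (ε default 0.05).  The
detection point has a closed form for the mixed model
σ(i) = √(σ_p² + σ_t²/i):

    i* = σ_t² / (σ_p² · ((1+ε)² − 1))

used as the oracle in the test suite.  Two refinements guard against
false detections: (i) a curve that only enters the band inside the tail
is reported undetected, and (ii) a detected plateau must stand at least a
factor 2 above the thermal 1/√i extrapolation of the single-voxel noise
evaluated at the middle of the tail.  The second guard exists because a
pure 1/√i curve crosses the (1+ε) band of its own tail median at
≈ 0.82·N — within 2% of the tail boundary — so sampling noise would
otherwise produce spurious detections on thermal-only data at any run
length.  Both ε and `tail_fraction` are exposed on the CLI.

**Noise-regime classification** (`noise_vs_te`): the plateau level of each
echo with a detected plateau is regressed on the mean resting signal
S(TE).  Multiplicative (non-BOLD-like) noise gives plateau ∝ S(TE) — a
significantly positive slope (one-sided p < 0.05) — while BOLD-like rate
noise gives plateau ∝ TE·S(TE), which does not track S(TE); absent a
significantly positive slope the regime is classified BOLD-like.  Fewer
than 3 usable echoes withholds the classification.

**ROI arithmetic**: n voxels of edge a occupy volume n·a³; the equivalent
one-voxel-thick cortical patch has area n·a² and square-side length
√(n·a²).  At 0.75 mm, 40/60/100 mm³ correspond to 53/80/133 mm² and
7.3/8.9/11.5 mm.

## Pipeline and reproducibility

`run_pipeline` executes thickness filter → (optional) high-pass → depth
integration → activation metrics (+ normalisation, GM/pial ratio) →
relaxometry → Weisskoff curves → plateau detection → regime
classification, writing TSV/JSON outputs plus a human-readable summary.
Activation metrics use the activation-mask ROI; noise metrics use all
labelled voxels.  Every table carries a hash of the analytic configuration
(output paths excluded) and the seed; identical configs and seeds produce
byte-identical tables.  Stage failures propagate with the stage name;
outputs already written are retained.

## What the synthetic tests do and do not show

The generator reproduces the *statistical* structure the analysis assumes
— mono-exponential compartments, depth ramps, one global BOLD-like and
one global multiplicative fluctuation, white thermal noise — so passing
tests establish that the estimators recover known ground truth under that
structure, at the problem sizes stated below.  Real data differ in ways
the generator deliberately omits: motion and its correction residuals,
coil-profile and B1 inhomogeneity, spatially *correlated but not global*
physiological noise, cardiac/respiratory spectral peaks (aliased at these
volTRs), partial-volume mixtures beyond a single venous fraction, and
Rician magnitude statistics.  Conclusions about real-data performance
therefore rest on the structural match, not on the tests alone.

Problem sizes used by the test suite (chosen to keep Monte-Carlo
uncertainty a factor of a few below each tolerance): noise-law and
parameter-recovery checks use 300–800 voxels and 150–300 resting volumes,
10–50 seeds; relaxometry bias uses 500 replicates at 1% noise; pipeline
smoke tests use 120–400 voxels and 16–60 volumes.

## Known limitations

* Multi-compartment relaxometry is intentionally absent (the echo grids
  and SNR here cannot support it); the mono-exponential estimator's bias
  on mixed voxels is characterised, not corrected.
* Plateau detection assumes the curve is (noisily) non-increasing toward
  a floor; exotic non-monotone curves return "undetected".
* The Welch t is not a GLM: its absolute values are not comparable with
  published t-maps, only its orderings.
* The high-pass operation is of limited use for runs whose task sits at
  Nyquist (see above); it exists for long-run and resting analyses.
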