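# Methods

This note documents the models and procedures implemented in `neofc`,
the assumptions behind them, the parameter defaults and why they were
chosen, and what the synthetic-data tests do and do not establish.

## Motion censoring (`neofc.qc`)

Two per-volume exclusion criteria are combined:

- **Framewise displacement (FD)**, Power-style: the sum of absolute
  backward differences of the six rigid-body realignment parameters,
  with the three rotations (radians) converted to arc length on a
  50 mm sphere. `fd[0] = 0` (no predecessor). Volumes with
  FD > 0.5 mm (strict) are flagged.
- **DVARS**, computed here on *network time courses*: the RMS backward
  difference across networks, expressed as a percentage of the
  grand-mean signal; volumes with DVARS > 3 % are flagged. This is an
  approximation of the voxel-level quantity (the voxel data are
  upstream of this pipeline); it requires un-demeaned, BOLD-scale
  signals and refuses demeaned input. RMS (not mean absolute change)
  follows the DVARS literature.

Each flagged volume is removed together with the 1 preceding and 2
following volumes; overlapping windows are unioned. A session is
included iff at least 50 % of volumes remain (boundary inclusive:
"a minimum of 50 %"), and longitudinal stages additionally require both
of a subject's sessions to be included. Flagging thresholds are strict
(`>`), the retention rule inclusive (`≥`).

## Accordance (`neofc.accordance`)

Signals are z-scored per network with the sample standard deviation
(ddof = 1), computed on the post-censoring series. Each standardized
signal z is gated two-sidedly at u = Φ⁻¹(0.8) ≈ 0.8416 (the 80 %
standard-normal quantile): x⁺ keeps values ≥ u, x⁻ keeps values ≤ −u.
Accordance and discordance between networks i, j are

    a_ij = (⟨x_i⁺, x_j⁺⟩ + ⟨x_i⁻, x_j⁻⟩) / (σ_i σ_j)
    d_ij = −(⟨x_i⁺, x_j⁻⟩ + ⟨x_i⁻, x_j⁺⟩) / (σ_i σ_j)

with σ² = ⟨x⁺, x⁺⟩ + ⟨x⁻, x⁻⟩. Normalizing by the thresholded energy
makes self-accordance exactly 1 and bounds both statistics in [0, 1]
(Cauchy–Schwarz on same-sign inner products); accordance and
discordance obey the sign-flip duality a(x, y) = d(x, −y). The default
`magnitude` variant keeps thresholded values; a `binary` variant
(±1 indicators on the same supports) is available behind a flag.

Design choices made where the method description left room:

- the lower gate is fixed at −u (symmetric two-sided gating of a
  standardized signal);
- thresholds are applied to the censored (scrubbed) series;
- an edge whose signal never crosses the gate (zero energy) is marked
  undefined (NaN) and excluded from statistics with a warning, rather
  than imputed as 0 — imputation would fabricate coupling;
- the diagonal is excluded from every edge enumeration, so an
  11-network connectome has m = 55 edges.

For two independent standard-normal series the population accordance is
2φ(u)² / (2(uφ(u) + Φ(−u))) ≈ 0.180 at u = Φ⁻¹(0.8) — the null level is
*not* 0, which is why downstream inference is paired and longitudinal
rather than a test of accordance against zero.

## COI definition and intervention test (`neofc.stats`)

**Maturating COI.** For each edge, a classical paired t-test on
per-subject accordance differences d_s = a_s(t2) − a_s(t1) over the
pooled cohort (both groups; two-sided by default, a one-sided-increase
mode is available). Raw p-values are corrected with the
Benjamini–Hochberg step-up over m = 55 edges; edges with adjusted
p ≤ 0.05 form the COI. The edge-weight difference (EWD) reported per
edge is the mean d_s. The in-package BH implementation supports
m > len(p) — the unobserved tests are assumed larger than every
observed one — so adjusted values can be recomputed from a partial
table of the smallest p-values. Edges with an undefined accordance in
any subject are dropped from testing (logged) while m stays at the
configured family size. Ties in raw p are resolved by a stable sort so
reports are deterministic.

**Intervention effect.** On each COI edge, within-group paired t-tests
(session 2 > session 1, one-sided increase — the hypothesis is
*stronger* maturation under the intervention) yield p-values converted
to z-scores by z = Φ⁻¹(1 − p), clamped to p ∈ [1e−15, 1 − 1e−15] with a
warning. The contrast z_diff = (Z_music − Z_control)/√2 is standard
normal under the null of equal maturation, by the variance-sum law with
cov(Z_PM, Z_PC) = 0 across independent groups (assumed, not estimated).
Edges with z_diff ≥ 1.3 (inclusive) are flagged; 1.3 is the rounded
normal quantile at p = 0.1, and the exact upper-tail p of the observed
z_diff is always reported alongside.

## Synthetic cohort (`neofc.simulate`)

Each session is an AR(1)-filtered multivariate normal: innovations
e_t ~ N(0, (1 − φ²)·C) with x_t = φ·x_{t−1} + e_t and a stationary
start, so the stationary cross-network correlation equals the target
correlation matrix C exactly (a shared φ leaves instantaneous
cross-correlations untouched). The latent process is placed on a
BOLD-like scale (baseline 100, fluctuation sd 1) so DVARS percentages
are meaningful. Gaussian AR(1) was chosen because accordance on
thresholded Gaussian signals has a tractable Monte-Carlo (and partly
closed-form) oracle.

Defaults — the stated world of the tests:

| parameter | default | rationale |
|---|---|---|
| n_music / n_control | 24 / 19 | target study design |
| n_networks / n_volumes / TR | 11 / 590 / 0.7 s | target acquisition scale |
| baseline coupling | equicorrelation 0.25 | plausible neonatal inter-network level; keeps all session-2 targets PSD |
| maturation_delta | +0.12 on 12 edges | mirrors the published maturating-edge pattern; yields EWDs ≈ 0.07, in the published 0.07–0.14 range |
| group_delta | +0.15 on thalamic/brainstem–salience | the planted intervention effect |
| ar1_coefficient φ | 0.4 | plausible BOLD autocorrelation at TR 0.7 s |
| spike_rate | 0.02 | ~12 spike volumes/session → ~8 % censored, typical neonatal motion without endangering the 50 % rule |

Maturation and intervention effects are additive correlation
increments; every resulting (group, session) matrix is re-validated as
a correlation matrix (symmetric, unit diagonal, PSD) at construction.

Motion spikes are planted jointly in both censoring channels: the
motion parameters take a *sustained* ±1 mm translation step at the
spike volume (FD exceeds 0.5 mm at exactly that volume; baseline
jitter keeps FD < 0.2 mm elsewhere), while the signal receives a
global *decaying* pulse (6 signal units ≈ 6 % of baseline, decay 0.65
per volume) so DVARS exceeds 3 % at the onset and returns to baseline.
A rectangular pulse would trip both criteria twice (jump and return);
the step/decay pair makes one spike flag one volume, hence remove
exactly four. Adjacent spikes may stack pulses and occasionally flag an
extra return volume — harmless over-censoring.

Seeds: per-subject/session streams are derived from the master seed via
`numpy.random.SeedSequence` with counter keys, so outputs are
byte-identical across reruns, independent of cohort size, and distinct
across subjects.

What the generator does **not** emulate: voxel-level data and spatial
ICA (it starts at network time courses), physiological noise structure
(cardiac/respiratory), scanner drift, non-Gaussian BOLD amplitude
distributions, subject-specific coupling heterogeneity (all subjects in
a cell share one target matrix), and realistic motion dynamics beyond
step-plus-jitter. A green recovery test therefore establishes that the
statistics recover effects of the planted size under Gaussian AR(1)
conditions — not performance on real fMRI. The temporal autocorrelation
and noise level of real extracted time courses are not documented in
the source study; the defaults are conventions.

## Numerical choices

- z-normalization refuses zero-variance columns by name; DVARS refuses
  near-zero grand means (demeaned input).
- PSD validation tolerates eigenvalues ≥ −1e−8; sampling uses an
  eigendecomposition (`method="eigh"`), so exactly singular targets
  (coupling 1.0) are legal.
- All TSV artifacts are written with `%.17g`, making write→read
  round-trips lossless and reruns byte-identical; undefined entries are
  `NA`.
- The BH step-up uses a reverse running minimum, clipped at 1; p-value
  to z conversion clamps at 1e−15 to keep z finite.
- Statistical-calibration tests run the generator at reduced T (200)
  where the checked null law is T-independent, and at the full T = 590
  stated world for planted-effect recovery; replicate counts (500 null,
  50 recovery) are sized for one CPU at fixed seeds.

## Known limitations

- DVARS on network averages understates voxel-level DVARS; the 3 %
  criterion is exercised against the generator's planted spikes, not
  validated against voxel data.
- The accordance normalization is the package's declared algebra
  (energy normalization with self-coupling 1); other conventions exist.
- BH-FDR control is exact under independence/PRDS; the generator's
  equicorrelated baseline induces weak dependence across edge
  statistics, and the false-discovery-proportion test allows
  Monte-Carlo slack accordingly.
- No covariate adjustment (gestational age at birth, sex), no
  permutation or cluster-level inference, and no graph-theoretic
  summaries — out of scope by design.
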