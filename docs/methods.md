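# Methods

`toricpred` quantifies how accurately different corneal-astigmatism
measurement modalities predict the astigmatism a toric intraocular lens
(IOL) actually had to correct.  Because anterior-only keratometry cannot
see the posterior corneal surface — whose steep meridian is vertical in
most eyes and therefore contributes an against-the-rule effect of roughly
0.2–0.6 D — anterior-only devices systematically over-read with-the-rule
(WTR) and under-read against-the-rule (ATR) corneal astigmatism.  The
package implements the vector machinery to expose that bias, the
back-calculation that defines "the astigmatism the IOL had to correct",
and a synthetic cohort generator that makes the whole chain testable
without patient data.

## Double-angle vector algebra

An astigmatism is a magnitude `M` (D) at a steep-meridian axis `θ`
(degrees, `[0, 180)`).  Mapped to `(x, y) = (M·cos 2θ, M·sin 2θ)`,
astigmatisms add, subtract and average linearly (Alpins-style vector
analysis).  All sums/differences/centroids happen in this space; the
centroid of a set is the vector mean, and its magnitude is always ≤ the
arithmetic mean of magnitudes (Jensen).  Reporting components are
`wtr_atr = M·cos 2θ` and `oblique = −M·sin 2θ`: a negative WTR/ATR
component points toward 90° (overcorrection of WTR, undercorrection of
ATR), and the sign flip on the oblique term makes errors directed along
135° positive and along 45° negative.  The flip is applied only at the
reporting boundary; internal algebra uses the raw `(x, y)`.

Axis classes partition `[0, 180)`: WTR on `[60, 120]`, ATR on
`[0, 30] ∪ [150, 180)`, oblique in between; the named bounds are closed on
the WTR/ATR side.  Zero-magnitude values canonicalize their axis to 0 and
equality is tested in double-angle space (default tolerance 1e-9 D).

## Corneal optics

* **SimK** uses the fictitious keratometric index 1.3375 on the anterior
  radii; **true** surface powers use 1.0→1.376 (anterior) and 1.376→1.336
  (posterior), `P = (n_out − n_in)/r`.  For the posterior surface the
  powers are negative, so its astigmatic *effect* lies 90° away from its
  curvature-steep meridian.
* **Vector modality** — double-angle sum of the two true surface
  astigmatisms.
* **TNP (true net power)** — per meridian, the Gaussian thick-lens power
  `F = F1 + F2 − (d/n)·F1·F2`, `d` = central corneal thickness (m),
  `n = 1.376`.
* **TCP (total corneal refractive power)** — exact meridional Snell-law
  ray trace of parallel rays through both spherical (per-meridian)
  surfaces; the per-ray equivalent power `−n′·tan u′ / h` is averaged over
  heights uniform in `(0, zone/2]` (default zone 4.0 mm, 50 heights).  In
  the small-zone limit TCP reproduces TNP to < 0.01 D (tested over random
  corneas).

Surfaces whose steep meridians are not co-axial are combined by sampling
the meridional power profile on a 1° grid and re-fitting
`a + b·cos 2φ + c·sin 2φ` by least squares — the continuous analogue of the
double-angle sum.  Because the TNP cross-term and the exact trace introduce
small `cos 4φ` content, the fit extracts the cylinder component, which is
what a clinical power map reports.

Plane conversions use the per-meridian vertex formula `P′ = P/(1 − d·P)`
(default vertex distance 12 mm).  IOL-plane toric cylinder is converted to
the corneal plane by back-solving the refractive vergence chain (cornea at
the mean keratometric power, IOL of power `sphere ± cyl/2` at the effective
lens position, retina at the axial length, media index 1.336); the
effective lens position comes from the published SRK/T expression with a
configurable A-constant (default 118.5, a typical value for a one-piece
toric line — the ratio is insensitive at the 0.01 level to ±0.5 A-constant
changes).  The resulting corneal/IOL cylinder ratio is ≈ 0.65–0.70 for
average biometry and decreases with deeper lens positions.

## Estimation chain

Per eye and follow-up timepoint (1 and 3 months, analyzed independently):

1. **SICA** (surgically induced astigmatism change) =
   `postop ⊖ preop` of the two-surface Vector astigmatism from the
   Scheimpflug radii.  The individually computed SICA — not the surgeon's
   assumed 0.50 D constant — enters the estimation; the constant is used
   only at IOL-selection time.
2. **Estimated preoperative corneal astigmatism** inverts
   `postop manifest cylinder = preop + IOL cylinder + SICA`
   as `estimated = postop ⊖ IOL ⊖ SICA`, with the manifest cylinder
   vertex-corrected to the corneal plane and the IOL vector oriented at the
   *observed* postoperative axis (axis + 90° in vector form, fixed by the
   round-trip identity `estimate(t ⊕ i ⊕ s, i, s) = t`, which is
   property-tested).
3. **Prediction error** per modality = modality estimate ⊖ estimated
   preoperative astigmatism.
4. **Aggregation** per modality × subgroup × timepoint: centroid,
   component means/SDs, % of eyes with |error| ≤ 0.50 / 1.00 D, ICC, and
   one-sample tests of each component against zero.

Eyes are grouped WTR/ATR by their *preoperative* anterior steep meridian
only; oblique eyes are excluded with an explicit report.

## Agreement statistics

ICC between the estimated and the modality-measured components uses the
two-way, single-measures, absolute-agreement form (McGraw–Wong ICC(A,1),
computed by `pingouin`); absolute agreement is the right variant because
the question is resemblance of values, not rank consistency.  Strata with
fewer than 3 pairs or degenerate variance report an explicit not-a-value
with a reason rather than a number.  Component means are tested against
zero with a Shapiro–Wilk gate (α = 0.05) choosing one-sample t versus
Wilcoxon signed-rank, Bonferroni-corrected by the number of modalities in
the stratum.  The sample-size helper implements the standard two-sided
one-sample normal approximation
`n = ⌈((z₁₋α/₂ + z_power)·sd/δ)²⌉`; for δ = 0.2 D, sd = 0.5 D, 80 % power,
α = 0.05 it returns 50 (a one-sided calculation would give ≈ 39 — the
helper deliberately implements the standard two-sided formula).

## Synthetic cohort generator

The generator's defaults are the study conditions: 41 eyes, 24/41 WTR;
anterior keratometric astigmatism 2.25 ± 1.04 D (WTR, 1.00–4.54) and
1.39 ± 0.56 D (ATR, 1.00–2.19); posterior astigmatism 0.56 ± 0.21 D (WTR,
0.20–1.00) and 0.26 ± 0.20 D (ATR, 0.10–0.70) with the posterior steep
meridian near vertical in both subgroups; AL 23.98 ± 0.97 mm, ACD
2.80 ± 0.42 mm, CCT 550 ± 35 µm, IOL sphere 19.4 ± 3.8 D; temporal
incision with true SICA magnitude 0.50 ± 0.25 D steep at 90° (axis jitter
SD 30°, consistent with observed centroid-to-mean ratios around 0.5); IOL
alignment error SD 3°; device noise SDs per double-angle component 0.10 D
(IOLMaster), 0.15 D (SimK), 0.20 D (wavefront), 0.015 mm on radii, 0.25 D
on manifest sphere/cylinder.  Values the study does not print (CCT,
posterior mean radius 6.35 mm, mean K 43.5 D, noise SDs, jitters) are set
once to typical clinical repeatability figures and documented here.

Truth per eye: anterior keratometric astigmatism `A`, posterior effect
`P`, total `T = A ⊕ P`.  Device channels read `A` (IOLMaster/SimK) or `T`
(wavefront) plus channel noise; anterior radii are synthesized so the true
(1.376-index) anterior surface astigmatism equals `A`, posterior radii so
the posterior effect equals `P` — hence the Vector modality computed from
noise-free radii reproduces `T` exactly.  A real IOLMaster would read
`337.5/r` off those radii (≈ 0.90·A); modelling the device channels
directly in astigmatism space is a deliberate simplification that keeps a
single unambiguous truth per eye.  The IOL toricity is chosen from the
step list (default 1.0–7.5 D by 0.5) whose corneal-plane equivalent is
nearest the target `T ⊖ assumed-SICA`, ties toward the lower step; the
postoperative manifest refraction is composed *forward* through the
estimation equation at the implanted (misaligned) axis and moved to the
spectacle plane, so that the analysis pipeline's back-calculation is exact
by construction when noise is zero.

Truncated-normal channels are **mean-calibrated**: the parent normal's
location is solved (Brent bisection) so the truncated mean equals the
configured mean.  The nominal SD is retained, so realized SDs sit slightly
below nominal; for the ATR posterior channel no truncated normal on
[0.10, 0.70] can reach SD 0.20 (the uniform limit is ≈ 0.17), so matching
the mean exactly and accepting the smaller SD is the only consistent
choice.

### What passing tests do and do not show

The generator emulates marginal distributions, a shared posterior steep
meridian, device noise and a forward-composed refraction.  It does not
model correlation between anterior and posterior magnitudes, fellow-eye
correlation, IOL tilt, ELP-dependent toricity error, biomechanical SICA
covariates, or clinically rounded refractions (0.25 D / 5° quantization
exists but is off by default).  Noise-free closure therefore certifies the
*algebra* of the pipeline, not the clinical accuracy of any device; the
noisy defaults reproduce the qualitative pattern of the study (anterior-
only overcorrection of WTR, nomogram overshoot to the horizontal axis,
near-zero error and highest ICC for the two-surface vector modality) but
per-eye realism is limited to the structure listed above.

## Numerical choices

* Degrees at every interface; radians only inside trig calls.
* Meridian grid 1°, TCP 50 ray heights: both configurable; halving either
  changes TCP astigmatism by < 1e-3 D on typical corneas.
* Ray-trace failures (total internal reflection, ray missing a surface)
  raise with the offending geometry rather than returning NaNs.
* Tie-breaks: equidistant toricity steps resolve to the lower step.
* Degenerate statistics (constant samples, < 3 pairs) return explicit
  not-a-value results with reasons.
* Analysis problem sizes used by the acceptance checks — 200-eye
  noise-free pipelines, 10,000-eye calibration cohorts, 10⁴ random
  algebra triples — were chosen as the smallest sizes at which the
  Monte-Carlo/closure statements are sharp.

## Known limitations

* The Baylor nomogram's published cells are not shipped; the default
  ±0.7 D rule is an approximation and real analyses should provide the
  table as configuration.
* Barrett toric calculator values are accepted only as pass-through
  columns (the calculator is a proprietary web tool).
* The wavefront modality is a device emulation (total astigmatism +
  noise), not a Zernike reconstruction.
* TNP/TCP here use the standard thick-lens and two-surface trace; device
  firmware may differ in zone weighting and smoothing.
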