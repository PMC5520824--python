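# Methods

## Kinetic model

The two-tissue compartment model describes exchange between arterial plasma
(concentration Cp, metabolite-corrected) and two tissue compartments with
rate constants K1 (mL·cm⁻³·min⁻¹, delivery) and k2, k3, k4 (min⁻¹; efflux,
binding, dissociation). The measured concentration in a region is

    C(t) = (1 − vB) · (IRF ⊛ Cp)(t − Δ) + vB · Cb(t − Δ)

where Cb is whole-blood activity, vB the fractional blood volume, Δ the
blood-to-tissue delay, and

    IRF(t) = K1/(θ1−θ2) · [(θ1−k3−k4)·e^(−θ1·t) + (k3+k4−θ2)·e^(−θ2·t)],

with θ1 ≥ θ2 the macro rates (θ1+θ2 = k2+k3+k4, θ1·θ2 = k2·k4). The model is
frame-averaged over each half-open frame `[start, start+duration)`. The
outcome is the total distribution volume V_T = ∫₀^∞ IRF dt = K1/k2·(1+k3/k4).
The (1−vB) factor on the tissue term is applied explicitly (some literature
omits it); it is part of both the simulator and the fit, and is tested.

Assumptions: passive single arterial input, linear time-invariant kinetics,
no radioactive-decay term (curves are treated as decay-corrected), and a
plasma curve already corrected for radiometabolites.

## Fitting protocol

Two stages, mirroring how scan-level nuisance parameters are usually
handled:

1. **Whole brain**: K1, k2, k3, k4, vB and Δ all free, weighted least
   squares on frames starting before 63 min.
2. **Per ROI** (whole brain included, refitted): K1, k2, k3, k4 free; vB
   and Δ fixed at the stage-one estimates.

Numerics: bounded trust-region least squares (bounds K1 ∈ [0,1];
k2, k3, k4 ∈ [10⁻⁴, 0.5]; vB ∈ [0, 0.15]; Δ ∈ [−0.5, 0.5] min), five
multi-starts from deterministically jittered defaults with the best weighted
residual sum of squares winning (ties to the first start). The delay enters
non-smoothly (through interpolation of the input), so it is handled by a
coarse grid search (5-s steps over ±30 s) around the smooth inner
optimisation, followed by golden-section refinement to 0.25 s; grid, bound
and tolerance are configurable (`FitOptions`). Residual weights are uniform
by default with frame-duration weighting available — the appropriate choice
depends on the acquisition, so it is exposed rather than fixed.

The convolution runs on a uniform 0.5-s grid via an exponentially weighted
IIR recursion with trapezoid correction (`y[n] = a·y[n−1] + dt/2·(x[n] +
a·x[n−1])`, a = e^(−θ·dt)); frame averages are trapezoid means over the
grid, with frame boundaries rounded half-up to grid indices and sub-grid
frames widened to one grid interval. Repeated macro-rate roots (k3 → 0 with
k2 = k4) are nudged apart by 10⁻⁹ to keep the closed form finite. Degenerate
inputs raise: fewer frames than free parameters, frames beyond the input
function's support, non-positive k2/k4.

## Outcome measures

SUV over a window (default 40–60 min) is the time-weighted mean activity
with fractional-overlap weighting for frames straddling the window, divided
by injected dose per body weight; with kBq/mL, MBq and kg the result is in
g/mL. Only ratios of SUVs are interpreted downstream. SUVR and DVR divide
the target region's SUV or V_T by the whole-brain or cerebellum value. The
outcome table carries one row per scan × target ROI × measure in
deterministic order.

## Test-retest statistics

For n subjects with k = 2 scans: MS_B = 2·Σ(subject mean − grand mean)²/(n−1),
MS_W = Σ(test−retest)²/(2n). ICC is the one-way fixed-effects form
(MS_B−MS_W)/(MS_B+(k−1)·MS_W); it can be negative, and the all-values-identical
case is defined as 1.0 with a warning (limiting value as noise → 0). COV
pools all 2n measurements (sample SD / mean; a per-scan alternative is a
deliberate non-feature — pooling is the convention used here). VAR is the
mean symmetric absolute percentage difference 200·|test−retest|/(test+retest);
equivalent |d|/pair-mean and |d|/test variants exist in the literature, and
the symmetric form was chosen as the default convention. SEM is √MS_W as a
percentage of the grand mean, i.e. the within-subject COV. Subjects missing
a scan are excluded from pairing with a warning. The report stratifies V_T
and SUV by genotype only; ratio outcomes additionally get a pooled "All"
row, since the genotype effect largely cancels in the quotient.

## Latent structure

Interregional Pearson correlation matrices are computed over scans (both
sessions pooled by default; zero-variance columns yield flagged NaN, never
imputation). For the PCA, regional V_T columns are z-scored within genotype
(sample SD), and the variance fractions are the eigenvalues of the column
covariance of the standardised matrix — equal to correlation-matrix PCA —
with sessions decomposed independently. With 12 rows and 6 regions this is a
small-sample regime and is flagged as such when rows < columns. Outcome-vs-V_T
association is the squared Pearson correlation within genotype, with both
scans of a subject entering as separate points (a subject-mean alternative
would halve n; the pooled form matches how such data are usually plotted).

## Synthetic cohort generator

The generator emulates a two-scan arterial-input TSPO PET study in healthy
subjects: 6 high-affinity (HAB) and 6 mixed-affinity (MAB) binders, six
regions (whole brain, cerebellum, frontal/temporal cortex, striatum,
thalamus), ~60-min scans.

**Binding structure.** Regional binding scales only k3:
k3(subject i, scan s, region r) = k3_base(genotype) · S_i · G_is · (1+ε_isr),
with S and G lognormal with mean exactly 1 (CV 0.30 between subjects, 0.10
between scans) and ε Gaussian with SD 0.02 drawn per scan and region. K1 =
0.12, k2 = 0.08, k4 = 0.05 are fixed, so V_T = K1/k2·(1+k3/k4) is
analytically controlled and group-mean V_T converges exactly to the genotype
targets (3.9 HAB; 3.9 ÷ 1.773 ≈ 2.2 MAB). Attributing the genotype and
latent effects to k3 alone reflects TSPO availability differences while
keeping delivery constant.

**Input function.** Metabolite-corrected plasma is a piecewise-linear rise
to a peak at 1.5 min followed by a tri-exponential decay (amplitudes 60, 12,
4 kBq/mL; rates 3.0, 0.35, 0.010 min⁻¹), scaled per scan by injected dose
per body weight (dose 400 MBq, weight 70 kg, each 10% CV) times a lognormal
clearance/delivery factor (CV 0.05). The dose-per-weight scaling makes body
size cancel in SUV, as it does physiologically. Whole blood is plasma/0.8
(constant parent-plasma-to-blood ratio). Arterial sampling: 5-s spacing to
3 min, 15 s to 10 min, then 2.5 min.

**Nuisance truth.** vB ~ U(0.027, 0.064) and delay ~ U(−20 s, +20 s) per
scan. The whole-brain noise-free curve is the equal-weight mean of the five
tissue-region curves — the target region is *inside* the denominator, which
is exactly the overlap under study.

**Noise.** Frame noise is zero-mean Gaussian with SD =
noise_scale·√(value/duration), the counting-statistics scaling;
noise_scale = 0.025 puts late 5-min frames below 1% relative noise,
appropriate for large-ROI curves from a high-resolution research tomograph,
and leaves the fitted V_T with ≈1–2% median error. Frames: 6×10 s, 3×20 s,
3×60 s, 5×180 s, 8×300 s (0–60 min). All randomness flows from the single
cohort seed through named substreams; identical specs give bit-identical
cohorts.

**Calibration.** The defaults are calibrated so the generated cohorts show
the structure the analysis design presumes: genotype V_T means 3.9/2.2,
vB within the printed 2.7–6.4% range, within-genotype interregional R² >
0.85, a first principal component above 98%, and a strong SUV–V_T
association coexisting with weak ratio–V_T association. One consequence of
fixing the scan-level latent CV at 0.10 while scaling k3 only is that V_T
SEM comes out near 6–8% (HAB) / 3–5% (MAB) — the scan factor moves only the
binding share of V_T (≈62% HAB, ≈32% MAB), so the simulator's within-subject
variability sits below what human test-retest data typically show (~12–14%).

**What it does not emulate.** No image space (ROI curves are generated
directly), no scanner resolution or partial-volume effects, no metabolite
kinetics (plasma is born corrected), no decay correction, no head motion,
no attenuation or reconstruction artefacts, and region-specific individual
differences have no subject-stable component (ε is redrawn per scan, making
true DVR reliability ≈ 0). Passing tests therefore demonstrate internal
consistency of the estimation chain and of the variance mechanism — not
that real data would show identical numbers.

## Problem sizes in tests and the acceptance script

The test suite fits: one noise-free 12-subject cohort (24 scans) for exact
recovery; 100 noisy scans for error quantiles; five default cohorts for the
reliability/association orderings (asserted on medians across cohorts, since
single-cohort ICC/R² at n = 6 per genotype are highly variable); and twenty
scan-1 sessions for the PCA criterion. The acceptance script runs twenty
12-subject cohorts and reports the median first-component percentage. These
sizes keep every oracle comparison at full strength while each suite runs in
minutes on one CPU.

## Known limitations

- The 2TCM likelihood under noise is multi-modal; five multi-starts make
  global misfits rare but not impossible (the convergence flag and WRSS are
  reported per fit).
- The delay grid wraps a non-convex inner problem; pathological inputs could
  in principle mislead the golden-section refinement between grid points.
- SUV absolute scale depends on the simulator's input amplitude convention;
  only ratios and correlations of SUV are meaningful here.
- With 6 subjects per genotype, ICC and R² estimates from any single cohort
  are extremely noisy; conclusions should always be drawn from replicated
  cohorts (the library makes that cheap).
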