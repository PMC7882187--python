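# Methods

## Walking-track components and factors

Each paw print carries six components: print length (PL, mm), total toe
spread (TS, digit I–V, mm), intermediate toe spread (IT, digit II–IV, mm),
distance to the opposite foot (TOF, mm), deviation angle (DA, degrees; stored
raw with 180° meaning the foot axis is parallel to the direction of travel)
and stance width (SW, mm). PL, TS and IT must be strictly positive, TOF and
SW may be zero, and IT ≤ TS by anatomy; the types enforce these at
construction.

A trial's prints (typically two per limb) are collapsed per component into a
**trial-maximum** or **trial-average** summary. For DA under trial-maximum the
"largest" measurement is ambiguous — largest raw angle or largest deviation
from straight travel. The default keeps the print deviating most from 180°
(sign preserved), with `da_mode="raw"` as the alternative; nothing downstream
depends on the choice.

**Percent deficit** is `100 · (measured − reference) / reference`, on the
×100 scale so composite indices land on the conventional 0 / −100 range. It
is exactly 0 at the reference, and anti-symmetric only to first order:
`percent_deficit(b·(1+x/100), b) = x` but the inverse transformation does not
recover −x except in the limit x→0; this is documented rather than asserted.

Two normalizations exist. *Contralateral* uses the same trial's C-limb
values (only the six E factors exist — the C limb is its own reference).
*Baseline* uses pre-injury (week-0) means and yields all twelve factors,
exposing compensatory shifts of the uninjured limb. Baseline scope defaults
to **per_rat** (each animal its own pre-injury control); a pooled *cohort*
scope is provided because the averaging convention is genuinely ambiguous in
the field — neither is asserted as canonical. The baseline table records the
aggregation mode it was built from and refuses to normalize trials of the
other mode.

## Classic index

The classic peroneal index is affine in two deficit ratios:

    PFI = 174.9 · (EPL − ref_PL)/ref_PL + 80.3 · (ETS − ref_TS)/ref_TS − 13.4.

The coefficients are the published Bain–Mackinnon–Hunter peroneal values,
shipped as configurable defaults (`ClassicIndexParams`) and treated as
external constants — this package does not re-derive them. Note the constant:
a trial identical to its reference scores −13.4, not 0. On paper substrates
the early heel strike elongates the experimental print (PL ↑ with injury),
which drives this index *upward* after injury; the synthetic paper cohorts
reproduce that artifact so the failure mode is testable.

## Revised (anchored) index derivation

The dependent scale is defined only at anchor weeks: week 0 ↦ 0 (healthy) and
weeks 3–4 ↦ −100 (maximal dysfunction; both nadir weeks carry the same
value). All other weeks have no dependent value and are excluded from the
anchored set. Fitting therefore uses **anchor-week trials only**, while
scoring covers all weeks — with a dependent variable defined nowhere else,
fitting on "all time points" is not a well-posed regression, and this is the
package's resolution of that ambiguity.

Screening fits **one joint OLS** of the anchored value on all 13 candidates
(12 factors + velocity) and reports per-term coefficient t-test p-values; a
univariate per-term screen is available behind `method="univariate"` for
comparison. Constant or collinear candidate columns raise a rank-deficiency
error naming the offending terms (found by greedy incremental rank growth).

Tier selection uses **strict** inequality (p < α), so a term at exactly the
threshold is excluded — this matches the published tier memberships, where
the term printed at p = .004 belongs to the α = .05 model but not the α =
.004 model. P-values known only as bounds ("< .0001") are stored as censored
bounds, never as fabricated numbers, and pass a tier iff bound ≤ α. By
construction the tiers nest: Model 1 ⊇ Model 2 ⊇ Model 3.

Model fits are OLS with intercept (statsmodels); an empty term list yields
the intercept-only model with adjusted R² defined as 0. Scoring is
`β₀ + Σ βⱼ·factorⱼ` per trial, summarised per week as mean ± SEM (SEM is 0
for singleton weeks).

## Longitudinal statistics

One-way ANOVA is the classic (non-Welch) between/within decomposition with
the F tail from scipy; zero pooled within-group variance is a degenerate
input. Tukey HSD pairwise p-values come from `scipy.stats.tukey_hsd`;
letters are assigned by the insert-and-absorb compact-letter-display
algorithm, which guarantees that groups share a letter iff their pair is not
significant. Dunnett many-to-one comparisons use the multivariate-t
criterion (`scipy.stats.dunnett`, seeded for reproducibility of its QMC
integration); the documented conservative fallback (`method="bonferroni"`)
applies Bonferroni to the same pooled-variance t statistics, so it is never
anti-conservative relative to the multivariate-t p. α = 0.05 throughout,
configurable.

Repeated trials within an animal are pseudo-replicates; `collapse_trials`
averages them to one value per rat × week, and the pipelines do this before
every test. A flag is not needed to disable it — callers of the low-level
functions pass whatever groups they wish.

## Kinematics

The hock angle is the interior angle at the calcaneus between the
calcaneus→stifle and calcaneus→metatarsal vectors (arccos of the normalized
dot product, [0, 180°]); it is invariant to rigid motion and uniform scaling,
and coincident markers are a degenerate-geometry error. The analysis is
strictly 2-D sagittal (single lateral camera, default 60 frames/s).

Gait cycles are segmented from the digit-4 (toe) pad: stance is where the
toe's forward speed falls below 15% of the reference swing speed *and* its
height is within 20% of its vertical range above minimum. The reference
swing speed is the median of speeds above the trace mean — a plain median
fails when stance occupies most frames (median speed ≈ 0). Partial first and
last cycles are discarded; phases shorter than 2 frames are skipped with a
warning. On the synthetic generator detected toe-off is within one frame of
the programmed event (the one-frame lag comes from central-difference
velocity smearing at the boundary).

"Mid-swing" is operationalised as the **temporal midpoint** of the swing
phase (nearest frame; exact ties average the two nearest frames) — the peak
toe-height alternative would differ only for asymmetric swing profiles and is
not implemented. Which distal landmark defines the foot axis is likewise a
convention; the metatarsal-4 head is used.

The weekly **recovery fraction** is
`100 · (1 − |angle_w − baseline| / |angle_nadir − baseline|)` — 100% at
baseline, 0% at the nadir excursion. It is reported alongside raw weekly
angles because "percent of pre-injury value" has no standard formula; if no
excursion exists the fraction is undefined (NaN).

## Synthetic cohorts: what they emulate, and what they do not

Study designs mirror the emulated experiments exactly: paper study —
transection+repair n = 12, critical gap n = 6, weeks
{0,1,2,3,4,8,12,16,20,24}; video study — repair n = 8, crush n = 8,
transect+ligate n = 7, weeks {0,2,4,8,12,16}; ≥3 trials per time point, 2
prints per limb per trial.

Each component's E-limb mean follows
`baseline · (1 + amplitude · shape(week))` with `shape` rising linearly to 1
at the nadir week then decaying exponentially toward the residual
`1 − plateau_fraction`. Defaults: TS −35%, IT −30%, PL −8% (or +20% when the
heel-strike artifact is on), TOF +15%, DA −8%, SW +20%; DA and SW reach
their nadir one week later (week 4) than the geometry components (week 3).
Injury profiles: crush (nadir week 2, rate 1.0/wk, plateau 0.97), repair
(3, 0.35, 0.85), critical gap (amplitudes ×1.3; 4, 0.08, 0.35), ligate
(plateau 0 — no recovery), sham (all amplitudes 0). The rate/plateau
ordering crush > repair is asserted in the defaults. The contralateral limb
shifts in the same direction at 12% of the E amplitude (compensatory
loading). Velocity is 280 ± 30 mm/s with an optional per-week drift (−3
mm/s/wk in the paper-study profiles, matching the observed slowing there and
its absence in the video study).

Noise is Gaussian at three levels — rat intercept (SD 3% of baseline), trial
(4%), print (2%) — chosen once as plausible for trained rats; the true
variance components are unknowable from published SEM bars, so these are
config-exposed defaults, not calibrated values. IT is clipped to ≤ 0.95·TS
so every print satisfies the anatomical invariant. An optional
per-trial dropout probability models trial rejection (rats pausing, bad
inking); off by default.

Marker traces place the toe pad on the ground during stance (duty factor
0.6, cycle 0.5 s, stride 120 mm) and on a smooth arc during swing; the
stifle is positioned by rotating the foot axis about the calcaneus by the
programmed hock angle, so the emitted geometry reproduces the target
waveform exactly up to 0.05 mm marker jitter and 0.5° angle noise. The
healthy waveform holds 130° through stance and dips to 85° at mid-swing;
injury raises the mid-swing dip by up to 40° (30° for crush) along the same
deficit shape, with a 2° SD rat-level offset. Ground truth (contact and
toe-off times, programmed mid-phase angles) is returned with every trace.

What a green test on these cohorts does **not** establish: the generator has
no biomechanics (no limb dynamics, no inter-component correlation beyond the
shared trajectory, no autocorrelation across weeks within a rat beyond the
random intercept), no print-quality failures, and Gaussian noise throughout.
It validates the *pipeline* — factor algebra, anchoring, selection, fitting,
scoring, statistics, segmentation — not any biological claim, and the fitted
index coefficients on synthetic data have no correspondence to coefficients
fitted on real animals (which are not re-derivable without the original
data).

## Numerical choices

- OLS via statsmodels; tests cross-check against explicit normal equations
  (≤1e-8 relative error).
- Screening p-values are clipped away from exact 0 (strong signals underflow
  the t tail) so they remain in (0, 1].
- SEM uses the n−1 denominator; singleton groups report SEM 0.
- Strict-increase validation on trace time stamps; angle cosines are clipped
  to [−1, 1] before arccos.
- All randomness flows through `numpy.random.default_rng(seed)`; the same
  (design, profile, seed) triple is bit-reproducible, and every pipeline
  output's metadata records the seed and a config hash.

## Known limitations

- The revised-index coefficients printed for the original animal data cannot
  be validated: the underlying measurements were never deposited. The package
  reproduces the *procedure* (anchoring, screening, tiers, scoring), and its
  acceptance checks operate on the published screening table and on synthetic
  cohorts.
- Dunnett's test assumes homoscedastic groups; no Welch variant is provided
  (classic ANOVA matches the original analysis software's default).
- Gait segmentation assumes steady locomotion with clear stance plateaus;
  traces from stumbling or pausing animals will be rejected rather than
  salvaged.
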