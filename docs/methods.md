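# Methods

`nacshell` re-implements, as a tested pipeline over a synthetic test
bench, the computational analyses used to characterize rostro-caudal
functional gradients in the medial nucleus accumbens shell (medNAcSh):
dual-channel fiber-photometry quantification of D1-SPN population
activity, behavioral session scoring, marker co-expression counting, and
the accompanying statistics. This note documents the models, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
bench does and does not establish about real data.

## Photometry model and preprocessing

A recording carries two co-sampled channels at 1017.3 Hz: the
calcium-dependent signal F (465 nm excitation) and a calcium-independent
isosbestic reference (405 nm). The generator composes them as

    F(t)      = B_s(t) · (1 + ΔF/F₀(t)/100) + m(t) + ε_s(t)
    F_iso(t)  = B_i(t) + c · m(t) + ε_i(t)

* **Bleaching** `B(t) = L·((1−f) + f·e^(−t/τ))`: a fast initial decay
  toward a stable plateau, per channel (defaults τ = 25 s signal / 35 s
  reference, bleached fraction f = 0.3, plateaus 100 and 80 a.u.). The
  fast time constants make the artifact essentially complete before the
  180-s trim — that is the artifact class the trim is designed to remove.
  Slow session-scale drift is deliberately assigned to the motion term
  instead: a deterministic slow bleach mismatch between channels is not
  removable by the per-window isosbestic regression and would masquerade
  as an event-locked effect identical across animals, which is not how
  trimmed real recordings behave.
* **Motion/artifact** m(t): a stationary Ornstein–Uhlenbeck process
  (defaults SD 1 a.u., time constant 30 s), shared across channels with
  reference gain `c` (default 1). Mean-reverting shared drift is exactly
  the disturbance the isosbestic regression exists to remove.
* **Noise** ε: white Gaussian per channel (default SD 1 a.u.). With a
  3 a.u. transient this gives a raw per-sample SNR of 3; the 1 Hz filter
  raises the effective SNR ~7-fold.
* **Transients**: difference-of-exponentials kernels
  `k(t) = (e^(−t/τ_d) − e^(−t/τ_r))/peak`, unit peak by construction
  (analytic peak time `τ_r τ_d/(τ_d−τ_r)·ln(τ_d/τ_r)`), scaled by an
  amplitude in ΔF/F₀ percent. Defaults τ_r = 0.5 s, τ_d = 2 s — a
  population-level consumption pause/excitation lasting a few seconds,
  slow enough that the 1 Hz low-pass leaves its peak nearly intact.
  Pauses are negative-going, excitations positive; the sign is validated
  against the kernel kind.

The preprocessing chain runs in a fixed order: 10× block-mean
downsampling (the block mean doubles as a crude anti-alias stage; the
nominal "100 Hz" is carried as the exact 101.73 Hz and all time bins
derive from it), zero-phase 4th-order Butterworth low-pass at 1 Hz
applied to both channels (symmetric treatment; single-channel filtering
is a flag), removal of the first 180 s (event clock preserved, early
events flagged excluded), extraction of −10…+20 s windows around each
surviving event (−10…+30 s configurable), an independent least-squares
fit `F ≈ a·F_iso + b` per window (overlapping windows fitted
independently), and `ΔF/F₀(%) = (F − F₀)/F₀ × 100` with `F₀ = a·F_iso + b`.
A non-positive F₀ raises an error naming the offending samples — never
silent clipping — because a non-positive baseline means corrupt input.
One numerical edge: a window in which **both** channels are exactly
constant returns the exact degenerate solution F₀ = F (ΔF/F₀ ≡ 0); the
degenerate-fit error is reserved for the genuinely underdetermined case
of a varying signal over a constant reference.

## Event-locked quantification

Aligned trials share one relative time grid (rows are trials, each mapped
to its animal). Baseline correction subtracts each row's mean over
−10…−1 s. PSTHs average hierarchically — trials within animal, then
across animals — so unequal trial counts do not reweight animals; SEM is
taken over the units of the requested level. Heatmaps export one row per
animal for the reward task and one per trial for aversive sessions, both
overridable.

Epoch metrics (trapezoidal AUC, maximum, minimum) are computed on each
animal's trial-averaged trace over closed epochs, baseline −6…−1 s and
event 0…5 s by default (the tail-lift preset uses −4…0 vs 0…4 s). Closed
boundaries maximize sample use; at 1 Hz bandwidth the choice is
immaterial but must be fixed for reproducibility. Computing metrics on
animal-averaged traces (rather than per trial, then averaging) matches
paired tests whose degrees of freedom equal animal counts; the per-trial
alternative is exposed as a flag. The epoch contrast returns per-animal
(baseline, event) pairs — minima for consumption pauses, maxima for
aversive excitations — feeding the paired t-test.

## Behavioral scoring

* **Reward task**: a trial succeeds iff at least one lick falls in the
  closed interval [onset, onset+10 s]; the first such lick is the
  alignment event. Reported percentages round half-up to integers.
  Training criteria: ≥10 successful trials to advance to tethered
  training, ≥12 to advance to recorded testing; the optogenetic task
  requires lick-count variability |L₁−L₂|/mean(L₁,L₂) < 0.30 across the
  last two sessions (the relative-difference reading of "variability",
  documented as an interpretation).
* **Optogenetic blocks** are half-open [start, end), partitioning the
  session without double counting. Epoch means average per-block
  licks/min within each laser state (identical to pooling for
  equal-duration blocks, and well-defined for unequal ones);
  `Δ = mean(non-opto) − mean(opto)`, and an animal is classified
  lick-inhibited iff Δ > 0 strictly. Under no suppression the
  classification is a fair coin by symmetry, which the bench verifies.
* **RTPPA**: two 30×30 cm chambers split at x = 30 cm. Each inter-sample
  interval and step distance is attributed to the chamber of its starting
  sample; chamber time fractions sum to 100 by construction. The laser is
  paired on days 2–3 to the day-1 preferred chamber; an exact 50/50 tie
  breaks toward chamber A with a warning (never observed in practice).
* **Calorimetry**: Weir energy expenditure `EE = 3.9·VO₂ + 1.1·VCO₂`
  (kcal, volumes in L) and respiratory quotient `RQ = VCO₂/VO₂`.

The behavioral generator uses homogeneous Poisson lick trains inside
access windows (rate default 5 Hz during reward access, engagement
probability 0.9; session-wide 2 Hz in the free-licking opto task) — the
simplest model making block means analytically predictable. Real lick
trains are bursty at ~7 Hz within bouts; block counts over minutes are
insensitive to this, so the block-level contracts transfer, but
sub-second lick statistics do not. RTPPA dwell times are exponential with
per-chamber exit rates and positions are uniform within the current
chamber at 10 Hz — sufficient for time-fraction and distance contracts,
not a locomotor model.

## Marker expression

Count matrices are genes × cells sparse integers. Filtering retains genes
detected in ≥3 cells and cells with ≥1,250 detected genes, both evaluated
on the input matrix in a single pass (no iteration), and is idempotent.
Positivity is a raw-count property — a single copy suffices — so the
optional log-CPM transform (ln(1+CPM), scale 10⁶) never enters any
reported proportion; it preserves the zero pattern. Co-expression is
`100·|A⁺∩B⁺|/|denominator⁺|`, both orientations exposed; the
probe-in-receptor orientation (share of Drd1a⁺/Drd2⁺ cells carrying
Stard5 or Peg10) is the reported one, and proportions are computed
post-filter (pre-filter values are also derivable by skipping the filter
step). FISH proportions are computed per section, averaged within animal,
then across animals, making the group value invariant to section
duplication and row order; a section without receptor-positive cells is
flagged undefined (NaN) rather than zero. Optical density is
`mean ROI square − background square` per hemisphere (background in the
anterior commissure of the same section), hemispheres averaged; negative
corrected values are preserved.

The count generator couples marker indicators through a Gaussian copula:
pairwise latent correlations are solved by root-finding on the bivariate
normal CDF, with comonotone/independent/countermonotone joints
short-circuited analytically, and a non-positive-semidefinite latent
correlation rejected as jointly infeasible. The atlas-scale configuration
(36,670 cells, 2,000 genes, mean depth 5,000, lognormal per-gene rates
and per-cell depths) treats the published probe-in-receptor percentages
as ground-truth conditional probabilities and recovers them through the
filter → positivity → co-expression path. One structural limit: a latent
Gaussian cannot combine near-disjoint Drd1a/Drd2 classes with both probes
positively coupled to both receptors, so the receptor–receptor joint is
left unspecified (independent); no reported proportion depends on it.
Because the bench is synthetic, agreement here demonstrates that the
quantification code computes the intended estimand at the intended scale
— it is parameter recovery, not a re-analysis of the public accession,
which would require downloading the original matrix and running this same
path on it.

## Statistics

Paired two-tailed Student's t: `t = mean(d)/(sd(d)/√n)` with the n−1
standard deviation, df = n−1, algebraically identical to the one-sample t
of differences. Zero-variance differences with nonzero mean raise an
infinite-t error; all-equal pairs return t = 0, p = 1.

The mixed (split-plot) repeated-measures ANOVA decomposes a complete
design with one between-subjects and one within-subjects factor: the
between effect is tested against subjects-within-groups MS, within and
interaction effects against the within-subjects error MS. No sphericity
correction is applied — with two within levels the uncorrected test is
exact anyway — and the implementation refuses incomplete designs. Group
sizes may differ; sums of squares use group-size-weighted means and
partition the total (asserted to 1e−8 relative on random designs). For 34
subjects in 3 groups with 2 levels this yields the characteristic
df pattern F(2,31)/F(1,31) with a shared error df of 31. A three-level
within factor (the 3-day RTPPA design) is produced uncorrected by
construction; a sphericity-corrected table (which fractional printed dfs
would imply) is deliberately not imitated.

Post-hoc within-level contrasts per group use the shared within-error MS:
`t = Δmean/√(2·MS_err/n_g)` with the error df, so all groups share one
df; raw p-values are Sidak-adjusted, `p_adj = 1 − (1−p)^m`, with m the
number of groups (m = 1 returns p unchanged). Tail probabilities come
from the t and F distributions (regularized incomplete beta underneath);
the suite pins them to the closed-form incomplete-beta identity at
1e−10.

## Validation bench and problem sizes

Four end-to-end checks run at fixed sizes, chosen as the smallest designs
that estimate each rate with useful precision:

1. **Null calibration** — 500 kernel-free cohorts (8 animals × 10 events)
   through the full chain; the paired epoch-minima contrast should reject
   at ~5%. Note the contrast is invariant to the per-trial baseline
   subtraction (a constant per trace cancels in min_b − min_e), so
   calibration follows from stationarity of the artifact model.
2. **Amplitude recovery** — 50 cohorts with a −3% pause at raw SNR 3;
   median recovered event-epoch minimum within 20% of truth and the
   contrast significant in ≥90% of cohorts.
3. **Motion-correction benefit** — signal-free cohorts with a shared
   artifact: isosbestic-corrected ΔF/F₀ RMS vs a window-mean baseline
   (observed ratio well above the 5× requirement).
4. **Classifier calibration** — the inhibition call fires in >95% of
   half-rate simulations and ~50% of null simulations.

Passing these shows the implementation recovers what the generator
injects under the stated artifact model. It does not certify performance
on real recordings with hemodynamic contamination, non-stationary noise,
lick-artifact coupling, or indicator nonlinearity — none of which the
generator emulates.

## Known limitations

* The isosbestic regression assumes the artifact enters both channels
  affinely within a window; multiplicative artifacts are only locally
  approximated.
* The generator's per-event amplitude is constant within a session; trial-
  to-trial amplitude variability is not modeled.
* The copula count model reproduces pairwise co-positivity only; triple
  co-expression structure is whatever the latent Gaussian implies.
* GraphPad's exact post-hoc variance formula for mixed designs is not
  publicly documented; the classical within-error formulation implemented
  here reproduces the published df pattern and is the standard textbook
  choice.
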