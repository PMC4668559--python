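# Methods

This note documents the models, defaults and numerical choices behind
`mazeview`, and what its synthetic data can and cannot establish.

## Task simulator

**Map model.** A map is a 7×7 boolean grid (True = path) surrounded by
implicit walls. Validity requires: every path square has ≥ 2 path
4-neighbors (no dead ends) and < 4 (no cross roads); no 2×2 all-path
window; no 2×2 all-wall window fully inside the grid (the implicit wall
surround is exempt, otherwise the surround itself would violate the rule);
no 2×2 diagonal checker; at least one path square; one connected
component. `generate_map` searches by annealed stochastic local search on
a vectorized violation count (single-square flips; sideways moves always
accepted; worsening moves accepted with a cooling probability; the
connected-components term is evaluated lazily because it only matters near
convergence). An optional flag additionally enforces 180°-rotation
symmetry; it is off by default because the symmetry class of the original
stimulus maps is not specified anywhere machine-readable.

**Distracter-rich map selection.** Valid random maps differ enormously in
how many squares can be flipped without creating a new violation — and a
scene-choice task needs legally flippable squares of *both* statuses for
all three view parts. `generate_study_maps` therefore screens candidates:
every (view part, status) bucket of legal state sequences must contain at
least 5 entries and the squares reachable as post-move positions must
cover ≥ 60% of path squares. Roughly one candidate in ten passes.

**Trial generation** enumerates, per map, every (initial pose, movement 1,
movement 2) whose movements are all effective (a turn is always effective;
forward requires a path ahead) and whose third, always-forward movement is
legal, bucketed by the view part that will be flipped and its true status.
Flipped parts and maps are assigned by shuffled round-robin within each
session (pairwise flip counts differ by ≤ 2 over the whole set), and each
part's true status follows a per-session balanced wall/path deck, which
steers the target wall rates to 0.5 with the small per-session scatter a
balanced design produces. Draws prefer state sequences ending on
not-yet-visited squares, so post-move positions cover the attainable
squares rather than clustering. Of 64 trials per session, 60 carry the
analyzable 5 s pre-choice delay and 4 carry 1 s/3 s jitter delays; only
delay-5 trials enter analyses.

**Behavior model.** A miss is drawn first (p = 0.01), otherwise the trial
is correct with a view-part-specific probability (defaults 0.93/0.97/0.93
for L/C/R — forward-center discriminations are slightly easier), else the
distracter was chosen. These defaults reproduce the ~93/6/1% outcome split
of practiced participants. Reaction times are lognormal with a shorter
location for forward-center, z-scored within session.

## Voxel-data generator

Each ROI is a scans × voxels array: TR = 2 s, 8 scans per trial (map
period → scan 2, moves → 3–4, early delay → 5, pre-choice → 6, choice →
8), 6 signal-free lead-in scans per session. Default voxel counts are the
study means per region (mPFC 577, dPFC 471, precuneus 645, sPC 671,
HC-paraHC 367, OC 858). For every encoded code, a fixed random ±1 pattern
over `n_informative` voxels (default 30) is added at the configured encode
scans (default 5–6), signed by the code value (±1 contrast) and scaled by
`snr`; the model is linear-additive, the simplest form consistent with a
linear decoder, and no hemodynamic convolution is applied — matching the
analysis, which decodes unconvolved single-scan signals. Nuisance terms:
per-voxel quadratic drift per session (scale 0.5), three rank-1
session-wide noise components (per-voxel sd 5 — deliberately the largest
variance source, so that removing the top singular components is the
*correct* action for the denoiser), and unit white noise. With
`subjective_mode` on, the upcoming-view codes injected on incorrect trials
are those of the chosen (distracter) scene.

**What this does not emulate:** hemodynamic convolution and undershoot,
autocorrelated (AR) noise, motion and physiological artifacts, voxel
spatial correlation, nonstationary SNR. Passing recovery tests therefore
show the *pipeline* is correct and leak-free — not that real cortical data
would yield these accuracies.

## Preprocessing

Fixed order: discard the first 6 scans per session → per-voxel, per-session
least-squares quadratic detrend (regressor is the scan index; residuals
orthogonal to {1, t, t²}) → per-session SVD noise reduction with K = 3,
read as *removing* the top-K singular components (shared global
fluctuations); retaining K components would instead delete almost all
voxel-specific pattern information → per-voxel, per-session z-scoring.
Zero-variance voxels are zeroed with a logged warning rather than
aborting. Samples are either single scans or the mean of scans 5–6 (the
2×TR window just before the options appear); misses and jitter trials are
excluded.

## Sparse logistic regression

Binary labels y ∈ {0,1}, model P(y=1|x) = σ(wᵀx + b). Each weight has a
Gaussian prior N(0, α_i⁻¹); the bias is an always-retained input with
fixed precision 10⁻⁸ (effectively unpenalized). The logistic likelihood is
handled with the Jaakkola–Jordan local bound, giving a Gaussian posterior
N(m, S) in closed form given bound parameters ξ_n, which are themselves
updated as ξ_n² = x_nᵀ(S + mmᵀ)x_n. Precisions follow the evidence
fixed-point rule α_i ← γ_i/m_i², γ_i = 1 − α_i S_ii. We use this rule
rather than the EM alternative α_i ← 1/(m_i² + S_ii) because under EM the
precision of an unsupported weight grows only linearly per iteration
(empirically ~5 per iteration on ROI-sized problems), so no feature would
ever cross a 10⁸ pruning threshold within a realistic iteration budget —
i.e. the decoder would never actually be sparse. Features with α_i > 10⁸
are pruned permanently. Convergence: relative change of the posterior mean
< 10⁻⁴ (restarted after a prune), max 500 iterations.

The variational free energy is evaluated once per cycle; because each
cycle is coordinate ascent in (q, ξ, α), the trace is non-decreasing
between pruning events (at a prune the objective is redefined on the
surviving features), and the test suite asserts this with tolerance 10⁻⁸.
For p > n the posterior uses the Woodbury identity (an n×n Cholesky), so a
fit at 671 voxels × tens of trials costs milliseconds.

Two switches matter for verification. `update_alpha=False` freezes the
prior (ridge-logistic). `xi_from_posterior=False` sets ξ_n = |x_nᵀm|,
which turns the iteration into an MM scheme whose fixed point is the exact
penalized-likelihood (MAP) optimum — useful as an algebraic cross-check
against an independent gradient-based solver (they agree to ~10⁻¹⁰). The
default full variational fit deliberately differs from the MAP by O(S):
the posterior-covariance term in ξ is what distinguishes VB from MAP.

## Decoding harness

12 binary decoders (3 upcoming, 2 observed, 4 position, 3 map) run in
parallel per ROI and sample definition; a family's accuracy is the
arithmetic mean over its code decoders. Training folds are class-rebalanced
by subsampling the majority class to the minority size with a fold-derived
seed (reproducible, uncoupled across folds); evaluation always uses all
held-out samples at the 0.5 threshold (probability exactly 0.5 counts as
positive). Every fold of every scheme asserts empty train/test trial-id
intersection — and empty map-id intersection for LOMO — before fitting, so
leakage is impossible by construction. The empirical chance level helper
reports the majority-class rate of an evaluation set; tests against chance
use Wilcoxon signed-rank with Bonferroni-adjusted α = 0.05/m, rank-sum for
two-sample contrasts, and Friedman for ≥ 3 matched conditions (all-tied
inputs report an undefined test instead of raising).

For incorrect-trial evaluation, the three view-part decoders are trained
on correct *and* incorrect trials; training labels for incorrect trials
follow a switch (default: the chosen scene, since the participant's
expectation is the quantity of interest; the truth-labeled variant is one
flag away because the original description does not pin the training
labeling down). Evaluation is LOTO restricted to incorrect trials, scored
under both the choice-based and truth-based schemes.

## Map reconstruction

Each analyzable trial of a held-out map receives one analogue prediction
per view part from part-specific decoders trained without that map (LOMO);
each prediction is deposited on the square its part points at from the
trial's post-move pose. View parts of border poses that face the implicit
wall surround have no square to fill and are skipped. Square-wise values
combine as v = σ(β(ȳ − ½)) with β = 5 — the mean-then-sigmoid form is
chosen as the canonical reading of "mean of the analogue outputs with the
sigmoidal rule" (it fixes ȳ = ½ ↦ ½, and β acts as an inverse
temperature); a sum form σ(β Σ(y−½)) is available behind a config switch.
Squares with no predictions are excluded ("gray"). Binarization selects
the k largest values as paths where k is the true path count *over
evaluable squares* (whole-map counting is a flag), with ties broken by
larger prediction count then row-major order; this makes the
predicted-path count invariant exact and testable. Accuracy is square-wise
agreement over evaluable squares; the cohort-level relation to behavior is
reported as Spearman (headline) plus Pearson.

## Problem sizes used by the test and acceptance suites

All simulated experiments are sized for statistical adequacy at desk
scale; sizes are package choices, stated here once:

- constraint-checker equivalence: 1000 random grids at densities 0.3/0.5/0.7;
- decoder-vs-MAP agreement and sparse recovery: 20 seeds each (40×10 and
  60×100 designs, 2σ class separation on informative features);
- label recovery: study-mean ROI sizes (sPC 671 voxels encoding at SNR 1,
  dPFC 471 silent), view-part LOTO pooled across 8 participants; the
  encoded condition uses 3 sessions × 52 trials (~1100 pooled predictions),
  and the zero-SNR chance condition the full 5 × 60 scale (~2400 pooled
  predictions) so that the ±3% chance band exceeds two standard errors of
  the pooled estimate (per-cell spread is approximately binomial;
  Monte Carlo over independent noise datasets shows no systematic bias);
- subjective-expectation contrast: 8 participants × 48 trials at choice
  accuracy ~0.7, paired Wilcoxon over participants;
- permutation null: 300 analyzable trials, 12 decoders, mean over 10
  within-session label permutations;
- reconstruction: one full-scale high-SNR participant (all three maps) and
  an 8-participant SNR-coupled cohort (24 points) for the behavior
  correlation.

## Known limitations

- The generator's linear, unconvolved, temporally white signal model is a
  best case for a linear decoder; absolute accuracies are not comparable
  to real-data values.
- Map search is stochastic; distracter-rich map selection can take tens of
  seconds per set (results are memoized per process).
- Session-wise z-scoring couples samples within a session, so
  leave-one-trial-out estimates on small sessions are noisy (not biased:
  verified by Monte Carlo); group-level claims always pool across
  participants.
- Multinomial (8-class scene) decoding, kernel variants, searchlight
  mapping and real scanner-format ingestion are out of scope.
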