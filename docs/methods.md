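# Methods

This note documents the models implemented in `lagkit`, the choices made
where the procedures left freedom, and what the synthetic-data generators
do and do not emulate.

## Single-cell induction lags

The induction lag of a cell after a medium switch is the delay until its
reporter level has risen a fixed number of molecules (default 200) above
its post-switch baseline. The baseline is the mean fluorescence over the
samples in the 9 minutes following the switch, inclusive of both endpoints
(three points at 3-min sampling, a single point at 6-min sampling). The
200-molecule threshold is conservative: autofluorescence fluctuations have
a standard deviation of roughly 20 molecule equivalents, so a crossing is a
10-sigma event. At least four post-switch timepoints are required; with
fewer the lag is undefined and an error is raised rather than a sentinel
returned.

If a cell divides before inducing, the summed fluorescence of its tracked
descendants is followed (generalised from two daughters to the full subtree
when daughters divide again). Tracking stops when any tracked descendant
leaves the field of view; the record is then right-censored with status
`washed_out`. A trace whose observation window ends without a crossing is
`non_induced`. Censoring is always encoded as status labels, never as
sentinel lag values. Reported lags are the first *sampled* time at or above
the threshold, so a noiseless ramp crossing at 81.67 min on a 3-min grid is
reported as 84 min. Lags are not corrected for reporter maturation time.

## Growth lags: profile likelihood with a Laplace step

Log cell size is modelled as flat until the arrest ends at time τ and
linear with slope λ afterwards,

    L(t) = λ·Λτ(t) + Λ0 + ε,   Λτ(t) = (t − τ)·Θ(t − τ),   ε ~ N(0, σ²).

For a series D = {L1 … LT}, marginalising Λ0 with a uniform prior and σ
with the Jeffreys prior gives P(D|λ, τ) ∝ Var[L − λΛτ]^((1−T)/2), where
Var and Cov denote mean-centred second moments normalised by T. The
integral over λ is treated with the Laplace method around its optimum
λτ = Cov[L, Λτ]/Var[Λτ], which yields the one-dimensional profile

    log p(D|τ) = ((2 − T)/2)·log Var[L − λτ·Λτ] − ½·log Var[Λτ] + const.

Numerical choices:

- τ is maximised on a grid from 0 to the last observation minus two
  sampling intervals, in 1-min steps (configurable). The upper bound keeps
  at least two points on the growing arm, so Var[Λτ] > 0 and λτ is
  identified; grid values with a constant ramp are dropped with a warning.
- Ties in the profile are broken toward the smaller τ. On noiseless
  piecewise-linear input the residual variance at the true changepoint is
  zero and the profile diverges to +∞ there, so the fit is exact.
- At τ*, the remaining parameters follow in closed form:
  λ* = Cov[L, Λτ*]/Var[Λτ*], Λ0* = mean(L) − λ*·mean(Λτ*),
  σ²* = Var[L − Λ0* − λ*·Λτ*]. The additive constant of the profile is
  dropped; only differences in τ matter.
- The profile is invariant to adding a constant to L or rescaling lengths
  by a positive factor (Λ0 absorbs both); this is property-tested.
- The test suite cross-checks the Laplace step against a brute-force
  numerical marginalisation of Var^((1−T)/2) over λ on small instances
  (T ≤ 12); the two argmaxes agree within one grid step.

The series entering the fit is assembled like the induction series: summed
descendant length from the switch until total length has tripled since the
switch or a descendant is lost. A cell that never triples and whose best
fit sits at the upper grid boundary is `non_resumed`; a cell whose branch
is lost before tripling is `washed_out`. Logs are natural throughout;
growth rates convert to doubling times as ln 2 / λ.

Quality-control fits of single cell cycles (log-length OLS against time,
returning rate, Pearson r and predicted birth length) use at least three
points; constant-length input returns slope 0 with r = NaN as a degenerate
flag.

## Transcriptional memory

The number of reporter molecules a cell inherits from an induced ancestor
is estimated by pure dilution: Lm/2^nd, where Lm is the lineage's maximum
fluorescence within the first-exposure window and nd the number of
divisions strictly between that maximum and the focal observation. The
estimate is a lower bound — it assumes no degradation and even partitioning
and corrects for neither photobleaching (which biases it down) nor
stochastic expression during the gap (which biases it up).

Cells are stratified into 8 log-spaced inherited-molecule bins with edges
{0–1, 1–3, 3–10, 10–30, 30–100, 100–300, 300–1000, >1000}; the group count
is standard but the edges are this package's choice. Empty bins are
reported as missing, not zero. Fluorescence comparisons between short- and
long-lag cells first subtract each experiment's mean (day-to-day offsets
exceed the few-molecule signal) and then use a one-sided Welch t-test
(short > long); identical constant groups return p = 0.5, the exact
exchangeable answer, where the t statistic is 0/0.

The FLCS GFP-positive call requires all three criteria at once: brightness
at least 2.375× the cohort CPM median (the 5-sigma point of the normalised
CPM distribution), diffusion time within 3–30 ms, and fitted particle
number N ≤ 20. Fit-validity failures (diffusion time out of range, N > 20)
are classed `dubious`; a valid fit that only misses the brightness
threshold is `gfp_negative`. The upstream photon-stream processing is out
of scope; the classifier consumes already-fitted (CPM, τD, N).

## Population-lag simulation

A lag distribution is discretised into 100 equally weighted subpopulations
at the empirical quantiles of the midpoint probabilities (i − ½)/100. Each
subpopulation grows in discrete 1-min steps, multiplying by 2^(step/Td)
per step (exact exponential on the grid, Td = 49 min before and 58 min
after the switch), holds constant from the switch until its lag has
elapsed, then regrows. Initial sizes are irrelevant because nutrient
effects on rate are ignored; they are fixed at 1.

The population lag is the time shift between the summed curve and a no-lag
reference, extracted at the final simulated size by log-interpolating the
reference's time-at-size; the shift must be constant to within one step
over the last 10% of the curve, otherwise the simulation is too short and
an error is raised. After all subpopulations have resumed the summed curve
is an exact shift of the reference, which gives the closed form

    Δ/Td = −log2( Σᵢ wᵢ·2^(−τᵢ/Td) ),

used as an oracle: with off-grid lags rounded up to the next step, the
simulated lag can exceed the closed form by at most one step. The lag in
"doublings lost" is Δ/Td with the post-switch doubling time. It is always
at most the mean lag (Jensen: exponential growth favours early resumers)
and independent of the pre-switch rate, which cancels between the curve
and its reference.

## Diauxie plate curves

Per well, the background is the lowest mean among sliding windows of 10
consecutive absorbance measurements whose coefficient of variation
(sample SD over mean) is below 0.02; wells with no qualifying window are
flagged and excluded. OD = absorbance − background, and each curve is
shifted so its linearly interpolated first crossing of OD = 0.01 is at
t = 0. First-passage maps t = f(OD) interpolate between the samples where
the running maximum increases, so later dips are ignored. Delay curves are
the difference of replicate-mean f(OD) between a condition and the same
condition with IPTG (fully induced, hence no lag), with the two groups'
standard errors combined; the OD grid is restricted below 90% of the
smallest per-curve maximum (carrying-capacity cutoff, default 200
log-spaced points).

The population lag is read off the delay plateau. Plateau detection is
automated (originally done by eye): the delay is smoothed with a 5-point
centred moving average and differentiated with respect to log OD; plateau
candidates are the interior-80% grid points whose |derivative| lies within
2% of the interior range of its minimum, and the candidate at the largest
OD is returned. The largest-OD rule matters because the delay is also flat
at zero below the glucose-exhaustion OD; the population lag is by
definition the delay once every subpopulation has resumed, i.e. the
terminal plateau. A monotone or constant derivative means no identifiable
plateau: a warning is emitted and the endpoint value returned. Manual
transfer experiments instead report the interpolated first time OD exceeds
its starting value by 0.001 (censored when never exceeded).

## Sensorless survey

Under Poisson copy-number fluctuations the zero-copy fraction at mean m is
e^(−m); at m = 3 it is 0.0498 ≈ 5%, so "mean ≤ 3 copies/cell" (inclusive)
is the sensorless-condition criterion. Per sensory system, the number of
conditions whose sensor-kinase mean is at or below 3 is counted and
systems with ≥ 6 such conditions are flagged; regulator-only systems are
summarised by the same operations with the role switched. Bursty
(super-Poissonian) expression would only increase zero fractions, so the
Poisson assumption is conservative; an overdispersed variant is not
implemented.

## Synthetic data: what it emulates, and what it does not

The trace generator simulates mother-machine lineages through a
glucose-to-lactose switch at 3-min sampling: 49-min doubling before the
switch, 58-min after, a complete growth arrest at the switch, and division
by a deterministic size-doubling trigger with length halving (adder-like
corrections are not modelled). With probability 0.30 a cell holds a
nonzero basal reporter count (1 + Poisson(4), mean 5 molecules — matching
the few-molecule shift measurable between short- and long-lag cohorts) and
draws a short lag from a normal(25, 8²) truncated to (5, 50) min;
otherwise it is sensorless and draws a lag uniform on (60, 180) min. The
mode boundaries and the 30/70 split are constrained by observation; the
within-mode shapes are this package's choice. After the lag the lineage's
total reporter count ramps linearly at 30 molecules/min to a full
induction level of 4000 (within the observed 3000–6000 range) and is
apportioned to cells in proportion to length, so counts partition at
division and the lineage total follows the deterministic ramp exactly.
Observed lengths carry multiplicative noise (CV 0.02) and observed
fluorescence adds Gaussian autofluorescence noise (SD 20 molecules).
Wash-out is emulated only as optional right-censoring of post-switch
branches (off by default).

Dilution lineages chain lactose → glucose → lactose: full induction during
the first exposure (which ends exactly at the ramp peak, so the lineage
maximum is attained at a unique timepoint), expression off and counts
halving (or binomially thinning) at each division during the gap, and a
second-switch lag that is short iff at least one molecule was inherited —
with fully diluted cells reverting to the naive stochastic rule, which is
what makes the sub-molecule stratum reproduce the naive short-lag
fraction. Plate curves grow on glucose from OD 1e-4 to exhaustion at
OD 0.05, arrest per subpopulation, regrow on lactose to a 0.5 carrying
capacity at 2-min sampling, with multiplicative OD noise above an additive
baseline; these OD anchors are generator choices that leave a wide plateau
window below the capacity cutoff. The paired IPTG-control set is identical
with all lags zero.

With all noise set to zero every observable is an exact closed-form
function of the scenario, runs are bit-reproducible given a seed, and
ground truth (true lags, basal and inherited counts, division counts) is
always emitted alongside. None of the generators emulate imaging
artifacts, bleaching, gradual medium transitions, growth-rate dependence
on nutrient concentration, or adder-type division control — so passing
recovery tests demonstrates correctness of the estimators under the stated
noise model, not robustness to every failure mode of real microscopy data.

## Problem sizes

The test suite and the acceptance script use cohorts of 200–300 lineages,
50 random mixtures for the population-lag oracle, 40 lineages per dilution
gap and 3 plate replicates per curve set; these sizes put binomial
standard errors comfortably inside the asserted tolerances while keeping a
full run in the seconds-to-a-minute range.
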