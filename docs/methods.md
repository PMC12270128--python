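# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations behind `microtunnel`.

## Signal model and detection

Extracellular traces are modelled as white Gaussian noise plus stereotyped
spike waveforms. The noise scale is estimated as `median(|x|) / 0.6745`, the
standard MAD estimator in extracellular sorting: on the fixtures it is
within 5% of the true S.D. and moves < 2% when large spikes are added, so
all thresholds can be quoted in noise-S.D. units. Band-pass filtering is a
4th-order Butterworth applied forward-backward (`sosfiltfilt`), so spike
times do not shift (≤ 1 sample on the fixtures); the 300–3000 Hz default
passband is the conventional extracellular spike band.

Detection finds peaks of |x| at either polarity, time-stamped at the
extremum. Tunnel electrodes use two amplitude bands, 5–50 and 50.1–500 S.D.
(axonal spikes in microchannels can be enormous because the channel
concentrates current); wells use a single ±3.5 S.D. threshold to match
their poorer SNR. A 1.5 ms refractory period is enforced per electrode by
keeping the larger-amplitude event of any closer pair. Waveforms are cut
0.6 ms before to 1.0 ms after the extremum and stored in S.D. units.

**Complex (multi-axon) spikes.** Overlapping waveforms from two axons in one
tunnel must not contaminate templates. Two rules flag them: (i) two *kept*
detections whose waveform windows overlap in time are both flagged; (ii) a
detection suppressed by the refractory rule flags the survivor if it has the
same polarity and rises at least the detection threshold above the
inter-peak valley of |x| — i.e. it was a threshold-worthy event in its own
right. The valley condition matters: without it, noise ripples riding the
flank of one broad waveform are mistaken for second events (on wide
templates this false-flagged roughly a third of spikes), while the
opposite-polarity exemption keeps the two lobes of one biphasic waveform
from flagging themselves.

**Clustering** is leader–follower template matching: each non-complex spike
joins the nearest running-mean template within 3 S.D. RMS distance (the
field's stated inclusion rule; the wide tolerance absorbs variable
axon–electrode coupling of one axon) or seeds a new cluster. This replaces
heavier sorter machinery on purpose: with single-axon tunnels and
single-electrode units, the 3 S.D. rule is the only criterion that matters,
and the procedure is deterministic in time order.

## Tunnel directionality

Spikes on the two tunnel electrodes are paired one-to-one within a ±1 ms
window (the maximum valid conduction delay). The pairing is the exact
minimum-cost maximum-cardinality matching, computed per window-connected
component with the Hungarian algorithm; components are split wherever
consecutive events across both trains are > 1 ms apart, so each subproblem
has a handful of spikes and the whole pass is linear in practice. A greedy
closest-first matcher was considered and rejected: it is not always
maximum-cardinality (two interleaved pairs can starve one spike), whereas
the exact matching provably equals the brute-force optimum — the test suite
verifies this against an independent dynamic-programming oracle on dense
random instances.

The **normalized matching index** `NMI = #pairs / max(n_a, n_b)` (0 when
both trains are empty) measures how completely the two electrodes see the
same axon; `NMI > 0.2` (strict) is required for a valid single-axon tunnel,
which suppresses spurious pair correlations at high rates.

Signed delays (downstream − upstream) are histogrammed over ±1 ms in
0.04 ms bins (one sample at 25 kHz). A peak must contain ≥ 5 pairs and have
prominence ≥ 20% of the pair count; the reported delay is the
count-weighted centroid of the peak ± 2 bins, giving sub-bin accuracy
(median error ~0.004 ms on the synthetic fixtures, against a 0.08 ms
budget). Validity additionally requires the peak magnitude to lie in
0.2–1 ms — the plausible single-axon conduction range for a 400 µm tunnel;
the same window is applied to the longer (400–600 µm) EC–CA3 diagonals, with
a per-tunnel override available in the layout parameters.

Direction: the delay sign gives the travel direction through the declared
tunnel orientation; travel in {EC→DG, DG→CA3, CA3→CA1, CA1→EC, EC→CA3,
EC→CA1} is feed-forward, everything else feedback. EC→CA1 is deliberately
classified feed-forward: it is an excitatory (temporoammonic-like)
projection even though it runs against the CA1→EC tunnel orientation.

## Interval dynamics

ISIs are consecutive differences of a sorted train. Bursts are maximal runs
of consecutive ISIs strictly below 50 ms containing at least 4 spikes
(strict inequality, matching the definition's wording — a 50.0 ms spacing
does not qualify). IBIs default to end-of-burst → start-of-next-burst;
onset-to-onset is available (`mode="onset_to_onset"`) since the gap
definition is a genuine convention choice. Burstiness is the fraction of a
unit's spikes inside bursts; `fr_burst` counts units above 50% burstiness
and normalizes by the number of arrays (a per-array count, following the
figure-level convention rather than a double-normalized fraction).

**CCDs.** Intervals are summarized as complementary cumulative
distributions P(T ≥ t) on 50 logarithmically spaced bins spanning the data
range (bin count is a convention; 50 gives ~25 bins per decade over two
decades). The first bin is pinned to the smallest interval and P is
normalized there to exactly 1. Bin endpoints are assigned exactly rather
than trusting `logspace` rounding — a 1-ulp excess at the first bin
silently drops the minimum sample from the normalizing count and shifts
every probability by 1/n.

**Fits.** A line is fitted to (log10 t, log10 P) by least squares inside a
window; both window limits are grid-searched over ±50% in 5% multiplicative
steps and the window with maximal Pearson R² wins, ties going to the widest
window (so noise-free power laws return the full nominal window with
R² = 1, and the estimate is scale-equivariant: rescaling all intervals
changes c, never m). ISI fits are restricted to probabilities 1 → 0.1,
where the power law holds before finite-size truncation bends the tail.
Default ISI windows: 0.01–0.2 s, with CA1–EC overrides (0.01–0.11 s
feed-forward, 0.01–0.09 s feedback) to avoid known non-linearities; all
windows are layout-parameter overridable for other designs.

**Two-piece IBI fits.** IBI CCDs show a fast ("up state") and a slow
("down state") regime. The fast line covers bins below a shared boundary,
the slow line bins above it; the boundary is grid-searched (±50%, 5% steps,
defaulting to the geometric midpoint of the bin range) jointly with the
outer limits, maximizing the mean of the two R². The POI (position of
intersect) is `10^((c_slow − c_fast)/(m_fast − m_slow))`, flagged unstable
when the slopes differ by < 0.05 (the intersection is then numerically
meaningless; a noise-free single-regime CCD yields equal slopes and an
unstable flag). The boundary convention follows the geometrically coherent
reading — fast fit at short intervals, slow fit at long intervals, sharing
one boundary.

## Group statistics

Slope comparisons pool each group's CCD points inside its fit window and
fit `log10 P ~ log10 t × group` by OLS; the interaction F tests slope
homogeneity at α = 0.05, partial η² = SS_effect/(SS_effect + SS_error) is
reported per effect, and pairwise slope contrasts are adjusted with Tukey's
HSD via the studentized range distribution. For two groups the interaction
F provably equals the squared classical two-sample slope t statistic (the
suite checks agreement to 1e-8 relative). Under a simulated null with
independent points the empirical type-I rate is ~5% at α = 5%.

Treating CCD bins as independent observations mirrors the fitting domain
but overstates the effective sample size — adjacent bins of a cumulative
curve are strongly dependent — so these p-values rank contrasts rather than
calibrate error rates; this is documented rather than silently corrected.
Burstiness distributions are far from normal, so groups are compared with
the tie-corrected Kruskal–Wallis test (H = 0, p = 1 on identical constant
samples). Percent slope differences are
`100 · (|m_other| − |m_ref|)/|m_ref|`, positive when the other group is
steeper ("faster").

## The synthetic generator

The generator emulates exactly the statistical structure the analysis
assumes, with every parameter recorded as ground truth:

- **Interval law.** P(T ≥ t) = (t/t_min)^m on [t_min, t_max]; the residual
  tail mass (t_max/t_min)^m sits as an atom exactly at t_max. This is the
  unique distribution whose CCD is *exactly* log-log linear over its whole
  support, which makes slope recovery well-posed: the continuous truncated
  Pareto (available via `truncation="pareto"`) bends its CCD near t_max and
  biases the fitted slope by up to −85% at m = −0.5 over a 20× range.
  Conditioned below t_max, the atom law *is* the truncated Pareto, which is
  how its sampler is KS-tested. Default ISI law: m = −1.5 on 0.01–0.2 s
  (typical axonal values over the standard fit window).
- **Bursts.** Fixed-shape bursts (default 5 spikes at 10 ms) satisfy the
  burst definition by construction; gaps follow a two-regime broken
  power-law survival function — fast slope below a crossover t_x, slow
  slope above, tail atom at the upper limit — so the IBI CCD is exactly
  piecewise log-linear with the POI at t_x. A free-weight mixture of two
  disjoint truncated laws cannot do this (its fast segment flattens toward
  the mixture floor, shifting the apparent slope by the weight), so the
  fast-regime mass w and the crossover are tied:
  w = 1 − (t_x/t_min)^m_fast. Supplying `mixture_weight` relocates the
  crossover accordingly. Defaults: fast m = −1.5 on 0.2–2 s, slow m = −0.5
  on 2–20 s, the canonical 0.2–20 s IBI range.
- **Tunnel pairs.** Upstream spikes are copied downstream at the signed
  conduction delay (positive for feed-forward travel), with Gaussian jitter
  (default S.D. 0.05 ms, small against the 0.2–1 ms validity window),
  independent Bernoulli detection per electrode (default 0.9) and
  homogeneous Poisson noise spikes (default 0.5 Hz) per electrode. Delays
  are drawn uniformly from the valid 0.2–1 ms window; feed-forward
  probability defaults to 0.7 (feed-forward axons dominate in these
  cultures).
- **Traces.** Optional rendering places a biphasic 1.2 ms template (peak
  normalized to 1) at the nearest sample to each spike on white Gaussian
  noise; closer-than-template spikes simply sum, which is how the
  complex-spike discard is exercised. 25 kHz default sampling.

What the generator does **not** emulate — and hence what green tests do not
establish about real recordings: correlated network activity across
electrodes, non-stationary rates, electrode drift, waveform variability
within an axon, colored noise, multi-axon tunnels with more than two units,
and any coupling between a unit's ISI law and its burst structure (the two
are composable but independent layers here). Recovery rates quoted by the
validation experiments are upper bounds that real data will not reach.

## Problem sizes and tolerances in the validation experiments

Slope recovery is measured at n = 10⁴ intervals (bias ≤ ~2.5% across
m ∈ {−0.5, −1, −1.5, −2}, against a 5% budget). Two-regime recovery is
measured at 5000 bursts in the acceptance script: at the 10³ bursts used in
the unit test, the fast segment (probability 1 → 0.3, ≈ 7 log bins) is
shot-noise limited and individual seeds can stray near the ±15% budget even
though the noise-free fit is exact. Direction recovery uses 200 tunnels of
300 spikes (≥ 95% correct required; observed ≈ 99%). The ANCOVA null
simulation uses 1000 replicates (observed ≈ 5% type-I at α = 5%, budget
7%). Determinism is checked as byte-identity of rerun output bundles; all
generators consume a single `numpy.random.Generator` in a fixed order, and
all tables are written with exact shortest-round-trip float text.

## Known limitations

- Units are per-electrode merged trains; no multi-electrode unit merging or
  drift correction (single-electrode units suffice for tunnel analysis).
- R²-maximizing window search on *noisy* short CCD segments prefers
  straighter sub-windows, inflating variance when a regime spans few bins;
  use more data or wider regimes rather than trusting single-unit two-piece
  fits at small burst counts.
- The POI stability flag is a slope-separation heuristic (threshold 0.05),
  not a confidence statement.
- ANCOVA p-values on CCD bins are anti-conservative (see above).
- The well-electrode path analyses each electrode as one unit and performs
  no spike sorting beyond thresholding, appropriate when single neurons
  dominate each electrode.
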