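# Methods

`atcq` simulates and analyses dual-reporter single-cell time-lapse data for
quantifying cellular quiescence. The two reporters are the G0 sensor
mVenus-p27K⁻ (a fluorescent fusion to a CDK-binding-defective p27 mutant
that accumulates in quiescence and is degraded at the G0–G1 transition and
in S/G2/M) and the G1 sensor mCherry-hCdt1(30/120) from the FUCCI system
(present in G0/G1, degraded at S-phase entry). Read together they partition
a cell's life after mitosis into four observable states:

| Venus | Cherry | state    | interpretation                         |
|-------|--------|----------|----------------------------------------|
| off   | off    | `DN`     | S/G2/M or the pre-onset newborn window |
| on    | off    | `V_ONLY` | early post-mitotic window              |
| on    | on     | `DP`     | the G0 decision window / quiescence    |
| off   | on     | `C_ONLY` | G1                                     |

The quantity of interest is the dwell time in the double-positive (`DP`)
window. A `DP` phase prolonged beyond 14 h is scored as **spontaneous G0**
(strict inequality, configurable); a `DP` phase of more than 4 h that ends
in G1 entry is **transient G0**. After each mitosis the two daughters are
scored jointly as synchronous G0, synchronous G1 (both enter G1 within a
1 h tolerance) or **asynchronous** (one daughter enters G1 while its sibling
remains in G0, or the entry times differ beyond tolerance).

## Reporter state machine (simulator)

A non-silent cycling cell born at `b` progresses through

    b → venus_on → cherry_on → venus_off → cherry_off → division

with Venus onset delay, Cherry onset delay, `DP` dwell
(`venus_off − cherry_on`), G1 duration and S/G2/M duration drawn from
per-condition distributions. Each division produces exactly two daughters
whose fates are coupled by the pair categories:

* `SYNC_G0` — both dwells from the prolonged distribution
  (support > 14 h); these cells stay double positive through the end of
  observation (no Venus off, no further division).
* `SYNC_G1` — both transient, with *G1-entry times* (birth + onset delays
  + dwell) within 0.5 h of each other.
* `ASYNC` — the siblings' G1-entry times differ by `Δ` from the
  asynchrony-delta distribution.

Synchrony is defined on entry times, not dwells: each daughter draws its
own onset delays, and the lagging daughter's dwell absorbs the onset
difference so that the realized entry gap equals the drawn `Δ` (or stays
within tolerance for synchronous pairs). The lagging sibling's label
follows its realized dwell: in conditions with wide deltas (NIH/3T3,
Δ ∈ 1–15 h) it can cross 14 h, generating the observed "G0 entry followed
by exit" trajectory family.

Founder cells take the fate of one randomly chosen daughter of a virtual
pair, so the per-cell marginal probability of a dwell beyond 14 h equals the
profile's `p_spontaneous_g0` exactly when

    p_sync_g0 = p_spontaneous_g0 − 0.5 · p_async · P(d + Δ > 14 h).

Shipped profiles encode the measured conditions (all parameters
overridable by key; durations in hours):

| profile | onset delays | transient dwell | spont. G0 | async (Δ) |
|---|---|---|---|---|
| `pc3_hotel` | U[1.5,2.5] + U[1.5,2.5] | U[2.5,5.5] | 27.5 % | 30 %, U[1,6] |
| `pc3_plate` | as hotel | as hotel | 20 % | 30 %, U[1,6] |
| `t3t3_fullserum` | U[2,4] + U[3,4] | U[5,10] | 64.4 % | 30 %, U[1,15] |
| `t3t3_lowserum` | as 3T3 | as 3T3 | 90 % | 10 %, U[1,15] |

Prolonged dwells are `15 + Exponential` (scale 8–25 h by condition), so the
prolonged/transient split never straddles the 14 h threshold. PC3 cycle
phases are not printed anywhere; G1 ≈ 10 h and S/G2/M ≈ 12 h were chosen to
give a doubling time of ~30 h, consistent with "similar to parental PC3".
Reporter intensities are piecewise-linear ramps (3 h rise and fall by
default); only the ordering and approximate durations of the rises and
falls are constrained by observation, and ramps make event-time estimation
transparent. Whether reporters keep accumulating during prolonged G0 is
ambiguous in the source data; a plateau is used.

Serum-free endpoint cohorts are modelled separately: `serumfree_from_g1`
starts with Cherry already on and Venus rising after a broad U[6,48] h
delay; `serumfree_from_sgm` founders are past the restriction point, finish
the cycle (residual S/G2/M ~ U[1,12] h), divide once, and both daughters
arrest double positive. The non-double-positive remainder at 72 h (10 % /
15 %) is modelled as clonal reporter silence (`p_reporter_silent`), with no
mechanistic claim.

Treatment presets (`pc3_gas6`, `pc3_tgfb2`, `pc3_gmcsf`) encode only the
directional effects of the dormancy signals: Gas6 and TGFβ2 raise
synchronous G0 entry; GM-CSF raises synchronous G1 entry among dividers;
all three reduce the fraction of founders that commit to division (a
founder-level `founder_p_g0` override, decoupled from the daughter pair
probabilities because treatment at t = 0 acts on uncommitted cells while
already-committed cells still divide); Gas6 additionally lengthens
transient dwells (U[5,10]) and asynchrony deltas (U[2,15]). Magnitudes are
configurable.

### Motion and rendering

Cells move as an isotropic Gaussian random walk (`motility_sigma`
px/frame; 0.4 for hotel-like confinement, 0.8 for plate imaging) with a
short-range pairwise repulsion that keeps centroids about one cell diameter
apart (volume exclusion). Without exclusion, progeny random-walk into
permanently unresolvable clumps (centroids 1–3 px apart at a 2 px PSF),
which no segmenter could separate; adherent cells do not interpenetrate.
Daughters start one spot radius from the parent centroid in opposite
directions along a random axis. Positions clamp at the image borders.

Rendering draws each live cell as an isotropic Gaussian spot (PSF σ = 2 px)
with amplitude `basal + level × peak` per channel, over a flat background
(100 counts), with Poisson shot noise and Gaussian read noise, clipped to
16 bit. The basal intensity (3 % of the 10 000-count peak, in both
channels) is the minimal assumption that keeps reporter-negative cells
detectable without a constitutive nuclear marker. Default geometry: 72 h at
0.5 h per frame (the imaging interval range is 20–30 min), 256×256 px
fields. Identical inputs and seed give bit-identical stacks.

## Detection

Per frame: subtract the per-channel background (image median — robust while
spots cover a minority of pixels, and unbiased under symmetric noise, which
matters because the detection threshold is expressed in noise sigmas);
sum the channels; smooth (Gaussian, σ = 1 px); threshold at `k = 5` robust
noise sigmas (MAD) of the smoothed image. Otsu thresholding is available as
an alternative rule but is not the default: with bright reporter spots in
the frame, Otsu lands far above the basal level and dark cells disappear,
which breaks division linking. Touching objects are split by watershed with
markers at intensity peaks (≥ 3 px apart): adjacent dim and bright spots
keep distinct intensity maxima where the distance transform of their merged
mask does not. Objects outside `[min_area, 50·min_area]` (with
`min_area = round(π σ²/2)`) are rejected. Centroids are intensity-weighted
(sub-pixel); per-channel means/totals are background-subtracted and clamped
at zero. Segmentation of a frame is a pure function of its pixels.

## Tracking

Frame-to-frame linking is an optimal (Hungarian) assignment on centroid
distance with an 8 px gate (a greedy variant is available). Track ends may
be joined to later starts within `max_gap = 4` frames (~2 h — newborn cells
turn Venus on ~2 h after cytokinesis, so dark gaps are short given basal
signal). Divisions are recovered two ways: an ended track adopting two new
starts, and the common case where the linker silently continued the parent
into one daughter — a new start beside a continuing track splits that track
into parent + two daughters. Candidates are scored by the *minimum*
distance between the new start and the candidate parent over a
`max_gap+1`-frame lookback (a newborn appears near the pre-division parent
centroid even after a few undetected frames) inside a 6·σ_PSF radius, and
adopted greedily without overlap. Tracks shorter than 6 frames are excluded
from classification and counted.

## Classification

Each channel of a per-track trace is smoothed (moving median, 1.5 h),
normalised by its 95th percentile — per-trace, because absolute reporter
intensity varies from cell to cell even in clonal lines — and binarized
with hysteresis (on > 0.25, off < 0.15 of normalised amplitude); runs
shorter than 1 h are merged away. When a cohort is classified together, an
absolute normalisation floor (40 % of the cohort's 95th-percentile trace
maximum, per channel) stops reporter-silent traces from being normalised up
into noise-driven "on" calls. Each on/off edge is then refined by locating
two level crossings (0.15 and 0.5) and extrapolating the linear edge back
to its start, so boundaries estimate the *onset of the rise* and the
*start of the fall* — the event-time convention of the simulator — and the
measured `DP` dwell is unbiased regardless of ramp durations (on noiseless
traces, boundaries land within ±0.2 h of the true event times).

For between-cell timing comparisons (daughter-pair deltas) the G1-entry
landmark is the mid-level crossing of the Venus fall rather than the
extrapolated fall start: the constant mid-to-start offset cancels in the
sibling difference, and the mid crossing carries several-fold less noise.
Falling-edge levels are measured relative to the run's own plateau so that
per-trace normalisation differences between cells do not shift edge times.

The scored `DP` phase is the first one immediately preceded by `V_ONLY`
(the post-mitotic pattern). Traces that begin inside `DP` are
left-censored and withheld. Cells still double positive at the end of
observation are spontaneous if the observed dwell already exceeds 14 h and
otherwise undetermined. Canonical-order violations are flagged, never
silently fixed.

### Censoring policy

Population percentages use only cells with at least `min_followup_h = 24 h`
of potential observation from birth (the same window is the denominator for
percent-divided, since the source denominator is unstated). This makes the
estimate unbiased: any gated-in cell still double positive at movie end has
necessarily been so for > 14 h, so spontaneous and transient fates are
resolvable for every counted cell. Without the gate, late-born cells
censored inside a short `DP` are dropped while their late-born G1-entrant
siblings are kept, deflating the spontaneous percentage by several points.
Daughter pairs from divisions later than `duration − 24 h` are
`UNDETERMINED` for the same reason. A sibling "censored in DP" counts as
the G0 partner of an asynchronous pair only if it had been double positive
for ≥ 4 h when its sister entered G1 *and* its trace reaches the end of the
observation window — a track lost mid-movie is not evidence of asynchrony.

## Group comparison

Dwell-time distributions are compared by two-sided Mann-Whitney U with
midranks for ties: exact enumeration of all group relabelings when the
combined sample size is ≤ 20 (the printed comparisons are small), otherwise
the normal approximation with tie and continuity corrections.

## Statistical design of the recovery experiments

The recovery experiments are clustered censuses: all descendants of one
founder share an imaging field, and sibling fates are correlated by the
pair-category draw, so the sampling error of a pooled percentage is larger
than binomial at the cell-level `n` (measured field-level overdispersion is
~1.6× binomial at the generator level, before any imaging or analysis).
Recovery checks therefore use a field-level ratio-estimator (cluster-robust)
standard error; frozen-seed statistical tests use 99 % bands so the design
false-alarm rate stays low.

Problem sizes: the test suite runs 24 ten-founder fields per pipeline
condition; `scripts/acceptance.py` runs 250 founders × 3 seeds per pipeline
condition and 1 000-cell cohorts × 3 seeds for the serum-free endpoints.

## What the synthetic data does and does not emulate

Emulated: reporter onset/degradation ordering and time scales, dwell-time
heterogeneity, coupled daughter fates and their asynchrony, censoring by
movie end, asynchronous population structure (founders born up to one cycle
before the movie), shot/read noise, basal signal, cell motility with volume
exclusion, confluence-free densities.

Not emulated: photobleaching, focus drift, 3-D optics, cell-shape changes,
segmentation-relevant texture (cells are Gaussian spots), apoptosis, cells
entering or leaving the field, microfluidic chamber walls beyond low
motility. Passing recovery tests therefore demonstrates that the analysis
chain is unbiased for spot-like, in-focus, non-crowded data — not that it
would meet the same accuracy bars on arbitrary real movies; the
plate-imaging profile in particular uses a motility at which automated
tracking is still reliable, whereas genuinely fast cells may require
confinement or manual curation.

## Known limitations

* Scorability differs slightly by pair category (an asynchronous pair can
  be scored from one entry plus a verified G0 sibling, while synchronous G1
  needs both entries), which can shift the scored-pair composition by
  ~1–2 percentage points at 72 h.
* Dwell percentages are census fractions, not survival estimates; no
  Kaplan-Meier/Cox machinery is applied to censored dwells.
* The Venus/Cherry onset-delay distributions are uniform readings of the
  reported ranges; real delay distributions are unknown.
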