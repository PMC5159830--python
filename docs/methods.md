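# Methods

## Grid model and coordinates

The coverslip grid is an `n_rows × n_cols` array of squares of side
`square_size_um` (defaults 133 × 133 × 150 µm = 17,689 squares, sized so
one square fills a 40× field of view). Coordinates are µm from the grid's
top-left corner, y downward (image convention). Square addresses are
`"R###C###"` strings; `locate(x, y)` uses half-open squares
`[x0, x0+s) × [y0, y0+s)` with the far grid edges closed, so every in-grid
point has exactly one address. An imaged *region* is identified with one
grid square throughout.

## Perifusion protocol and trace model

A protocol is a contiguous sequence of (condition, level, start, end)
segments in minutes, starting at 0. The reference NAD(P)H protocol is
glucose 3 mM (0–20), 20 mM (20–70), 3 mM (70–115), KCN (115–135), FCCP
(135–155); the calcium protocol is glucose 4/20/4 mM over 0–20–70–110 min.
Segment lengths were chosen so the 35–45 min steady-state windows fit
inside the high-glucose and post-return segments and the calibration
agents get ≥ 15 min before their read-out windows (first-order residual
e^(−15/3) ≈ 0.7% of the step).

Each synthetic cell carries plateau parameters (baseline RFU, KCN ceiling,
FCCP floor with `KCN > FCCP ≥ 0` by construction), a true response (% of
the KCN–FCCP span, or ratio units for calcium), a drift slope and a noise
sd. The noiseless signal relaxes toward the active segment's plateau with
one first-order time constant (default 3 min; 0 = instantaneous); the
stimulated-glucose plateau is `baseline + response/100 · span`. On top of
this, `drift · t` and i.i.d. Gaussian read noise are added. Sampling is
every 120 s from t = 0. A sample taken exactly at a condition switch shows
the previous plateau: the first-order solution is continuous across
segment boundaries, and the instantaneous-kinetics branch preserves that
limit (this also keeps the closed baseline window uncontaminated by the
switch sample).

## Generator defaults (the emulated experiment)

- 227 cells = 183 beta + 32 alpha + 12 hormone-negative ("other"), the sum
  of the reference per-type counts, over 10 regions; exact-quota type
  assignment by default (largest remainder, shuffled), multinomial
  optional.
- Response distributions: beta N(27, 12.2)%, alpha and other N(−5, 9.1)%;
  sds are the composite SEMs scaled by √n (0.9·√183, 1.6·√32). Calcium:
  54 cells (40 beta / 14 alpha, 2 regions), N(0.33, 0.054·√40) vs
  N(0.051, 0.013·√14) ratio units. Optional truncation bounds give
  disjoint-support populations.
- Signal scale: FCCP floor ~N(50, 10) RFU clipped ≥ 0, span ~N(450, 40),
  baseline ~N(280, 30) clipped into (floor, ceiling).
- Drift slope ~N(0, 0.01 RFU/min) and read noise sd 2 RFU per sample.
  These are not reported quantities; they were fixed once at values
  appropriate to a cooled CCD at 200 ms integration (total drift over a
  155-min run ≈ 0.3% of the calibration span, per-sample noise ≈ 0.4% of
  span) and are config knobs.
- Geometry: cells placed by rejection sampling with a 15 µm hard minimum
  spacing and 10 µm edge margin (cell radius 7.5 µm). Staining centroids
  are live centroids + a rigid between-session offset (default (3, −4) µm)
  + Gaussian jitter (sd 2 µm); the stain record's square address is read
  off the grid at the stained position, so a cell jittered across an
  etched line lands in the neighbouring square exactly as it would to the
  eye.
- Staining: type-determined positive channel ~N(900, 120) a.u., negative
  channels |N(0, 15)|, threshold 100. "Other" cells never stain;
  `unstained_fraction` silences a quota of hormone-positive cells;
  `co_stain_fraction` makes a quota of stained cells double-positive
  (default 0 for both).

What the generator does **not** emulate: photobleaching, shot-noise
statistics, point-spread blur, focus drift, cell movement or death,
segmentation error, and spectral bleed-through between stain channels.
Passing tests therefore demonstrate correctness of the analysis given
faithful ROI traces and stain intensities, not robustness to those imaging
pathologies.

## Response scoring

Steady states are arithmetic means over closed windows; with 120-s
sampling the 35–45 min windows hold 5–6 samples. Default windows: baseline
= last 10 min of the initial glucose segment; high-glucose and post-return
(or "stimulated" for calcium) = 35–45 min after the respective transition;
KCN/FCCP = last 5 min of each calibration segment.

Normalization maps each cell's FCCP plateau to 0% and KCN plateau to 100%;
it is affine-invariant, so camera gain and offset cancel. Cells whose
measured KCN plateau does not exceed their FCCP plateau are flagged
(`degenerate_calibration`), excluded, and counted — never silently
dropped.

The NAD(P)H statistic is `min(Δup, Δdown)` as defined in the README. The
"minimum change" wording admits other readings (e.g. the smaller absolute
change); the signed-toward-the-high-plateau reading is used because it is
the one that makes the statistic conservative under drift, which is the
stated purpose; both component deltas are retained in the response table
so alternatives can be recomputed. Two small intrinsic properties worth
knowing: (1) with noisy windows the min of the two deltas is biased low by
roughly σ_SS/√π (≈ 0.1–0.2% at default noise); (2) linear drift of either
sign reduces the statistic by |drift| × (time between the baseline and
post-return windows' centers), which is the intended conservatism. The
calcium statistic is the raw up-step ratio change (no down-step term and
no calibration, since the ratio is already an absolute readout and does
not fully return to baseline).

## Identity mapping

Matching is strictly per square — the fiducial grid guarantees square
correspondence between sessions, and cross-square matches are disallowed.
Per square, the rigid session offset is estimated by grid search over
± half a square side at 1 µm resolution, minimizing the summed squared
nearest-neighbour distance of shifted stained centroids to live centroids
(a k-d tree evaluates all ~22,800 candidate offsets in one query); empty
squares fall back to zero offset. After removing the offset, pairs are
accepted greedily in ascending distance order, one-to-one, up to a 10 µm
tolerance (≈ one cell radius; the reference work matched by eye and states
no tolerance). Greedy matching was chosen over optimal assignment for
transparency; an exhaustive minimum-cost oracle (`linear_sum_assignment`)
lives in the test suite and agrees with greedy in ≥ 99% of seeded trials
at realistic jitter. Labels: insulin-positive only → beta,
glucagon-positive only → alpha, neither → unclassified, both → ambiguous
(reported, excluded from type statistics), no match → unmatched.

## Distributions and error rates

Histograms are left-closed right-open with fixed widths (4% over 0–52% for
NAD(P)H, 0.1 over 0–0.7 for calcium) plus open-ended underflow/overflow
bins, because alpha-type responses are typically negative and must not be
dropped by a display range that starts at 0. SEM uses the sample sd (n−1).
A false positive is a glucagon-stained cell with statistic ≥ threshold, a
false negative an insulin-stained cell below it; the default threshold of
4% (one bin width) is motivated by the observation that no cell of a pure
beta-cell line responds below 4%, and is a config knob. Rates are relative
to each type's count of cells with a valid statistic; every exclusion
(unclassified, ambiguous, unmatched, failed calibration) is tallied in the
report.

## Numerical and design notes

- All randomness flows through `numpy.random.Generator`; every generator
  is bitwise-reproducible under a fixed seed, and the pipeline derives
  independent child streams for population, traces and staining from the
  run seed.
- CSV round-trips are lossless: shortest-repr float formatting on write
  and `float_precision="round_trip"` parsing on read.
- Window membership uses closed intervals with a 1e-9 min time tolerance
  at protocol boundaries.
- Throughput: `max_throughput(regions_per_second, cells_per_region) =
  regions_per_second · 60 · cells_per_region`. At the reference
  instrument's ~3 regions/s and ~20 cells/region this gives 3,600
  cells/min; the instrument's stated ~7,200 cells/min corresponds to the
  same formula at ~40 cells/region. The function implements the formula
  and takes no position on which reading is intended.
- Problem sizes in the shipped tests (a few hundred cells per replicate,
  ≤ 100 replicates, 1,000 matching trials) were chosen as the smallest
  sizes at which the statistical assertions are meaningful.

## Known limitations

- The within-cycle stage stagger (cells in later-scanned regions are
  imaged fractionally later) is modelled in the scan schedule but folded
  into the nominal cycle time point for analysis, as the live acquisition
  software does.
- The offset search assumes a rigid per-square translation; rotation and
  scale changes between sessions are not modelled or corrected.
- The min-change statistic's small negative bias under noise (above) means
  per-type means recovered from noisy data sit a fraction of a percent
  below the generator's response means; this is a property of the
  drift-robust estimator itself, not of its implementation.
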