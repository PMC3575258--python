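# Methods

This note records the models, conventions and design choices behind
`hdemgmap`, in the spirit of a statistical-software methods appendix: what
is computed, under which assumptions, and what the synthetic studies do and
do not demonstrate.

## Signal model of the synthetic generator

Monopolar HD-EMG channels a centimetre apart observe the same motor-unit
activity through volume conduction, so their signals are strongly
correlated and their RMS amplitudes form a smooth spatial field. The
generator reproduces this with a latent-source model: each activation blob
is one zero-mean Gaussian source band-limited to 15–350 Hz (4th-order
Butterworth, forward–backward), mixed onto the grid through its spatial
gain profile; a spatially uniform far-field source (default 1% of the peak
gain) models distant-muscle activity. Channel *i* is

    v_i(t) = sqrt(1-beta) * sum_b g_b(i) s_b(t) + sqrt(beta) * r_i o_i(t),

with `r_i = sqrt(sum_b g_b(i)^2)`, so the channel RMS equals the requested
profile for every decorrelation level `beta`. `beta = 0` is the fully
volume-conducted limit; `beta = 0.3` (task-simulation default) gives
adjacent-channel correlations near 0.85 and non-degenerate
single-differential signals. RMS contributions of independent sources add
in quadrature; where one blob dominates, the channel RMS equals the blob
profile to better than a percent.

Artifact classes follow the three failure modes seen in grid recordings:
`drift` adds a 1–4 Hz component, `powerline` adds 50 Hz plus four harmonics
(amplitudes decaying 1 : 0.5 : 0.3 : 0.2 : 0.15), both scaled so the added
RMS is `severity` times the clean channel RMS; `isolated_amplitude`
rescales the channel by `severity` (0.05 emulates a near-dead contact).

What the generator does **not** model: motor-unit action-potential trains
and their propagation (signals are Gaussian), innervation-zone phase
reversals, fatigue-related spectral compression, force–EMG dynamics, and
non-stationary artifacts. Passing tests therefore demonstrate the
correctness and calibration of the *pipeline*, not detector performance on
real recordings.

## The channel-quality rule set and its geometry

The detector uses the three-feature threshold system with defaults
`k1 = 11.2`, `k2 = 0.2`, `k_line = 2.5`, line cap 0.85, reference selection
at 1.5·IQR. Conventions the formulas leave open are fixed as follows:
the constant multiplies only the median term (`k*median + 1.5*IQR`; a
config switch scales the whole expression instead); the pair standard
deviation uses the n−1 convention (`|a-b|/sqrt(2)`); missing border
neighbours are mirror-padded; the rule direction is `below`
(`RMS < thresh_rms` flags), with `above`/`both` available — `both` adds an
upper bound reflected about the six-neighbour mean for channels with
abnormally *high* energy. Thresholds are frozen once per set (one-shot
cascade, no re-referencing).

A structural property of the amplitude rule matters for anyone applying it:
because the threshold is `min(pair means) + k2*max(pair stds)`, a channel
whose neighbourhood is statistically exchangeable with it (flat region,
independent channel noise) falls below the threshold ~30% of the time
*regardless of the noise scale*. High specificity is only achievable when
neighbour comparisons are nearly deterministic — that is, when channels
share sources (volume conduction) and the RMS field is smooth with at least
one locally non-increasing direction per channel. The QC benchmark
(`qc_benchmark_set`) therefore represents a single muscle whose activation
is a broad hump, concave across the full column range (sd 0.6× the column
count), with a gentle innervation-zone-style concave modulation along rows
on interior columns (straddle slack 6e-4) and flat rows on the two
outermost columns each side, whose mirror-degenerate neighbour pairs are
kept safe by exact within-column ties. Artifact sites avoid the rows
adjacent to the borders and the outer four columns, and no channel ever has
three corrupted neighbours, so every clean channel keeps one clean
decreasing pair. Severities (drift 0.5–0.8, powerline 0.65–0.85,
amplitude ×0.05) put artifacts clearly past the spectral thresholds while
inflating RMS by ≲30%, which bounds their perturbation of neighbours'
thresholds. Under these study conditions the precision-recall-tuned
constants (k2 in the 0.001–0.002 range on the tuning grid
{4, 7.1, 11.2, 16, 22} × {0.001, 0.002, 0.005, 0.01, 0.05, 0.2}) reach
specificity and accuracy ≥ 0.99 with sensitivity ≥ 0.90. On decorrelated
data (`beta > 0`) the amplitude rule over-flags by design of its formula;
in the full pipeline this only results in benign surface re-interpolation
of smooth maps, and is reported per condition (`n_flagged`).

Known limitations, stated plainly: border rows/columns of the array are
intrinsically fragile under mirror padding (their pairs collapse to inner
duplicates); high-amplitude isolated artifacts (`severity >> 1`) are not
caught by the default `below` direction and additionally inflate their
neighbours' pair stds; and clusters of three artifacts around one channel
can flag it spuriously.

## Maps, segmentation and spatial statistics

Maps use the mean over M = 6 epoch RMS values of the 12–350 Hz zero-phase
filtered signal (filtering applies to map computation only; detection
features use the raw monopolar signal with its own band definitions).
Flagged cells are replaced by Clough–Tocher cubic interpolation on the
Delaunay triangulation of the remaining electrodes (exact for planar
fields); cells outside the convex hull fall back to the nearest valid
neighbour. Replacement refuses to run when ≥50% of channels are flagged or
fewer than three clean channels remain.

The h-dome height is not fixed by theory; the default is
`h = 0.25*(max - median)` of the map, which scales across effort levels.
Fraction-of-range mode also gives the flat-map safeguard: a noise-only map
yields a ragged, single-pixel dome support that the radius-1 opening
removes (an *absolute* h larger than the map range would instead return the
whole map as one dome — a property of the transform, not a bug).
Connectivity is 8 (motor-unit spread is not axis-aligned on a 10 mm grid);
the disc of radius 1 is the 5-pixel city-block cross (3×3 square
configurable). Regions are the strictly positive support of the opened
dome, labelled by decreasing peak height; region selection uses a seed
electrode (the anatomical origin by default), standing in for the manual
exclusion of neighbouring-muscle regions. The full pipeline retries with
deeper domes (h fraction 0.5, then 0.9) when the opening removes all
support — weak antagonist maps — and finally falls back to the
top-quartile region so intensity features remain defined for inactive
muscles.

Projections take the per-axis maxima of the segmented dome restricted to
the selected region. The equal-area median treats Q as a piecewise-constant
density over cells with edges at coordinate midpoints and inverts the
cumulative at half the total, giving sub-grid resolution (the discrete
equal-sum condition rarely holds exactly; the alternative smallest-k
convention is noted in the code). The bipolar feature uses the origin
electrode and its one-row-distal neighbour (10 mm along the fiber
direction).

## Inter-subject normalisation and the task simulation

Normalised coordinates are `(col - origin_col)*pitch/circumference` and
`(row - origin_row)*pitch/segment_length`; the common grid is 2× the
densest source resolution over the intersection of coordinate ranges (no
extrapolation). Variability is pixel-wise std (n−1) divided by the
mean-map intensity, undefined where the mean is zero; the summary is its
(mean, min, max) over the selected region. Because the origin electrode is
placed on an anatomical landmark, array-placement error largely cancels in
normalised coordinates; the averaging studies therefore use a residual
landmark error of 0.5 pitch (~5 mm palpation uncertainty), which together
with log-normal subject gains of sd 0.25 puts the 50 %MVC variability
summary in the 0.2–0.4 range.

The task simulation assigns each of five muscles (biceps, triceps,
brachioradialis, anconeus, pronator teres; upper-arm arrays 8×15, forearm
6×17) a blob (sd 2.5 columns, elongated along the fiber direction) whose
amplitude is a task-specific co-activation weight × a linear effort gain
(effort/50) × the subject's log-normal gain. Subjects carry a lateral
placement error of sd 1.25 pitch on the *recording* (it perturbs which
electrodes sample the blob); an optional per-effort lateral shift probes
spatial-shift recovery. The co-activation matrix encodes the expected
agonist/synergist pattern (e.g. flexion: biceps 1.0, brachioradialis 0.8;
supination: anconeus 1.0, biceps 0.7). Under these conditions the
segmented-area mean (RMS_av-HD) is robust to placement error while the
fixed bipolar pair is not, which produces the HD ≥ bipolar classification
ordering; both classify far above chance.

## Statistical conventions

The blocked Friedman test ranks each block's treatments × replicates
observations jointly (midranks on ties) and uses

    chi2 = sum_j (R_j - n c (m+1)/2)^2 / sum_b [c m s2_b / (m-1)],

m = k·c, with k−1 degrees of freedom; for c = 1 this reproduces the
classical tie-corrected statistic (verified against
`scipy.stats.friedmanchisquare`). The repeated-measures variant judges
significance against the Bonferroni-corrected critical value for the
condition-family size (12 conditions → α = 0.05/12, critical 27.28 at
11 dof). Wilcoxon drops zero differences and uses midranks. LDA uses
uniform priors (balanced design) and the SVD solver, which tolerates
near-singular pooled covariances without explicit regularisation;
leave-one-out predictions accumulate a confusion matrix from which
micro-averaged one-vs-rest indexes are pooled. Per-muscle normalisation
divides each muscle's feature by its grand mean over all conditions.

## Problem sizes and seeds

The default studies are sized for a laptop-class run: 20 labelled QC sets
(6×17, 3 s at 2048 Hz) for tuning and scoring, 12 subjects × 4 tasks ×
3 efforts × 5 arrays for classification, 1000 replicates for type-I rates.
Every stochastic component takes an explicit seed (NumPy `default_rng` /
`SeedSequence`); identical seeds give bit-identical recordings.
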