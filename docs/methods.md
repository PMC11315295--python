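# Methods

## The Q-induction estimator

The assay infects cultures that all carry an arabinose-inducible copy of
the phage lytic regulator *q*. After the infection period the cells are
diluted into calcium-free medium (no further infection), grown to mid-log,
and *q* is induced. Only lysogenized cells lyse; the OD600 dip measures the
lysogen fraction.

The estimator operates on a phage-treated curve and its paired
buffer-treated control, on a common plate clock whose t = 0 is the first
recorded timepoint after dilution:

1. **Peak/valley.** OD_P is the maximum OD at `t <= boundary` and OD_V the
   minimum at `t > boundary`, with the boundary at 4 h for planktonic and
   5 h for surface-harvested cultures. The split is half-open so a reading
   exactly at the boundary can be the peak; ties resolve to the earliest
   timestamp. Both rules are deterministic and match the reading order of
   a pre-lysis peak and post-lysis valley.
2. **Control fit.** The buffer-treated control is fit with the logistic
   `N(t) = K / (1 + ((K−N0)/N0) e^(−rt))` and evaluated at the phage
   curve's t_P and t_V to give N_tP and N_tV. Using the continuous fit
   (never raw control ODs) decouples the two wells' time grids.
3. **Piecewise %L.** With E the expansion factor,
   `%L = (OD_P − OD_V/E)/OD_P × 100`. If `N_tV/N_tP <= OD_V/OD_P` the
   infected culture kept pace with the control — no net lysis — and
   `E = N_tV/N_tP`, which makes the raw %L algebraically nonpositive (the
   branch theorem, property-tested on 10^4 random quadruples). Otherwise
   `E = N_tV/N_tP + (N_tV/OD_V − 1)`: the base growth correction plus the
   fold-reduction of the infected valley relative to the control,
   crediting survivors with accelerated regrowth on nutrients released by
   lysis. Raw %L is preserved for diagnostics; reported %L is clamped to
   [0, 100] (no negative percentages are reported).

Both branches depend on the four inputs only through ratios, so a common
rescaling of all of them (a unit change) leaves the estimate unchanged.
The scaled branch is, however, sensitive to a calibration factor applied
to the infected-culture readings alone, because `N_tV/OD_V` compares the
two wells directly; the no-net-lysis branch is not. Replicates are
estimated per phage/buffer pairing (paired by replicate index) and then
averaged (mean ± sample sd; a single replicate reports sd 0 with a flag).

## Logistic fitting

Nonlinear least squares (trust-region reflective) with the carrying
capacity parameterized as `K = N0 + delta`, `delta >= 0`, so `K >= N0`
holds by construction and the expansion factor stays >= 1. The
deterministic starting point is N0 = first positive OD, K = max OD, and r
= the slope of log OD over the window where OD lies between 20% and 80% of
its maximum. Tight optimizer tolerances (1e−14) make noiseless
self-generated curves an exact fixed point: the test grid
N0 ∈ {0.01, 0.05} × K ∈ {0.5, 1, 2} × r ∈ {0.3, 0.8, 1.5} refits to better
than 1e−6 relative (measured: ~1e−15). Flat or strictly decreasing curves
raise a non-identifiability error rather than returning junk; a fitted K
outside [0.5, 3] × max OD attaches a warning. Curves need >= 5 points; a
separate flatness tolerance (1e−6 OD units) guards degenerate input.

## qPCR quantitation

Standard curves are OLS fits of Cq on log10(copies) (>= 3 distinct
positive levels), with efficiency `10^(−1/slope) − 1` reported but never
used to correct copies — single-curve absolute quantitation. Unknowns
convert by `copies = 10^((Cq − intercept)/slope)`; the conversion pair is
an exact inverse (round-trip tested at 1e−9). Technical replicates are
averaged in Cq space, the measured scale; a replicate group censored
throughout stays censored. Below-LOD values never become silent numbers:
conversions return a flagged LOD-equivalent bound, and a censored 0 h
titer turns fold particle production into a flagged lower bound.

Lysogen quantitation divides *cos* copies by *ompW* copies (prophage per
host genome — the prophage is multi-copy, so the per-cell count is not 0/1)
and normalizes to the same ratio in a stable lysogen grown under matched
conditions; the result is invariant to the DNA amount extracted. The IRS
target is carried as a control channel and never enters the formula.
Adsorption is `100 × (1 − free/control)` clamped to [0, 100], with
over-recovery flagged.

## The simulator

`SimulationConfig` defaults define the conditions the package is tested
under:

| parameter | default | meaning |
| --- | --- | --- |
| `n0_total` | 0.05 OD | 1:100 dilution of an overnight culture |
| `k` | 1.0 OD | plate-reader carrying capacity |
| `r` | 0.8 /h | intrinsic growth rate (mid-log OD ~0.37 at 3 h) |
| `induction_time` | 3.0 h | inducer added at mid-log |
| `lysis_lag` | 1.0 h | regulatory delay from induction to lysis onset |
| `lysis_rate` | 2.5 /h | exponential OD decay of lysing biomass |
| `lysis_efficiency` | 1.0 | induction lyses every lysogen |
| `regrowth_boost` | 1.0 | survivor growth-rate multiplier |
| `noise_sd` | 0.01 | multiplicative lognormal OD noise |
| `sampling_interval` | 1/12 h | one OD reading per 5 min |
| `duration` | 12 h | post-dilution plate run |

The lag is set so lysis begins at the 4 h planktonic boundary: pre-lysis
peaks then fall at or before the boundary and valleys after it, the
geometry the peak/valley rule assumes (for surface runs, induction at 4 h
aligns onset with the 5 h boundary). The lysis rate exceeds
`r × regrowth_boost`, which makes the zero-noise conservation invariant —
induced OD <= uninduced OD pointwise — provable, not just observed.
Raising `regrowth_boost` above 1 can violate that bound and washes out the
shallow valleys of low-fraction mixtures, so the default keeps it at 1 and
treats boosted regrowth as a sensitivity study. Noise is multiplicative
lognormal because plate-reader error scales with signal. All randomness
flows from the config's explicit seed; there is no global random state.

What the simulator does not emulate: condensation and edge artifacts,
drift and blanking offsets, carryover phage re-infection, heterogeneous
lysis timing across cells, and survivor lag after lysis. Passing tests
therefore certify the arithmetic and the estimator's behavior under the
stated generative model, not plate-reader data pathology.

## Estimator accuracy on synthetic mixtures

An 11-point known-mixture experiment (fractions 0 … 1, 1% noise, complete
lysis) calibrates with slope ≈ 1.06 and R² ≈ 0.99, inside the [0.9, 1.1] /
0.95 acceptance window. Pointwise, the estimator is exact at the anchors
(0% and 100%) but carries an intrinsic bias of several points at
intermediate fractions even at zero noise (range about −8 to +5): the
post-boundary minimum of a shallow-valley curve captures only part of the
lysed deficit at low fractions, and the scaled expansion factor roughly
doubles the valley deficit at mid fractions. This mirrors the method's
published wet-lab calibration (slope 0.86 for q-induction), so the
pointwise recovery test allows 10 points at interior fractions while
holding the anchors to 2.

## Numerical and interface choices

- Times are hours; readers convert from minutes on request. Missing OD
  values are dropped per well (logged), never imputed — the estimator uses
  extrema, which imputation would bias. Blank subtraction is available but
  off by default, since the assay's published description does not state
  blanking.
- CSV round-trips are exact: floats are written as their shortest
  round-trip representation and parsed with round-trip precision.
- CLI reports embed the package version and a SHA-256 hash of the resolved
  configuration; JSON keys are sorted, so reruns on identical inputs are
  byte-identical. TSV percents are rounded to 0.1; JSON keeps full
  precision.
- Problem sizes throughout (11-fraction grids, 100-replicate noise
  studies, 10^4-quadruple property sweeps, 5-min/12-h curves) are the
  package's chosen desk-scale defaults; they run in seconds.

## Known limitations

- The estimator assumes the buffer control and the infected culture share
  growth kinetics before lysis; systematic differences (e.g. phage burden
  slowing growth pre-induction) bias %L.
- The scaled branch's accelerated-regrowth credit is a model, not a
  measurement; cultures whose survivors do not regrow faster will read
  slightly high at intermediate fractions.
- Censored qPCR handling propagates bounds but does no distributional
  imputation (no Tobit-style fits).
- Statistical comparison across strains (ANOVA and multiple-comparison
  corrections) is out of scope; exported tables feed external stats tools.
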