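# Methods

## Descriptor encoding

A descriptor scale assigns each of the 20 canonical amino acids a real
number. Encoding replaces residue `s_i` with `d(s_i)`, so an L-residue
sequence becomes an L-vector. The bundled database holds 532 scales:

- 531 AAindex1 entries — every entry of the AAindex1 flat file whose value
  block is fully numeric (entries containing `NA` cannot serve as
  descriptors and are excluded by the parser). Database order is the
  snapshot file order; with that ordering index 151 is KYTJ820101
  (Kyte–Doolittle hydropathy, the package default) and index 146 is
  KLEP840101 (net charge). An integrity check at load time verifies the
  identity of index 151.
- 1 empirical scale at index 532 — a synthetic alphabet-rank stand-in
  (A=1 … V=20 in canonical A R N D C Q E G H I L K M F P S T W Y V order),
  flagged `empirical`. It carries no physicochemical meaning and exists so
  the database exposes one clearly-labelled non-AAindex slot.

**Interval normalization** (`none` / `[0,1]` / `[−1,1]`, integer codes
0/1/2, default 0) is an affine map applied to a scale's 20 values
*globally*, never per sequence: per-sequence min–max scaling would give the
same residue different feature values in different sequences and destroy
comparability across rows. The map pins the scale's extremes to the
interval endpoints exactly and is idempotent; a degenerate scale (all 20
values equal) is rejected.

**Residue policy.** `strict` (default) admits only the 20 canonical codes
and reports the offending character and position otherwise. `lenient` must
be requested explicitly because imputation changes feature values: it maps
B → mean(D,N), Z → mean(E,Q), X → the mean of all 20 scale values, and
strips the gap characters `-` and `.` (with a logged count). Lowercase
input is uppercased everywhere.

## Length normalization

Knots sit at integer positions 1…L. The target grid

    x_j = 1 + (j − 1)(L − 1) / (D − 1),   j = 1…D

spans [1, L] inclusively, so every method maps the first input value to the
first output and the last to the last; this endpoint-preserving convention
is the contract the package promises (bit-compatibility with other grid
conventions that stop short of the final knot is deliberately not claimed).
Evaluation outside [1, L] is always an error — no extrapolation.

Methods:

- `linear` — straight segments between neighbouring knots. Output is
  bounded by the input range.
- `natural` — cubic spline with M₁ = M_L = 0 (M denotes the knot second
  derivatives).
- `periodic` — cubic spline with equal first and second derivatives at the
  two endpoints. Requires y₁ = y_L (tolerance 1e-9); by default unequal
  endpoints are an error, and `coerce_periodic=True` instead overwrites the
  last value with the first, with a warning, for data ported from
  implementations that warn-and-coerce.
- `fmm` — the Forsythe–Malcolm–Moler condition: the third derivative of
  each end piece is set to the (constant) third derivative of the exact
  cubic through the outermost four points at that end. This reproduces any
  global cubic polynomial exactly. Verified against R's `stats::spline`
  (`method="fmm"`) to 1e-12 on a fixture; those reference values are frozen
  in the test suite.
- `spline` — alias of `fmm`, so all five public names remain valid while
  exactly three distinct cubic boundary treatments exist.

With unit spacing the interior continuity equations are

    (1/6) M_{i−1} + (2/3) M_i + (1/6) M_{i+1} = y_{i+1} − 2 y_i + y_{i−1},

closed by the boundary rows above. Natural and fmm systems are solved with
the Thomas algorithm after folding the boundary rows into the first and
last interior equations (the resulting systems are strictly diagonally
dominant, so no pivoting is needed); the periodic cyclic-tridiagonal system
is reduced by a Sherman–Morrison rank-one update to two Thomas solves
(cyclic systems of size ≤ 2, i.e. L ≤ 3, are solved in closed form). All
solves are direct — no iteration, no tolerance knobs.

Small-L fallbacks for fmm/spline: L = 3 falls back to natural (a genuine
four-point end condition needs four points) and L = 2 to linear
interpolation, each with a logged warning.

Numerical guarantee: evaluation at the end knots is exact in exact
arithmetic; `resample` additionally pins the two endpoint outputs to the
knot values so endpoint preservation holds bitwise in floating point.

## Pipeline

`build_matrix` encodes every record and resamples it to a common dimension;
row order follows input order, the computation is deterministic, and rows
are independent (permuting inputs permutes rows identically). Choices:

- `dims` default: the rounded median input length. Normalizing to less
  than about half the original length loses information, and stretching
  short sequences is preferable to squeezing long ones, so a central
  default is used and a warning is emitted whenever any stretch/squeeze
  ratio exceeds 2×.
- Cubic overshoot: a cubic interpolant can leave the input range, so
  mode-[0,1] rows may contain values slightly outside [0,1]. The default
  keeps the mathematically faithful interpolant; `clamp=True` restricts
  rows to the mode interval for consumers that require hard bounds.
- Errors: a failing sequence aborts with its record id; `skip_errors=True`
  instead drops it and collects (id, reason) pairs into
  `metadata["skipped"]`.

`demo_classification` is an honest evaluation harness, not a modelling
contribution: stratified k-fold cross-validation (default 5 folds, seeded
shuffling), scores pooled out-of-fold, AUC as the trapezoidal area under
the ROC curve of the pooled scores. Resubstitution-style estimates
overestimate performance, which is why cross-validation is the only mode
offered. The classifier is a pluggable factory; the default is scikit-learn
logistic regression (fast, deterministic, and sufficient for the planted
synthetic signal — the method is classifier-agnostic by design).

## Synthetic data generator

The generator emulates the *structure* of a V3-loop coreceptor-usage set,
not its sequences:

- sizes 1151 / 200 (majority / minority class) — the strong class imbalance
  of the motivating dataset;
- lengths uniform on 33–38, produced by redrawing each sequence's length
  around a 35-residue reference (`indel_rate` is the probability a
  sequence's length is redrawn at all; default 1.0);
- every sequence starts and ends with cysteine, as the disulfide-bonded V3
  loop does. This also makes encoded endpoint values equal, so the periodic
  method is applicable to the generated data without coercion;
- class 0 interior residues are i.i.d. uniform over the 20 residues (no
  biological claim); class 1 draws from the mixture
  `(1 − signal) · uniform + signal · shifted`, where `shifted` multiplies
  the mass of the hydrophobic set {I,V,L,F,C,M,A} by `hydrophobic_weight`
  and renormalizes. The hydrophobic shift gives hydropathy-based encodings
  a planted, tunable signal, mirroring why hydropathy predicts coreceptor
  usage.

`hydrophobic_weight` was calibrated once against a brute-force
nearest-centroid baseline (no trained classifier) so that the default
signal of 0.6 yields a clearly learnable problem: weight 2 → centroid AUC
≈ 0.81, weight 3 → ≈ 0.90, weight 4 → ≈ 0.95 (seeds 1–3, default sizes).
The default is 4.0 and is not revisited. Generation is a pure function of
the config, including its seed.

What passing tests on this generator do **not** show: performance on real
V3 data. Real sequences have strong positional conservation, phylogenetic
correlation between samples (hence the leave-one-patient-out protocols
used in serious evaluations), and signal carried by specific charged
positions rather than bulk composition. The generator's i.i.d. composition
signal is deliberately simple; end-to-end tests demonstrate that the
plumbing transmits a planted signal, nothing more.

## Known limitations

- Length normalization discards sequence length itself, which can carry
  class information (the classic example being polyglutamine-repeat length
  in huntingtin); if length is informative, append it as an extra feature.
- Squeezing below ~50 % of the original length degrades information; the
  pipeline warns but does not refuse.
- The bundled database order is the snapshot file order. Index 151
  (hydropathy) and 146 (net charge) are verified; index-for-index agreement
  of the remaining entries with any other tool's numbering is not promised.
- AAindex2/AAindex3 (pair/contact matrices), nucleotide encoding, smoothing
  or monotone splines, and 2-D interpolation are out of scope.

## Problem sizes used in the shipped checks

The spline-solver cross-check uses 200 random vectors of length 4–12
against a dense solve of the full 4(L−1)-equation system (agreement
≈ 1e-14, asserted at 1e-9). The end-to-end check runs the full default
generator (1351 sequences), 5-fold logistic regression, one seed at signal
0.6 and 20 seeds at signal 0; the whole acceptance script completes in
about ten seconds on one CPU.
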