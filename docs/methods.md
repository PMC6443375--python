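# Methods

## The interchange model

A `Workspace` is the hub every reader produces and every writer
consumes: samples (event matrices plus FCS keywords), gating trees
(per-sample, or one shared template instantiated per sample by
copy-on-resolve so later edits never mutate the template), a registry of
display transforms keyed by id, a registry of spillover matrices keyed
by id, and the source dialect. Transform and compensation registries are
workspace-level with per-gate-dimension references rather than global
per-channel settings, because the FlowJo dialect allows per-sample
custom matrices and, in principle, different gates may be drawn on
different scales.

Gate coordinates are stored **on the transformed scale** internally.
This is a convention, not something any platform mandates: it buys a
single evaluation path in the engine (prepare channel → evaluate
predicate) at the cost of coordinate conversion in dialect readers and
writers that exchange raw-scale coordinates (FlowJo). Conversions use
the exact inverse of each declared transform.

Event data are treated as 32-bit-float-valued matrices promoted to
double for computation, matching FCS `$DATATYPE F`. The synthetic
generator quantizes its output to float32 for the same reason: a sample
written to FCS and read back is then bit-identical, which is what lets
cross-dialect conversion preserve population counts *exactly* rather
than approximately.

## Hierarchical gating

Membership is defined recursively: the reserved root population contains
every event; every other population contains the events that are in its
parent **and** satisfy its gate. Before a geometric predicate runs, each
gate axis is prepared in Gating-ML processing order — compensation on
the linear scale first, then the display transform. Prepared columns are
cached per (compensation matrix, transform, channel) within one resolve
call; the cache is observational only.

Boolean gates may reference any population already defined anywhere in
the tree (FlowJo permits cross-branch references), so evaluation runs in
dependency order with explicit cycle detection; a cycle is reported with
the paths involved.

All predicates are boundary-inclusive ("on the line = in the gate"),
polygons use the even-odd (crossing-count) rule so self-intersecting
vertex lists have deterministic semantics, and quadrant dividers are
closed on the "+" side so the four quadrants exactly partition the
plane. Ellipsoid membership is evaluated through a Cholesky
factorization of the shape matrix, never an explicit inverse.

## Compensation selection

Selection precedence per sample: explicit matrix reference on a gate
dimension → workspace per-sample custom matrix → FCS
`$SPILLOVER`/`$SPILL` keyword → none. The reference value
`"uncompensated"` on a gate dimension means "no explicit reference,
apply the automatic precedence", so a workspace that records an
analysis-time custom matrix wins over the acquisition-time keyword — the
behaviour a faithful import requires. Every selection is logged at INFO
with its provenance. Readers deliberately expose no option to override
matrices or transforms at import; modifications are explicit
post-import edits.

Spillover convention: rows = true signal, columns = detectors
(observed = true @ S), the FCS `$SPILLOVER` orientation; dialect readers
must transpose if their source stores the other orientation. A keyword
matrix stored with non-unit diagonal is normalized by row-scaling.

## Transforms

Families and fixed points (T top of scale, M decades, A negative
decades, W linearization width):

| family  | forward                                                | fixed points |
|---------|--------------------------------------------------------|--------------|
| linear  | (x + A) / (T + A)                                      | f(T) = 1 |
| log     | log10(x/T)/M + 1                                       | f(T) = 1, f(T·10^-M) = 0 |
| asinh   | (asinh(x·sinh(M ln10)/T) + A ln10) / ((M+A) ln10)      | f(0) = A/(M+A), f(T) = 1 |
| logicle | root of B(y) = x                                       | f(0) = (A+W)/(M+A), f(T) = 1 |

The log transform clamps inputs ≤ 0 to T·10^(−M−1), one decade below the
display floor, instead of erroring: compensated data contain negatives
and import must not fail on them.

The logicle inverse is the closed-form Parks–Moore biexponential; its
coefficients are derived from (T, W, M, A) with the damping constant d
found by Brent root-finding of 2(ln d − ln b) + w(b + d) = 0 on (0, b).
The forward map is computed by monotone grid interpolation (513 nodes on
the bracket [−A/(M+A) − 1, 2]) followed by Newton steps safeguarded by
bisection; iteration stops only when the residual is below 10⁻¹⁰·T on
the raw axis **and** the step is below 10⁻¹² on the display axis, so
precision is uniform across the scale and matches a plain bisection
oracle to better than 10⁻⁹.

When a dialect omits logicle parameters the Gating-ML conventional
defaults are used (T = 262144, W = 0.5, M = 4.5, A = 0) and the default
is logged. FlowJo-style biexponential width-basis declarations map to
W = max(0, (M − log10(T/|wb|))/2); this is a documented approximation.

A property worth knowing: with W = 0 and A = 0 the logicle does *not*
degenerate to the log transform at the bottom of the range — it stays
linear near zero, deviating from log by ≈ 0.046 display units at
x = T·10^−M and falling below 10⁻³ only about one decade higher. The
test suite asserts the log-limit from one decade above the floor.

## FCS I/O

The reader accepts FCS 3.0/3.1, list mode, `$DATATYPE F` (32-bit float)
or `I` (unsigned 8/16/32/64-bit), both byte orders, with DATA offsets
taken from the HEADER or, when zeroed there, from
`$BEGINDATA`/`$ENDDATA`. Log-amplified integer channels
(`$PnE = "f1,f2"`, f1 > 0) are linearized at read as f2·10^(f1·x/$PnR)
(f2 = 0 treated as 1, a common instrument quirk), logged at INFO; gates
are assumed drawn on linearized data. The ANALYSIS segment and
supplemental TEXT are ignored; non-finite values in DATA are an error.

The writer emits one canonical dialect: FCS 3.1, little-endian float32,
`$PnE "0,0"`, `$PnR = max(1, ceil(column max))`, delimiter `/` with
doubled-delimiter escaping, CRC bytes written as zeros. Offsets in the
TEXT segment are zero-padded to fixed width so the two-pass layout is
stable. User keywords (notably `$SPILLOVER`) are carried through;
structural keywords are recomputed. Not supported: FCS 2.0, histogram
modes, `$DATATYPE D/A`, multi-dataset files.

## Dialects

* **Gating-ML 2.0** is the lossless dialect: transforms, spectrum
  matrices and gates serialize with coordinates on the transformed scale
  and 17-significant-digit decimal text (`repr`), so re-parsed numbers
  are bit-identical. Population names (not part of the standard
  vocabulary) travel in `data-type:custom_info` children; hierarchy via
  `gating:parent_id`; orphan gates attach to root; a parent id naming no
  gate is an error.
* **FlowJo** targets the v10 wsp layout (SampleList / Sample / Keywords /
  Transformations / spilloverMatrix / SampleNode / Subpopulations) with
  embedded Gating-ML gate fragments. One transform binds to each channel
  (a channel gated on two scales is an export error), coordinates are
  written raw-scale (inverse-transformed) to match FlowJo's rendering,
  and samples are located by `$FIL`, then by the DataSet uri. 2-D
  ellipsoids are polygonized to 100 vertices scaled to straddle the true
  contour (half the chord sagitta out, half in), which keeps
  boundary-adjacent membership disagreement under 0.5%; ellipsoids in
  3+ dimensions have no polygon representation, so the native fragment
  is embedded with coordinates left on the transformed scale and marked
  `scale="transformed"` — a documented dialect extension. Boolean
  populations map to NotNode/AndNode/OrNode with Dependents. Cluster
  (index-defined) populations export here and only here, as `IndexGate`
  elements enumerating parent-relative indices.
* **Cytobank** shares the Gating-ML machinery plus `custom_info`
  extensions: an experiment title at the root and, per gate, a
  `cytobank` block with the population name and the FCS filenames the
  gate is scoped to. Per-sample trees become per-gate scoping; scoped
  files re-associate with samples by exact id then by basename stem,
  with ambiguity an error, never a guess. ACS handling is minimal zip
  packing/unpacking: members discovered by extension, a TOC written but
  not required, an ACS without an XML member rejected.

Writers consult an explicit capability matrix and fail loudly
(`UNSUPPORTED_EXPORT`) on features the target cannot carry — silently
dropping populations would defeat the point of interchange.

## The synthetic generator

`simulate_sample` draws events from a Gaussian mixture on the linear
fluorescence scale, mixes them through a known spillover matrix
(observed = true @ S), stores that matrix in the `$SPILLOVER` keyword,
and returns the component-of-origin label of every event. Randomness
comes from numpy's PCG64 generator under an explicit seed, so fixtures
are reproducible across platforms. The standard fixture is 3 components
with weights (0.5, 0.3, 0.2) in 4 channels, within-component sd 150,
means separated by ~60 component standard deviations, spillover
off-diagonals ≤ 0.15, n = 10⁴, seed 42.

`reference_workspace` builds one ellipsoid gate per component at the
generating parameters (μ, C) with threshold D², defaulting to the 99.9%
chi-square quantile. The gates bind the identity transform and evaluate
on the compensated linear scale: the mixture is Gaussian there, so the
gate is exactly the generating Mahalanobis ball and label recovery is a
sharp test — under a nonlinear display transform the component would not
be an ellipsoid and exact recovery would be unattainable by
construction. Per-channel asinh transforms are still declared in the
registry (and exercised heavily by the randomized round-trip
workspaces). With identity spillover and D² set to each component's
realized maximum squared Mahalanobis distance (with a 10⁻⁹ relative
margin so the defining boundary event survives a different factorization
route), every population's F-measure against the labels is exactly 1.0;
with spillover and chi-square coverage it is ≥ 0.999, the coverage mass.

What the generator does **not** emulate: doublets, debris, acquisition
drift, non-Gaussian population shapes, or spectral effects beyond linear
spillover. Passing tests therefore demonstrate correctness of the
interchange and gating machinery, not robustness to messy real-world
distributions.

## Problem sizes and determinism

The verification battery runs at: 50 randomized workspaces × 3 dialects
(300 events each) for semantic round-trips; the full 10⁴-event standard
fixture for cross-dialect conversion and ground-truth recovery; 10⁶
random points per transform family for inverse fidelity and 10³ points
against the bisection oracle; 100 random diagonally dominant matrices
for compensation; 20 polygons/ellipsoids × 10⁴ points for geometry; 50
random trees of ≤ 100 events against a per-event recursive evaluator;
and 200 random samples for FCS round-trips. All randomness is seeded;
`scripts/acceptance.py` derives every stream from its `--seed`.

## Known limitations

* Diva workspaces are out of scope (undocumented format), as are FlowJo
  v9 Mac-format workspaces, Hyperlog/Splitscale transforms, and curly or
  "magnetic" gates.
* The FlowJo and Cytobank dialect vocabularies are pinned by this
  package's own fixtures; files from real installations may use
  additional elements (layouts, figures, web-API metadata) that are
  ignored or unrecognized.
* Raw↔transformed coordinate conversion in the FlowJo dialect is exact
  only up to floating-point round-trip of the transform pair; an event
  lying within ~1 ulp of a gate boundary could in principle flip
  membership across a round trip.
* Event storage is in-memory only; no disk-backed or lazy access.
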