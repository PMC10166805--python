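# Methods

## Consensus matching

Cell detections are reduced to centroids in pixel coordinates (0-based,
x = column, y = row, sub-pixel floats). A field of view of width W and
height H admits centroids in the half-open box [0, W) × [0, H); the
half-open convention matches array indexing and keeps a boundary pixel
from belonging to two fields. When a detection is available as a pixel
mask, its centroid is the coordinate-wise arithmetic mean of the member
pixels — the same rule used to reduce anatomically labelled ground-truth
masks to reference locations.

Two centroid sets are matched one-to-one under a Euclidean distance
threshold. Euclidean (rather than Chebyshev) distance is used because
the threshold describes an isotropic "one cell diameter" separation; the
default threshold is 15 px and the comparison is inclusive (a pair at
exactly 15.0 px is merged). The matching rule is greedy nearest-first:
enumerate all cross pairs within the threshold, sort ascending by
(distance, id_a, id_b), and accept a pair when both endpoints are still
unmatched. The id tie-break makes the result deterministic and
symmetric in its arguments whenever distances are distinct. The
matching is maximal — after it finishes, no unmatched cross pair lies
within the threshold — but it is not an optimal-assignment (Hungarian)
matching; greedy was chosen because a threshold criterion, not a global
cost, defines consensus, and maximality is directly testable. A
maximal matching carries at least half the pairs of a maximum one, and
the test suite cross-checks this bound against an independent
Hungarian solution on small instances. How a cell within threshold of
several candidates is resolved is a design choice of this package
(nearest first), documented rather than claimed to be canonical.

Matched pairs are merged at the coordinate-wise midpoint of the two
centroids; consensus ids are sequential in acceptance order and the set
is labelled `consensus`. Exactly two input sets are supported; N-way
consensus is out of scope.

## Evaluation statistics

All percentages are reported on the 0–100 scale.

* TPR = 100 · n_matched / n_reference. Undefined (error) for an empty
  reference.
* precision = 100 · n_matched / n_detected; the same formula scores a
  single detector's overlap with ground truth and the consensus set's
  overlap with ground truth. Undefined for an empty detected set.
* count ratio = |A| / |B|; 1.0 flags equal counts.
* matched percentage = 100 · n_matched / min(|A|, |B|). The denominator
  is a design choice: min yields a 0–100 bounded agreement measure and
  equals 100 exactly when the smaller set is fully matched. Its known
  bias is that a subset relation (one detector's cells contained in the
  other's) also scores 100.

For patch-based segmentation, rf = 4·gSig and stride = 2·gSig. The
patch count is approximated as ceil(W / pitch) · ceil(H / pitch) with
pitch = 2·rf − stride (patch diameter minus overlap); this is an
explicit, testable approximation of a patch tiling, not a claim about
any specific tool's internal layout. K = round(K_total / npatches)
floors at 1 because a patch always expects at least one component.
Defaults used in examples: gSig = 5 (so rf = 20, stride = 10) and
K_total = 330 on a 512×512 field, giving 324 patches and K = 1.

## Detector simulator

The simulator emulates centroid-level behaviour of two segmentation
algorithms; it does not model images or fluorescence dynamics, so
passing tests say nothing about any real algorithm's image-processing
quality — only about the consensus arithmetic downstream of detection.

Ground truth: n cells placed uniformly at random with pairwise
separation ≥ min_separation (default 15 px, one cell diameter — cells
do not overlap), by rejection sampling with a bounded retry budget.
Study conditions used throughout the tests: 200 cells on 512×512.

Each simulated detector, from one integer seed (NumPy PCG64; all draws
flow from the config's seed, making every scene bit-reproducible):

* reports each true cell independently with probability
  `detection_prob` (default 0.8);
* perturbs reported locations with iid Gaussian noise of per-axis SD
  `jitter_sigma` (default 2 px), clipped to the field (a physical field
  of view does not wrap);
* adds `n_false_positives` (default 50) spurious ROIs placed uniformly
  at distance > `fp_min_distance` (default 15 px) from every true cell,
  so a false positive can never be counted as a true match at the
  default threshold and precision is exactly measurable. Setting
  `fp_min_distance = 0` gives a harder regime with false positives near
  cells; it is off by default.

A detector pair must use two different seeds: the central premise of
consensus filtering is that the two algorithms' errors are independent.
False positives of the two detectors can still coincide by chance; on a
512×512 field with 50 per detector the expected number of chance FP–FP
matches at 15 px is ≈ 50·50·π·15²/512² ≈ 6.7, which is why consensus
precision at those conditions sits near 95% rather than 100%.

## Parameter sweeps

The sweep machinery expands runtime-bound prompt keys over a Cartesian
grid (row-major in key declaration order) and assembles one scalar
metric per combination into a dense 2-D map, rejecting duplicate or
missing combinations. The two standard one-parameter sweeps used as
fixtures are threshold_scaling ∈ 0.7–3.4 in 0.1 steps (28 runs) and
max_overlap ∈ 0–1 in 0.1 steps (11 runs).

The qualitative sweep demonstration varies one detector's sensitivity
(0.6–1.0) against its false-positive load (0–80) with the partner
detector fixed at sensitivity 0.9 and 20 false positives. Where the two
detectors report equal counts the count-ratio map shows a contiguous
anti-diagonal band; the agreement (matched-percentage) maximum is
attained on that band at its well-configured end, and agreement falls
along the band as sensitivity drops. This sweep uses a 1024×1024 field:
with the min-count denominator, chance FP–FP coincidences otherwise
inflate agreement at high FP load, and the larger field keeps that
confound an order of magnitude below the structure being demonstrated.

## Workflow engine and provenance

Modules declare typed ports (eight semantic types); type compatibility
is exact equality with one safe widening, int → float. Input ports bind
in four ways: a manual literal, a runtime prompt key supplied at
execution, a pipe from an output of a strictly earlier step, or a
dataset in an HDF5 file. Execution is strictly serial in listed order —
provenance of a linear record is trivially complete, and nothing in the
intended workloads needs DAG scheduling. Validation is static
(unbound required ports, forward/self pipes, type mismatches, missing
HDF5 targets, unknown modules) and sound for the binding system: a
workflow with no issues resolves all bindings at run time.

Reproducibility: a workflow carries one integer seed; any step that
declares a `seed` port and leaves it unbound receives seed + step_index,
giving independent per-step streams that are still a pure function of
the workflow seed. A step failure marks later steps skipped and the
record is still written. Queued workflows run in submission order and a
failure does not halt the queue.

Execution records are single HDF5 files (format version "1.0" in
`/meta`; a breaking layout change bumps the major version): the full
workflow definition as YAML, every resolved input and output value per
step stored natively by kind, per-step status, the seed, timestamps,
and any figures as embedded PNG blobs so the record alone is complete.
All datasets are written with HDF5 time-tracking disabled, so
write → read → write with pinned timestamps is byte-identical;
timestamps are the only non-reproducible content and are excluded from
digest comparisons, which cover scientific content only (SHA-256 over a
canonical serialization of each output value). Re-execution of a record
must reproduce every stored output digest exactly; a rerun with
overridden runtime values is flagged `derived` and not compared.

## Problem sizes and numerical notes

Tests and the acceptance script use 200-cell fields (512×512) with 50
replicate simulations for the consensus-improvement analysis, 1,000
random small instances (≤ 10 ROIs per side) for exhaustive matching
verification, and 3–5 replicates per sweep cell; these sizes give
binomial standard errors well below the effects being measured (the
consensus-vs-single precision gap is ≈ 18 percentage points against a
replicate SD of ≈ 2). Degenerate inputs are errors, not silent values:
empty metric denominators, non-positive thresholds, mismatched field
dimensions, infeasible packings, and identical pair seeds all raise.

## Limitations

* Centroid-level only: no pixel-mask overlap (IoU) matching, no image
  or signal simulation.
* Greedy matching is not guaranteed to maximize the number of matched
  pairs (it is within a factor of two and exact in the sparse,
  well-separated regimes simulated here).
* The false-positive model is spatially uniform and independent of cell
  density; real segmentation errors cluster around neuropil and
  overlapping cells, a regime only partially covered by the
  `fp_min_distance = 0` mode.
* The workflow engine executes Python callables in-process; no
  cross-language modules, no parallel scheduling, no GUI.
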