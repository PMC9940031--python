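# Methods

## The registry model

A registry is one UTF-8 JSON object whose keys are model ids
(`^\d{5}(_[A-Z0-9]+)+$`, case-sensitive) and whose values carry three
sections: `execution` (how to fetch and run the package), `selection`
(metrics and keywords for search/ranking), and `description`
(human-facing details). The serialized shape is documented in
`src/synthzoo/data/registry.schema.json`; validation is implemented in
code (`registry.validate_metadata`) so that violations come back as a
structured list naming field and rule rather than as an exception chain.
Two execution keys are optional capabilities rather than universal
fields: `latent_dim` (declared latent input size; required before a
model can be latent-explored) and `value_range` (declared output pixel
range, default `[0, 255]`; checked by the contribution smoke test).
Duplicate top-level keys in a registry file keep the last occurrence and
log a warning, matching the behaviour of ordinary JSON parsers while
making the collision visible.

The bundled `model_zoo.json` is a catalog of 21 published medical-image
generators with their reported FID metrics. Its entries carry
placeholder package locations (`example.org`): the catalog documents and
drives search, ranking, and the FID-ratio computations, not remote
execution — the hosted weights are not shipped with this package.

## Execution and the determinism contract

A model package is a directory with an `__init__.py` entry script and
optional weights. The entry script exposes a generate function with the
standardized signature
`generate(model_file, num_samples, save_images, output_path, seed=None,
sample_offset=0, **kwargs)`, returning a list of `{image, mask?,
label?}` items; `kwargs` carries model-specific inputs
(`input_latent_vector`, `condition`, `input_images`).

Generation is chunked into `ceil(num_samples / batch_size)` batches so
arbitrarily large requests keep at most one batch in memory when saving
to disk. For chunking to be invisible in the output, randomness must not
depend on how samples are grouped: each sample keys its randomness by
the pair *(request seed, absolute sample index)* — the executor passes
`seed` unchanged and `sample_offset` per batch, and packages derive
sample *i*'s generator from `(seed, sample_offset + i)` (the fixture
templates use `numpy`'s `default_rng([seed, index])`, i.e. a
`SeedSequence` over the pair). A per-batch seed such as `seed +
batch_index` cannot satisfy this: re-chunking changes which samples
share a stream. The batch-size-3 vs. batch-size-10 equality test pins
the property.

Dependency checks are import-presence probes only; version specifiers
are recorded and logged but not enforced, and installation is delegated
to a pluggable installer invoked for missing packages only. Package
resolution is lazy (nothing is fetched or imported before the first
generation request for that id) and idempotent (a second request reuses
the unpacked cache without refetching). The batch iterator is a plain
Python iterable of sample batches; any framework's data loader can wrap
it, and no deep-learning framework is required.

## The Fréchet distance and its numerics

`frechet_distance` computes
`||μ_a − μ_b||² + tr(Σ_a) + tr(Σ_b) − 2 tr((Σ_a Σ_b)^{1/2})` with the
unbiased (n−1) covariance estimator, matching the dominant FID
implementations. The trace of the matrix square root is evaluated by the
symmetric eigenvalue route: `Σ_a Σ_b` is similar to the symmetric PSD
matrix `√Σ_a Σ_b √Σ_a`, so the trace term is the sum of square roots of
that matrix's eigenvalues (`eigh`), keeping the computation real and
deterministic. Feature covariances are typically rank-deficient here
(n images < d features), which leaves noise eigenvalues of order
`eps·λ_max` whose square roots are *not* negligible; eigenvalues below
`d·eps·λ_max` are therefore zeroed before the square root. Residual
negative distances within 1e−6 of zero clamp to exactly 0; anything more
negative raises a numerical error rather than being silently truncated.
For diagonal covariances the distance must equal the per-dimension
closed form `Σ_i (μ_1i − μ_2i)² + (σ_1i − σ_2i)²`; the test suite checks
this to 1e−8 up to d = 10 as an independent oracle.

Image preparation: optional normalization into [0, 1] (`bitdepth`
divides by the dtype maximum — 255 for 8-bit — and warns when float data
already lies in [0, 1]; `minmax` rescales by the dataset-wide range,
mapping a constant dataset to zeros), then bilinear anti-aliased
resizing to the extractor's declared input, then channel adaptation
(grayscale replicated to RGB, RGB averaged to grayscale). Normalization
is applied to both sets identically, and every report records the
normalization mode and extractor id, since both demonstrably move FID.

## FIDrr, rFID, and desk-scale sample sizes

`fid_lower_bound` shuffles the real set with a recorded seed and splits
it into disjoint halves of sizes ⌊n/2⌋ and ⌈n/2⌉ — one split, not an
average over repeats, so the quantity is cheap and exactly reproducible;
an explicit index override exists for controlled experiments.
`rfid(fid_rs, fid_rr) = 1 − (fid_rs − fid_rr)/fid_rs` requires
`fid_rs > 0` and clamps to 1.0 (with a warning) when the empirical lower
bound exceeds the real–synthetic distance.

That clamp is not hypothetical at desk scale. The default test extractor
is a seeded random projection of 8×8 average-pooled pixels to d = 64
dimensions, and the study size used throughout the tests and examples is
200 images per set. FID is biased upward when n is not ≫ d, and the bias
grows as sets shrink: the half-split FID<sub>rr</sub> (100 vs. 100) then
exceeds a well-matched full-size FID<sub>rs</sub> (200 vs. 200), and a
distribution-matched generator lands exactly on the clamp. The
evaluation therefore asserts *orderings* (matched generator scores a
higher rFID than an intensity-shifted one; within-distribution FID below
cross-distribution FID), never absolute FID magnitudes, which are
extractor- and n-specific. 200 per set keeps every evaluation under a
few seconds while leaving the shift effect (~two orders of magnitude in
FID) unmistakable.

`evaluate_model` matches set sizes for FID<sub>rs</sub> by seeded
subsampling of the larger side, fills every provenance field (counts,
split sizes, extractor id, normalization mode, seed), and `report_table`
emits CSV plus (FID<sub>rr</sub>, FID<sub>rs</sub>) scatter pairs with a
least-squares trend line (undefined, and reported as `None`, for fewer
than two distinct points).

## Search and ranking semantics

Search flattens an entry into lowercase strings — every key name and
every string leaf, plus the model id; numbers are excluded, their key
names are not, so `"fid"` finds models carrying an FID metric. Matching
is case-insensitive substring containment; the operator counts matched
query values per model (`AND` all, `OR` ≥ 1, `XOR` exactly one — the
k-ary generalization of two-input XOR). Results keep registry order.
Ranking resolves a dotted path into `selection.performance`; ties break
by model id ascending, models lacking the metric are appended flagged
(visible, not dropped), and the default direction is ascending for the
lower-is-better set {FID, FIDrr} and descending otherwise. When *no*
model carries the metric the ranking is empty with a warning — except
inside `find_and_rank`, where keyword matches survive as flagged,
unranked entries so a successful search is never silently discarded.

## Fixtures: what they emulate and what they do not

The fixture zoo covers the four generation scenarios with closed-form
procedural models: Gaussian-blob "mass" patches (64×64×1, latent d=16),
ellipse "polyp" patches with binary masks (d=8), class-conditional
striped/checkerboard textures with labels {0, 1} (d=16), and an
intensity-inverting image-to-image translator (no latent input). All are
z-sensitive by construction — every latent dimension moves pixels — and
deterministic per (seed, sample index). `synth_image_set` draws from the
*same* blob distribution (one shared renderer source), optionally with
an intensity offset, so real-vs-synthetic experiments have a known
ground truth; a fifth registry entry reuses the blob package with a +64
offset as the known-mismatched generator.

These fixtures exercise every interface contract without trained
weights, but they are not medical images: passing tests demonstrate that
the metric stack, executor, and workflows behave correctly, not that any
particular published model is faithful to its training data. Absolute
FID values on fixtures are meaningless outside the fixture world;
published-model FID values in the bundled catalog are recorded
measurements, reproducible here only at the level of the rFID arithmetic
computed from them.

## Design choices on genuinely open points

- Substring (not exact) keyword matching, so a query for "mammography"
  hits descriptions and titles as well as keyword lists.
- The FID<sub>rr</sub> split is a single seeded half-split rather than an
  average over repeated subsamples: reproducible, cheap, and sufficient
  for a lower-bound estimate; the seed is part of the report.
- Normalization applies to both image sets, never one.
- Slider display values initialize to the mean of their group's latent
  dimensions, the unique choice that makes group-size-1 sliders coincide
  with z itself.
- Publishing is a contract with a filesystem default (archive copy +
  JSON notice + sha256 receipt); API-backed publishers can be plugged in
  without touching validation, testing, or registration.
- Configuration layers as explicit override > `SYNTHZOO_*` environment
  variable > TOML file > built-in default.

## Known limitations

- No pretrained ImageNet/RadImageNet backbone ships with the package;
  the FeatureExtractor contract accepts one, but out of the box only the
  toy random-projection extractor is registered, so absolute FID values
  are not comparable with published numbers computed on deep features.
- Dependency checking is presence-only; conflicting version requirements
  across model packages are logged, not resolved.
- Model code runs unsandboxed in-process; registries should only point
  at trusted packages (the catalog records checksums in publish
  receipts, it does not enforce them at load time).
- The latent explorer assumes a standard-normal latent prior; models
  with other priors need their own handling of `input_latent_vector`.
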