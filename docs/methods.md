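# Methods

## The library model

`ammlib` treats an analysis as three artefacts worth keeping: its input
data, its output model, and the metadata that makes either intelligible
later. An `AmLibrary` holds all three in one object — a description, a
library-level info map, and two ordered, uniquely-named collections of
records (models and data). A record wraps an arbitrary payload together
with a type label (`payload_class`), an optional self-declared producing
tool (`origin_package`, shown as NA when absent), and its own metadata
map. Payloads are deep-copied on entry and on check-out, so neither
later library edits nor caller-side edits can silently rewrite a stored
object.

Metadata is deliberately weak-typed: ordered text keys mapping to text
values, with `None` as the deletion sentinel and keys treated as
case-sensitive. Four keys are reserved by convention only: `date`
(record creation time), `date.created` (library creation time), `data`
(the dataset a model was fit to) and `prior` (the model used as a
prior). A user-supplied value for a timestamp key wins over the
automatic one. Links are stored verbatim with no referential check — a
link may point outside the library or at nothing. This is a considered
choice, not an omission: libraries are split, merged and pruned over
their lifetime, and a hard integrity constraint would make half of those
operations illegal. The cost is that dangling links are the user's
problem; the tooling therefore never follows a link that does not
resolve, and never errors on one.

Public indices are 1-based and shift when records are removed, which is
exactly why links are by name. Record names are sanitized to valid
identifiers (invalid characters become `.`, a leading digit gains an `X`
prefix). Inserting a name that already exists in a collection is an
error rather than an overwrite: silent replacement would destroy the
provenance the container exists to protect.

## Search, closure, and splitting

`grep_library` matches a regular expression (Python `re` dialect,
case-sensitive by default with an opt-in flag) against each record's
name, metadata keys and metadata values. Payload internals are not
searched: recursing into arbitrary opaque objects is ill-defined and
would make search results depend on how a payload happens to be stored.

After matching, a single closure pass preserves model–data pairings:
each matched model pulls in the dataset its `data` key names, and each
matched dataset pulls in every model citing it. Closure follows only the
`data` key by default; `follow_prior=True` additionally chains through
`prior` links between models. One pass is a fixed point for the `data`
relation (model→data→models-of-that-data adds no new data), which the
tests verify by re-running closure on its own output.

`subset_library` selects records explicitly (bare names resolve models
first, then data, with a warning on collision; `(role, selector)` pairs
are unambiguous) and keeps each selected model's linked dataset.
`split_library` partitions a library into `grep` matches and the rest;
extraction and remainder are disjoint and exhaustive by construction.
All three return new libraries and never mutate their input.

## Archives

`save_library` writes one library per archive: a ZIP with
`manifest.json` at the root and one payload file per record. The
manifest stores the format version, creation time, tool version and a
platform note, plus per entry the record's identity, codec, metadata and
a SHA-256 checksum of the payload bytes; `load_library` verifies every
checksum before decoding and restores records in manifest order. Writes
go to a temporary file renamed into place, so a failed save (e.g. an
unserializable payload) leaves no partial archive.

Codecs, chosen per payload: DataFrames become UTF-8 CSV plus a JSON
sidecar of column dtypes (categorical level order included) so values
and types round-trip exactly — floats rely on Python's
shortest-representation text, which is lossless for binary64;
JSON-representable structures (and registered types such as
`OpaquePayload`, `OlsResult`, `BetaParams`) become tagged JSON; anything
else is pickled as a `native-blob`, flagged non-portable in the
manifest, and surfaced as raw bytes with a warning if it cannot be
restored. Foreign serialization formats (R's `.rda`/`.RDS`) are not
read.

## Covariate simulation

`simulate_covariates` draws each column independently from its own
`numpy.random.default_rng(seed)`, so a column is reproducible
bit-for-bit regardless of which other columns are requested — the
property that makes per-variable seeds worth their bookkeeping.
Families: uniform(min, max), normal(mean, sd), beta(shape1, shape2),
binomial(size, prob), and bernoulli(prob) implemented as a single-trial
binomial. Function-style aliases (`runif`, `rnorm`, `rbeta`, `bin`, a
callable's `__name__`) are normalized on entry; parameters are validated
per family and errors name the offending spec. Optional rounding is
applied after drawing. `add_year` appends a trailing integer `yr`
column, constant 1 by default — a single-season marker — with the value
configurable; a sequential-year semantic was the plausible alternative,
but a constant is the conservative reading for a one-season table and is
trivially overridden. Columns drawn with a generator seeded this way are
not expected to reproduce draws from any other environment's RNG; the
guarantees are distributional (bounds, moments) and reproducibility
within this package.

## The worked analyses

**OLS.** `ols_fit` fits `y_i = β0 + β1·1{group_i = level 2} + ε_i` by
solving the normal equations `(XᵀX)β = Xᵀy` directly (the 2×2 system is
exactly the textbook closed form: β0 is the first-level mean, β1 the
difference in level means). Standard errors come from
`σ̂²(XᵀX)⁻¹` with `σ̂² = SSE/(n−2)`; t statistics use the t
distribution on n−2 degrees of freedom and the overall F test on
(1, n−2) — both p-values via scipy's distribution functions, the one
deliberate use of a library where the statistic itself is still computed
here. Residual quartiles use the default linear interpolation rule,
which matches the convention of mainstream statistical summaries. Factor
level order comes from a categorical's declared categories, else
first appearance. Degenerate inputs are rejected explicitly: fewer than
3 observations, a single-level factor (rank-deficient design), more
coefficients than observations, and a zero-variance response (R² would
be 0/0; an error is more honest than a convention).

**Beta-binomial.** `beta_binomial_update` applies the conjugate closed
form Beta(α + y, β + n − y). The tests check it against a grid
quadrature of Bayes' theorem (10⁻⁴ resolution, posterior mean agreement
to 10⁻⁶) and its associativity over data splits; `beta_pdf` is checked
for normalization and mode location.

**Demo library.** `build_demo_library` replays a fixed worked sequence —
five dataset insertions, two removals (one by index, one by name), five
model insertions with `data`/`prior` links, one removal — ending with
models `[plant.model, frog.model1, frog.model2, apple.m1]` and data
`[plant.data, apple.data, frog.data]`. It is the shared fixture for
search, subsetting, archiving and the CLI. The plant table embeds the
twenty canonical control/treatment weights; the apple observation is
y = 25 infested of n = 100 sampled; the simulated covariate table uses
seven fixed per-column specs at n = 10. Occupancy-model objects from an
external estimator are represented by `OpaquePayload` stand-ins labelled
synthetic in their content, carrying only the class label
(`unmarkedFitOccu` / `unmarkedFrameOccu`) and origin (`unmarked`); no
occupancy likelihood, model selection or goodness-of-fit computation is
performed or claimed.

## What the synthetic fixtures do and do not show

The randomized libraries used in the property tests have themed record
names, small metadata maps, and a mix of resolving and dangling `data`
links; they exercise the search/closure/split algebra against brute-force
oracles but say nothing about scale (hundreds of records, megabyte
payloads) or about payload diversity beyond tabular/structured/pickled.
The covariate simulator's moment checks (sample mean within 3·sd/√n,
sample sd within 5% at n = 10⁵) validate calibration of the generator,
not any claim about real covariates. Problem sizes in the tests — 200
randomized libraries for the search oracle, 10⁵ draws for moments,
n = 30 for the OLS oracle — were chosen to make the checked properties
sharp while keeping the suite fast to run routinely.

## Known limitations

- No referential integrity for links, by design (see above).
- Search cannot see inside payloads; a term that appears only in a
  payload will not match.
- `native-blob` payloads are only portable across compatible Python
  environments; the manifest flags them.
- Metadata values are text; structure stored in a value (dates, JSON)
  is not interpreted.
- The OLS routine handles the one-factor two-level design it exists
  for; it is not a general linear-model fitter.
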