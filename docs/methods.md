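# Methods

## What the tool records, and the model behind it

`provtrace` captures data lineage at the granularity of *tracked function
calls*. An analysis script is assumed to be a sequence of calls to
data-processing functions, possibly inside loops; each call takes data
inputs, configuration parameters, and produces outputs. The tool does not
trace the interpreter or the call graph: a tracked function is a black
box, and control flow is deliberately not represented — a loop over N
objects appears as N independent paths in the lineage, which is exactly
the data-centric view the records are meant to expose.

For every call of a wrapped function while a capture session is active,
the decorator records:

- **Inputs/outputs** — descriptors of the data objects (type, content
  hash, memory address, attribute snapshot, annotation dictionaries) and
  of files (SHA-256 of the bytes plus the absolute path).
- **Parameters** — every argument that is not an input or a file role,
  resolved against the declared signature, so defaults that were never
  written at the call site are recorded too.
- **Context** — a fresh execution UUID, start/end timestamps (ISO-8601
  UTC, microseconds), the value of the session-global execution counter,
  and the source statement containing the call.
- **Container accesses** — the statement's AST is inspected; argument
  expressions that reach the call through attribute access, indexing or
  slicing (`block.segments[0]`) produce one membership record per hop,
  with the intermediate containers resolved from the live frame.

Capture must never change the user's computation: the wrapper returns
exactly what the wrapped function returns, and any description failure
degrades to a bounded string placeholder with a warning.

## Identity

Object identity is content-based. The default digest is SHA-1 over the
type identity plus the object state — for array-likes, the raw buffer
bytes, shape, dtype and unit string; for everything else a canonical
pickle via `joblib.hash`. Two objects with equal type and digest denote
the same logical data state; this single property is what makes graphs
from different runs, processes or machines unify when their RDF files are
concatenated. Two deliberate exceptions:

- `None` (a single interpreter-wide object) is identified by one UUID per
  session rather than a content hash.
- Packages registered in `builtin_hash_packages` use the object's own
  `hash()`. This serves objects with a meaningful `__hash__`, and objects
  whose serialized state is not reproducible — the demo registers
  `matplotlib`, because figure pickles embed unstable internals and a
  content hash would shred one figure into a chain of spurious entities.

Files are identified by the SHA-256 of their content, so the same file
read and written under different paths (or on different hosts) is one
entity.

The recorded memory address is kept as a session-local disambiguator in
the descriptor but takes no part in identity: URNs use the hash only.

## Serialization

Records are serialized as RDF using a PROV-O extension (the Alpaca
vocabulary, namespace `https://purl.org/alpaca#`): `DataObjectEntity` and
`FileEntity` (prov:Entity), `FunctionExecution` (prov:Activity),
`ScriptAgent` (prov:SoftwareAgent), plus `Function` and `NameValuePair`.
Parameters, attribute snapshots and annotations are `NameValuePair`
blank nodes; the hash provenance is written as one of the three literals
`joblib_SHA1`, `Python_hash`, `UUID`. Every node carries a deterministic
URN, e.g.

    urn:[authority]:alpaca:object:Python:[class path]:[object hash]
    urn:[authority]:alpaca:file:sha256:[file hash]

with analogous templates for functions, executions and the script agent.
The `authority` is a plain organizational string set via `configure`.
Merging documents is a triple-set union; no rewriting is needed because
identity lives in the URNs.

Turtle is the default syntax (RDF/XML, N-Triples, JSON-LD, N3 and TriG
work through the same interface). Blank-node identifiers are drawn from
the same injectable ID source as UUIDs and timestamps, so a capture run
under `FixedIdSource` serializes byte-identically — the property the
round-trip/determinism tests pin down. Attribute and annotation pairs are
emitted once per entity URN within a document; merging documents can
duplicate pairs on shared entities, which is harmless (same names, same
values) and resolved by the graph projection.

## Visualization graphs

The projection turns the RDF into a directed NetworkX graph with three
node types (`object`, `file`, `function`) and edges following data flow:
used entity → activity → generated entity, plus labeled membership edges
container → element. Nodes carry `label`, the dotted-path attribute
(`Python_name`, kept bit-exact for interoperability with existing GEXF
consumers), selected attributes/annotations, and a `Time Interval` string
`<[a, b]>` built from execution order: a function spans its own order;
entities span first generation to last use; pure-container nodes inherit
the hull of their neighbors. Supernode intervals are likewise the hull of
their members — chosen over a union list because timeline tools consume
a single interval.

Simplifications: `remove_none` drops entities describing `None` returns;
`condense_memberships` collapses maximal chains of membership edges whose
intermediate nodes have no other provenance edges into one edge labeled
with the concatenated accessor (`.segments[0]`). Condensation cannot
change reachability between the retained nodes (it only contracts
degree-2 interior nodes), and a property test checks this on the demo
graph.

Aggregation is SNAP-style: nodes start grouped by (type, label, dotted
path, the selected attribute values — a missing attribute is its own
key — and, optionally, function parameters), then groups are split until
every node in a group has successors and predecessors in the same set of
groups. The result is the coarsest stable refinement of the attribute
partition. Supernodes carry `members` (sorted URNs) and `member_count`;
Σ member_count always equals the input node count. The implementation is
independent of NetworkX's `snap_aggregation`, which serves as a reference
oracle in the tests on small graphs.

## One deviation worth knowing about

Static call-site analysis cannot see through loop variables: in
`for trial in trials: butter(trial...)`, the link between the list
`trials` and each `trial` never appears as a subscript in any tracked
statement. To keep loop iterations connected to the stage that produced
the container, tracked calls additionally expand builtin list/tuple/dict
inputs and return values (up to 64 elements, non-scalar elements only)
into element-wise membership records. This is a capture-side design
choice, not part of the AST analysis; it produces the same
`prov:hasMember`/`containerIndex` triples the subscript analysis would
have produced.

Conversely, membership analysis applies only to arguments bound to
*input* roles — an expression like `config.cutoff` feeding a parameter
describes configuration, not data flow, and produces no entities.

## The synthetic demo

`provtrace.demo` emulates the structure of a multielectrode
reach-to-grasp session so the whole toolchain can be exercised without
data access: a 96-channel, 30 kHz continuous signal (a 20 Hz sinusoid of
amplitude 10 on every channel plus unit-variance white noise, float32)
with labeled behavioral events of four trial types (SGLF/SGHF/PGLF/PGHF;
CUE-ON/CUE-OFF/GO-ON per trial, all marked `correct_trial`). Defaults:
2 trials per type spaced 1.5 s (≈14.5 s per recording), 500 ms epochs
after CUE-OFF, channels `chan 2`/`chan 4` excluded, 250 Hz 4th-order
Butterworth low-pass (zero-phase), downsampling by 60 to 500 Hz, Welch
PSD with 2 Hz resolution, Hann window, 50% overlap. Those settings make
the recorded shapes exact and predictable: 500 ms × 30 kHz = 15,000
samples per cut, 250 after downsampling, 94 of 96 channels, and
⌊250/2⌋+1 = 126 frequency bins.

The containers (`Block`/`Segment`/`AnalogSignal`/`Event` with
`annotations`/`array_annotations`, and a unit-carrying `Quantity` array)
are lightweight stand-ins implementing just the structure the capture
layer consumes through its plugin registry. What the synthetic data does
*not* emulate: real LFP spectra (no 1/f background, no band structure),
artifacts, trial-count asymmetries between conditions, or the NIX
container format. Passing tests therefore demonstrate the provenance
machinery — shape/parameter recording, lineage connectivity, merging —
not any neuroscientific property of the signals.

`run_split_pipeline` re-runs the same analysis split across capture
sessions: `two_process` emulates a two-rank parallel run (sessions share
in-memory PSD arrays, whose equal content hashes join the graphs) and
`two_stage` a two-script workflow (sessions share intermediate `.npz`
files, whose equal SHA-256 join the graphs). Both merge into one weakly
connected graph whose aggregated form differs from the single-run graph
only by the save/load stages.

## Numerical and degenerate-input choices

- Attribute/parameter snapshots: scalars are kept typed; anything else is
  a `repr` capped at 256 characters, so bulk data never lands in
  metadata.
- Hash failure falls back to the builtin hash (then the object id) with a
  warning; file-output hashing of a missing file records the path with an
  empty hash.
- Statements that cannot be matched to the parsed source (interactive or
  generated code) are recorded without statement text or memberships.
- An empty session serializes to a valid document with only the agent and
  namespace declarations.
- `trial_sem` with a single trial returns NaN (SciPy's convention); the
  demo default of 2 trials per type avoids this in the shipped
  conditions.

## Problem sizes

Tests run the demo at 4 channels (all temporal parameters at their
defaults, so every recorded shape except the channel axis is identical to
the full-size run); `scripts/acceptance.py` runs the full 96-channel
default and reads the reported quantities back from the Turtle sidecar
alone. The quantities it reports (126 frequency bins; 15,000 → 250
samples across the downsample stage) depend only on sampling rate, epoch
length, downsample factor and spectral resolution.

## Known limitations

- Only calls lexically reachable from the activated scope's source file
  are statement-resolved; calls of tracked functions from other modules
  are recorded without statement/membership context.
- No capture of the execution environment (interpreter, packages, OS) —
  out of scope by design; pair with an environment-capture tool if
  needed.
- One tracked call per statement is assumed when matching AST call nodes;
  two calls of the same wrapped function in one statement share the first
  match's memberships.
- The builtin-hash dispatch makes identity process-local for the affected
  packages (ids are not stable across processes), so such entities do not
  unify across runs — acceptable for terminal sinks like figures.
- Annotation extraction is plugin-based; only the generic
  `annotations`/`array_annotations` convention ships by default.
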