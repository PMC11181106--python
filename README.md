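# provtrace

Lightweight provenance capture for Python data-analysis scripts.

Analysis results in data-intensive fields — the motivating case is
trial-resolved spectral analysis of multielectrode electrophysiology
recordings — are typically produced by scripts whose crucial details
(which events defined the trials, which channels were dropped, which
filter cutoff and spectral resolution were used, which array shapes
flowed through each stage) exist only at run time and are invisible in
the result file. `provtrace` records those details while the script
runs, with minimal instrumentation, and stores them as a machine-readable
sidecar file next to the result.

It is aimed at scientists who share analysis outputs (figures, derived
arrays) with collaborators and need the lineage of each output to be
inspectable *after the fact*, without re-running or reading the code.

## The model

The capture layer wraps each data-processing function `f` with a
decorator. While a session is active, every call of `f` yields one
execution record containing

- descriptors of the data inputs and outputs: type, a content hash
  (SHA-1 over type identity + object state; SHA-256 of the bytes for
  files), and a metadata snapshot (attributes such as `shape`, `dtype`,
  `units`, `t_start`, and `annotations`/`array_annotations`
  dictionaries);
- every remaining argument as a parameter, including declared defaults
  that were never written at the call site;
- the source statement of the call and the container accesses in it
  (`block.segments[0]` → `hasMember` relations with the accessor);
- an execution counter, UUID and timestamps.

The history serializes to RDF (Turtle by default) under a PROV-O
extension: entities (`DataObjectEntity`, `FileEntity`), activities
(`FunctionExecution`), one `ScriptAgent` per run, with `prov:used`,
`prov:wasGeneratedBy`, `prov:wasAssociatedWith`, `prov:hasMember`
relations. Every node has a deterministic, content-derived URN
(`urn:[authority]:alpaca:object:Python:[class]:[hash]`), so RDF files
from separate runs, processes or pipeline stages merge into one
connected graph by plain concatenation. The serialized graph can be
projected to a NetworkX property graph, simplified (drop `None` returns,
condense access chains), summarized by SNAP aggregation (group nodes on
attributes, refine until edges are compatible; supernodes carry
`members`/`member_count`), and exported to GEXF/GraphML for Gephi and
friends.

## Worked example

```python
import numpy as np
import scipy.signal

from provtrace import (Provenance, ProvenanceGraph, activate, configure,
                       save_provenance, deactivate)

configure(authority="my-lab")

@Provenance(inputs=["signal"])
def lowpass(signal, cutoff=250.0, fs=30000.0):
    sos = scipy.signal.butter(4, cutoff, btype="low", fs=fs, output="sos")
    return scipy.signal.sosfiltfilt(sos, signal, axis=0)

@Provenance(inputs=["signal"])
def welch_psd(signal, fs=500.0, frequency_resolution=2.0):
    nperseg = int(fs / frequency_resolution)
    freqs, psd = scipy.signal.welch(signal, fs=fs, nperseg=nperseg, axis=0)
    return freqs, psd.T

activate()
raw = np.random.default_rng(0).normal(size=(15000, 96))
filtered = lowpass(raw)
freqs, psd = welch_psd(filtered[::60])
save_provenance("example.ttl")
deactivate()

view = ProvenanceGraph("example.ttl")
view.remove_none()
print(f"nodes: {view.graph.number_of_nodes()}, "
      f"edges: {view.graph.number_of_edges()}")
for node, data in view.graph.nodes(data=True):
    if data["type"] == "object":
        print(f"{data['label']:8s} shape={data.get('shape')} "
              f"interval={data['Time Interval']}")
view.save_gexf("example.gexf")
```

prints

```
nodes: 7, edges: 6
ndarray  shape=(15000, 96) interval=<[1, 1]>
ndarray  shape=(15000, 96) interval=<[1, 1]>
ndarray  shape=(250, 96) interval=<[2, 2]>
ndarray  shape=(126,) interval=<[2, 2]>
ndarray  shape=(96, 126) interval=<[2, 2]>
```

Reading it: the two tracked calls became two activity nodes; the raw
(15000, 96) array, the filtered array, the downsampled slice (250, 96),
the 126-bin frequency array and the per-channel PSD (96, 126) are entity
nodes connected along the data flow. The `Time Interval` strings encode
execution order for Gephi's timeline. `example.ttl` additionally holds
the parameters (`cutoff=250.0`, `frequency_resolution=2.0`, including the
unwritten defaults) and the slice accessor `::60` linking `filtered` to
its downsampled view — all recoverable from the sidecar alone.

A complete end-to-end demonstration lives in `provtrace.demo`: a
synthetic 96-channel, 30 kHz recording with four trial types, and a
tracked pipeline (event selection → 500 ms epochs → cut → channel
exclusion → 250 Hz Butterworth → downsample ×60 → Welch PSD at 2 Hz →
averages → plot), producing a PNG plus its Turtle sidecar. The same
analysis can be run split across sessions (`run_split_pipeline`) to show
that the per-run RDF files concatenate into a single connected lineage.

## Command line

```sh
provtrace-graph run1.ttl run2.ttl --out graph.gexf \
    --remove-none --condense --aggregate trial_type --use-parameters
```

loads and merges the RDF files, applies the simplifications, and writes
GEXF (or `--format graphml`).

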