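"""Readers and writers for recordings, estimates, networks and reports.

The canonical on-disk recording format is a channels-by-time CSV whose first
column holds the channel label and whose header row indexes the samples.
EDF files are read through :mod:`mne` when it is installed (the ``edf``
extra); everything else is plain CSV/JSON/GraphML so every artifact is
re-parseable by the package's own readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .estimators import ConnectivityEstimate
from .networks import MultilayerNetwork, supra_adjacency
from .recording import MultichannelRecording, RecordingError

__all__ = [
    "read_recording",
    "write_recording",
    "read_estimate",
    "write_estimate",
    "write_adjacency_csv",
    "write_supra_adjacency_csv",
    "layer_to_graphml",
    "multilayer_to_graphml",
]


def write_recording(recording: MultichannelRecording, path: str | Path) -> Path:
    """Write a channels x time CSV: first column label, header sample index."""
    path = Path(path)
    df = pd.DataFrame(
        recording.data,
        index=pd.Index(recording.labels, name="channel"),
        columns=np.arange(recording.t),
    )
    df.to_csv(path, float_format="%.17g")
    return path


def read_recording(
    path: str | Path,
    fs: float | None = None,
    labels: list[str] | None = None,
    condition: str = "",
) -> MultichannelRecording:
    """Read a recording from CSV (``fs`` required) or EDF (``fs`` from header).

    Malformed files, duplicate labels and non-finite values raise
    descriptive errors with row/column locations.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path, labels=labels, condition=condition)
    if fs is None:
        raise ValueError("fs is required when reading CSV recordings")
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise RecordingError(f"could not parse {path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = sorted(df.index[df.index.duplicated()].unique().tolist())
        raise RecordingError(f"duplicate channel labels in {path}: {dup}")
    data = df.to_numpy(dtype=float)
    file_labels = [str(x) for x in df.index]
    rec = MultichannelRecording(
        data=data, fs=fs, labels=file_labels, condition=condition
    )
    if labels is not None:
        rec = rec.select_channels(labels)
    return rec


def _read_edf(
    path: Path, labels: list[str] | None, condition: str
) -> MultichannelRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading EDF requires mne (install the 'edf' extra)"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    rec = MultichannelRecording(
        data=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        labels=list(raw.ch_names),
        condition=condition,
    )
    if labels is not None:
        rec = rec.select_channels(labels)
    return rec


def write_estimate(estimate: ConnectivityEstimate, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(estimate.to_dict(), indent=1, sort_keys=True))
    return path


def read_estimate(path: str | Path) -> ConnectivityEstimate:
    return ConnectivityEstimate.from_dict(json.loads(Path(path).read_text()))


def write_adjacency_csv(
    matrix: np.ndarray, labels: list[str], path: str | Path
) -> Path:
    path = Path(path)
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(
        path, float_format="%.17g"
    )
    return path


def write_supra_adjacency_csv(
    network: MultilayerNetwork, which: str, path: str | Path
) -> Path:
    mat, index = supra_adjacency(network, which)
    names = [f"{layer}:{ch}" for layer, ch in index]
    return write_adjacency_csv(mat, names, path)


def layer_to_graphml(layer, path: str | Path) -> Path:
    """Export one chain-graph layer as GraphML (directed multigraph; the
    undirected contemporaneous edges are stored with ``kind=functional`` in
    both orientations' canonical one)."""
    g = nx.DiGraph(layer=layer.name)
    g.add_nodes_from(layer.nodes)
    for e in layer.effective:
        g.add_edge(e.source, e.target, weight=e.weight, kind="effective")
    h = nx.Graph()
    h.add_nodes_from(layer.nodes)
    for e in layer.functional:
        h.add_edge(e.source, e.target, weight=e.weight, kind="functional")
    combined = nx.compose(g, nx.DiGraph(h))
    path = Path(path)
    nx.write_graphml(combined, path)
    return path


def multilayer_to_graphml(network: MultilayerNetwork, path: str | Path) -> Path:
    """Export the flattened supra-graph: nodes named ``layer:channel``."""
    g = nx.DiGraph()
    for lname, layer in network.layers.items():
        for ch in layer.nodes:
            g.add_node(f"{lname}:{ch}", layer=lname, channel=ch)
        for e in layer.effective:
            g.add_edge(
                f"{lname}:{e.source}",
                f"{lname}:{e.target}",
                weight=e.weight,
                kind="effective",
            )
        for e in layer.functional:
            g.add_edge(
                f"{lname}:{e.source}",
                f"{lname}:{e.target}",
                weight=e.weight,
                kind="functional",
            )
    if network.interlayer_coupling != 0.0:
        names = network.layer_names
        for i, li in enumerate(names):
            for lj in names[i + 1 :]:
                for ch in network.nodes:
                    g.add_edge(
                        f"{li}:{ch}",
                        f"{lj}:{ch}",
                        weight=network.interlayer_coupling,
                        kind="interlayer",
                    )
    path = Path(path)
    nx.write_graphml(g, path)
    return path
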