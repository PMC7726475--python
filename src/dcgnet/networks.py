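"""Dynamic chain graphs, multilayer networks and comparison reports.

A fitted model becomes a *chain-graph layer*: directed lagged edges (source
at ``t-1`` to target at ``t``) wherever the lag matrix is nonzero, and
undirected contemporaneous edges wherever the error-precision off-diagonal
is nonzero, weighted by the partial correlation.  Layers — one per waveband,
or one per estimation method — share a node set and stack into a multilayer
(multiplex) network, summarized by its supra-adjacency matrix: diagonal
blocks are the per-layer adjacencies, off-diagonal blocks couple node
replicas across layers (zero by default, since each band is fit
independently).

Two comparison reports operationalize how the estimators differ: one scores
every candidate method against the quantile-thresholded unpenalized VAR
reference (strong links preserved, weak links removed, spurious links
created), the other contrasts two conditions band by band (edges gained /
lost / shared).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import ConnectivityEstimate

__all__ = [
    "Edge",
    "GraphLayer",
    "MultilayerNetwork",
    "ComparisonReport",
    "effective_edges",
    "functional_edges",
    "edges_to_matrix",
    "build_multilayer",
    "supra_adjacency",
    "compare_methods",
    "compare_conditions",
]

NONZERO_TOL = 1e-8


@dataclass(frozen=True)
class Edge:
    """Weighted edge; ``directed`` distinguishes lagged from contemporaneous."""

    source: str
    target: str
    weight: float
    directed: bool

    @property
    def key(self) -> tuple[str, str]:
        """Support identity: ordered pair if directed, sorted pair if not."""
        if self.directed:
            return (self.source, self.target)
        return tuple(sorted((self.source, self.target)))  # type: ignore[return-value]


def effective_edges(
    gamma: np.ndarray, labels: list[str] | None = None, tol: float = NONZERO_TOL
) -> list[Edge]:
    """Directed lagged edges ``j -> i`` for every ``|G[i, j]| > tol``.

    Self-loops (diagonal entries) are legitimate: they are within-channel
    autocorrelation.
    """
    gamma = np.asarray(gamma, dtype=float)
    if gamma.ndim != 2 or gamma.shape[0] != gamma.shape[1]:
        raise ValueError("gamma must be square")
    m = gamma.shape[0]
    labels = labels or [f"ch{i}" for i in range(m)]
    out = []
    for i in range(m):
        for j in range(m):
            if abs(gamma[i, j]) > tol:
                out.append(Edge(labels[j], labels[i], float(gamma[i, j]), True))
    return out


def functional_edges(
    omega: np.ndarray, labels: list[str] | None = None, tol: float = NONZERO_TOL
) -> list[Edge]:
    """Undirected contemporaneous edges from precision off-diagonals.

    Edge ``{a, b}`` (stored once, ``a < b``) wherever ``|O[a, b]| > tol``;
    the weight is the partial correlation ``-O[a,b]/sqrt(O[a,a] O[b,b])``.
    Raises for an asymmetric input.
    """
    omega = np.asarray(omega, dtype=float)
    if omega.ndim != 2 or omega.shape[0] != omega.shape[1]:
        raise ValueError("omega must be square")
    if not np.allclose(omega, omega.T, atol=1e-8):
        raise ValueError("omega must be symmetric")
    m = omega.shape[0]
    labels = labels or [f"ch{i}" for i in range(m)]
    out = []
    for a in range(m):
        for b in range(a + 1, m):
            if abs(omega[a, b]) > tol:
                w = -omega[a, b] / np.sqrt(omega[a, a] * omega[b, b])
                out.append(Edge(labels[a], labels[b], float(w), False))
    return out


def edges_to_matrix(
    edges: list[Edge], labels: list[str], directed: bool
) -> np.ndarray:
    """Adjacency matrix from an edge list (inverse of the extractors'
    support: round-tripping reproduces the nonzero pattern)."""
    idx = {lbl: k for k, lbl in enumerate(labels)}
    m = len(labels)
    out = np.zeros((m, m))
    for e in edges:
        i, j = idx[e.target], idx[e.source]
        if directed:
            out[i, j] = e.weight
        else:
            out[i, j] = out[j, i] = e.weight
    return out


@dataclass
class GraphLayer:
    """One chain-graph layer: a band's (or method's) edge sets."""

    name: str
    nodes: list[str]
    functional: list[Edge] = field(default_factory=list)
    effective: list[Edge] = field(default_factory=list)

    @classmethod
    def from_estimate(
        cls, name: str, estimate: ConnectivityEstimate, tol: float = NONZERO_TOL
    ) -> "GraphLayer":
        return cls(
            name=name,
            nodes=list(estimate.labels),
            functional=functional_edges(estimate.omega_hat, estimate.labels, tol),
            effective=effective_edges(estimate.gamma_hat, estimate.labels, tol),
        )

    def edge_keys(self, which: str) -> set[tuple[str, str]]:
        return {e.key for e in getattr(self, which)}

    def adjacency(self, which: str) -> np.ndarray:
        return edges_to_matrix(
            getattr(self, which), self.nodes, directed=(which == "effective")
        )


@dataclass
class MultilayerNetwork:
    """Node set replicated across ordered layers (multiplex network)."""

    layers: dict[str, GraphLayer]
    nodes: list[str]
    interlayer_coupling: float = 0.0

    def __post_init__(self) -> None:
        names = list(self.layers)
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        for layer in self.layers.values():
            if layer.nodes != self.nodes:
                raise ValueError(
                    f"layer {layer.name!r} node set differs from the shared node set"
                )

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def build_multilayer(
    estimates: dict[str, ConnectivityEstimate],
    tol: float = NONZERO_TOL,
    interlayer_coupling: float = 0.0,
) -> MultilayerNetwork:
    """One chain-graph layer per estimate (keys become layer names, in order).

    All estimates must share the same channel labels; replica couplings
    between layers default to zero because each band is fit independently.
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    items = list(estimates.items())
    nodes = list(items[0][1].labels)
    for name, est in items:
        if list(est.labels) != nodes:
            raise ValueError(f"estimate {name!r} has mismatched channel labels")
    layers = {
        name: GraphLayer.from_estimate(name, est, tol) for name, est in items
    }
    return MultilayerNetwork(
        layers=layers, nodes=nodes, interlayer_coupling=interlayer_coupling
    )


def supra_adjacency(
    network: MultilayerNetwork, which: str = "functional"
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Supra-adjacency block matrix and its (layer, channel) row index.

    The matrix is ``(N*L) x (N*L)`` with per-layer adjacencies on the
    diagonal blocks (symmetric for functional layers, signed and directed
    for effective ones) and ``coupling * I`` on every off-diagonal block.
    """
    if which not in ("functional", "effective"):
        raise ValueError("which must be 'functional' or 'effective'")
    n, names = network.n_nodes, network.layer_names
    size = n * len(names)
    out = np.zeros((size, size))
    for li, name in enumerate(names):
        sl = slice(li * n, (li + 1) * n)
        out[sl, sl] = network.layers[name].adjacency(which)
        if network.interlayer_coupling != 0.0:
            for lj in range(len(names)):
                if lj != li:
                    sj = slice(lj * n, (lj + 1) * n)
                    out[sl, sj] = network.interlayer_coupling * np.eye(n)
    index = [(name, ch) for name in names for ch in network.nodes]
    return out, index


# ---------------------------------------------------------------------------
# Comparisons
# ---------------------------------------------------------------------------


def _support(est: ConnectivityEstimate, which: str, tol: float) -> set[tuple[str, str]]:
    if which == "effective":
        return {e.key for e in effective_edges(est.gamma_hat, est.labels, tol)}
    return {e.key for e in functional_edges(est.omega_hat, est.labels, tol)}


@dataclass
class ComparisonReport:
    """Per-method link bookkeeping against a thresholded VAR reference.

    For each candidate and each edge kind: ``preserved_strong`` (reference
    strong links the candidate keeps), ``removed_weak`` (reference weak
    links the candidate drops — the desired behavior), ``created`` (links
    absent from the *unthresholded* reference support).  Conservation holds
    per kind: preserved + missing strong = total strong reference links.
    """

    reference_method: str
    strong: dict[str, list[tuple[str, str]]]
    weak: dict[str, list[tuple[str, str]]]
    per_method: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "reference_method": self.reference_method,
            "strong": {k: sorted(v) for k, v in self.strong.items()},
            "weak": {k: sorted(v) for k, v in self.weak.items()},
            "per_method": self.per_method,
        }

    def to_text(self) -> str:
        lines = [f"reference: {self.reference_method}"]
        for kind in ("effective", "functional"):
            lines.append(
                f"[{kind}] strong={len(self.strong[kind])} weak={len(self.weak[kind])}"
            )
            for meth, entry in self.per_method.items():
                e = entry[kind]
                lines.append(
                    f"  {meth:<14s} sparsity_gamma={entry['sparsity_gamma']:.3f} "
                    f"sparsity_omega={entry['sparsity_omega']:.3f} "
                    f"preserved={len(e['preserved_strong'])} "
                    f"removed_weak={len(e['removed_weak'])} "
                    f"created={len(e['created'])}"
                )
        return "\n".join(lines)


def compare_methods(
    reference: ConnectivityEstimate,
    reference_thresholded: ConnectivityEstimate,
    candidates: dict[str, ConnectivityEstimate],
    tol: float = NONZERO_TOL,
) -> ComparisonReport:
    """Score candidates against the strong/weak split of a VAR reference.

    ``reference`` is the unthresholded fit (its support defines which links
    exist at all, hence what counts as "created"); ``reference_thresholded``
    is the same fit after :func:`~dcgnet.estimators.threshold_weak_links`,
    whose surviving links are the strong set.
    """
    strong: dict[str, list] = {}
    weak: dict[str, list] = {}
    full: dict[str, set] = {}
    for kind in ("effective", "functional"):
        full[kind] = _support(reference, kind, tol)
        s = _support(reference_thresholded, kind, tol)
        strong[kind] = sorted(s)
        weak[kind] = sorted(full[kind] - s)
    report = ComparisonReport(
        reference_method=reference.method, strong=strong, weak=weak
    )
    for name, est in candidates.items():
        if list(est.labels) != list(reference.labels):
            raise ValueError(f"candidate {name!r} has mismatched channel labels")
        entry: dict = {
            "sparsity_gamma": est.sparsity_gamma,
            "sparsity_omega": est.sparsity_omega,
        }
        for kind in ("effective", "functional"):
            sup = _support(est, kind, tol)
            s = set(strong[kind])
            w = set(weak[kind])
            preserved = sorted(sup & s)
            missing = sorted(s - sup)
            removed = sorted(w - sup)
            created = sorted(sup - full[kind])
            assert len(preserved) + len(missing) == len(s)
            entry[kind] = {
                "preserved_strong": preserved,
                "missing_strong": missing,
                "removed_weak": removed,
                "created": created,
            }
        report.per_method[name] = entry
    return report


def compare_conditions(
    baseline: MultilayerNetwork, post: MultilayerNetwork
) -> dict[str, dict]:
    """Band-by-band edge gains and losses between two conditions.

    Returns, per layer and per edge kind, the edges only in the post
    network (``gained``), only in the baseline (``lost``) and ``shared``,
    plus post-minus-baseline weight differences for the shared ones.
    """
    if baseline.layer_names != post.layer_names:
        raise ValueError("networks have different layers")
    if baseline.nodes != post.nodes:
        raise ValueError("networks have different node sets")
    out: dict[str, dict] = {}
    for name in baseline.layer_names:
        lb, lp = baseline.layers[name], post.layers[name]
        entry: dict = {}
        for kind in ("effective", "functional"):
            wb = {e.key: e.weight for e in getattr(lb, kind)}
            wp = {e.key: e.weight for e in getattr(lp, kind)}
            shared = sorted(wb.keys() & wp.keys())
            entry[kind] = {
                "gained": sorted(wp.keys() - wb.keys()),
                "lost": sorted(wb.keys() - wp.keys()),
                "shared": shared,
                "weight_delta": {str(k): wp[k] - wb[k] for k in shared},
            }
        out[name] = entry
    return out
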