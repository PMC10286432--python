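"""Adjacency graphs and scaled ICAR precision structures.

Disease-mapping models of the Besag/ICAR family are defined on an undirected
adjacency graph over the study areas.  This module builds such graphs from
polygon contiguity or from the plain-text graph dialect used by R-INLA,
derives their connected components ("regions" when the study map is split,
e.g. by a sea), and assembles the scaled ICAR structure matrix together with
the sum-to-zero constraint system that identifies the intrinsic field.

The ICAR prior on structured effects ``u`` has precision ``tau * R`` with
``R = D - W`` (the graph Laplacian for 0/1 weights).  ``R`` is rank-deficient
by one per connected component, so the field needs one sum-to-zero constraint
per component (or a single global one).  Following Sorbye & Rue's scaling
recommendation, ``R`` is rescaled so the geometric mean of the constrained
marginal variances is one and ``tau`` is interpretable as a marginal
precision; scaling can be done jointly or per component.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
from shapely.geometry import shape as _geojson_shape
from shapely.strtree import STRtree

__all__ = [
    "AdjacencyGraph",
    "IcarStructure",
    "GraphFormatError",
    "SingletonComponentError",
    "build_contiguity_graph",
    "read_geojson",
    "read_graph",
    "write_graph",
    "connected_components",
    "constraint_system",
    "scale_icar",
    "icar_marginal_variances",
    "icar_scaling_factors",
]


class GraphFormatError(ValueError):
    """Malformed or inconsistent graph-file content (carries the line number)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SingletonComponentError(ValueError):
    """A connected component with a single area, unsupported by the ICAR models."""


@dataclass(frozen=True)
class AdjacencyGraph:
    """Undirected area adjacency graph with derived component (region) labels.

    Parameters
    ----------
    area_ids
        Ordered, unique labels; all matrices in the package are indexed in
        this order (0-based internally).
    edges
        Unordered pairs of 0-based area indices, stored as ``(i, j)`` with
        ``i < j``.  Self-edges are rejected.
    component_labels
        Per-area region index, constant within each connected component and
        numbered by the smallest area index contained in the component.
    """

    area_ids: tuple
    edges: frozenset
    component_labels: tuple

    def __post_init__(self):
        n = len(self.area_ids)
        if len(set(self.area_ids)) != n:
            raise ValueError("duplicate area labels")
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-edge on area index {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i}, {j}) out of range for {n} areas")

    # -- construction ---------------------------------------------------
    @classmethod
    def from_edges(cls, area_ids: Sequence, edges: Iterable[tuple[int, int]]) -> "AdjacencyGraph":
        canon = frozenset((min(i, j), max(i, j)) for i, j in edges)
        labels = _component_labels(len(area_ids), canon)
        return cls(tuple(area_ids), canon, tuple(labels))

    # -- basic queries ---------------------------------------------------
    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_components(self) -> int:
        return 0 if not self.component_labels else max(self.component_labels) + 1

    def index(self, area_id) -> int:
        return self.area_ids.index(area_id)

    def components(self) -> list[np.ndarray]:
        """Index arrays for each component, in component-label order."""
        labels = np.asarray(self.component_labels)
        return [np.flatnonzero(labels == c) for c in range(self.n_components)]

    def neighbours(self, i: int) -> list[int]:
        out = [j for a, j in self.edges if a == i] + [a for a, j in self.edges if j == i]
        return sorted(out)

    def singleton_components(self) -> list:
        return [self.area_ids[idx[0]] for idx in self.components() if len(idx) == 1]

    # -- matrices ----------------------------------------------------------
    def adjacency_matrix(self) -> sp.csr_matrix:
        """Symmetric 0/1 neighbourhood weight matrix W."""
        n = self.n_areas
        if not self.edges:
            return sp.csr_matrix((n, n))
        ii, jj = np.array(sorted(self.edges)).T
        rows = np.concatenate([ii, jj])
        cols = np.concatenate([jj, ii])
        return sp.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))

    def structure_matrix(self) -> sp.csr_matrix:
        """ICAR structure matrix R = D - W, D = diag of row sums of W."""
        W = self.adjacency_matrix()
        d = np.asarray(W.sum(axis=1)).ravel()
        return (sp.diags(d) - W).tocsr()

    def subgraph(self, component: int) -> tuple["AdjacencyGraph", np.ndarray]:
        """Restriction to one connected component.

        Returns the component's graph plus the index array mapping its areas
        back into this graph's ordering.
        """
        idx = self.components()[component]
        pos = {int(a): k for k, a in enumerate(idx)}
        edges = [(pos[i], pos[j]) for i, j in self.edges if i in pos and j in pos]
        return AdjacencyGraph.from_edges([self.area_ids[i] for i in idx], edges), idx


def _component_labels(n: int, edges: frozenset) -> list[int]:
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    comps = sorted(nx.connected_components(g), key=min)
    labels = [0] * n
    for c, comp in enumerate(comps):
        for i in comp:
            labels[i] = c
    return labels


def connected_components(graph: AdjacencyGraph) -> tuple[int, ...]:
    """Per-area region labels, numbered by smallest contained area index."""
    return graph.component_labels


# ---------------------------------------------------------------------------
# polygon contiguity
# ---------------------------------------------------------------------------

def build_contiguity_graph(geometries, rule: str = "queen") -> AdjacencyGraph:
    """Adjacency graph from labelled planar geometries.

    ``queen`` (default) links areas sharing any boundary point; ``rook``
    requires a shared boundary segment of positive length.  Input is a mapping
    ``label -> geometry`` or an iterable of ``(label, geometry)`` pairs.
    """
    if rule not in ("queen", "rook"):
        raise ValueError(f"unknown contiguity rule {rule!r}")
    if isinstance(geometries, Mapping):
        items = list(geometries.items())
    else:
        items = list(geometries)
    labels = [lab for lab, _ in items]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate area labels: {dupes}")
    geoms = []
    for lab, g in items:
        if g is None or g.is_empty:
            raise ValueError(f"empty geometry for area {lab!r}")
        geoms.append(g)

    tree = STRtree(geoms)
    edges = set()
    for i, g in enumerate(geoms):
        for j in tree.query(g):
            j = int(j)
            if j <= i:
                continue
            inter = g.intersection(geoms[j])
            if inter.is_empty:
                continue
            if rule == "queen" or inter.length > 0 or getattr(inter, "area", 0.0) > 0:
                edges.add((i, j))
    return AdjacencyGraph.from_edges(labels, edges)


def read_geojson(path, id_property: str = "id") -> list[tuple]:
    """Labelled shapely geometries from a GeoJSON FeatureCollection."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    out = []
    for k, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        label = props.get(id_property, feat.get("id"))
        if label is None:
            raise ValueError(f"feature {k} has no {id_property!r} property and no id")
        out.append((label, _geojson_shape(feat["geometry"])))
    return out


# ---------------------------------------------------------------------------
# R-INLA ASCII graph dialect
# ---------------------------------------------------------------------------

def read_graph(path) -> AdjacencyGraph:
    """Read the R-INLA plain-text graph format.

    First line: number of areas ``n``; then one line per area,
    ``id  k  nbr_1 ... nbr_k`` with 1-based ids.  Listings must be symmetric.
    Area labels are the 1-based ids as strings.
    """
    text = Path(path).read_text() if not hasattr(path, "read") else path.read()
    lines = [ln for ln in text.splitlines()]
    stripped = [(k + 1, ln.strip()) for k, ln in enumerate(lines) if ln.strip()]
    if not stripped:
        raise GraphFormatError("empty graph file")
    first_no, first = stripped[0]
    try:
        n = int(first)
    except ValueError:
        raise GraphFormatError(f"expected area count, got {first!r}", first_no)
    if n <= 0:
        raise GraphFormatError(f"area count must be positive, got {n}", first_no)
    if len(stripped) - 1 != n:
        raise GraphFormatError(
            f"expected {n} node lines, found {len(stripped) - 1}", first_no
        )
    nbrs: dict[int, list[int]] = {}
    for line_no, ln in stripped[1:]:
        parts = ln.split()
        try:
            vals = [int(p) for p in parts]
        except ValueError:
            raise GraphFormatError(f"non-integer token in {ln!r}", line_no)
        if len(vals) < 2:
            raise GraphFormatError(f"malformed node line {ln!r}", line_no)
        node, k, rest = vals[0], vals[1], vals[2:]
        if not (1 <= node <= n):
            raise GraphFormatError(f"node id {node} out of range 1..{n}", line_no)
        if node in nbrs:
            raise GraphFormatError(f"duplicate listing for node {node}", line_no)
        if len(rest) != k:
            raise GraphFormatError(
                f"node {node} declares {k} neighbours but lists {len(rest)}", line_no
            )
        for nb in rest:
            if not (1 <= nb <= n):
                raise GraphFormatError(
                    f"neighbour id {nb} of node {node} out of range 1..{n}", line_no
                )
            if nb == node:
                raise GraphFormatError(f"node {node} lists itself as neighbour", line_no)
        nbrs[node] = rest
    missing = sorted(set(range(1, n + 1)) - set(nbrs))
    if missing:
        raise GraphFormatError(f"missing listings for nodes {missing}")
    for node, rest in nbrs.items():
        for nb in rest:
            if node not in nbrs[nb]:
                raise GraphFormatError(
                    f"asymmetric adjacency: {node} lists {nb} but not vice versa"
                )
    edges = {(min(a, b) - 1, max(a, b) - 1) for a, rest in nbrs.items() for b in rest}
    return AdjacencyGraph.from_edges([str(i) for i in range(1, n + 1)], edges)


def write_graph(graph: AdjacencyGraph, path) -> None:
    """Write in the R-INLA plain-text graph format (canonical form)."""
    n = graph.n_areas
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for i, j in sorted(graph.edges):
        adj[i].append(j)
        adj[j].append(i)
    out = [str(n)]
    for i in range(n):
        nb = sorted(adj[i])
        out.append(" ".join([str(i + 1), str(len(nb))] + [str(j + 1) for j in nb]))
    text = "\n".join(out) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text)


# ---------------------------------------------------------------------------
# constraints and scaling
# ---------------------------------------------------------------------------

def constraint_system(graph: AdjacencyGraph, mode: str = "per_region") -> np.ndarray:
    """Sum-to-zero constraint matrix A with ``A u = 0``.

    ``single``: one row of ones over all areas (joint constraint for the
    union of the subgraphs).  ``per_region``: one indicator row per connected
    component.
    """
    n = graph.n_areas
    if mode == "single":
        return np.ones((1, n))
    if mode == "per_region":
        A = np.zeros((graph.n_components, n))
        for c, idx in enumerate(graph.components()):
            A[c, idx] = 1.0
        return A
    raise ValueError(f"unknown constraint mode {mode!r}")


@dataclass(frozen=True)
class IcarStructure:
    """Scaled ICAR structure with its constraint system.

    ``structure_matrix`` is the scaled ``R``; ``tau * structure_matrix`` is
    the (rank-deficient) prior precision of the structured field.  The
    scaling makes the geometric mean of the constrained marginal variances
    exactly one per scaling group, so ``1/tau`` is a marginal variance.
    """

    structure_matrix: sp.csr_matrix
    scaling_factors: tuple
    scaling_mode: str
    constraint_matrix: np.ndarray
    constraint_mode: str
    component_labels: tuple
    _spectral_cache: dict = field(default_factory=dict, compare=False, repr=False)

    @property
    def n_areas(self) -> int:
        return self.structure_matrix.shape[0]

    def components(self) -> list[np.ndarray]:
        labels = np.asarray(self.component_labels)
        return [np.flatnonzero(labels == c) for c in range(max(self.component_labels) + 1)]

    def component_spectra(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Cached eigendecomposition (w, V) of each scaled component block."""
        if "spectra" not in self._spectral_cache:
            spectra = []
            for idx in self.components():
                block = self.structure_matrix[np.ix_(idx, idx)].toarray()
                w, V = np.linalg.eigh(block)
                spectra.append((w, V))
            self._spectral_cache["spectra"] = spectra
        return self._spectral_cache["spectra"]

    def log_generalized_determinants(self) -> np.ndarray:
        """Per component: sum of log positive eigenvalues of the scaled block."""
        out = []
        for w, _ in self.component_spectra():
            tol = max(1e-10, 1e-10 * w[-1])
            out.append(float(np.log(w[w > tol]).sum()))
        return np.array(out)

    def ranks(self) -> np.ndarray:
        """Per component rank of the scaled block (size minus one)."""
        return np.array([len(idx) - 1 for idx in self.components()])


def icar_marginal_variances(R, component_labels) -> np.ndarray:
    """Constrained marginal variances diag(R^+) per area.

    The Moore-Penrose pseudo-inverse of each component block is the
    covariance of the intrinsic field under that component's sum-to-zero
    constraint (the null space of a connected block is its constant vector).
    """
    R = sp.csr_matrix(R)
    labels = np.asarray(component_labels)
    var = np.empty(R.shape[0])
    for c in range(labels.max() + 1):
        idx = np.flatnonzero(labels == c)
        if len(idx) == 1:
            raise SingletonComponentError(
                f"singleton component at area index {idx[0]}"
            )
        block = R[np.ix_(idx, idx)].toarray()
        w, V = np.linalg.eigh(block)
        tol = max(1e-10, 1e-10 * w[-1])
        pos = w > tol
        var[idx] = (V[:, pos] ** 2 / w[pos]).sum(axis=1)
    return var


def icar_scaling_factors(R, component_labels, mode: str = "per_component") -> np.ndarray:
    """Geometric-mean marginal variance per scaling group of a structure matrix."""
    var = icar_marginal_variances(R, component_labels)
    labels = np.asarray(component_labels)
    if mode == "global":
        return np.array([np.exp(np.mean(np.log(var)))])
    if mode == "per_component":
        return np.array(
            [np.exp(np.mean(np.log(var[labels == c]))) for c in range(labels.max() + 1)]
        )
    raise ValueError(f"unknown scaling mode {mode!r}")


def scale_icar(
    graph: AdjacencyGraph,
    mode: str = "per_component",
    constraint_mode: str | None = None,
) -> IcarStructure:
    """Scaled ICAR structure for a graph.

    ``mode='global'`` pools the geometric mean over all areas of all
    components into a single factor (matching a joint treatment of the
    disconnected graph); ``mode='per_component'`` scales each component
    block independently.  Singleton components are rejected.

    The default constraint mode follows the scaling mode: ``single`` for
    global scaling, ``per_region`` otherwise.
    """
    singles = graph.singleton_components()
    if singles:
        raise SingletonComponentError(
            f"graph has singleton component(s) at area(s) {singles!r}; "
            "the ICAR models require every region to contain at least two areas"
        )
    if constraint_mode is None:
        constraint_mode = "single" if mode == "global" else "per_region"
    R = graph.structure_matrix().astype(float)
    factors = icar_scaling_factors(R, graph.component_labels, mode)
    labels = np.asarray(graph.component_labels)
    scale = np.empty(graph.n_areas)
    if mode == "global":
        scale[:] = factors[0]
    else:
        for c, f in enumerate(factors):
            scale[labels == c] = f
    # symmetric scaling: multiplying block g of R by its factor divides the
    # constrained marginal variances of that block by the same factor
    S = sp.diags(np.sqrt(scale))
    R_scaled = (S @ R @ S).tocsr()
    A = constraint_system(graph, constraint_mode)
    return IcarStructure(
        structure_matrix=R_scaled,
        scaling_factors=tuple(float(f) for f in factors),
        scaling_mode=mode,
        constraint_matrix=A,
        constraint_mode=constraint_mode,
        component_labels=graph.component_labels,
    )
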