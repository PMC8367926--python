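"""Principal coordinates of neighbour matrices (PCNM / Moran eigenvector
maps) from plot coordinates, with a broad / mid / fine scale classification.

Construction: Euclidean distances between plots; distances above a
truncation threshold ``t`` (the longest edge of the minimum spanning tree,
which keeps the neighbour graph connected) are replaced by ``4t``; the
modified matrix is double-centered and eigendecomposed (principal
coordinates).  Axes with positive eigenvalues are kept, unit-normed and
ordered by decreasing eigenvalue.  Leading axes vary smoothly over the
whole extent (broad scale); later axes oscillate at shorter wavelengths.

Scale classification estimates each eigenvector's characteristic
wavelength from a Lomb-Scargle periodogram of its values along a path
ordering of the minimum spanning tree, then bins by two wavelength
cutoffs into {broad, mid, fine}.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.signal import lombscargle
from scipy.spatial.distance import pdist, squareform

from .datasets import Coordinates, DissimilarityMatrix

log = logging.getLogger("betascape")

__all__ = [
    "PCNMBasis",
    "geographic_distances",
    "truncation_threshold",
    "pcnm_basis",
    "classify_scale",
    "DEFAULT_SCALE_BOUNDARIES",
]

# Wavelength cutoffs (km) separating broad/mid and mid/fine scale classes.
# The reference scale areas 50, 5 and 0.5 km^2 correspond to length scales
# sqrt(50), sqrt(5), sqrt(0.5) km; cutoffs sit at the geometric midpoints.
DEFAULT_SCALE_BOUNDARIES = (
    float(np.sqrt(np.sqrt(50.0) * np.sqrt(5.0))),   # ~3.98 km
    float(np.sqrt(np.sqrt(5.0) * np.sqrt(0.5))),    # ~1.26 km
)


@dataclass(frozen=True)
class PCNMBasis:
    """Spatial eigenfunctions with their eigenvalues and scale labels."""

    plot_ids: tuple
    eigenvectors: np.ndarray  # (n_plots, k), unit-norm columns
    eigenvalues: np.ndarray   # (k,), positive, descending
    truncation_threshold: float
    wavelengths: np.ndarray | None = None
    scale_class: tuple | None = None  # per axis in {"broad","mid","fine"}

    def __post_init__(self):
        ev = np.asarray(self.eigenvalues, float)
        if (ev <= 0).any():
            raise ValueError("eigenvalues must be positive")
        if (np.diff(ev) > 1e-9 * max(ev[0], 1.0)).any():
            raise ValueError("eigenvalues must be sorted descending")
        if self.eigenvectors.shape[1] != ev.size:
            raise ValueError("eigenvector/eigenvalue count mismatch")

    @property
    def k(self) -> int:
        return self.eigenvalues.size

    def select(self, scale: str) -> np.ndarray:
        """Eigenvectors of one scale class (columns)."""
        if self.scale_class is None:
            raise ValueError("scale classes not assigned; run classify_scale")
        idx = [i for i, s in enumerate(self.scale_class) if s == scale]
        return self.eigenvectors[:, idx]


def geographic_distances(coordinates: Coordinates) -> DissimilarityMatrix:
    """Pairwise Euclidean distances (km) between plots."""
    d = squareform(pdist(coordinates.xy))
    dup = (squareform(d) == 0).sum()
    if dup:
        warnings.warn(f"{dup} plot pair(s) at identical coordinates",
                      stacklevel=2)
    return DissimilarityMatrix(coordinates.plot_ids, d, "geographic_km")


def truncation_threshold(distances: DissimilarityMatrix) -> float:
    """Longest edge of the minimum spanning tree of the distance graph.

    The smallest threshold for which the keep-neighbours graph stays
    connected.
    """
    d = distances.values
    if d.shape[0] < 2:
        raise ValueError("need at least 2 plots")
    mst = minimum_spanning_tree(d).toarray()
    return float(mst.max())


def pcnm_basis(coordinates: Coordinates,
               threshold: float | None = None,
               fill_factor: float = 4.0) -> PCNMBasis:
    """Spatial eigenfunctions of the truncated distance matrix.

    ``threshold=None`` uses :func:`truncation_threshold`;
    ``threshold=inf`` disables truncation, reducing the construction to
    classical PCoA of the raw distances.  Distances beyond the threshold
    are replaced by ``fill_factor * threshold`` (canonical factor 4).
    """
    if len(coordinates.plot_ids) < 3:
        raise ValueError("need at least 3 plots")
    dm = geographic_distances(coordinates)
    if not dm.values[np.triu_indices(len(coordinates.plot_ids), 1)].any():
        raise ValueError("all coordinates identical")
    t = truncation_threshold(dm) if threshold is None else float(threshold)
    d = dm.values.copy()
    if np.isfinite(t):
        mask = d > t
        np.fill_diagonal(mask, False)
        d[mask] = fill_factor * t
    n = d.shape[0]
    # Gower double-centering of -0.5 * D^2
    a = -0.5 * d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    g = 0.5 * (g + g.T)
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-9 * max(abs(evals).max(), 1.0)
    pos = evals > tol
    n_dropped = int((~pos).sum())
    log.info("pcnm: retained %d positive axes, discarded %d",
             int(pos.sum()), n_dropped)
    vecs = evecs[:, pos]
    # deterministic sign: largest-magnitude loading positive
    for col in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, col]))
        if vecs[i, col] < 0:
            vecs[:, col] = -vecs[:, col]
    return PCNMBasis(plot_ids=coordinates.plot_ids,
                     eigenvectors=vecs, eigenvalues=evals[pos],
                     truncation_threshold=t)


def _mst_path_ordering(coordinates: Coordinates) -> tuple[np.ndarray, np.ndarray]:
    """Plot ordering by depth-first traversal of the MST from one end of
    its diameter, with cumulative along-path positions (km)."""
    import networkx as nx

    d = squareform(pdist(coordinates.xy))
    mst = minimum_spanning_tree(d).toarray()
    g = nx.Graph()
    n = d.shape[0]
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if mst[i, j] > 0:
                g.add_edge(i, j, weight=mst[i, j])
    # approximate diameter endpoint: farthest node from node 0, twice
    start = 0
    for _ in range(2):
        lengths = nx.single_source_dijkstra_path_length(g, start)
        start = max(lengths, key=lengths.get)
    order = list(nx.dfs_preorder_nodes(g, start))
    pos = np.zeros(n)
    for k in range(1, n):
        pos[k] = pos[k - 1] + d[order[k - 1], order[k]]
    return np.asarray(order), pos


def classify_scale(basis: PCNMBasis,
                   boundaries: tuple[float, float] = DEFAULT_SCALE_BOUNDARIES,
                   coordinates: Coordinates | None = None) -> PCNMBasis:
    """Assign each eigenvector a characteristic wavelength and scale class.

    The wavelength is the dominant period of the eigenvector's values along
    the MST path ordering of the plots (Lomb-Scargle periodogram, which
    tolerates irregular spacing).  ``boundaries = (broad_mid, mid_fine)``
    in km: wavelength >= broad_mid -> broad, >= mid_fine -> mid, else fine.
    """
    if basis.k < 1:
        raise ValueError("basis has no eigenvectors")
    b1, b2 = boundaries
    if b2 > b1:
        raise ValueError("boundaries must be (broad_mid >= mid_fine)")
    if coordinates is None:
        raise ValueError("classify_scale needs the plot coordinates")
    order, pos = _mst_path_ordering(coordinates)
    extent = pos[-1] if pos[-1] > 0 else 1.0
    # candidate wavelengths from twice the extent down to twice the mean gap
    min_wl = max(2.0 * extent / max(len(pos) - 1, 1), 1e-6)
    wls = np.geomspace(2.0 * extent, min_wl, 256)
    ang = 2.0 * np.pi / wls
    wavelengths = np.empty(basis.k)
    for a in range(basis.k):
        y = basis.eigenvectors[order, a]
        y = y - y.mean()
        power = lombscargle(pos, y, ang)
        wavelengths[a] = wls[np.argmax(power)]
    classes = tuple("broad" if w >= b1 else ("mid" if w >= b2 else "fine")
                    for w in wavelengths)
    return replace(basis, wavelengths=wavelengths, scale_class=classes)
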