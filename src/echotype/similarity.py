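"""Pairwise similarity mathematics and percentile-based edge pruning.

Every network in the pipeline — per-bin click networks, the cross-bin
summary-node network, and the classifier's test-to-training score set —
is built from the same three ingredients:

* **spectral similarity**: correlation distance between the first
  differences of amplitude-normalized spectra, mapped through
  ``S = exp(-D)`` so weights live in ``(0, 1]``,
* **ICI similarity**: ``exp(-|ici_a - ici_b|)`` between modal
  inter-click intervals measured in seconds,
* **dynamic percentile pruning**: the weakest fraction ``p_e`` of edges
  is removed from each network, so strongly and weakly inter-related
  networks are pruned by the same proportion.

Working on first differences of min-max-normalized spectra makes the
spectral metric invariant to absolute received level and to any affine
rescaling of the dB values; only spectral *shape* matters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "DegenerateSpectrumError",
    "normalize_spectrum",
    "normalize_spectra",
    "spectral_similarity",
    "ici_similarity",
    "combined_similarity",
    "PrunedNetwork",
    "prune_network",
    "complete_edge_count",
    "retained_edge_count",
]


class DegenerateSpectrumError(ValueError):
    """Raised when a spectrum is constant and cannot be min-max normalized."""


def normalize_spectrum(u: np.ndarray) -> np.ndarray:
    """Min-max normalize a spectrum to the unit interval.

    ``u_n = (u - min(u)) / max(u - min(u))`` so that ``min(u_n) = 0`` and
    ``max(u_n) = 1``.  Idempotent.

    Parameters
    ----------
    u : array of dB spectral levels (at least 2 bins).

    Raises
    ------
    DegenerateSpectrumError
        If the spectrum is constant (zero range); callers are expected to
        drop the offending click.
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 1 or u.size < 2:
        raise ValueError("spectrum must be a 1-D vector with >= 2 bins")
    lo = u.min()
    span = u.max() - lo
    if not np.isfinite(span) or span == 0.0:
        raise DegenerateSpectrumError("constant or non-finite spectrum")
    return (u - lo) / span


def normalize_spectra(spectra: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise min-max normalization of a stack of spectra.

    Returns ``(normalized, valid)`` where ``valid`` flags rows with a
    non-zero, finite range.  Invalid rows are left as NaN and should be
    excluded by the caller (they cannot carry shape information).
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 2:
        raise ValueError("expected a 2-D (n_spectra, n_bins) array")
    lo = spectra.min(axis=1, keepdims=True)
    span = spectra.max(axis=1, keepdims=True) - lo
    valid = np.isfinite(span[:, 0]) & (span[:, 0] > 0)
    out = np.full_like(spectra, np.nan)
    if valid.any():
        out[valid] = (spectra[valid] - lo[valid]) / span[valid]
    return out, valid


def spectral_similarity(a: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Pairwise spectral-shape similarity between sets of normalized spectra.

    For each pair, the first difference across frequency bins is taken and
    the correlation distance ``D = 1 - r`` computed between the two
    difference vectors; the similarity is ``S = exp(-D)``, in
    ``[exp(-2), 1]``.

    Parameters
    ----------
    a, b : (n, n_bins) arrays of normalized spectra on a common grid.
        With ``b=None`` the within-set (square, symmetric) matrix is
        returned.

    Notes
    -----
    Rows whose first difference has zero variance (monotone-linear
    spectra) have no defined correlation; their similarities are returned
    as NaN with a warning, and downstream pruning treats NaN edges as
    absent, isolating the node.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    within = b is None
    b = a if within else np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("spectra must share a common frequency grid")
    da = np.diff(a, axis=1)
    db = da if within else np.diff(b, axis=1)

    def _degenerate(d):
        scale = np.abs(d).max(axis=1)
        return d.std(axis=1) <= 1e-10 * np.maximum(scale, 1e-30)

    bad_a = _degenerate(da)
    bad_b = bad_a if within else _degenerate(db)
    if bad_a.any() or bad_b.any():
        warnings.warn(
            "zero-variance first-difference spectra: similarity undefined "
            "for %d row(s); affected pairs set to NaN"
            % int(bad_a.sum() + (0 if within else bad_b.sum())),
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = cdist(da, db, metric="correlation")
    s = np.exp(-d)
    if bad_a.any():
        s[bad_a, :] = np.nan
    if bad_b.any():
        s[:, bad_b] = np.nan
    if within:
        # enforce exact symmetry against float round-off
        s = 0.5 * (s + s.T)
    return s


def ici_similarity(ici_a, ici_b):
    """Similarity between modal inter-click intervals (seconds).

    Euclidean distance between the modal ICIs mapped through
    ``exp(-|a - b|)``; symmetric, equals 1 at zero distance.  Accepts
    scalars or broadcastable arrays.
    """
    return np.exp(-np.abs(np.asarray(ici_a, dtype=float) - np.asarray(ici_b, dtype=float)))


def combined_similarity(s_spec, s_ici):
    """Fused similarity ``S2 = S_ICI * S_SPEC``.

    Multiplicative fusion requires both spectral shape and click-rate
    evidence to be strong for the combined score to be strong; the result
    never exceeds either factor.
    """
    return np.asarray(s_spec, dtype=float) * np.asarray(s_ici, dtype=float)


def complete_edge_count(n_nodes: int, self_inclusive: bool = True) -> int:
    """Edge count of a complete n-node similarity network.

    Two counting conventions are exposed:

    * ``self_inclusive=True`` — the reporting convention used for printed
      network sizes, ``n**2 / 2`` (a 5,000-node network "contains 12.5
      million edges");
    * ``self_inclusive=False`` — the number of distinct unordered pairs
      ``n * (n - 1) / 2`` actually stored internally.
    """
    n = int(n_nodes)
    return (n * n) // 2 if self_inclusive else (n * (n - 1)) // 2


def retained_edge_count(n_edges: int, p_e: float) -> int:
    """Pruning quota: edges retained from ``n_edges`` at pruning fraction ``p_e``."""
    if not 0.0 <= p_e < 1.0:
        raise ValueError("p_e must be in [0, 1)")
    return int(np.rint((1.0 - p_e) * n_edges))


@dataclass
class PrunedNetwork:
    """A weighted network after percentile edge pruning.

    ``edges_i``/``edges_j`` index into ``node_ids``; ``weights`` are the
    surviving edge weights.  ``isolated_nodes`` are node ids left with no
    surviving edge (including nodes whose every pair was degenerate).
    """

    node_ids: np.ndarray
    edges_i: np.ndarray
    edges_j: np.ndarray
    weights: np.ndarray
    p_e: float
    n_edges_before: int = 0  # finite distinct pairs prior to pruning

    isolated_nodes: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.isolated_nodes is None:
            connected = np.zeros(len(self.node_ids), dtype=bool)
            connected[self.edges_i] = True
            connected[self.edges_j] = True
            self.isolated_nodes = np.asarray(self.node_ids)[~connected]

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    @property
    def isolation_fraction(self) -> float:
        if self.n_nodes == 0:
            return 0.0
        return len(self.isolated_nodes) / self.n_nodes

    def edge_list(self) -> list[tuple]:
        """Edges as ``(node_i, node_j, weight)`` tuples."""
        ids = np.asarray(self.node_ids)
        return [
            (ids[i], ids[j], float(w))
            for i, j, w in zip(self.edges_i, self.edges_j, self.weights)
        ]


def prune_network(sim: np.ndarray, p_e: float, node_ids=None) -> PrunedNetwork:
    """Remove the weakest ``p_e`` fraction of edges from a similarity matrix.

    The percentile is dynamic (computed per network, not an absolute
    threshold): the quota of retained edges is
    ``round((1 - p_e) * n_finite_pairs)``.  Edges with NaN weight
    (degenerate pairs) are discarded before the quota is computed.
    Ties at the cut are broken by a stable sort on ``(weight, i, j)`` so
    the surviving edge sets are deterministic and nested across
    increasing ``p_e``.

    Parameters
    ----------
    sim : (n, n) symmetric similarity matrix; the diagonal is ignored.
    p_e : pruning fraction in ``[0, 1)``.
    node_ids : optional sequence of node identifiers (defaults to
        ``0..n-1``).
    """
    if not 0.0 <= p_e < 1.0:
        raise ValueError("p_e must be in [0, 1)")
    sim = np.asarray(sim, dtype=float)
    if sim.size == 0:
        empty = np.empty(0, dtype=int)
        return PrunedNetwork(
            node_ids=np.empty(0, dtype=object) if node_ids is None else np.asarray(node_ids),
            edges_i=empty, edges_j=empty, weights=np.empty(0), p_e=p_e,
            n_edges_before=0,
        )
    n = sim.shape[0]
    if sim.shape != (n, n):
        raise ValueError("similarity matrix must be square")
    ids = np.arange(n) if node_ids is None else np.asarray(node_ids)
    if len(ids) != n:
        raise ValueError("node_ids length must match matrix size")

    iu, ju = np.triu_indices(n, k=1)
    w = sim[iu, ju]
    finite = np.isfinite(w)
    iu, ju, w = iu[finite], ju[finite], w[finite]
    m = w.size
    keep = retained_edge_count(m, p_e)
    order = np.lexsort((ju, iu, w))  # ascending weight; deterministic ties
    kept = order[m - keep:] if keep > 0 else order[:0]
    kept = np.sort(kept)  # restore (i, j) ordering for readability
    return PrunedNetwork(
        node_ids=ids,
        edges_i=iu[kept],
        edges_j=ju[kept],
        weights=w[kept],
        p_e=p_e,
        n_edges_before=m,
    )
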