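"""Functional connectivity by wPLI and nodal graph metrics over sparsity.

The weighted phase lag index for a channel pair pools the imaginary part
of the STFT cross-spectrum over segments and in-band frequency bins of
one trial:

    wPLI = |sum Im(Z)| / sum |Im(Z)|,       Z = X_i * conj(X_j)

with the 0/0 case (identically zero imaginary part, e.g. a zero-lag
copy) mapped to 0, treating purely instantaneous coupling as a
non-connection.  The estimator is the standard (non-debiased) form and
is invariant to positive rescaling of either channel.

Each 19x19 wPLI matrix is binarised by a proportional sparsity
threshold (retain the top ``ceil(ratio * n(n-1)/2)`` edges) over a grid
of retention ratios, default 10 % to 40 % in 1 % steps.  Four nodal
metrics are computed on each binary graph and summarised as the
trapezoidal area under the metric-vs-ratio curve (AUC):

    ND_i = sum_j A_ij                          (degree)
    NB_i = 2/(n(n-1)) * sum_{j<h} s_jh(i)/s_jh (betweenness)
    NE_i = mean_{j != i} 1/d_ij                (efficiency, 1/inf = 0)
    CC_i = 2 t_i / (ND_i (ND_i - 1))           (clustering, 0 if ND_i < 2)

where ``s_jh`` counts shortest paths, ``d`` is shortest path length and
``t_i`` counts triangles through ``i``.  The betweenness normalisation
``2/(n(n-1))`` follows the published metric table; the conventional
``2/((n-1)(n-2))`` is available via ``normalization="conventional"``.

Shortest-path lengths and counts are obtained from powers of the
adjacency matrix (a walk of length equal to the graph distance is
necessarily a shortest path), which keeps the whole metric set
vectorised -- the pipeline evaluates tens of thousands of small graphs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .spectral import Band, DEFAULT_BANDS, stft_complex

__all__ = [
    "SparsityGrid",
    "wpli",
    "proportional_threshold",
    "graph_metrics",
    "metric_auc",
    "trial_graph_metrics",
    "GRAPH_METRIC_NAMES",
]

GRAPH_METRIC_NAMES: tuple[str, ...] = ("ND", "NB", "NE", "CC")


def _default_ratios() -> tuple[float, ...]:
    return tuple(round(0.10 + 0.01 * k, 2) for k in range(31))


@dataclass(frozen=True)
class SparsityGrid:
    """Ordered edge-retention fractions, default 0.10..0.40 step 0.01."""

    ratios: tuple[float, ...] = field(default_factory=_default_ratios)

    def __post_init__(self) -> None:
        r = np.asarray(self.ratios, dtype=float)
        if r.size == 0:
            raise ValueError("sparsity grid is empty")
        if not (np.all(r > 0) and np.all(r <= 1)):
            raise ValueError("sparsity ratios must lie in (0, 1]")
        if r.size > 1 and not np.all(np.diff(r) > 0):
            raise ValueError("sparsity ratios must be strictly increasing")


def wpli(
    samples: np.ndarray,
    fs: float,
    band: Band,
    window_s: float = 1.0,
    overlap: float = 0.5,
    min_segments: int = 8,
) -> np.ndarray:
    """Weighted phase lag index matrix for one trial.

    ``samples`` is ``(n_channels, n_samples)``.  Returns a symmetric
    ``(n, n)`` matrix with values in [0, 1] and zero diagonal.  Raises if
    fewer than ``min_segments`` STFT segments are available (the pooled
    estimator is unstable below that).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] < 2:
        raise ValueError("need a (n_channels >= 2, n_samples) array")
    freqs, X = stft_complex(samples, fs, window_s=window_s, overlap=overlap)
    n_seg = X.shape[-2]
    if n_seg < min_segments:
        raise ValueError(
            f"only {n_seg} STFT segments available; wPLI needs >= {min_segments}"
        )
    in_band = (freqs >= band.low_hz) & (freqs < band.high_hz)
    if not in_band.any():
        raise ValueError(f"band {band.name!r} contains no frequency bins")
    Xb = X[:, :, in_band]  # (ch, seg, bin)
    # Im(Z_ij) pooled over segments x bins.
    imz = np.einsum("isf,jsf->ijsf", Xb, np.conj(Xb)).imag
    imz = imz.reshape(imz.shape[0], imz.shape[1], -1)
    num = np.abs(imz.sum(axis=-1))
    den = np.abs(imz).sum(axis=-1)
    W = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    np.fill_diagonal(W, 0.0)
    # Enforce exact symmetry against floating-point asymmetries.
    W = 0.5 * (W + W.T)
    return np.clip(W, 0.0, 1.0)


def proportional_threshold(
    W: np.ndarray,
    ratio: float,
    ties: str = "lexicographic",
) -> np.ndarray:
    """Binarise ``W`` by retaining the strongest fraction of edges.

    Retains the top ``ceil(ratio * n(n-1)/2)`` off-diagonal edges by
    weight.  ``ties="lexicographic"`` (default) breaks ties at the cut by
    (i, j) order so exactly the requested count is kept;
    ``ties="all"`` keeps every edge whose weight ties with the cut.
    An all-zero matrix yields an all-zero adjacency with a warning.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if W.ndim != 2 or W.shape[1] != n:
        raise ValueError("W must be square")
    if not np.allclose(W, W.T):
        raise ValueError("W must be symmetric")
    if not 0 < ratio <= 1:
        raise ValueError(f"ratio must be in (0, 1], got {ratio}")
    if ties not in ("lexicographic", "all"):
        raise ValueError(f"unknown tie rule {ties!r}")
    iu, ju = np.triu_indices(n, k=1)
    weights = W[iu, ju]
    A = np.zeros((n, n), dtype=int)
    if not np.any(weights > 0):
        warnings.warn("all-zero connectivity matrix; returning empty graph")
        return A
    k = math.ceil(ratio * weights.size)
    order = np.lexsort((ju, iu, -weights))
    if ties == "lexicographic":
        keep = order[:k]
    else:
        cut = weights[order[k - 1]]
        keep = np.flatnonzero(weights >= cut)
    A[iu[keep], ju[keep]] = 1
    A += A.T
    return A


def _apsp_counts(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs shortest-path lengths and counts on binary graphs.

    ``A`` has shape ``(..., n, n)``.  Uses adjacency powers:
    ``(A^k)[j, h]`` counts walks of length k, and a walk whose length
    equals the graph distance is necessarily a shortest path.
    """
    n = A.shape[-1]
    Af = A.astype(float)
    d = np.broadcast_to(
        np.where(np.eye(n) == 1, 0.0, np.inf), Af.shape
    ).copy()
    sigma = np.broadcast_to(np.eye(n), Af.shape).copy()
    Ak = sigma.copy()
    for k in range(1, n):
        Ak = Ak @ Af
        new = (Ak > 0) & ~np.isfinite(d)
        if new.any():
            d[new] = k
            sigma[new] = Ak[new]
        if np.isfinite(d).all():
            break
    return d, sigma


def _metrics_batch(A: np.ndarray, normalization: str) -> dict[str, np.ndarray]:
    """The four nodal metrics for a batch of graphs, shape ``(..., n, n)``."""
    n = A.shape[-1]
    nd = A.sum(axis=-1).astype(float)

    d, sigma = _apsp_counts(A)
    finite = np.isfinite(d)

    # Efficiency: mean inverse distance to the other n-1 nodes (1/inf = 0).
    inv_d = np.zeros_like(d)
    np.divide(1.0, d, out=inv_d, where=finite & (d > 0))
    ne = inv_d.sum(axis=-1) / max(n - 1, 1)

    # Clustering: triangles through i over possible neighbour links.
    Af = A.astype(float)
    tri = np.diagonal(Af @ Af @ Af, axis1=-2, axis2=-1) / 2.0
    denom = nd * (nd - 1.0)
    cc = np.divide(2.0 * tri, denom, out=np.zeros_like(nd), where=denom > 0)

    # Betweenness: fraction of shortest j-h paths through i, unordered
    # pairs j != h, both distinct from i; disconnected pairs contribute 0.
    # Axes of the broadcast tensors: (..., j, i, h).
    on_path = (
        finite[..., :, :, None]
        & finite[..., None, :, :]
        & finite[..., :, None, :]
        & (d[..., :, :, None] + d[..., None, :, :] == d[..., :, None, :])
    )
    s_jh = np.broadcast_to(sigma[..., :, None, :], A.shape[:-2] + (n, n, n))
    frac = np.zeros(A.shape[:-2] + (n, n, n))
    np.divide(
        sigma[..., :, :, None] * sigma[..., None, :, :],
        s_jh,
        out=frac,
        where=on_path & (s_jh > 0),
    )
    idx = np.arange(n)
    frac[..., idx, idx, :] = 0.0  # j == i
    frac[..., :, idx, idx] = 0.0  # h == i
    frac[..., idx, :, idx] = 0.0  # j == h
    raw = 0.5 * frac.sum(axis=(-3, -1))
    if normalization == "printed":
        norm = 2.0 / (n * (n - 1)) if n > 1 else 0.0
    else:
        norm = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 0.0
    nb = norm * raw

    return {"ND": nd, "NB": nb, "NE": ne, "CC": cc}


def graph_metrics(A: np.ndarray, normalization: str = "printed") -> dict[str, np.ndarray]:
    """Nodal degree, betweenness, efficiency and clustering coefficient.

    ``A`` must be binary, symmetric, with a zero diagonal.  Disconnected
    pairs contribute 0 to betweenness and efficiency.  Returns a mapping
    ``{"ND": ..., "NB": ..., "NE": ..., "CC": ...}`` of per-node arrays.
    """
    A = np.asarray(A)
    n = A.shape[0]
    if A.ndim != 2 or A.shape[1] != n:
        raise ValueError("A must be square")
    if not np.array_equal(A, A.T):
        raise ValueError("A must be symmetric")
    if not np.isin(A, (0, 1)).all():
        raise ValueError("A must be binary")
    if np.any(np.diagonal(A) != 0):
        raise ValueError("A must have a zero diagonal")
    if normalization not in ("printed", "conventional"):
        raise ValueError(f"unknown normalization {normalization!r}")
    return _metrics_batch(A, normalization)


def metric_auc(
    W: np.ndarray,
    grid: SparsityGrid | None = None,
    ties: str = "lexicographic",
    normalization: str = "printed",
    degenerate: str = "zero",
) -> dict[str, np.ndarray]:
    """Trapezoidal AUC of each nodal metric over the sparsity grid.

    Returns ``{metric: (n_nodes,) AUC}`` with the retention ratio as the
    x-axis in fractional units.  A single-ratio grid yields zero-width
    AUCs of 0 when ``degenerate="zero"`` and raises when
    ``degenerate="error"``.
    """
    grid = grid or SparsityGrid()
    ratios = np.asarray(grid.ratios, dtype=float)
    if ratios.size < 2:
        if degenerate == "error":
            raise ValueError("sparsity grid has a single ratio; AUC is degenerate")
        n = np.asarray(W).shape[0]
        return {m: np.zeros(n) for m in GRAPH_METRIC_NAMES}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-zero W warns once per ratio
        stack = np.stack(
            [proportional_threshold(W, float(r), ties=ties) for r in ratios]
        )
    metrics = _metrics_batch(stack, normalization)  # batched over ratios
    return {
        m: np.trapezoid(metrics[m], x=ratios, axis=0) for m in GRAPH_METRIC_NAMES
    }


def trial_graph_metrics(
    samples: np.ndarray,
    fs: float,
    bands: Iterable[Band] = DEFAULT_BANDS,
    grid: SparsityGrid | None = None,
    window_s: float = 1.0,
    overlap: float = 0.5,
    ties: str = "lexicographic",
    normalization: str = "printed",
) -> dict[str, dict[str, np.ndarray]]:
    """Per-band graph-metric AUCs for one trial.

    Returns ``{band name: {metric: (n_channels,) AUC}}``.
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    for band in bands:
        W = wpli(samples, fs, band, window_s=window_s, overlap=overlap)
        out[band.name] = metric_auc(
            W, grid=grid, ties=ties, normalization=normalization
        )
    return out
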