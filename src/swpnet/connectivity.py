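"""Envelope connectivity: orthogonalization, log-power correlation, thresholding.

Per subject and carrier, every node pair is scored by the Fisher-z of the
Pearson correlation between log power envelopes after removing the zero-lag
coherent component (pairwise orthogonalization), averaged over both
directions.  Across subjects, edges are ranked by their coefficient of
variation and the lowest-CV edges are kept at each target density, yielding
identical (equally sparse) masks for every subject.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .spectral import AnalyticSpectra, CarrierGrid

__all__ = [
    "AdjacencyStack",
    "DensitySweepGraphs",
    "orthogonalize",
    "envelope_correlation",
    "build_adjacency",
    "consistency_threshold",
]

MIN_VALID_SAMPLES = 30
R_CLIP = 1.0 - 1e-12


@dataclasses.dataclass
class AdjacencyStack:
    """Per-subject, per-carrier symmetric Fisher-z adjacency matrices."""

    weights: np.ndarray  # (n_subjects, n_carriers, n, n)
    grid: CarrierGrid
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 4 or w.shape[-1] != w.shape[-2]:
            raise ValueError("weights must be (subject, carrier, n, n)")
        if w.shape[1] != len(self.grid):
            raise ValueError("carrier axis must match the grid length")
        if not np.allclose(w, np.swapaxes(w, -1, -2)):
            raise ValueError("adjacency matrices must be symmetric")
        if np.any(np.diagonal(w, axis1=-2, axis2=-1) != 0):
            raise ValueError("adjacency diagonals must be zero")
        self.weights = w

    @property
    def n_subjects(self) -> int:
        return self.weights.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[-1]


@dataclasses.dataclass
class DensitySweepGraphs:
    """Shared boolean edge masks per carrier and density level.

    Masks are nested: every edge kept at density d is kept at any d' > d.
    ``edge_cv`` records the per-edge coefficient of variation used for the
    ranking (``inf`` where the cross-subject mean was zero).
    """

    masks: np.ndarray  # bool, (n_carriers, n_densities, n, n)
    densities_pct: np.ndarray
    edge_cv: np.ndarray  # (n_carriers, n, n)

    def __post_init__(self) -> None:
        if self.masks.ndim != 4:
            raise ValueError("masks must be (carrier, density, n, n)")


def orthogonalize(x: np.ndarray, y: np.ndarray, floor: float | None = None) -> np.ndarray:
    """Component of analytic signal y orthogonal to x at zero lag.

    Implements ``imag(y * conj(x) / |x|)`` sample-wise, which removes the
    instantaneously coherent (same-phase) part of y along x.  Returned as a
    real series (the magnitude of the orthogonal component with sign).
    """
    x = np.asarray(x, dtype=complex)
    y = np.asarray(y, dtype=complex)
    mag = np.abs(x)
    top = mag.max(initial=0.0)
    if top == 0.0:
        raise ValueError("cannot orthogonalize against an all-zero reference signal")
    if floor is None:
        floor = np.finfo(float).eps * top
    mag = np.maximum(mag, floor)
    return np.imag(y * np.conj(x) / mag)


def _log_power(env: np.ndarray) -> np.ndarray:
    mag = np.abs(env)
    top = mag.max(initial=0.0)
    if top == 0.0:
        raise ValueError("constant zero envelope: log power undefined")
    mag = np.maximum(mag, np.finfo(float).eps * top)
    return 2.0 * np.log(mag)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    tol = 1e-10
    if a.std() < tol * (1.0 + np.abs(a.mean())) or b.std() < tol * (1.0 + np.abs(b.mean())):
        raise ValueError("constant envelope: correlation undefined")
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    return float(np.clip((a @ b) / denom, -R_CLIP, R_CLIP))


def envelope_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Symmetric orthogonalized log-power envelope correlation, Fisher-z.

    Correlates log|x|^2 with log|y orthogonalized to x|^2 and vice versa,
    Fisher-transforms each direction and returns the average.
    """
    x = np.asarray(x, dtype=complex)
    y = np.asarray(y, dtype=complex)
    if x.size < MIN_VALID_SAMPLES:
        raise ValueError(
            f"need at least {MIN_VALID_SAMPLES} valid samples, got {x.size}"
        )
    r_xy = _pearson(_log_power(x), _log_power(orthogonalize(x, y)))
    r_yx = _pearson(_log_power(y), _log_power(orthogonalize(y, x)))
    return float(0.5 * (np.arctanh(r_xy) + np.arctanh(r_yx)))


def build_adjacency(
    spectra: AnalyticSpectra,
    rectify_negative: bool = True,
    carriers: np.ndarray | None = None,
) -> np.ndarray:
    """One symmetric FC matrix per carrier for a single subject.

    Returns ``(n_carriers, n, n)``; pass the result of several subjects to
    :class:`AdjacencyStack`.  ``carriers`` optionally restricts computation
    to a subset of carrier indices (others are returned as zero matrices).
    """
    n = spectra.n_nodes
    n_carriers = len(spectra.grid)
    out = np.zeros((n_carriers, n, n))
    carrier_idx = range(n_carriers) if carriers is None else carriers
    for ci in carrier_idx:
        valid = spectra.valid_mask[ci]
        if valid.sum() < MIN_VALID_SAMPLES:
            raise ValueError(f"carrier index {ci}: too few valid samples")
        coef = spectra.coefficients[:, ci, valid]
        for i in range(n):
            for j in range(i + 1, n):
                try:
                    z = envelope_correlation(coef[i], coef[j])
                except ValueError as err:
                    raise ValueError(f"pair ({i}, {j}), carrier {ci}: {err}") from err
                if rectify_negative and z < 0:
                    z = 0.0
                out[ci, i, j] = out[ci, j, i] = z
    return out


def consistency_threshold(
    stack: AdjacencyStack, densities_pct: np.ndarray | None = None
) -> DensitySweepGraphs:
    """Rank edges by cross-subject CV and keep the most consistent ones.

    Per carrier, each edge's CV is the sample standard deviation over
    subjects divided by the mean; at density d% the ``round(d/100 * E)``
    lowest-CV edges are kept (round half away from zero).  Zero-mean edges
    have undefined CV and rank last.  Ties break by descending mean weight,
    then by edge index, so the sweep is fully deterministic and nested.
    """
    if stack.n_subjects < 2:
        raise ValueError("consistency thresholding needs at least 2 subjects")
    if densities_pct is None:
        densities_pct = np.arange(1, 101)
    densities_pct = np.asarray(densities_pct, dtype=float)
    n = stack.n_nodes
    iu, ju = np.triu_indices(n, 1)
    n_edges = iu.size
    n_carriers = stack.weights.shape[1]

    masks = np.zeros((n_carriers, densities_pct.size, n, n), dtype=bool)
    edge_cv = np.zeros((n_carriers, n, n))
    for ci in range(n_carriers):
        w = stack.weights[:, ci, iu, ju]  # (subjects, edges)
        mean = w.mean(axis=0)
        sd = w.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean > 0, sd / mean, np.inf)
        edge_cv[ci, iu, ju] = edge_cv[ci, ju, iu] = cv
        # lexsort: last key is primary
        order = np.lexsort((np.arange(n_edges), -mean, cv))
        for di, d in enumerate(densities_pct):
            keep = int(np.floor(d / 100.0 * n_edges + 0.5))
            keep = min(keep, n_edges)
            sel = order[:keep]
            m = np.zeros((n, n), dtype=bool)
            m[iu[sel], ju[sel]] = True
            masks[ci, di] = m | m.T
    return DensitySweepGraphs(masks=masks, densities_pct=densities_pct, edge_cv=edge_cv)
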