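"""Weighted graph metrics: strength, Onnela clustering, shortest paths,
lattice/random null models, small-world propensity and the sigma index.

All metrics operate on symmetric nonnegative weight matrices with zero
diagonals.  Zero weight means "no edge"; shortest-path edge lengths are the
reciprocal weights.
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings

import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .connectivity import AdjacencyStack, DensitySweepGraphs

__all__ = [
    "SWPResult",
    "SWPCurveSet",
    "node_strength",
    "average_connectivity",
    "weighted_clustering_onnela",
    "weighted_path_length",
    "lattice_equivalent",
    "random_equivalent",
    "small_world_propensity",
    "sigma_small_worldness",
    "swp_from_deltas",
    "metric_density_curves",
]

#: Above this value the network is considered to be in the small-world regimen.
SWP_THRESHOLD = 0.6
UNREACHABLE_WARN_FRACTION = 0.05

_delta_l_notice_emitted = False


def _check_square(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    if np.any(a < 0):
        raise ValueError("weights must be nonnegative")
    return a


def node_strength(a: np.ndarray, mode: str = "mean_offdiag") -> np.ndarray:
    """Per-node strength; default is the mean over off-diagonal column entries."""
    a = _check_square(a)
    n = a.shape[0]
    if n < 2:
        raise ValueError("node strength needs at least 2 nodes")
    col_sums = a.sum(axis=0) - np.diag(a)
    if mode == "mean_offdiag":
        return col_sums / (n - 1)
    if mode == "mean_incl_diag":
        return a.sum(axis=0) / n
    if mode == "sum":
        return col_sums
    raise ValueError(f"unknown strength mode {mode!r}")


def average_connectivity(a: np.ndarray, mode: str = "mean_offdiag") -> float:
    """Node strength averaged across nodes."""
    return float(node_strength(a, mode=mode).mean())


def weighted_clustering_onnela(a: np.ndarray) -> tuple[np.ndarray, float]:
    """Onnela weighted clustering per node and its mean.

    Weights are normalized by the matrix maximum; the per-node coefficient is
    the mean geometric intensity of the triangles around the node.  Nodes of
    degree < 2 get 0.  An all-zero matrix yields all zeros (documented, not
    an error).
    """
    a = _check_square(a)
    top = a.max()
    if top == 0:
        return np.zeros(a.shape[0]), 0.0
    w = np.cbrt(a / top)
    num = np.diag(w @ w @ w)  # 2 * sum of triangle intensities per node
    deg = np.count_nonzero(a, axis=1)
    c = np.zeros(a.shape[0])
    mask = deg >= 2
    c[mask] = num[mask] / (deg[mask] * (deg[mask] - 1.0))
    return c, float(c.mean())


def weighted_path_length(a: np.ndarray) -> tuple[float, float]:
    """Characteristic path length with edge length 1/weight.

    Returns ``(L, unreachable_fraction)`` where L is the mean of the finite
    off-diagonal shortest-path distances and the fraction counts ordered
    node pairs with no connecting path.
    """
    a = _check_square(a)
    n = a.shape[0]
    if not np.any(a > 0):
        raise ValueError("path length undefined on a graph with no edges")
    with np.errstate(divide="ignore"):
        lengths = np.where(a > 0, 1.0 / a, 0.0)
    dist = _csgraph_shortest_path(lengths, method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist[off])
    unreachable = 1.0 - finite.mean()
    return float(dist[off][finite].mean()), float(unreachable)


def _edge_list(a: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(a.shape[0], 1)
    present = a[iu, ju] > 0
    return iu[present], ju[present], a[iu, ju][present]


def lattice_equivalent(a: np.ndarray, seed: int | None = None) -> np.ndarray:
    """Deterministic lattice null: same nodes, edge count and weight multiset.

    Edges fill ring positions in order of increasing ring distance, and the
    observed weights, sorted descending, are laid onto them so the strongest
    weights are the most local — maximizing clustering for the given weights.
    """
    a = _check_square(a)
    n = a.shape[0]
    _, _, weights = _edge_list(a)
    e = weights.size
    iu, ju = np.triu_indices(n, 1)
    ring_dist = np.minimum(ju - iu, n - (ju - iu))
    order = np.lexsort((ju, iu, ring_dist))[:e]
    out = np.zeros((n, n))
    w_sorted = np.sort(weights)[::-1]
    out[iu[order], ju[order]] = w_sorted
    return out + out.T


def random_equivalent(
    a: np.ndarray, seed: int, n_reps: int = 10
) -> tuple[float, float]:
    """(C_rand, L_rand) averaged over random topology/weight permutations.

    Each repetition draws a uniformly random simple graph with the observed
    node and edge counts and permutes the observed weight multiset onto it.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    a = _check_square(a)
    n = a.shape[0]
    _, _, weights = _edge_list(a)
    e = weights.size
    if e == 0:
        raise ValueError("random equivalent undefined on an edgeless graph")
    iu, ju = np.triu_indices(n, 1)
    rng = np.random.default_rng(seed)
    cs, ls = [], []
    for _ in range(n_reps):
        pick = rng.choice(iu.size, size=e, replace=False)
        w = rng.permutation(weights)
        mat = np.zeros((n, n))
        mat[iu[pick], ju[pick]] = w
        mat = mat + mat.T
        cs.append(weighted_clustering_onnela(mat)[1])
        ls.append(weighted_path_length(mat)[0])
    return float(np.mean(cs)), float(np.mean(ls))


@dataclasses.dataclass
class SWPResult:
    """Small-world propensity and its ingredients for one graph."""

    swp: float
    delta_c: float
    delta_l: float
    c_obs: float
    c_latt: float
    c_rand: float
    l_obs: float
    l_latt: float
    l_rand: float
    n_null: int
    seed: int
    unreachable_fraction: float = 0.0
    reliable: bool = True

    @property
    def is_small_world(self) -> bool:
        return self.swp > SWP_THRESHOLD


def _null_metrics(
    a: np.ndarray, seed: int, n_reps: int
) -> tuple[float, float, float, float, float, float, float]:
    c_obs = weighted_clustering_onnela(a)[1]
    l_obs, unreachable = weighted_path_length(a)
    latt = lattice_equivalent(a)
    c_latt = weighted_clustering_onnela(latt)[1]
    l_latt = weighted_path_length(latt)[0]
    c_rand, l_rand = random_equivalent(a, seed=seed, n_reps=n_reps)
    return c_obs, l_obs, unreachable, c_latt, l_latt, c_rand, l_rand


def swp_from_deltas(delta_c: float, delta_l: float) -> tuple[float, float, float]:
    """Clip the deviations to [0, 1] and evaluate the propensity formula."""
    delta_c = float(np.clip(delta_c, 0.0, 1.0))
    delta_l = float(np.clip(delta_l, 0.0, 1.0))
    return 1.0 - float(np.sqrt(0.5 * (delta_c**2 + delta_l**2))), delta_c, delta_l


def small_world_propensity(a: np.ndarray, seed: int = 0, n_reps: int = 10) -> SWPResult:
    """SWP = 1 - sqrt(0.5 * (dC^2 + dL^2)) against lattice and random nulls.

    dC = (C_latt - C_obs) / (C_latt - C_rand) and
    dL = (L_obs - L_rand) / (L_latt - L_rand), both clipped to [0, 1].
    Degenerate denominators yield a deviation of 0 with a warning.
    """
    global _delta_l_notice_emitted
    if not _delta_l_notice_emitted:
        warnings.warn(
            "path-length deviation uses (L_obs - L_rand) in the numerator "
            "(the lattice/random-null definition); the alternative C_rand "
            "form is dimensionally inconsistent and not implemented",
            UserWarning,
            stacklevel=2,
        )
        _delta_l_notice_emitted = True
    c_obs, l_obs, unreachable, c_latt, l_latt, c_rand, l_rand = _null_metrics(
        a, seed, n_reps
    )
    if np.isclose(c_latt, c_rand):
        warnings.warn("degenerate clustering denominator (C_latt == C_rand); dC = 0")
        delta_c = 0.0
    else:
        delta_c = (c_latt - c_obs) / (c_latt - c_rand)
    if np.isclose(l_latt, l_rand):
        warnings.warn("degenerate path denominator (L_latt == L_rand); dL = 0")
        delta_l = 0.0
    else:
        delta_l = (l_obs - l_rand) / (l_latt - l_rand)
    swp, delta_c, delta_l = swp_from_deltas(delta_c, delta_l)
    return SWPResult(
        swp=swp,
        delta_c=delta_c,
        delta_l=delta_l,
        c_obs=c_obs,
        c_latt=c_latt,
        c_rand=c_rand,
        l_obs=l_obs,
        l_latt=l_latt,
        l_rand=l_rand,
        n_null=n_reps,
        seed=seed,
        unreachable_fraction=unreachable,
        reliable=unreachable <= UNREACHABLE_WARN_FRACTION,
    )


def sigma_small_worldness(a: np.ndarray, seed: int = 0, n_reps: int = 10) -> float:
    """Classic sigma = (C_obs / C_rand) / (L_obs / L_rand); > 1 is small-world.

    Returns NaN when C_rand is zero (no triangles in any null draw).
    """
    c_obs = weighted_clustering_onnela(a)[1]
    l_obs = weighted_path_length(a)[0]
    c_rand, l_rand = random_equivalent(a, seed=seed, n_reps=n_reps)
    if c_rand == 0.0 or l_rand == 0.0:
        warnings.warn("sigma undefined: null clustering or path length is zero")
        return float("nan")
    return float((c_obs / c_rand) / (l_obs / l_rand))


@dataclasses.dataclass
class SWPCurveSet:
    """SWP and sigma curves, subject x carrier x density."""

    swp: np.ndarray
    sigma: np.ndarray
    delta_c: np.ndarray
    delta_l: np.ndarray
    reliable: np.ndarray  # bool, same shape
    densities_pct: np.ndarray
    carrier_hz: np.ndarray
    subject_ids: list[str] | None = None


def metric_density_curves(
    sweep: DensitySweepGraphs,
    stack: AdjacencyStack,
    seed: int = 0,
    n_reps: int = 10,
    carriers: np.ndarray | None = None,
    densities: np.ndarray | None = None,
) -> SWPCurveSet:
    """Apply each density mask and compute SWP and sigma per subject/carrier.

    ``carriers`` / ``densities`` optionally restrict computation to index
    subsets (other entries are NaN).  Entries where the masked graph is
    edgeless are NaN and flagged unreliable.
    """
    n_subj = stack.n_subjects
    n_car = stack.weights.shape[1]
    n_den = sweep.densities_pct.size
    shape = (n_subj, n_car, n_den)
    swp = np.full(shape, np.nan)
    sigma = np.full(shape, np.nan)
    dc = np.full(shape, np.nan)
    dl = np.full(shape, np.nan)
    reliable = np.zeros(shape, dtype=bool)
    carrier_idx = np.arange(n_car) if carriers is None else np.asarray(carriers)
    density_idx = np.arange(n_den) if densities is None else np.asarray(densities)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for s in range(n_subj):
            for ci in carrier_idx:
                for di in density_idx:
                    a = stack.weights[s, ci] * sweep.masks[ci, di]
                    if not np.any(a > 0):
                        continue
                    # content-derived seed: deterministic, independent of the
                    # subject's position in the stack and of execution order
                    digest = hashlib.sha256(
                        np.ascontiguousarray(a).tobytes()
                        + np.int64([seed, ci, di]).tobytes()
                    ).digest()
                    sub_seed = int.from_bytes(digest[:8], "little")
                    try:
                        res = small_world_propensity(a, seed=sub_seed, n_reps=n_reps)
                    except ValueError:
                        continue
                    swp[s, ci, di] = res.swp
                    dc[s, ci, di] = res.delta_c
                    dl[s, ci, di] = res.delta_l
                    reliable[s, ci, di] = res.reliable
                    c_rand, l_rand = res.c_rand, res.l_rand
                    if c_rand > 0 and l_rand > 0 and res.l_obs > 0:
                        sigma[s, ci, di] = (res.c_obs / c_rand) / (res.l_obs / l_rand)
    return SWPCurveSet(
        swp=swp,
        sigma=sigma,
        delta_c=dc,
        delta_l=dl,
        reliable=reliable,
        densities_pct=sweep.densities_pct,
        carrier_hz=np.asarray(stack.grid.frequencies_hz),
        subject_ids=None,
    )
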