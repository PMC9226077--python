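"""Weighted bipartite specialization indices and null models.

Quantifies how selectively two guilds interact in a weighted bipartite
network (here DOM molecules x bacterial genera).  The network-level index
H2' is the two-dimensional Shannon entropy of the interaction distribution,
standardised between the marginal-constrained extremes; the node-level index
d' is a standardised Kullback-Leibler divergence of a node's interaction
profile from what its partners' availabilities predict.  Both run 0 (complete
generalization) to 1 (complete specialization).  A swap-type null model that
fixes row totals, column totals and connectance gives z-scores for observed
indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import random_table

__all__ = [
    "InteractionMatrix",
    "NullEnsemble",
    "h2_entropy",
    "h2_extremes",
    "h2_prime",
    "d_prime",
    "weighted_specialization",
    "swap_web_null",
    "null_zscore",
    "specialization_scores",
]


@dataclass
class InteractionMatrix:
    """Non-negative integer link weights a_ij (rows = molecules, cols = genera).

    ``m`` is the total number of interactions, ``row_totals``/``col_totals``
    the marginals A_i and A_j, and ``p`` the interaction proportions a_ij/m.
    """

    a: np.ndarray
    row_labels: list = field(default_factory=list)
    col_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        if self.a.ndim != 2:
            raise ValueError("interaction matrix must be 2-D")
        if np.any(self.a < 0):
            raise ValueError("negative link weights")
        if not self.row_labels:
            self.row_labels = [f"m{i}" for i in range(self.a.shape[0])]
        if not self.col_labels:
            self.col_labels = [f"g{j}" for j in range(self.a.shape[1])]

    @property
    def m(self) -> float:
        return float(self.a.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.a.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.a.sum(axis=0)

    @property
    def p(self) -> np.ndarray:
        if self.m == 0:
            raise ValueError("empty interaction matrix (m = 0)")
        return self.a / self.m


def _entropy(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float).ravel()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def h2_entropy(M: InteractionMatrix) -> float:
    """Two-dimensional Shannon entropy H2 = -sum p_ij ln p_ij (nats)."""
    return _entropy(M.p)


def _greedy_min_entropy(row_totals: np.ndarray, col_totals: np.ndarray) -> float:
    """Entropy of the greedy mass-packing allocation given margins.

    Repeatedly assigns min(largest remaining row, largest remaining column)
    to a single cell; this concentrates mass and approximates the minimum
    achievable entropy for those margins.
    """
    r = list(np.asarray(row_totals, dtype=float))
    c = list(np.asarray(col_totals, dtype=float))
    cells = []
    while True:
        i = int(np.argmax(r))
        j = int(np.argmax(c))
        amt = min(r[i], c[j])
        if amt <= 0:
            break
        cells.append(amt)
        r[i] -= amt
        c[j] -= amt
    m = sum(cells)
    return _entropy(np.asarray(cells) / m)


def h2_extremes(row_totals, col_totals) -> tuple[float, float]:
    """(H2max, H2min) achievable for the given interaction marginals.

    H2max is the entropy of the marginal product distribution
    p_ij = A_i A_j / m^2 (the maximum-entropy table with those margins in the
    real-valued relaxation); H2min comes from greedy mass packing.
    """
    r = np.asarray(row_totals, dtype=float)
    c = np.asarray(col_totals, dtype=float)
    if not np.isclose(r.sum(), c.sum()):
        raise ValueError("row and column totals must sum to the same m")
    m = r.sum()
    if m <= 0:
        raise ValueError("empty margins")
    pmax = np.outer(r, c) / m**2
    return _entropy(pmax), _greedy_min_entropy(r, c)


def h2_prime(M: InteractionMatrix) -> float:
    """Standardised specialization H2' = (H2max - H2) / (H2max - H2min).

    Clamped to [0, 1]; degenerate networks where H2max = H2min (e.g. a single
    row or column) return 0.0 so per-sample subnetwork sweeps never abort.
    """
    h2 = h2_entropy(M)
    h2max, h2min = h2_extremes(M.row_totals, M.col_totals)
    denom = h2max - h2min
    if denom <= 1e-12:
        return 0.0
    return float(np.clip((h2max - h2) / denom, 0.0, 1.0))


def _d_raw(a_i: np.ndarray, A_i: float, partner_totals: np.ndarray, m: float) -> float:
    """Kullback-Leibler divergence d_i = sum (a_ij/A_i) ln(a_ij m / (A_i A_j))."""
    mask = a_i > 0
    q = a_i[mask] / A_i
    return float((q * np.log(a_i[mask] * m / (A_i * partner_totals[mask]))).sum())


def _d_max(A_i: float, partner_totals: np.ndarray, m: float) -> float:
    """d of the greedy allocation concentrating A_i on the scarcest partners."""
    order = np.argsort(partner_totals, kind="stable")
    alloc = np.zeros_like(partner_totals, dtype=float)
    left = A_i
    for j in order:
        if partner_totals[j] <= 0:
            continue
        take = min(left, partner_totals[j])
        alloc[j] = take
        left -= take
        if left <= 0:
            break
    return _d_raw(alloc, A_i, partner_totals, m)


def d_prime(M: InteractionMatrix, axis: str = "rows") -> dict:
    """Standardised node-level specialization d' for molecules or genera.

    ``axis="rows"`` scores molecules (vulnerability), ``axis="cols"`` genera
    (generality).  d_min = 0 corresponds to interacting proportionally to
    partner availability; d_max is the greedy concentration on the partners
    with smallest totals.  Nodes with zero total are excluded and flagged.
    """
    a = M.a if axis == "rows" else M.a.T
    labels = M.row_labels if axis == "rows" else M.col_labels
    partner_totals = a.sum(axis=0)
    m = M.m
    out, excluded = {}, []
    for i, lab in enumerate(labels):
        A_i = a[i].sum()
        if A_i <= 0:
            excluded.append(lab)
            continue
        d = _d_raw(a[i], A_i, partner_totals, m)
        dmax = _d_max(A_i, partner_totals, m)
        out[lab] = {"d": d, "d_prime": float(np.clip(d / dmax, 0, 1)) if dmax > 0 else 0.0}
    return {"scores": out, "excluded": excluded}


def weighted_specialization(d_values, weights) -> float:
    """Weighted mean of node d' values (intensity- or abundance-weighted)."""
    d = np.asarray(d_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("negative weights")
    if w.sum() <= 0:
        raise ValueError("weights sum to zero")
    return float((d * w).sum() / w.sum())


def _patefield_table(r: np.ndarray, c: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return np.asarray(
        random_table(r.astype(int), c.astype(int)).rvs(random_state=rng)
    ).reshape(len(r), len(c)).astype(int)


def swap_web_null(
    M: InteractionMatrix, n: int = 100, seed: int | None = None,
    max_swaps: int = 200_000,
) -> list[np.ndarray]:
    """Null ensemble preserving row totals, column totals and connectance.

    Each replicate starts from a Patefield random table with the observed
    margins, then applies margin-preserving 2x2 unit swaps chosen to drive the
    nonzero-cell count to the observed value (quasiswap-style).  Raises if a
    replicate cannot reach the observed connectance within ``max_swaps``.
    """
    a = M.a
    if not np.allclose(a, np.round(a)):
        raise ValueError("swap-web null requires integer link weights")
    a = np.round(a).astype(int)
    r, c = a.sum(axis=1), a.sum(axis=0)
    target_fill = int((a > 0).sum())
    master = np.random.default_rng(seed)
    # one child generator per replicate for reproducibility
    seeds = master.integers(0, 2**31 - 1, size=n)
    nulls = []
    nr, nc = a.shape
    if nr == 1 or nc == 1:
        # a single-row or single-column table is fully determined by margins
        return [a.copy() for _ in range(n)]
    batch = 4096
    n_restarts = 5
    for s in seeds:
        rng = np.random.default_rng(int(s))
        b = _patefield_table(r, c, rng)
        fill = int((b > 0).sum())
        swaps = 0
        restarts = 0
        while fill != target_fill:
            if swaps >= max_swaps:
                restarts += 1
                if restarts > n_restarts:
                    raise RuntimeError(
                        f"could not reach connectance {target_fill} "
                        f"(stuck at {fill}); the margins may force a "
                        "near-unique table"
                    )
                b = _patefield_table(r, c, rng)
                fill = int((b > 0).sum())
                swaps = 0
                continue
            ii = rng.integers(0, nr, size=(batch, 2))
            jj = rng.integers(0, nc, size=(batch, 2))
            uu = rng.random(batch)
            for (i1, i2), (j1, j2), u in zip(ii, jj, uu):
                swaps += 1
                if i1 == i2 or j1 == j2:
                    continue
                # move `amt` from (i1,j1),(i2,j2) to (i1,j2),(i2,j1); this
                # preserves both margins for any amt <= min of the sources
                lo = min(b[i1, j1], b[i2, j2])
                if lo <= 0:
                    continue
                want = 1 if target_fill > fill else -1
                if want < 0:
                    amt = lo  # zero out a source cell to drop the fill
                elif lo > 1:
                    amt = int(u * (lo - 1)) + 1  # keep sources nonzero
                else:
                    amt = 1
                delta = (int(b[i1, j2] == 0) + int(b[i2, j1] == 0)
                         - int(b[i1, j1] == amt) - int(b[i2, j2] == amt))
                # accept moves toward the target fill and all fill-neutral
                # moves (the neutral moves keep the chain mixing)
                if delta * want > 0 or delta == 0:
                    b[i1, j1] -= amt
                    b[i2, j2] -= amt
                    b[i1, j2] += amt
                    b[i2, j1] += amt
                    fill += delta
                    if fill == target_fill:
                        break
        nulls.append(b)
    return nulls


@dataclass
class NullEnsemble:
    """Null-model scores for one statistic: replicate values, mean, SD."""

    values: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1))


def null_zscore(s_obs: float, ensemble: NullEnsemble) -> float:
    """z = (S_obs - mean(S_null)) / sd(S_null); NaN (flagged) when sd = 0."""
    if len(ensemble.values) < 2:
        raise ValueError("ensemble needs >= 2 replicates")
    if ensemble.sd == 0:
        warnings.warn("null ensemble has zero variance; z-score undefined")
        return float("nan")
    return (s_obs - ensemble.mean) / ensemble.sd


def specialization_scores(
    M: InteractionMatrix,
    row_weights=None,
    col_weights=None,
    n_null: int = 100,
    seed: int | None = None,
) -> dict:
    """All specialization indices for one network, with null z-scores.

    ``row_weights`` (relative intensities) and ``col_weights`` (relative
    abundances) weight the node-level d' means; defaults to the network's own
    marginals.  Null z-scores use the swap-web ensemble.
    """
    h2 = h2_entropy(M)
    h2max, h2min = h2_extremes(M.row_totals, M.col_totals)
    h2p = h2_prime(M)
    d_rows = d_prime(M, "rows")
    d_cols = d_prime(M, "cols")

    def _wmean(dres, labels, weights, fallback):
        scored = [lab for lab in labels if lab in dres["scores"]]
        d_vals = [dres["scores"][lab]["d_prime"] for lab in scored]
        if weights is None:
            w = [fallback[labels.index(lab)] for lab in scored]
        else:
            w = [weights[lab] for lab in scored]
        return weighted_specialization(d_vals, w) if scored else float("nan")

    wd_rows = _wmean(d_rows, M.row_labels, row_weights, M.row_totals)
    wd_cols = _wmean(d_cols, M.col_labels, col_weights, M.col_totals)

    result = {
        "H2": h2, "H2max": h2max, "H2min": h2min, "H2_prime": h2p,
        "d_rows": d_rows, "d_cols": d_cols,
        "weighted_d_prime_rows": wd_rows, "weighted_d_prime_cols": wd_cols,
    }
    if n_null and n_null >= 2 and min(M.a.shape) > 1:
        nulls = swap_web_null(M, n=n_null, seed=seed)
        ens = {"H2_prime": [], "weighted_d_prime_rows": [], "weighted_d_prime_cols": []}
        for b in nulls:
            Mn = InteractionMatrix(b, M.row_labels, M.col_labels)
            ens["H2_prime"].append(h2_prime(Mn))
            ens["weighted_d_prime_rows"].append(
                _wmean(d_prime(Mn, "rows"), M.row_labels, row_weights, Mn.row_totals))
            ens["weighted_d_prime_cols"].append(
                _wmean(d_prime(Mn, "cols"), M.col_labels, col_weights, Mn.col_totals))
        result["null"] = {}
        for key, vals in ens.items():
            e = NullEnsemble(np.asarray(vals))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                z = null_zscore(result[key], e)
            result["null"][key] = {"mean": e.mean, "sd": e.sd, "z": z}
    return result
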