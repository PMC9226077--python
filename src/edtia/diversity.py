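"""Community diversity, ordination congruence, and gradient breakpoints.

Alpha diversity is peak/OTU richness; beta diversity is Bray-Curtis
dissimilarity summarised by non-metric multidimensional scaling (NMDS).
Congruence between the molecular and microbial views of the same samples is
tested with Mantel (distance correlation) and Procrustes/PROTEST
(ordination superimposition).  Abrupt compositional change along the
nutrient gradient is located with continuous piecewise-linear (segmented)
regression selected by BIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr
from sklearn.decomposition import PCA
from sklearn.manifold import MDS

__all__ = [
    "richness",
    "bray_curtis",
    "nmds_embed",
    "correspondence_axis",
    "mantel_test",
    "procrustes_protest",
    "alpha_diversity_correlation",
    "piecewise_breakpoints",
    "OrdinationResult",
]


def richness(table: pd.DataFrame) -> pd.Series:
    """Per-sample richness: the number of strictly positive entries."""
    if (table.to_numpy() < 0).any():
        raise ValueError("negative abundances")
    return (table > 0).sum(axis=1).rename("richness")


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y), in [0, 1].

    A semimetric (the triangle inequality can fail).  Pairs of all-zero rows
    are undefined and flagged with NaN.
    """
    x = table.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative abundances")
    zero_rows = x.sum(axis=1) == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # 0/0 pairs handled below
        d = squareform(pdist(x, metric="braycurtis"))
    if zero_rows.any():
        idx = np.where(zero_rows)[0]
        for i in idx:
            for j in idx:
                if i != j:
                    d[i, j] = np.nan
        warnings.warn(f"{len(idx)} all-zero rows; their mutual distances are NaN")
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=table.index, columns=table.index)


@dataclass
class OrdinationResult:
    coords: pd.DataFrame
    stress: float | None = None
    converged: bool = True
    axis_variance: np.ndarray | None = None


def nmds_embed(dist: pd.DataFrame, k: int = 2, seed: int | None = None,
               n_init: int = 20, max_iter: int = 300) -> OrdinationResult:
    """NMDS embedding minimising Kruskal stress-1.

    Runs ``n_init`` random starts and keeps the best; the final configuration
    is rotated to its principal axes (with a deterministic sign convention) so
    repeated runs are comparable.
    """
    d = dist.to_numpy(dtype=float)
    mds = MDS(
        n_components=k, metric=False, dissimilarity="precomputed",
        n_init=n_init, max_iter=max_iter, random_state=seed,
        normalized_stress=True, eps=1e-6,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        xy = mds.fit_transform(d)
    stress = float(mds.stress_)
    # PCA rotation + sign normalization for reproducible orientation
    pca = PCA(n_components=k)
    xy = pca.fit_transform(xy)
    for j in range(k):
        if xy[np.argmax(np.abs(xy[:, j])), j] < 0:
            xy[:, j] *= -1
    coords = pd.DataFrame(xy, index=dist.index,
                          columns=[f"NMDS{i+1}" for i in range(k)])
    return OrdinationResult(coords=coords, stress=stress, converged=stress < 0.3)


def correspondence_axis(table: pd.DataFrame) -> pd.Series:
    """First correspondence-analysis axis of a samples x features table.

    A monotone composition score along the dominant compositional gradient,
    used as the response for breakpoint detection.
    """
    x = table.to_numpy(dtype=float)
    if x.sum() <= 0:
        raise ValueError("empty table")
    p = x / x.sum()
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    keep = c > 0
    p, c = p[:, keep], c[keep]
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sv, vt = np.linalg.svd(s, full_matrices=False)
    scores = u[:, 0] * sv[0] / np.sqrt(r)
    if scores[np.argmax(np.abs(scores))] < 0:
        scores = -scores
    return pd.Series(scores, index=table.index, name="CA1")


def _offdiag(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(d.shape[0], k=1)
    return d[iu]


def mantel_test(d1: pd.DataFrame, d2: pd.DataFrame, n_perm: int = 999,
                seed: int | None = None) -> tuple[float, float]:
    """Two-sided Mantel test between two distance matrices.

    r is the Pearson correlation of the upper off-diagonal entries; the
    p-value permutes the rows and columns of the second matrix jointly:
    p = (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1).
    """
    if list(d1.index) != list(d2.index):
        raise ValueError("distance matrices must share sample labels and order")
    a, b = d1.to_numpy(dtype=float), d2.to_numpy(dtype=float)
    va, vb = _offdiag(a), _offdiag(b)
    if np.std(va) == 0 or np.std(vb) == 0:
        warnings.warn("constant distances; Mantel r undefined")
        return float("nan"), float("nan")
    r_obs = float(np.corrcoef(va, vb)[0, 1])
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = np.corrcoef(va, _offdiag(b[np.ix_(perm, perm)]))[0, 1]
        if abs(r_p) >= abs(r_obs) - 1e-12:
            hits += 1
    return r_obs, (1 + hits) / (n_perm + 1)


def procrustes_protest(X, Y, n_perm: int = 999, seed: int | None = None):
    """Procrustes superimposition of Y onto X with a PROTEST permutation p.

    Both configurations are centred and scaled to unit trace; M2 is the sum of
    squared pointwise residuals after the optimal translation / rotation /
    reflection / scaling.  Returns ``(M2, residuals, p)`` where residuals are
    per-sample distances between matched points.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("configurations must have identical shape")
    if min(np.linalg.matrix_rank(X - X.mean(0)), np.linalg.matrix_rank(Y - Y.mean(0))) < 1:
        warnings.warn("rank-deficient configuration")
    mtx1, mtx2, m2 = _scipy_procrustes(X, Y)
    residuals = np.sqrt(((mtx1 - mtx2) ** 2).sum(axis=1))
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    hits = 0
    for _ in range(n_perm):
        _, _, m2p = _scipy_procrustes(X, Y[rng.permutation(n)])
        if m2p <= m2 + 1e-12:
            hits += 1
    return float(m2), residuals, (1 + hits) / (n_perm + 1)


def alpha_diversity_correlation(dom_richness: pd.Series, otu_richness: pd.Series,
                                grouping: pd.Series) -> pd.DataFrame:
    """Pearson r between molecular and bacterial richness within each group.

    Groups are design cells (e.g. nutrient levels); groups with < 3 samples or
    zero variance are flagged with NaN.
    """
    rows = []
    for g, idx in grouping.groupby(grouping).groups.items():
        x = dom_richness.loc[idx].to_numpy(dtype=float)
        y = otu_richness.loc[idx].to_numpy(dtype=float)
        if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
            rows.append({"group": g, "r": np.nan, "p": np.nan, "n": len(x)})
            continue
        r, p = pearsonr(x, y)
        rows.append({"group": g, "r": r, "p": p, "n": len(x)})
    return pd.DataFrame(rows).set_index("group")


def _segmented_rss(x: np.ndarray, y: np.ndarray, psi: np.ndarray) -> float:
    U = np.maximum(x[:, None] - psi[None, :], 0.0)
    X = np.column_stack([np.ones(len(x)), x, U])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def _muggeo_iterate(x, y, psi0, tol, max_iter):
    """Damped Muggeo iteration from one starting breakpoint vector."""
    n = len(x)
    lo, hi = x.min(), x.max()
    n_breaks = len(psi0)
    psi = psi0.copy()
    rss = _segmented_rss(x, y, psi)
    for _ in range(max_iter):
        U = np.maximum(x[:, None] - psi[None, :], 0.0)
        V = -(x[:, None] > psi[None, :]).astype(float)
        X = np.column_stack([np.ones(n), x, U, V])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        beta_u = coef[2:2 + n_breaks]
        gamma = coef[2 + n_breaks:]
        if np.any(np.abs(beta_u) < 1e-12):
            return None
        step = gamma / beta_u
        # evaluate progressively damped versions of the update and take the
        # best; this keeps the iteration from oscillating when the
        # linearization overshoots
        best_cand = None
        h = 1.0
        for _halve in range(8):
            cand = np.sort(np.clip(psi + h * step, lo + 1e-9, hi - 1e-9))
            if len(np.unique(np.round(cand, 9))) == n_breaks:
                cand_rss = _segmented_rss(x, y, cand)
                if best_cand is None or cand_rss < best_cand[1]:
                    best_cand = (cand, cand_rss)
            h *= 0.5
        if best_cand is None:
            return None
        if best_cand[1] >= rss - 1e-12:
            # no damped step improves the fit: psi is a local optimum of the
            # profile RSS along the Muggeo direction
            return psi, rss, True
        shift = np.max(np.abs(best_cand[0] - psi))
        psi, rss = best_cand
        if shift < tol:
            return psi, rss, True
    return psi, rss, False


def _fit_segmented(x: np.ndarray, y: np.ndarray, n_breaks: int,
                   tol: float = 1e-6, max_iter: int = 60):
    """Muggeo iterative-linearization fit of a continuous piecewise line.

    Refits y ~ x + sum_k (x - psi_k)_+ + gap covariates, updating psi by
    gamma/beta (with step halving), from several deterministic starts;
    returns (psi, rss, n_params) for the best converged start, or None when
    no start converges.
    """
    n = len(x)
    if n_breaks == 0:
        X = np.column_stack([np.ones(n), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return np.array([]), float(resid @ resid), 2
    starts = []
    qs = np.linspace(0, 1, n_breaks + 2)[1:-1]
    starts.append(np.quantile(x, qs))
    starts.append(np.quantile(x, qs * 0.6))
    starts.append(np.quantile(x, 1 - (1 - qs) * 0.6))
    best = None
    for psi0 in starts:
        if len(np.unique(psi0)) < n_breaks:
            continue
        res = _muggeo_iterate(x, y, psi0, tol, max_iter)
        if res is None or not res[2]:
            continue
        if best is None or res[1] < best[1]:
            best = res
    if best is None:
        return None
    # params: intercept + base slope + per-break slope change + break location
    return best[0], best[1], 2 + 2 * n_breaks


def piecewise_breakpoints(x, y, max_breakpoints: int = 3) -> dict:
    """Locate slope changes in y(x) with BIC-selected segmented regression.

    Fits continuous piecewise-linear models with 0..``max_breakpoints``
    breakpoints (unconstrained within the observed x range) and selects the
    count with the lowest BIC.  Returns the selected breakpoints, the BIC
    table, and any breakpoint counts dropped for non-convergence.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 8:
        raise ValueError("need >= 8 points")
    n = len(x)
    table, dropped = {}, []
    for b in range(max_breakpoints + 1):
        fit = _fit_segmented(x, y, b)
        if fit is None:
            dropped.append(b)
            continue
        psi, rss, k = fit
        bic = n * np.log(max(rss, 1e-300) / n) + k * np.log(n)
        table[b] = {"breakpoints": psi.tolist(), "rss": rss, "bic": float(bic)}
    if not table:
        raise RuntimeError("no piecewise model converged")
    best = min(table, key=lambda b: table[b]["bic"])
    return {
        "n_breakpoints": best,
        "breakpoints": table[best]["breakpoints"],
        "bic_table": table,
        "dropped": dropped,
    }
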