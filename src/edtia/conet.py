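"""Molecule-taxon association inference and bipartite network construction.

Associations between DOM molecules (relative intensities) and bacterial taxa
(counts) are screened with Spearman rank correlations and inferred with
SparCC, a correlation estimator designed for compositional data: it
estimates basis correlations from log-ratio variances under a sparsity
assumption, iteratively excluding strongly-correlated component pairs from
the linear system.  Pairs with |rho| >= 0.30 form signed bipartite networks
whose integer link weights (round(|rho| * 10000)) feed the specialization
indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .specialization import InteractionMatrix

__all__ = [
    "CorrelationMatrix",
    "BipartiteNetwork",
    "prevalence_filter",
    "spearman_matrix",
    "delta_rho",
    "sparcc_correlations",
    "build_bipartite",
    "sample_subnetwork",
    "network_edge_summaries",
]


@dataclass
class CorrelationMatrix:
    """Molecules x taxa correlation coefficients with optional p-values."""

    rho: pd.DataFrame
    p: pd.DataFrame | None = None
    method: str = "spearman"

    def __post_init__(self):
        v = self.rho.to_numpy(dtype=float)
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("correlations outside [-1, 1]")


@dataclass
class BipartiteNetwork:
    """Signed molecule-genus network with integer link weights."""

    sign: str
    edges: pd.DataFrame  # columns: molecule, genus, rho, weight
    node_meta: dict = field(default_factory=dict)

    @property
    def molecules(self) -> list:
        return sorted(self.edges["molecule"].unique())

    @property
    def genera(self) -> list:
        return sorted(self.edges["genus"].unique())

    def interaction_matrix(self) -> InteractionMatrix:
        if self.edges.empty:
            raise ValueError("empty network")
        mols, gens = self.molecules, self.genera
        a = np.zeros((len(mols), len(gens)))
        mi = {m: i for i, m in enumerate(mols)}
        gi = {g: j for j, g in enumerate(gens)}
        for _, e in self.edges.iterrows():
            a[mi[e["molecule"]], gi[e["genus"]]] = e["weight"]
        return InteractionMatrix(a, mols, gens)


def prevalence_filter(table: pd.DataFrame, min_fraction: float = 0.5):
    """Keep features observed (value > 0) in at least ``min_fraction`` of samples.

    The majority rule guards the correlation stage against type-I errors from
    low-occurrence features.  Returns ``(filtered, dropped_ids)``; raises if
    nothing survives.
    """
    prev = (table > 0).mean(axis=0)
    keep = prev >= min_fraction
    dropped = list(table.columns[~keep])
    filtered = table.loc[:, keep]
    if filtered.shape[1] == 0:
        raise ValueError("prevalence filter removed every feature")
    return filtered, dropped


def spearman_matrix(peaks: pd.DataFrame, otus: pd.DataFrame,
                    alpha: float = 0.05) -> CorrelationMatrix:
    """Pairwise Spearman rho between every molecule and every taxon.

    Tie-corrected, two-sided p-values, uncorrected for multiplicity (this is
    a screening statistic).  Constant columns give NaN (flagged, excluded
    from summaries downstream).
    """
    if list(peaks.index) != list(otus.index):
        raise ValueError("peak and OTU tables must share samples in order")
    nm, nt = peaks.shape[1], otus.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = spearmanr(peaks.to_numpy(dtype=float), otus.to_numpy(dtype=float))
    if nm == 1 and nt == 1:  # scipy collapses the 2x2 case to a scalar
        rho = np.array([[rho]])
        p = np.array([[p]])
    else:
        rho = np.atleast_2d(rho)[:nm, nm:]
        p = np.atleast_2d(p)[:nm, nm:]
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=peaks.columns, columns=otus.columns),
        p=pd.DataFrame(p, index=peaks.columns, columns=otus.columns),
        method="spearman",
    )


def delta_rho(corr: CorrelationMatrix, mode: str = "all",
              alpha: float = 0.05) -> pd.DataFrame:
    """Per-molecule Spearman difference: mean positive rho minus mean |negative rho|.

    Positive values mean the molecule is predominantly positively associated
    with the bacterial community.  ``mode="significant"`` restricts to
    correlations with p <= ``alpha``.  Molecules with correlations of only one
    sign get the signed mean of that side, flagged; molecules with no usable
    correlations are flagged missing.
    """
    rho = corr.rho.to_numpy(dtype=float)
    use = np.isfinite(rho)
    if mode == "significant":
        if corr.p is None:
            raise ValueError("significance mode requires p-values")
        use &= corr.p.to_numpy() <= alpha
    elif mode != "all":
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for i, mol in enumerate(corr.rho.index):
        vals = rho[i][use[i]]
        pos, neg = vals[vals > 0], vals[vals < 0]
        if len(vals) == 0:
            rows.append({"molecule": mol, "delta_rho": np.nan, "flag": "missing"})
        elif len(pos) and len(neg):
            rows.append({"molecule": mol,
                         "delta_rho": pos.mean() - np.abs(neg).mean(), "flag": ""})
        elif len(pos):
            rows.append({"molecule": mol, "delta_rho": pos.mean(),
                         "flag": "positive_only"})
        else:
            rows.append({"molecule": mol, "delta_rho": -np.abs(neg).mean(),
                         "flag": "negative_only"})
    return pd.DataFrame(rows).set_index("molecule")


def _sparcc_basis_rho(frac: np.ndarray, n_iter: int, threshold: float) -> np.ndarray:
    """One SparCC pass: basis correlations from log-ratio variances.

    Solves the sparse linear approximation t_i. = (d-2) w_i + sum_j w_j for
    the basis variances w, then rho_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j)).
    Strongly correlated pairs (|rho| > threshold) are iteratively removed from
    the system, as the sparsity assumption requires.
    """
    logf = np.log(frac)
    d = logf.shape[1]
    # variation matrix t_ij = var(log(x_i / x_j))
    t = np.var(logf[:, :, None] - logf[:, None, :], axis=0, ddof=1)
    excluded = np.zeros((d, d), dtype=bool)
    rho = None
    for _ in range(n_iter + 1):
        m_mat = np.ones((d, d)) + np.diag(np.full(d, d - 2.0))
        # excluded pairs drop out of both the row sums and the system matrix
        m_mat = m_mat - excluded.astype(float)
        np.fill_diagonal(m_mat, d - 1 - excluded.sum(axis=1))
        t_eff = np.where(excluded, 0.0, t)
        w = np.linalg.solve(m_mat, t_eff.sum(axis=1))
        w = np.maximum(w, 1e-12)
        denom = 2 * np.sqrt(np.outer(w, w))
        rho = (w[:, None] + w[None, :] - t) / denom
        np.fill_diagonal(rho, 1.0)
        rho = np.clip(rho, -1.0, 1.0)
        # find the strongest not-yet-excluded off-diagonal pair
        cand = np.abs(np.where(excluded, 0.0, rho))
        np.fill_diagonal(cand, 0.0)
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= threshold:
            break
        if excluded.sum(axis=1)[i] >= d - 3 or excluded.sum(axis=1)[j] >= d - 3:
            break
        excluded[i, j] = excluded[j, i] = True
    return rho


def sparcc_correlations(
    peaks: pd.DataFrame,
    otus: pd.DataFrame,
    n_exclusion_iters: int = 20,
    exclusion_threshold: float = 0.1,
    n_bootstrap: int = 100,
    seed: int | None = None,
    pseudo_total: float = 1e6,
    n_permutations: int = 20,
) -> CorrelationMatrix:
    """SparCC correlations between molecules and taxa (compositional data).

    Molecules and taxa are stacked into one compositional vector per sample
    (cross-block correlations require a joint composition).  Intensities are
    scaled to ``pseudo_total`` counts with a 0.5 pseudo-count for zeros; each
    replicate resamples fractions from Dirichlet(counts + 1) and the point
    estimate is the median over replicates (``n_bootstrap=0`` skips
    resampling and uses plain fractions, which is deterministic and exactly
    invariant to sample order).  Pseudo-p-values come from permuting each
    component independently across samples.
    """
    if list(peaks.index) != list(otus.index):
        raise ValueError("tables must share samples in order")
    counts_mol = peaks.to_numpy(dtype=float)
    counts_mol = counts_mol / counts_mol.sum(axis=1, keepdims=True) * pseudo_total
    joint = np.hstack([counts_mol, otus.to_numpy(dtype=float)])
    joint = np.where(joint <= 0, 0.5, joint)
    n, d = joint.shape
    if d < 4:
        raise ValueError("SparCC needs >= 4 components")
    nm = peaks.shape[1]
    rng = np.random.default_rng(seed)

    def estimate(mat: np.ndarray, n_rep: int) -> np.ndarray:
        if n_rep == 0:  # deterministic: plain fractions, no resampling
            frac = mat / mat.sum(axis=1, keepdims=True)
            return _sparcc_basis_rho(frac, n_exclusion_iters, exclusion_threshold)
        reps = np.empty((n_rep, d, d))
        for r in range(n_rep):
            frac = np.vstack([rng.dirichlet(row + 1.0) for row in mat])
            reps[r] = _sparcc_basis_rho(frac, n_exclusion_iters, exclusion_threshold)
        return np.median(reps, axis=0)

    rho = estimate(joint, n_bootstrap)
    block = rho[:nm, nm:]

    p = None
    if n_permutations and n_permutations > 0:
        hits = np.zeros_like(block)
        for _ in range(n_permutations):
            perm = np.column_stack([rng.permutation(joint[:, j]) for j in range(d)])
            rho_p = estimate(perm, 1)
            hits += np.abs(rho_p[:nm, nm:]) >= np.abs(block)
        p = (hits + 1) / (n_permutations + 1)
        p = pd.DataFrame(p, index=peaks.columns, columns=otus.columns)

    return CorrelationMatrix(
        rho=pd.DataFrame(block, index=peaks.columns, columns=otus.columns),
        p=p, method="sparcc",
    )


def build_bipartite(corr: CorrelationMatrix, threshold: float = 0.30,
                    sign: str = "negative") -> BipartiteNetwork:
    """Threshold a correlation matrix into a signed bipartite network.

    The negative network keeps rho <= -threshold, the positive network
    rho >= threshold; link weights are round(|rho| * 10000) so the entropy
    machinery sees integer interaction counts.
    """
    if sign not in ("negative", "positive"):
        raise ValueError("sign must be 'negative' or 'positive'")
    if corr.method not in ("sparcc",):
        warnings.warn(f"building network from {corr.method} correlations")
    rho = corr.rho
    mask = (rho <= -threshold) if sign == "negative" else (rho >= threshold)
    rows = []
    for mol in rho.index:
        for gen in rho.columns[mask.loc[mol]]:
            r = rho.loc[mol, gen]
            rows.append({"molecule": mol, "genus": gen, "rho": r,
                         "weight": int(round(abs(r) * 10_000))})
    edges = pd.DataFrame(rows, columns=["molecule", "genus", "rho", "weight"])
    if edges.empty:
        warnings.warn(f"{sign} network has no edges at |rho| >= {threshold}")
    return BipartiteNetwork(sign=sign, edges=edges)


def sample_subnetwork(network: BipartiteNetwork, peaks: pd.DataFrame,
                      otus: pd.DataFrame, sample_id) -> BipartiteNetwork:
    """Node-induced subnetwork of molecules and genera present in one sample."""
    if sample_id not in peaks.index or sample_id not in otus.index:
        raise KeyError(f"sample {sample_id!r} absent from tables")
    mols = set(peaks.columns[peaks.loc[sample_id] > 0])
    gens = set(otus.columns[otus.loc[sample_id] > 0])
    edges = network.edges[
        network.edges["molecule"].isin(mols) & network.edges["genus"].isin(gens)
    ].reset_index(drop=True)
    if edges.empty:
        warnings.warn(f"sample {sample_id!r} induces an empty subnetwork")
    return BipartiteNetwork(sign=network.sign, edges=edges,
                            node_meta=network.node_meta)


def network_edge_summaries(corr: CorrelationMatrix, alpha: float = 0.05,
                           threshold: float = 0.30) -> dict:
    """Summary statistics of a correlation matrix at the network threshold."""
    rho = corr.rho.to_numpy(dtype=float)
    finite = np.isfinite(rho)
    neg = rho[finite & (rho < 0)]
    pos = rho[finite & (rho > 0)]
    out = {
        "mean_negative_rho": float(neg.mean()) if neg.size else 0.0,
        "mean_positive_rho": float(pos.mean()) if pos.size else 0.0,
        "n_negative_edges": int((rho[finite] <= -threshold).sum()),
        "n_positive_edges": int((rho[finite] >= threshold).sum()),
        "pct_strong_negative": 100.0 * (rho[finite] <= -threshold).mean()
        if finite.any() else 0.0,
    }
    if corr.p is not None:
        pv = corr.p.to_numpy(dtype=float)
        strong_sig = finite & (rho <= -threshold) & (pv <= alpha)
        out["pct_strong_negative_significant"] = 100.0 * strong_sig.mean()
    return out
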