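"""Driver attribution and scenario prediction for network specialization.

Attributes variation in specialization (H2') to distal drivers (water
temperature, nutrient enrichment) and proximal drivers (contemporary
nutrients, energy supply, biodiversity, chemodiversity, molecular traits)
using forward selection, variation partitioning, random-forest importance,
and a recursive path model over composite variables.  The fitted path
coefficients (lambda) drive a chain of linear prediction equations that
propagate temperature and nitrogen scenarios through the proximal composites
to predicted specialization, reported as differences from a baseline year.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "PathModel",
    "forward_select",
    "variation_partition",
    "rf_importance",
    "fit_path_model",
    "predict_proximal",
    "predict_h2prime",
    "scenario_deltas",
    "DEFAULT_PATH_SPEC",
]

COMPOSITES = ("nut", "energy", "biodiv", "chemodiv", "trait")
EXOGENOUS = ("temp", "N")

# Full recursive composite graph: each endogenous variable with its parents.
DEFAULT_PATH_SPEC = {
    "nut": ["temp", "N"],
    "energy": ["temp", "N", "nut"],
    "biodiv": ["temp", "N", "nut", "energy"],
    "chemodiv": ["temp", "N", "nut", "energy"],
    "trait": ["temp", "N", "nut", "energy", "biodiv", "chemodiv"],
    "H2": ["temp", "N", "nut", "energy", "biodiv", "chemodiv", "trait"],
}


def _ols_aic(X: np.ndarray, y: np.ndarray) -> float:
    n = len(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(((y - X @ beta) ** 2).sum())
    return n * np.log(max(rss, 1e-300) / n) + 2 * (X.shape[1] + 1)


def forward_select(X: pd.DataFrame, y, criterion: str = "AIC",
                   tie_tol: float = 1e-9) -> list:
    """Greedy forward selection of regression predictors by AIC.

    Adds one column at a time while the AIC improves by more than ``tie_tol``;
    deterministic given the data (ties broken by column order).
    """
    if criterion != "AIC":
        raise ValueError("only AIC is supported")
    y = np.asarray(y, dtype=float)
    n = len(y)
    selected: list = []
    remaining = list(X.columns)
    current = _ols_aic(np.ones((n, 1)), y)
    while remaining and len(selected) + 2 < n:
        scores = []
        for col in remaining:
            cols = selected + [col]
            Xc = np.column_stack([np.ones(n), X[cols].to_numpy(dtype=float)])
            scores.append((_ols_aic(Xc, y), col))
        best_aic, best_col = min(scores, key=lambda t: t[0])
        if best_aic < current - tie_tol:
            selected.append(best_col)
            remaining.remove(best_col)
            current = best_aic
        else:
            break
    return selected


def _adjusted_r2(Y: np.ndarray, X: np.ndarray) -> float:
    """Adjusted redundancy R^2 of (possibly multivariate) Y on X."""
    n, p = X.shape
    Yc = Y - Y.mean(axis=0)
    Xc = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fitted = Xc @ beta
    ss_tot = float((Yc**2).sum())
    if ss_tot == 0:
        return 0.0
    r2 = float((fitted**2).sum()) / ss_tot
    if n - p - 1 <= 0:
        return float("nan")
    return 1 - (1 - r2) * (n - 1) / (n - p - 1)


def variation_partition(Y, groups: dict) -> dict:
    """Unique and shared adjusted-R^2 fractions for 2-3 predictor groups.

    Uses redundancy-analysis R^2 (multivariate Y allowed) with Ezekiel
    adjustment and inclusion-exclusion over group combinations.  Negative
    adjusted fractions are reported as-is, not clipped.
    """
    names = list(groups)
    if not 2 <= len(names) <= 3:
        raise ValueError("need 2 or 3 predictor groups")
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    mats = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in mats.items():
        if v.ndim == 1:
            mats[k] = v[:, None]

    from itertools import combinations
    r2 = {}
    for size in range(1, len(names) + 1):
        for combo in combinations(names, size):
            X = np.hstack([mats[k] for k in combo])
            r2[frozenset(combo)] = _adjusted_r2(Y, X)
    total = r2[frozenset(names)]
    out = {"total": total, "r2": {"+".join(sorted(k)): v for k, v in r2.items()}}
    if len(names) == 2:
        a, b = names
        out[f"unique_{a}"] = total - r2[frozenset([b])]
        out[f"unique_{b}"] = total - r2[frozenset([a])]
        out["shared"] = r2[frozenset([a])] + r2[frozenset([b])] - total
    else:
        a, b, c = names
        for k in names:
            others = [x for x in names if x != k]
            out[f"unique_{k}"] = total - r2[frozenset(others)]
        # pairwise shared (excluding triple) via inclusion-exclusion
        triple = (r2[frozenset([a])] + r2[frozenset([b])] + r2[frozenset([c])]
                  - r2[frozenset([a, b])] - r2[frozenset([a, c])]
                  - r2[frozenset([b, c])] + total)
        out["shared_all"] = triple
        for k1, k2 in combinations(names, 2):
            out[f"shared_{k1}_{k2}"] = (
                r2[frozenset([k1])] + r2[frozenset([k2])]
                - r2[frozenset([k1, k2])] - triple)
    return out


def rf_importance(X: pd.DataFrame, y, n_trees: int = 2000,
                  seed: int | None = None) -> pd.DataFrame:
    """Out-of-bag permutation (accuracy) importance from a random forest.

    For each tree, the increase in mean squared error on that tree's
    out-of-bag samples when one predictor is permuted, averaged over the
    forest; the returned table is sorted by importance (rank 1 = most
    important).
    """
    Xv = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = Xv.shape
    if n < 30:
        raise ValueError("need n >= 30 samples")
    rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed,
                               bootstrap=True, n_jobs=1)
    rf.fit(Xv, y)
    rng = np.random.default_rng(seed)
    imp = np.zeros(p)
    counts = np.zeros(p)
    from sklearn.utils import check_random_state
    for est in rf.estimators_:
        # recover each tree's out-of-bag samples from its bootstrap seed
        # (bootstrap indices are drawn as randint(0, n, n) from the tree seed)
        boot = check_random_state(est.random_state).randint(0, n, n)
        mask = np.ones(n, dtype=bool)
        mask[boot] = False
        oob = np.where(mask)[0]
        if len(oob) == 0:
            continue
        base_mse = np.mean((y[oob] - est.predict(Xv[oob])) ** 2)
        for j in range(p):
            Xp = Xv[oob].copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            perm_mse = np.mean((y[oob] - est.predict(Xp)) ** 2)
            imp[j] += perm_mse - base_mse
            counts[j] += 1
    imp = imp / np.maximum(counts, 1)
    out = pd.DataFrame({"importance": imp}, index=X.columns)
    out["rank"] = out["importance"].rank(ascending=False).astype(int)
    return out.sort_values("importance", ascending=False)


@dataclass
class PathModel:
    """Fitted recursive path model over composites.

    ``lambdas`` maps ``"to,from"`` (e.g. ``"nut,temp"``, ``"H2,trait"``) to a
    standardized coefficient; ``standardization`` stores the training means
    and SDs of X_T and X_N so scenario inputs can be standardized identically;
    ``composite_weights`` records the indicator weights of each composite.
    """

    lambdas: dict
    spec: dict = field(default_factory=lambda: dict(DEFAULT_PATH_SPEC))
    standardization: dict = field(default_factory=dict)
    composite_weights: dict = field(default_factory=dict)
    fit_stats: dict = field(default_factory=dict)
    lambda_se: dict = field(default_factory=dict)
    admissible: bool = True

    def lam(self, to: str, frm: str) -> float:
        key = f"{to},{frm}"
        if key not in self.lambdas:
            raise KeyError(f"missing path coefficient lambda_{{{to},{frm}}}")
        return self.lambdas[key]

    def to_json(self) -> str:
        return json.dumps({
            "lambdas": self.lambdas, "spec": self.spec,
            "standardization": self.standardization,
            "composite_weights": self.composite_weights,
            "fit_stats": self.fit_stats, "lambda_se": self.lambda_se,
            "admissible": self.admissible,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PathModel":
        d = json.loads(text)
        return cls(**d)


def _check_acyclic(spec: dict):
    order = list(EXOGENOUS)
    for var, parents in spec.items():
        for p in parents:
            if p not in order:
                raise ValueError(
                    f"path spec is not recursive: {p!r} used before defined "
                    f"(in equation for {var!r})")
        order.append(var)


def composite_scores(indicators: dict, h2: np.ndarray,
                     p_keep: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Form composite variables from candidate indicator blocks.

    Indicator weights come from a multiple regression of H2' on each block's
    (z-scored) indicators; indicators with p <= ``p_keep`` are retained (all
    retained if none reach it, so a composite always exists).  Scores are
    z-scored.
    """
    import statsmodels.api as sm
    scores, weights = {}, {}
    for name, block in indicators.items():
        block = block.loc[:, block.std(ddof=0) > 0]  # drop constant indicators
        if block.shape[1] == 0:
            warnings.warn(f"composite {name!r} has no varying indicators")
            scores[name] = np.zeros(len(h2))
            weights[name] = {}
            continue
        Z = (block - block.mean()) / block.std(ddof=0)
        model = sm.OLS(h2, sm.add_constant(Z.to_numpy())).fit()
        pv = model.pvalues[1:]
        keep = np.where(pv <= p_keep)[0]
        if len(keep) == 0:
            keep = np.arange(Z.shape[1])
        w = model.params[1:][keep]
        s = Z.iloc[:, keep].to_numpy() @ w
        sd = s.std(ddof=0)
        scores[name] = (s - s.mean()) / (sd if sd > 0 else 1.0)
        weights[name] = dict(zip(Z.columns[keep], (w / (sd if sd > 0 else 1.0))))
    return pd.DataFrame(scores, index=next(iter(indicators.values())).index), weights


def _implied_covariance(spec: dict, lambdas: dict, psi: dict,
                        s_exo: np.ndarray, order: list) -> np.ndarray:
    """Model-implied covariance of [exogenous + endogenous] variables."""
    k = len(order)
    A = np.zeros((k, k))
    omega = np.zeros((k, k))
    n_exo = s_exo.shape[0]
    omega[:n_exo, :n_exo] = s_exo
    idx = {v: i for i, v in enumerate(order)}
    for var, parents in spec.items():
        i = idx[var]
        for p in parents:
            A[i, idx[p]] = lambdas[f"{var},{p}"]
        omega[i, i] = psi[var]
    inv = np.linalg.inv(np.eye(k) - A)
    return inv @ omega @ inv.T


def _fml(S: np.ndarray, sigma: np.ndarray) -> float:
    k = S.shape[0]
    sign_sig, logdet_sig = np.linalg.slogdet(sigma)
    sign_s, logdet_s = np.linalg.slogdet(S)
    if sign_sig <= 0 or sign_s <= 0:
        # singular (degenerate) covariance: infinite ML discrepancy
        return float("inf")
    return float(logdet_sig - logdet_s
                 + np.trace(S @ np.linalg.inv(sigma)) - k)


def fit_path_model(driver_table: pd.DataFrame, h2_values,
                   model_spec: dict | None = None,
                   candidate_specs: list | None = None) -> PathModel:
    """Fit a recursive path model by chained OLS and rank candidates by AIC.

    ``driver_table`` must contain z-scored columns ``temp`` and ``N`` plus the
    composite scores named in the spec; ``h2_values`` is the response (H2' or
    its null z-score, z-scored).  For a recursive system, equation-by-equation
    OLS is the maximum-likelihood estimator.  Fit statistics (chi-square from
    the ML discrepancy, CFI against the independence baseline, SRMR) are
    computed from observed vs model-implied covariance; admissibility =
    chi-square p > 0.05, CFI > 0.95, SRMR < 0.05.  With ``candidate_specs``,
    the admissible model with lowest AIC is returned (best-AIC with a failure
    flag when none is admissible).
    """
    from scipy.stats import chi2 as chi2_dist

    spec = dict(model_spec or DEFAULT_PATH_SPEC)
    specs = candidate_specs if candidate_specs else [spec]
    data = driver_table.copy()
    h2 = np.asarray(h2_values, dtype=float)
    data = data.assign(H2=h2)
    # standardized path coefficients: z-score every variable before fitting
    sds = data.std(ddof=0).replace(0, 1.0)
    data = (data - data.mean()) / sds
    n = len(data)

    fitted = []
    for sp in specs:
        _check_acyclic(sp)
        order = list(EXOGENOUS) + [v for v in sp]
        X_all = data[order].to_numpy(dtype=float)
        X_all = X_all - X_all.mean(axis=0)
        S = np.cov(X_all, rowvar=False, ddof=1)
        lambdas, lambda_se, psi = {}, {}, {}
        idx = {v: i for i, v in enumerate(order)}
        for var, parents in sp.items():
            Xp = X_all[:, [idx[p] for p in parents]]
            yv = X_all[:, idx[var]]
            beta, *_ = np.linalg.lstsq(Xp, yv, rcond=None)
            resid = yv - Xp @ beta
            dof = max(n - len(parents) - 1, 1)
            s2 = float(resid @ resid) / dof
            cov_beta = s2 * np.linalg.pinv(Xp.T @ Xp)
            for i_b, (b, p) in enumerate(zip(beta, parents)):
                lambdas[f"{var},{p}"] = float(b)
                lambda_se[f"{var},{p}"] = float(np.sqrt(cov_beta[i_b, i_b]))
            psi[var] = float(resid.var(ddof=1))
        s_exo = S[:len(EXOGENOUS), :len(EXOGENOUS)]
        sigma = _implied_covariance(sp, lambdas, psi, s_exo, order)
        k = len(order)
        n_free = (len(lambdas) + len(psi)
                  + len(EXOGENOUS) * (len(EXOGENOUS) + 1) // 2)
        df = k * (k + 1) // 2 - n_free
        chi2 = max((n - 1) * _fml(S, sigma), 0.0)
        chi2_p = float(chi2_dist.sf(chi2, df)) if df > 0 else 1.0
        # baseline (independence) model for CFI
        sigma_0 = np.diag(np.diag(S))
        chi2_0 = (n - 1) * _fml(S, sigma_0)
        df_0 = k * (k + 1) // 2 - k
        cfi = 1.0
        if chi2_0 - df_0 > 0:
            cfi = float(np.clip(1 - max(chi2 - df, 0) / (chi2_0 - df_0), 0, 1))
        # SRMR over standardized residual covariances
        dstd = np.sqrt(np.diag(S))
        resid_std = (S - sigma) / np.outer(dstd, dstd)
        iu = np.triu_indices(k)
        srmr = float(np.sqrt(np.mean(resid_std[iu] ** 2)))
        aic = chi2 + 2 * n_free
        fitted.append(PathModel(
            lambdas=lambdas, spec=sp,
            standardization={}, lambda_se=lambda_se,
            fit_stats={"chi2": chi2, "df": df, "chi2_p": chi2_p,
                       "CFI": cfi, "SRMR": srmr, "AIC": float(aic),
                       "n": n},
            admissible=(chi2_p > 0.05 and cfi > 0.95 and srmr < 0.05),
        ))
    admissible = [m for m in fitted if m.admissible]
    pool = admissible if admissible else fitted
    best = min(pool, key=lambda m: m.fit_stats["AIC"])
    if not admissible:
        warnings.warn("no candidate path model was admissible; "
                      "returning best-AIC model with failure flag")
        best.admissible = False
    return best


def _standardize_inputs(x_t, x_n, model: PathModel):
    x_t = np.asarray(x_t, dtype=float)
    x_n = np.asarray(x_n, dtype=float)
    st = model.standardization
    if st:
        x_t = (x_t - st["temp_mean"]) / st["temp_sd"]
        x_n = (x_n - st["N_mean"]) / st["N_sd"]
    return x_t, x_n


def predict_proximal(x_t, x_n, model: PathModel) -> dict:
    """Evaluate the chained proximal-composite equations in dependency order.

    Returns predicted values for each proximal composite (contemporary
    nutrients, energy supply, biodiversity, chemodiversity, molecular traits)
    given standardized temperature and total nitrogen.
    """
    x_t, x_n = _standardize_inputs(x_t, x_n, model)
    values = {"temp": x_t, "N": x_n}
    for var in model.spec:
        if var == "H2":
            continue
        acc = np.zeros_like(x_t, dtype=float)
        for p in model.spec[var]:
            acc = acc + model.lam(var, p) * values[p]
        values[var] = acc
    return {k: v for k, v in values.items() if k not in ("temp", "N")}


def predict_h2prime(x_t, x_n, model: PathModel):
    """Predicted standardized specialization Y_H2 from temperature and nitrogen."""
    x_t, x_n = _standardize_inputs(x_t, x_n, model)
    prox = predict_proximal(x_t, x_n, model)
    values = {"temp": x_t, "N": x_n, **prox}
    acc = np.zeros_like(np.asarray(x_t, dtype=float))
    for p in model.spec["H2"]:
        acc = acc + model.lam("H2", p) * values[p]
    return acc


def scenario_deltas(site_year_table: pd.DataFrame, models: dict,
                    baseline_year: int = 2007) -> pd.DataFrame:
    """Predicted specialization change per site-year, relative to a baseline.

    ``site_year_table`` needs columns site, year, temperature, total_nitrogen;
    ``models`` maps network sign ("negative"/"positive") to a fitted
    :class:`PathModel`.  Delta = Y_H2(site, year) - Y_H2(site, baseline).
    """
    req = {"site", "year", "temperature", "total_nitrogen"}
    if not req <= set(site_year_table.columns):
        raise ValueError(f"scenario table needs columns {sorted(req)}")
    if baseline_year not in set(site_year_table["year"]):
        raise ValueError(f"baseline year {baseline_year} absent")
    rows = []
    for sign, model in models.items():
        y = predict_h2prime(site_year_table["temperature"].to_numpy(),
                            site_year_table["total_nitrogen"].to_numpy(), model)
        tab = site_year_table[["site", "year"]].copy()
        tab["network"] = sign
        tab["Y_H2"] = y
        base = tab[tab["year"] == baseline_year].set_index("site")["Y_H2"]
        tab["delta_H2"] = tab["Y_H2"] - tab["site"].map(base).to_numpy()
        rows.append(tab)
    return pd.concat(rows, ignore_index=True)
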