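"""End-to-end pipeline orchestration with manifests and structured logging.

Runs the stages in dependency order — simulate -> traits -> diversity ->
network -> specialization -> drivers -> predict — from a single validated
configuration, writing TSV/JSON outputs and a manifest of per-stage input
and output hashes so reruns with identical configuration and seeds are
verifiably reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conet, diversity, drivers, molformula as mf, specialization, synthetic

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "load_config"]

log = logging.getLogger("edtia")

STAGES = ("simulate", "traits", "diversity", "network",
          "specialization", "drivers", "predict")


@dataclass
class RunConfig:
    """Validated pipeline configuration; every random stage has an explicit seed."""

    out_dir: str = "edtia_out"
    stages: tuple = STAGES
    seed: int = 0
    n_formulas: int = 120
    n_taxa: int = 30
    depth: int = 20_000
    design: dict = field(default_factory=dict)
    prevalence_min_fraction: float = 0.5
    correlation_method: str = "spearman"  # spearman | sparcc
    rho_threshold: float = 0.30
    sparcc_bootstrap: int = 20
    n_null: int = 100
    n_perm: int = 999
    baseline_year: int = 2007
    scenario_file: str | None = None

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        if not 0 <= self.prevalence_min_fraction <= 1:
            raise ValueError("prevalence_min_fraction must be in [0, 1]")
        if not 0 <= self.rho_threshold <= 1:
            raise ValueError("rho_threshold must be in [0, 1]")
        if self.correlation_method not in ("spearman", "sparcc"):
            raise ValueError("correlation_method must be spearman or sparcc")
        if self.seed is None:
            raise ValueError("an explicit seed is required")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


@dataclass
class RunManifest:
    """Per-stage record of parameters, output hashes and wall time."""

    stages: dict = field(default_factory=dict)

    def record(self, stage: str, status: str, outputs: dict, elapsed: float,
               reason: str = ""):
        self.stages[stage] = {
            "status": status, "outputs": outputs,
            "wall_time_s": round(elapsed, 3), "reason": reason,
        }

    def to_json(self) -> str:
        return json.dumps({"stages": self.stages}, indent=1)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, sep="\t", float_format="%.10g")
    return _hash_file(path)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages; on stage failure, skip downstream stages."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest()
    state: dict = {}
    failed = False
    for stage in STAGES:
        if stage not in config.stages:
            manifest.record(stage, "skipped", {}, 0.0, "disabled in config")
            continue
        if failed:
            manifest.record(stage, "skipped", {}, 0.0, "upstream failure")
            continue
        needs = _STAGE_DEPS[stage] - set(
            s for s in config.stages if manifest.stages.get(s, {}).get("status") == "ok"
        )
        missing = {d for d in _STAGE_DEPS[stage]
                   if manifest.stages.get(d, {}).get("status") != "ok"}
        if missing:
            manifest.record(stage, "skipped", {}, 0.0,
                            f"requires stages {sorted(missing)}")
            continue
        t0 = time.time()
        try:
            outputs = _STAGE_FUNCS[stage](config, state, out)
            manifest.record(stage, "ok", outputs, time.time() - t0)
            log.info("stage=%s status=ok elapsed=%.2fs", stage, time.time() - t0)
        except Exception as exc:  # record and halt downstream
            manifest.record(stage, "failed", {}, time.time() - t0, repr(exc))
            log.error("stage=%s status=failed error=%r", stage, exc)
            failed = True
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _stage_simulate(cfg: RunConfig, state: dict, out: Path) -> dict:
    design = synthetic.make_design(cfg.design)
    lib = synthetic.gen_formula_library(cfg.n_formulas, seed=cfg.seed)
    # planted links scale with the community size so tiny demo configs
    # still leave most taxa unlinked
    n_links = max(1, min(15, (cfg.n_taxa * 3) // 8))
    effects = synthetic.PeakEffects(
        nutrient_slope_pre={"lipids": 0.06, "proteins": 0.05,
                            "carbohydrates": 0.04},
        nutrient_slope_post={"lipids": -0.03, "proteins": -0.02,
                             "lignin": 0.03, "tannin": 0.03},
        temperature_slope={"condensed aromatics": -0.02, "lipids": 0.02},
        n_consumer_links=n_links, n_producer_links=n_links,
        links_per_taxon=3, taxa_per_molecule=2, link_strength=1.2,
    )
    peaks, gt = synthetic.gen_peak_table(design, lib, effects=effects,
                                         seed=cfg.seed + 1)
    otus = synthetic.gen_otu_table(design, cfg.n_taxa, coupling=gt,
                                   depth=cfg.depth, seed=cfg.seed + 2)
    env = synthetic.gen_environment(design, seed=cfg.seed + 3)
    state.update(design=design, library=lib, peaks=peaks, otus=otus,
                 env=env, ground_truth=gt)
    gt_path = out / "ground_truth.json"
    gt_path.write_text(gt.to_json())
    return {
        "peaks.tsv": _write_tsv(peaks, out / "peaks.tsv"),
        "otus.tsv": _write_tsv(otus, out / "otus.tsv"),
        "environment.tsv": _write_tsv(env, out / "environment.tsv"),
        "ground_truth.json": _hash_file(gt_path),
    }


def _stage_traits(cfg: RunConfig, state: dict, out: Path) -> dict:
    traits = mf.trait_table(state["library"])
    wm = mf.weighted_mean_traits(state["peaks"], traits)
    clusters = mf.ward_clusters(traits, k=min(10, len(traits)))
    classes = pd.Series({f.id: mf.assign_compound_class(f)
                         for f in state["library"]}, name="compound_class")
    annot = pd.concat([classes, clusters], axis=1)
    state.update(traits=traits, trait_wm=wm, annotations=annot)
    return {
        "traits.tsv": _write_tsv(traits, out / "traits.tsv"),
        "trait_weighted_means.tsv": _write_tsv(wm, out / "trait_weighted_means.tsv"),
        "molecule_annotations.tsv": _write_tsv(annot, out / "molecule_annotations.tsv"),
    }


def _stage_diversity(cfg: RunConfig, state: dict, out: Path) -> dict:
    peaks, otus = state["peaks"], state["otus"]
    dom_rich = diversity.richness(peaks)
    otu_rich = diversity.richness(otus)
    d_dom = diversity.bray_curtis(peaks)
    d_bac = diversity.bray_curtis(otus.div(otus.sum(axis=1), axis=0))
    nmds_dom = diversity.nmds_embed(d_dom, seed=cfg.seed, n_init=4, max_iter=100)
    nmds_bac = diversity.nmds_embed(d_bac, seed=cfg.seed, n_init=4, max_iter=100)
    r, p = diversity.mantel_test(d_dom, d_bac, n_perm=min(cfg.n_perm, 199),
                                 seed=cfg.seed)
    m2, _, p_proc = diversity.procrustes_protest(
        nmds_dom.coords.to_numpy(), nmds_bac.coords.to_numpy(),
        n_perm=min(cfg.n_perm, 199), seed=cfg.seed)
    ca1 = diversity.correspondence_axis(peaks)
    bp = diversity.piecewise_breakpoints(
        state["design"].samples()["nutrient_n"].to_numpy(), ca1.to_numpy())
    state.update(dom_richness=dom_rich, otu_richness=otu_rich,
                 nmds_dom=nmds_dom, nmds_bac=nmds_bac)
    report = {"mantel_r": r, "mantel_p": p, "procrustes_M2": m2,
              "procrustes_p": p_proc, "nmds_stress_dom": nmds_dom.stress,
              "nmds_stress_bacteria": nmds_bac.stress,
              "breakpoints": bp["breakpoints"],
              "n_breakpoints": bp["n_breakpoints"]}
    path = out / "diversity.json"
    path.write_text(json.dumps(report, indent=1))
    return {"diversity.json": _hash_file(path)}


def _stage_network(cfg: RunConfig, state: dict, out: Path) -> dict:
    peaks, _ = conet.prevalence_filter(state["peaks"], cfg.prevalence_min_fraction)
    otus, _ = conet.prevalence_filter(state["otus"], cfg.prevalence_min_fraction)
    if cfg.correlation_method == "sparcc":
        corr = conet.sparcc_correlations(peaks, otus, seed=cfg.seed,
                                         n_bootstrap=cfg.sparcc_bootstrap,
                                         n_permutations=0)
    else:
        corr = conet.spearman_matrix(peaks, otus)
    nets = {}
    hashes = {}
    import warnings as _w
    for sign in ("negative", "positive"):
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            net = conet.build_bipartite(corr, threshold=cfg.rho_threshold, sign=sign)
        nets[sign] = net
        path = out / f"network_{sign}.tsv"
        net.edges.to_csv(path, sep="\t", index=False)
        hashes[path.name] = _hash_file(path)
    state.update(corr=corr, networks=nets, filtered_peaks=peaks,
                 filtered_otus=otus)
    return hashes


def _stage_specialization(cfg: RunConfig, state: dict, out: Path) -> dict:
    results = {}
    for sign, net in state["networks"].items():
        if net.edges.empty:
            results[sign] = {"empty": True}
            continue
        M = net.interaction_matrix()
        try:
            scores = specialization.specialization_scores(
                M, n_null=cfg.n_null, seed=cfg.seed)
        except RuntimeError as exc:
            # margins can force a near-unique table on tiny demo networks,
            # making the null ensemble infeasible; report scores without it
            log.warning("null ensemble infeasible for %s network: %s", sign, exc)
            scores = specialization.specialization_scores(M, n_null=0)
            scores["null"] = {"error": str(exc)}
        results[sign] = {k: scores[k] for k in
                         ("H2", "H2max", "H2min", "H2_prime",
                          "weighted_d_prime_rows", "weighted_d_prime_cols")}
        if "null" in scores:
            results[sign]["null"] = scores["null"]
    # per-sample sweep on subnetworks: H2' plus the intensity-weighted mean
    # d' of DOM (weights differ per sample even when the induced subnetwork
    # does not, so the weighted index always varies across microcosms)
    sweep, dwm = {}, {}
    for sign, net in state["networks"].items():
        if net.edges.empty:
            continue
        vals, wvals = {}, {}
        import warnings as _w
        for sid in state["peaks"].index:
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                sub = conet.sample_subnetwork(net, state["filtered_peaks"],
                                              state["filtered_otus"], sid)
                if sub.edges.empty:
                    vals[sid] = float("nan")
                    wvals[sid] = float("nan")
                    continue
                M = sub.interaction_matrix()
                vals[sid] = specialization.h2_prime(M)
                dres = specialization.d_prime(M, "rows")["scores"]
                mols = list(dres)
                weights = state["peaks"].loc[sid, mols].to_numpy()
                wvals[sid] = specialization.weighted_specialization(
                    [dres[m]["d_prime"] for m in mols], weights)
        sweep[sign] = vals
        dwm[sign] = wvals
    state["h2_per_sample"] = pd.DataFrame(sweep)
    state["dwm_per_sample"] = pd.DataFrame(dwm)
    path = out / "specialization.json"
    path.write_text(json.dumps(results, indent=1))
    hashes = {"specialization.json": _hash_file(path)}
    hashes["h2_per_sample.tsv"] = _write_tsv(state["h2_per_sample"],
                                             out / "h2_per_sample.tsv")
    return hashes


def _stage_drivers(cfg: RunConfig, state: dict, out: Path) -> dict:
    env = state["env"]
    samples = state["design"].samples()
    h2 = state["h2_per_sample"]
    sign = "negative" if "negative" in h2 and h2["negative"].notna().sum() >= 30 \
        else h2.columns[0]
    y = h2[sign].fillna(h2[sign].mean()).to_numpy()
    if np.nanstd(y) < 1e-8:
        # every sample induced the same subnetwork; fall back to the
        # intensity-weighted mean d' of DOM, which varies with composition
        y = state["dwm_per_sample"][sign].to_numpy()
        y = np.where(np.isnan(y), np.nanmean(y), y)
    indicators = {
        "nut": env[["TN", "TP"]],
        "energy": env[["TOC", "DOC", "pH", "Chl_a"]],
        "biodiv": pd.concat([state["otu_richness"],
                             state["nmds_bac"].coords], axis=1),
        "chemodiv": pd.concat([state["dom_richness"],
                               state["nmds_dom"].coords], axis=1),
        "trait": state["trait_wm"][["mass", "nosc", "ai_mod", "gfe"]],
    }
    comps, weights = drivers.composite_scores(indicators, y)
    zt = (samples["temperature"] - samples["temperature"].mean()) \
        / samples["temperature"].std(ddof=0)
    zn = (samples["nutrient_n"] - samples["nutrient_n"].mean()) \
        / samples["nutrient_n"].std(ddof=0)
    table = comps.assign(temp=zt, N=zn)
    model = drivers.fit_path_model(table, y)
    model.composite_weights = weights
    model.standardization = {
        "temp_mean": float(samples["temperature"].mean()),
        "temp_sd": float(samples["temperature"].std(ddof=0)),
        "N_mean": float(samples["nutrient_n"].mean()),
        "N_sd": float(samples["nutrient_n"].std(ddof=0)),
    }
    state["path_model"] = model
    path = out / "path_model.json"
    path.write_text(model.to_json())
    return {"path_model.json": _hash_file(path)}


def _stage_predict(cfg: RunConfig, state: dict, out: Path) -> dict:
    model = state["path_model"]
    if cfg.scenario_file:
        scen = pd.read_csv(cfg.scenario_file, sep="\t")
    else:  # synthetic demo scenario: gentle warming + eutrophication trend
        years = np.arange(cfg.baseline_year, cfg.baseline_year + 12)
        rows = [{"site": f"site_{s:02d}", "year": int(yr),
                 "temperature": 17.0 + 0.05 * (yr - cfg.baseline_year) + 0.1 * s,
                 "total_nitrogen": 3.0 + 0.2 * (yr - cfg.baseline_year)}
                for s in range(4) for yr in years]
        scen = pd.DataFrame(rows)
    deltas = drivers.scenario_deltas(scen, {"fitted": model},
                                     baseline_year=cfg.baseline_year)
    return {"scenario_deltas.tsv": _write_tsv(deltas.set_index("site"),
                                              out / "scenario_deltas.tsv")}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "traits": _stage_traits,
    "diversity": _stage_diversity,
    "network": _stage_network,
    "specialization": _stage_specialization,
    "drivers": _stage_drivers,
    "predict": _stage_predict,
}

_STAGE_DEPS = {
    "simulate": set(),
    "traits": {"simulate"},
    "diversity": {"simulate"},
    "network": {"simulate"},
    "specialization": {"network"},
    "drivers": {"simulate", "traits", "diversity", "specialization"},
    "predict": {"drivers"},
}
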