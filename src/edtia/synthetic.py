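"""Synthetic microcosm-experiment data with planted molecule-taxon links.

Emulates a two-mountain field microcosm study: 2 regions x 5 elevations x
10 nutrient levels x 3 replicates (300 samples), nitrate additions of
0-36 mg N/L with phosphate held at a fixed N/P mass ratio of 14.93, FT-ICR MS
peak tables with log-normal intensities responding to nutrients and
temperature (with a compositional breakpoint along the nutrient gradient),
and OTU count tables rarefied to 20,000 reads per sample.  Ground-truth
consumer (negative) and producer (positive) molecule-taxon links are planted
so the network-inference stages can be validated by recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import molformula as mf

__all__ = [
    "ExperimentDesign",
    "PeakEffects",
    "GroundTruth",
    "DEFAULT_NUTRIENT_LEVELS",
    "make_design",
    "gen_formula_library",
    "gen_peak_table",
    "gen_otu_table",
    "gen_environment",
]

DEFAULT_NUTRIENT_LEVELS = (
    0.0, 0.45, 1.80, 4.05, 7.65, 11.25, 15.75, 21.60, 28.80, 36.00,
)

# (name, elevations m a.s.l., reference temperature at 0 m, degC)
DEFAULT_REGIONS = (
    {"name": "subtropical", "elevations": (3822, 3505, 2915, 2580, 2286),
     "sea_level_temp": 25.0},
    {"name": "subarctic", "elevations": (750, 550, 350, 170, 20),
     "sea_level_temp": 16.0},
)


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial microcosm design: regions x elevations x nutrient levels x reps."""

    regions: tuple = DEFAULT_REGIONS
    nutrient_levels: tuple = DEFAULT_NUTRIENT_LEVELS
    np_mass_ratio: float = 14.93
    replicates: int = 3
    lapse_rate: float = -0.55  # degC per 100 m

    def __post_init__(self):
        lv = np.asarray(self.nutrient_levels, dtype=float)
        if len(lv) < 1 or np.any(lv < 0) or np.any(np.diff(lv) <= 0):
            raise ValueError("nutrient levels must be non-negative, strictly increasing")
        if self.replicates < 1 or not self.regions:
            raise ValueError("counts must be >= 1")
        if self.np_mass_ratio <= 0:
            raise ValueError("np_mass_ratio must be > 0")

    def temperature(self, region: dict, elevation: float) -> float:
        return region["sea_level_temp"] + self.lapse_rate * elevation / 100.0

    def samples(self) -> pd.DataFrame:
        """Enumerate the sample list; deterministic given the design."""
        rows = []
        for reg in self.regions:
            for elev in reg["elevations"]:
                t = self.temperature(reg, elev)
                for nut in self.nutrient_levels:
                    for rep in range(1, self.replicates + 1):
                        rows.append({
                            "sample_id": f"{reg['name']}_e{elev}_n{nut:g}_r{rep}",
                            "region": reg["name"], "elevation": elev,
                            "temperature": t, "nutrient_n": nut, "replicate": rep,
                        })
        return pd.DataFrame(rows).set_index("sample_id")

    @property
    def n_samples(self) -> int:
        return sum(len(r["elevations"]) for r in self.regions) \
            * len(self.nutrient_levels) * self.replicates


def make_design(config: dict | None = None) -> ExperimentDesign:
    """Build an :class:`ExperimentDesign`, validating the configuration."""
    return ExperimentDesign(**(config or {}))


def _targeted_formula(rng: np.random.Generator, oc_range, hc_range,
                      extra: dict | None = None, tries: int = 200):
    """Search for a screened-in formula inside a van Krevelen window."""
    extra = extra or {}
    for _ in range(tries):
        c = int(rng.integers(8, 40))
        oc = rng.uniform(*oc_range)
        hc = rng.uniform(*hc_range)
        o = extra["O"] if "O" in extra else int(round(oc * c))
        h = max(1, int(round(hc * c)))
        n = extra.get("N", 0)
        s = extra.get("S", 0)
        p = extra.get("P", 0)
        for dh in (0, 1, -1, 2, -2):
            f = mf.MolecularFormula(c=c, h=max(1, h + dh), n=n, o=o, s=s, p=p)
            ok, _ = mf.screen_formula(f)
            if ok and 150.0 <= f.exact_mass <= 1200.0:
                return f
    return None


# coverage targets: one van Krevelen window per compound class ...
_CLASS_WINDOWS = {name: ((ocl, och), (hcl, hch))
                  for name, ocl, och, hcl, hch in mf.COMPOUND_CLASSES}
# ... and the element sets needed for the 12 elemental combinations
_COMBO_EXTRA = {
    "CH": {"O": 0}, "CHN": {"N": 1, "O": 0}, "CHNO": {"N": 1},
    "CHNOP": {"N": 1, "P": 1}, "CHNOS": {"N": 1, "S": 1},
    "CHNOSP": {"N": 1, "S": 1, "P": 1}, "CHNS": {"N": 1, "S": 1, "O": 0},
    "CHO": {}, "CHOP": {"P": 1}, "CHOS": {"S": 1},
    "CHOSP": {"S": 1, "P": 1}, "CHS": {"S": 1, "O": 0},
}


def gen_formula_library(n_formulas: int, seed: int | None = None) -> list:
    """Random screened-in CHNOSP formulas spanning the compound classes.

    Seeds the library with one formula per compound class and per elemental
    combination (when ``n_formulas`` allows), then fills with random draws
    over the van Krevelen plane.  Every returned formula passes
    :func:`edtia.molformula.screen_formula` and has mass in 150-1200 Da.
    """
    import warnings as _warnings
    if n_formulas < 1:
        raise ValueError("n_formulas must be >= 1")
    rng = np.random.default_rng(seed)
    lib: list[mf.MolecularFormula] = []
    seen: set[str] = set()

    def add(f):
        if f is not None and f.id not in seen:
            seen.add(f.id)
            lib.append(f)

    targets = []
    for name, (ocr, hcr) in _CLASS_WINDOWS.items():
        targets.append((ocr, hcr, {}))
    for combo, extra in _COMBO_EXTRA.items():
        ocr = (0.0, 0.05) if "O" not in combo else (0.1, 0.6)
        targets.append((ocr, (0.8, 1.4), extra))
    for ocr, hcr, extra in targets:
        if len(lib) >= n_formulas:
            break
        add(_targeted_formula(rng, ocr, hcr, extra))
    if n_formulas < len(targets):
        _warnings.warn(
            f"n_formulas={n_formulas} too small to span all compound classes "
            "and elemental combinations")
    guard = 0
    while len(lib) < n_formulas and guard < 50 * n_formulas + 1000:
        guard += 1
        oc = rng.uniform(0.0, 1.0)
        hc = rng.uniform(0.3, 2.2)
        extra = {}
        if rng.random() < 0.3:
            extra["N"] = int(rng.integers(1, 3))
        if rng.random() < 0.1:
            extra["S"] = 1
        if rng.random() < 0.1:
            extra["P"] = 1
        add(_targeted_formula(rng, (oc, min(1.0, oc + 0.05)),
                              (hc, min(2.2, hc + 0.1)), extra, tries=5))
    return lib[:n_formulas]


@dataclass
class PeakEffects:
    """Per-class log-intensity responses used by :func:`gen_peak_table`.

    ``nutrient_slope_pre``/``_post`` give the slope of log intensity against
    nutrient level below/above ``breakpoint`` for each compound class;
    ``temperature_slope`` is per degC.  ``noise_sd`` is the log-normal
    intensity error; FT-ICR MS intensities are positive and right-skewed,
    which this reproduces.
    """

    nutrient_slope_pre: dict = field(default_factory=dict)
    nutrient_slope_post: dict = field(default_factory=dict)
    temperature_slope: dict = field(default_factory=dict)
    breakpoint: float = 4.05
    noise_sd: float = 0.3
    base_sd: float = 1.5
    detection_ratio: float = 1e-3
    n_consumer_links: int = 12
    n_producer_links: int = 12
    links_per_taxon: int = 3
    taxa_per_molecule: int = 1
    link_strength: float = 1.0

    def validate(self, classes: set):
        known = set(mf.COMPOUND_CLASS_NAMES)
        for d in (self.nutrient_slope_pre, self.nutrient_slope_post,
                  self.temperature_slope):
            unknown = set(d) - known
            if unknown:
                raise ValueError(f"effects reference unknown classes: {unknown}")


@dataclass
class GroundTruth:
    """Planted structure for recovery testing.

    ``consumer_links`` are (molecule, taxon) pairs with negative association
    (the taxon consumes the molecule), ``producer_links`` positive ones.
    ``latent`` holds the per-sample activity of each linked taxon, shared
    between the peak and OTU generators so the planted correlations are
    realised on both sides.
    """

    consumer_links: list
    producer_links: list
    breakpoint_location: float
    latent: pd.DataFrame
    link_strength: float = 1.0

    def __post_init__(self):
        if set(self.consumer_links) & set(self.producer_links):
            raise ValueError("a link cannot be both consumer and producer")

    def to_json(self) -> str:
        return json.dumps({
            "consumer_links": [list(t) for t in self.consumer_links],
            "producer_links": [list(t) for t in self.producer_links],
            "breakpoint_location": self.breakpoint_location,
            "link_strength": self.link_strength,
        }, indent=1)


def gen_peak_table(design: ExperimentDesign, library: list,
                   effects: PeakEffects | None = None,
                   seed: int | None = None):
    """Peak table (samples x molecules, relative intensities) + ground truth.

    Log intensities are a molecule baseline plus class-specific piecewise
    nutrient and temperature responses plus planted link terms plus log-normal
    noise; each sample row is normalised to sum to 1.  Labile molecules
    (H/C >= 1.5) receive the consumer links so that planted consumer taxa
    co-vary negatively with them.
    """
    effects = effects or PeakEffects(
        nutrient_slope_pre={"lipids": 0.06, "proteins": 0.05, "carbohydrates": 0.04},
        nutrient_slope_post={"lipids": -0.03, "proteins": -0.02,
                             "lignin": 0.03, "tannin": 0.03},
        temperature_slope={"condensed aromatics": -0.02, "lipids": 0.02},
    )
    classes = {f.id: mf.assign_compound_class(f) for f in library}
    effects.validate(set(classes.values()))
    samples = design.samples()
    rng = np.random.default_rng(seed)
    n_s, n_m = len(samples), len(library)

    base = rng.normal(0.0, effects.base_sd, size=n_m)
    nut = samples["nutrient_n"].to_numpy()
    temp = samples["temperature"].to_numpy()
    bp = effects.breakpoint
    pre = np.minimum(nut, bp)
    post = np.maximum(nut - bp, 0.0)
    t_c = temp - temp.mean()

    logi = np.tile(base, (n_s, 1))
    for j, f in enumerate(library):
        cl = classes[f.id]
        logi[:, j] += effects.nutrient_slope_pre.get(cl, 0.0) * pre
        logi[:, j] += effects.nutrient_slope_post.get(cl, 0.0) * post
        logi[:, j] += effects.temperature_slope.get(cl, 0.0) * t_c

    # plant consumer links on labile molecules, producer links on the rest
    hc = np.array([f.h / f.c for f in library])
    labile = [f.id for f, v in zip(library, hc) if v >= 1.5]
    other = [f.id for f, v in zip(library, hc) if v < 1.5]
    n_con = min(effects.n_consumer_links, len(labile))
    n_pro = min(effects.n_producer_links, len(other))
    con_mols = list(rng.choice(labile, size=n_con, replace=False)) if n_con else []
    pro_mols = list(rng.choice(other, size=n_pro, replace=False)) if n_pro else []
    lpt = max(effects.links_per_taxon, 1)
    tpm = max(effects.taxa_per_molecule, 1)
    n_con_taxa = max(-(-n_con * tpm // lpt), tpm) if n_con else 0
    n_pro_taxa = max(-(-n_pro * tpm // lpt), tpm) if n_pro else 0
    taxa = [f"taxon_{i:03d}" for i in range(n_con_taxa + n_pro_taxa)]
    latent = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(n_s, len(taxa))),
        index=samples.index, columns=taxa,
    )
    consumer_links, producer_links = [], []
    col = {f.id: j for j, f in enumerate(library)}
    # linked molecules are minor but stable constituents: their fluctuations
    # must not dominate the per-sample normalization (which would leak
    # closure correlations onto unlinked molecules), and they must sit well
    # above the detection limit so the planted links stay observable
    for mol in [*con_mols, *pro_mols]:
        logi[:, col[mol]] += rng.normal(-1.5, 0.5) - base[col[mol]]

    # a degrader consumes several substrates (links_per_taxon) and a molecule
    # may be degraded/produced by several taxa (taxa_per_molecule); effects
    # are scaled by 1/sqrt(taxa_per_molecule) to keep signal variance fixed
    def plant(mols, pool, sign_):
        scale = effects.link_strength / np.sqrt(tpm)
        out = []
        for k, mol in enumerate(mols):
            for j in range(tpm):
                tax = pool[(k * tpm + j) % len(pool)]
                out.append((mol, tax))
                logi[:, col[mol]] += sign_ * scale * latent[tax].to_numpy()
        return out

    if n_con:
        consumer_links = plant(con_mols, taxa[:n_con_taxa], -1.0)
    if n_pro:
        producer_links = plant(pro_mols, taxa[n_con_taxa:], +1.0)

    logi += rng.normal(0.0, effects.noise_sd, size=logi.shape)
    inten = np.exp(logi)
    if effects.detection_ratio > 0:
        # instrument dynamic range: peaks below a fixed fraction of each
        # sample's base peak go undetected, so richness varies by sample
        limit = inten.max(axis=1, keepdims=True) * effects.detection_ratio
        inten = np.where(inten < limit, 0.0, inten)
    inten /= inten.sum(axis=1, keepdims=True)
    peaks = pd.DataFrame(inten, index=samples.index,
                         columns=[f.id for f in library])
    gt = GroundTruth(consumer_links=consumer_links, producer_links=producer_links,
                     breakpoint_location=bp, latent=latent,
                     link_strength=effects.link_strength)
    return peaks, gt


def gen_otu_table(design: ExperimentDesign, n_taxa: int,
                  coupling: GroundTruth | None = None,
                  depth: int = 20_000, seed: int | None = None,
                  coupling_strength: float = 1.0,
                  taxon_noise_sd: float = 1.0) -> pd.DataFrame:
    """OTU count table rarefied to exactly ``depth`` reads per sample.

    Taxon relative abundances follow a log-normal baseline; taxa named in the
    ground-truth links take their log-abundance from the shared latent
    activity (scaled by ``coupling_strength``), which realises the planted
    molecule-taxon correlations.  Counts are a multinomial draw of ``depth``
    reads per sample, so every sample total equals ``depth`` exactly.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    samples = design.samples()
    rng = np.random.default_rng(seed)
    linked = list(coupling.latent.columns) if coupling is not None else []
    if n_taxa < len(linked):
        raise ValueError(f"n_taxa={n_taxa} < {len(linked)} linked taxa")
    names = linked + [f"taxon_{i:03d}" for i in range(len(linked), n_taxa)]
    n_s = len(samples)
    logab = np.tile(rng.normal(0.0, 1.0, size=n_taxa), (n_s, 1))
    logab += rng.normal(0.0, taxon_noise_sd, size=logab.shape)
    for j, tax in enumerate(names):
        if coupling is not None and tax in coupling.latent.columns:
            logab[:, j] += coupling_strength * coupling.latent[tax].to_numpy()
    rel = np.exp(logab)
    rel /= rel.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, row) for row in rel])
    return pd.DataFrame(counts, index=samples.index, columns=names)


def gen_environment(design: ExperimentDesign, seed: int | None = None,
                    noise_sd: float = 0.05) -> pd.DataFrame:
    """Per-sample environment table (temperature, nutrients, TN/TP/TOC/DOC/Chl-a/pH).

    Phosphate-P is nitrate-N / np_mass_ratio (the stoichiometric compensation
    rule at time zero); TN/TP track the additions, and TOC/DOC/Chl-a/pH are
    correlated responses with multiplicative log-normal noise.
    """
    samples = design.samples()
    rng = np.random.default_rng(seed)
    n = len(samples)
    nut = samples["nutrient_n"].to_numpy()
    temp = samples["temperature"].to_numpy()

    def jitter():
        return np.exp(rng.normal(0.0, noise_sd, size=n))

    env = samples.copy()
    env["nutrient_p"] = nut / design.np_mass_ratio
    env["TN"] = (0.8 + nut) * jitter()
    env["TP"] = (0.05 + nut / design.np_mass_ratio) * jitter()
    env["TOC"] = (8.0 + 0.08 * nut + 0.15 * (temp - temp.min())) * jitter()
    env["DOC"] = (4.0 + 0.05 * nut + 0.10 * (temp - temp.min())) * jitter()
    env["Chl_a"] = (1.0 + 0.12 * nut + 0.08 * (temp - temp.min())) * jitter()
    env["pH"] = 7.5 + 0.01 * nut + 0.01 * (temp - temp.mean()) \
        + rng.normal(0.0, noise_sd, size=n)
    return env
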