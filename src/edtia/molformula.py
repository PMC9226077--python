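"""Molecular-formula handling for FT-ICR MS dissolved organic matter data.

Ultrahigh-resolution mass spectrometry of DOM yields molecular *formulas*
(element counts for C, H, N, O, S, P), not structures.  This module parses and
validates assigned formulas, bins them into van Krevelen compound classes and
elemental combinations, derives the 16 molecular traits used throughout the
pipeline (mass, C count, aromaticity and unsaturation indices, oxidation
state, thermodynamic quantities, element ratios and Kendrick defect), and
aggregates traits to intensity-weighted per-sample means.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "MolecularFormula",
    "ELEMENTS",
    "MONOISOTOPIC_MASS",
    "NOMINAL_MASS",
    "TRAIT_NAMES",
    "COMPOUND_CLASSES",
    "ELEMENTAL_COMBINATIONS",
    "parse_formula",
    "screen_formula",
    "elemental_combination",
    "assign_compound_class",
    "compute_traits",
    "trait_table",
    "weighted_mean_traits",
    "trait_gower_matrix",
    "ward_clusters",
]

ELEMENTS = ("C", "H", "N", "O", "S", "P")

# Monoisotopic masses of the most abundant isotopes (Da).
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}

# Integer nominal masses used for the nitrogen-parity rule.
NOMINAL_MASS = {"C": 12, "H": 1, "N": 14, "O": 16, "S": 32, "P": 31}

MASS_ELECTRON = 0.00054857990907
MASS_PROTON = MONOISOTOPIC_MASS["H"] - MASS_ELECTRON

TRAIT_NAMES = (
    "mass",
    "c_atoms",
    "ai_mod",
    "dbe",
    "dbe_o",
    "dbe_ai",
    "gfe",
    "kmd_ch2",
    "nosc",
    "oc",
    "hc",
    "nc",
    "pc",
    "sc",
    "y_met",
    "np_ratio",
)

# van Krevelen boxes as (label, oc_low, oc_high, hc_low, hc_high), evaluated in
# this order with half-open [low, high) intervals; first match wins.
COMPOUND_CLASSES = (
    ("lipids", 0.0, 0.3, 1.5, 2.0),
    ("proteins", 0.3, 0.55, 1.5, 2.2),
    ("amino sugars", 0.55, 0.67, 1.5, 2.2),
    ("carbohydrates", 0.67, 1.2, 1.5, 2.0),
    ("unsaturated hydrocarbons", 0.0, 0.1, 0.7, 1.5),
    ("lignin", 0.1, 0.67, 0.7, 1.5),
    ("tannin", 0.67, 1.2, 0.5, 1.5),
    ("condensed aromatics", 0.0, 0.67, 0.2, 0.7),
)

COMPOUND_CLASS_NAMES = tuple(c[0] for c in COMPOUND_CLASSES) + ("unclassified",)

ELEMENTAL_COMBINATIONS = (
    "CH",
    "CHN",
    "CHNO",
    "CHNOP",
    "CHNOS",
    "CHNOSP",
    "CHNS",
    "CHO",
    "CHOP",
    "CHOS",
    "CHOSP",
    "CHS",
)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaParseError(ValueError):
    """Raised for formula strings outside the CHNOSP alphabet."""


@dataclass(frozen=True)
class MolecularFormula:
    """A neutral molecular formula over C, H, N, O, S, P.

    ``exact_mass`` is the neutral monoisotopic mass in Da; it is computed from
    the atom counts unless supplied (e.g. from an instrument export).
    """

    c: int
    h: int
    n: int = 0
    o: int = 0
    s: int = 0
    p: int = 0
    exact_mass: float = field(default=0.0)
    id: str = ""

    def __post_init__(self):
        for el in ELEMENTS:
            if getattr(self, el.lower()) < 0:
                raise ValueError(f"negative {el} count")
        if self.exact_mass == 0.0:
            object.__setattr__(self, "exact_mass", self._mass_from_counts())
        if not self.id:
            object.__setattr__(self, "id", self.to_string())

    def _mass_from_counts(self) -> float:
        return sum(
            getattr(self, el.lower()) * MONOISOTOPIC_MASS[el] for el in ELEMENTS
        )

    @property
    def counts(self) -> dict[str, int]:
        return {el: getattr(self, el.lower()) for el in ELEMENTS}

    @property
    def nominal_mass(self) -> int:
        return sum(getattr(self, el.lower()) * NOMINAL_MASS[el] for el in ELEMENTS)

    @property
    def nominal_ion_mz(self) -> int:
        """Nominal m/z of the deprotonated [M-H]- ion (negative-mode ESI)."""
        return self.nominal_mass - 1

    def to_string(self) -> str:
        parts = []
        for el in ELEMENTS:
            k = getattr(self, el.lower())
            if k == 1:
                parts.append(el)
            elif k > 1:
                parts.append(f"{el}{k}")
        return "".join(parts)


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-order formula string such as ``"C6H12O6"``.

    Only C, H, N, O, S and P are accepted; a missing count means one atom.
    Raises :class:`FormulaParseError` for unknown elements or zero carbon.
    """
    if not text or not text.strip():
        raise FormulaParseError("empty formula string")
    counts = dict.fromkeys(ELEMENTS, 0)
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text.strip()):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise FormulaParseError(f"unparseable formula {text!r}")
        pos = m.end()
        el, num = m.group(1), m.group(2)
        if el not in counts:
            raise FormulaParseError(f"unsupported element {el!r} in {text!r}")
        counts[el] += int(num) if num else 1
    if pos != len(text.strip()):
        raise FormulaParseError(f"unparseable formula {text!r}")
    if counts["C"] == 0:
        raise FormulaParseError(f"formula {text!r} contains no carbon")
    return MolecularFormula(
        c=counts["C"], h=counts["H"], n=counts["N"], o=counts["O"],
        s=counts["S"], p=counts["P"],
    )


def dbe(f: MolecularFormula) -> float:
    """Double-bond equivalents, counting N and P as trivalent contributors."""
    return 1 + f.c - f.h / 2 + (f.n + f.p) / 2


def screen_formula(f: MolecularFormula, ion_mz: int | None = None):
    """Apply the standard CHNOSP formula-assignment screening rules.

    The rules, applied to the nominal m/z of the deprotonated ion:

    1. nitrogen parity — odd N implies even nominal m/z and vice versa;
    2. C/3 <= H <= 2C + N + 2;
    3. N <= C and O <= C;
    4. O/C in [0, 1], H/C >= 0.3, N/C <= 1 and DBE >= 0.

    Returns ``(passed, violations)`` where ``violations`` lists the failed
    rule numbers; never raises.
    """
    if ion_mz is None:
        ion_mz = f.nominal_ion_mz
    violations: list[int] = []
    n_odd, mz_odd = f.n % 2 == 1, int(ion_mz) % 2 == 1
    if n_odd == mz_odd:
        violations.append(1)
    if not (f.c / 3 <= f.h <= 2 * f.c + f.n + 2):
        violations.append(2)
    if f.n > f.c or f.o > f.c:
        violations.append(3)
    if f.c == 0:
        violations.append(4)
    else:
        oc, hc, nc = f.o / f.c, f.h / f.c, f.n / f.c
        if not (0 <= oc <= 1 and hc >= 0.3 and nc <= 1 and dbe(f) >= 0):
            violations.append(4)
    return (not violations, violations)


def elemental_combination(f: MolecularFormula) -> tuple[str, bool]:
    """Map a formula onto the 12 standard elemental combinations.

    Returns ``(label, known)``; combinations outside the standard list (e.g.
    P without O) are labelled ``"other"`` with ``known=False``.
    """
    label = "".join(el for el in ELEMENTS if getattr(f, el.lower()) > 0)
    if label in ELEMENTAL_COMBINATIONS:
        return label, True
    return "other", False


def assign_compound_class(f: MolecularFormula) -> str:
    """Assign a van Krevelen compound class from the H/C and O/C ratios.

    Boxes are half-open ``[low, high)`` on both axes and evaluated in a fixed
    order (first match wins), so every formula maps to exactly one label;
    points outside every box are ``"unclassified"``.
    """
    oc, hc = f.o / f.c, f.h / f.c
    for label, ocl, och, hcl, hch in COMPOUND_CLASSES:
        if ocl <= oc < och and hcl <= hc < hch:
            return label
    return "unclassified"


def y_met(
    nosc: float,
    delta_g_acceptor: float = -78.72,
    delta_g_syn: float = 30.0,
    efficiency: float = 0.6,
) -> float:
    """Thermodynamic growth yield (carbon-use-efficiency proxy).

    Electron-equivalents model: the donor half-reaction energy per electron is
    ``GFE / (4 - NOSC)`` (GFE in kJ per mol C, ``4 - NOSC`` electrons per C),
    coupled to an O2/H2O acceptor (``delta_g_acceptor`` kJ per e-eq); a fixed
    synthesis cost ``delta_g_syn`` and an energy-transfer ``efficiency``
    partition electrons between catabolism and biomass.  Strictly monotone
    (increasing) in NOSC on the screened domain (NOSC < 4).
    """
    electrons_per_c = 4.0 - nosc
    if electrons_per_c <= 0:
        return float("nan")
    donor_per_e = (60.3 - 28.5 * nosc) / electrons_per_c
    released = -(donor_per_e + delta_g_acceptor)  # kJ per e-eq; > 0 with O2
    if released <= 0:
        return float("nan")
    return 1.0 / (1.0 + delta_g_syn / (efficiency * released))


def _round_half_away(x: float) -> float:
    return math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)


def compute_traits(f: MolecularFormula, kmd_floor: bool = False) -> dict[str, float]:
    """Compute the 16 molecular traits for one formula.

    Division-by-zero cases (P=0 for the molecular N/P ratio, degenerate
    aromaticity denominators) yield flagged values, never exceptions: the N/P
    ratio uses ``max(P, eps)`` and AI_mod is clamped to 0.
    """
    c, h, n, o, s, p = f.c, f.h, f.n, f.o, f.s, f.p
    d = dbe(f)
    nosc = 4 - (4 * c + h - 3 * n - 2 * o + 5 * p - 2 * s) / c
    gfe = 60.3 - 28.5 * nosc
    ai_num = 1 + c - 0.5 * o - s - 0.5 * h
    ai_den = c - 0.5 * o - s - n - p
    ai_mod = ai_num / ai_den if (ai_num > 0 and ai_den > 0) else 0.0
    dbe_ai = 1 + c - o - s - 0.5 * (h + n + p)
    kendrick_mass = f.exact_mass * 14.0 / 14.01565
    nominal_km = math.floor(kendrick_mass) if kmd_floor else _round_half_away(kendrick_mass)
    eps = 1e-9
    return {
        "mass": f.exact_mass,
        "c_atoms": float(c),
        "ai_mod": ai_mod,
        "dbe": d,
        "dbe_o": d - o,
        "dbe_ai": dbe_ai,
        "gfe": gfe,
        "kmd_ch2": nominal_km - kendrick_mass,
        "nosc": nosc,
        "oc": o / c,
        "hc": h / c,
        "nc": n / c,
        "pc": p / c,
        "sc": s / c,
        "y_met": y_met(nosc),
        "np_ratio": n / max(p, eps) if p > 0 else (float(n) / eps if n else 0.0),
    }


def trait_table(formulas) -> pd.DataFrame:
    """Traits for a collection of formulas as a molecules x 16 DataFrame."""
    rows = {f.id: compute_traits(f) for f in formulas}
    return pd.DataFrame.from_dict(rows, orient="index")[list(TRAIT_NAMES)]


def weighted_mean_traits(peaks: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Intensity-weighted mean of each trait per sample.

    ``peaks`` is samples x molecules (relative intensities), ``traits`` is
    molecules x traits.  For each sample and trait the weighted mean is
    ``sum(trait_i * I_i) / sum(I_i)``; zero-intensity molecules contribute
    nothing.  Raises on an all-zero sample row.
    """
    missing = peaks.columns.difference(traits.index)
    if len(missing):
        raise KeyError(f"traits missing for molecules: {list(missing)[:5]}")
    w = peaks.to_numpy(dtype=float)
    totals = w.sum(axis=1)
    if np.any(totals <= 0):
        bad = peaks.index[totals <= 0].tolist()
        raise ValueError(f"all-zero intensity rows: {bad[:5]}")
    t = traits.loc[peaks.columns].to_numpy(dtype=float)
    wm = (w @ t) / totals[:, None]
    return pd.DataFrame(wm, index=peaks.index, columns=traits.columns)


def trait_gower_matrix(traits: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Gower distance between molecules over their traits.

    Range-normalised absolute differences averaged over traits; constant
    trait columns carry no information and are excluded with a warning.
    """
    if len(traits) < 2:
        raise ValueError("need at least 2 molecules")
    x = traits.to_numpy(dtype=float)
    rng = x.max(axis=0) - x.min(axis=0)
    keep = rng > 0
    if not keep.all():
        dropped = list(traits.columns[~keep])
        warnings.warn(f"constant traits excluded from Gower distance: {dropped}")
    if not keep.any():
        d = np.zeros((len(traits), len(traits)))
        return pd.DataFrame(d, index=traits.index, columns=traits.index)
    xs = x[:, keep] / rng[keep]
    d = np.zeros((len(xs), len(xs)))
    for j in range(xs.shape[1]):
        d += np.abs(xs[:, [j]] - xs[None, :, j])
    d /= xs.shape[1]
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=traits.index, columns=traits.index)


def ward_clusters(traits: pd.DataFrame, k: int = 10) -> pd.Series:
    """Group molecules into ``k`` clusters by Ward linkage on z-scored traits.

    Ten clusters is the conventional default for DOM trait space. Deterministic
    given the input table.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(traits):
        raise ValueError("k exceeds number of molecules")
    x = traits.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    lk = linkage(z, method="ward")
    labels = fcluster(lk, t=k, criterion="maxclust")
    return pd.Series(labels, index=traits.index, name="cluster")
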