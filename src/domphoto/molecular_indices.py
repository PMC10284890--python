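"""Per-formula molecular indices and the four-class compound taxonomy.

For an elemental composition C_c H_h O_o N_n S_s:

* DBE  = 1 + (2C - H + N) / 2           (double bond equivalence)
* NOSC = 4 - (4C + H - 3N - 2O - 2S)/C  (nominal oxidation state of carbon)
* AI_mod = DBE_AI / C_AI with
  DBE_AI = 1 + C - O/2 - S - (N + H)/2 and C_AI = C - O/2 - N - S

AI_mod treats half of the oxygen as carbonyl-like and is a conservative
lower bound on aromaticity.  When either the AI numerator or denominator is
non-positive the index is undefined and reported as 0 (flagged); the rare
arithmetic value above 1 is returned as computed, also flagged.

Compound classes (evaluated in this precedence order):

* CA   combustion-derived polycyclic aromatics   AI_mod > 0.66
* Pol  vascular plant-derived polyphenols        0.50 < AI_mod <= 0.66
* Uns  highly unsaturated / phenolic compounds   AI_mod <= 0.50 and H/C < 1.5
* Ali  aliphatic compounds                       1.5 <= H/C <= 2.0
* Other residual 2.0 < H/C < 2.2 formulas (excluded from four-class ratios)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .formula_assignment import MolecularFormula

__all__ = [
    "CLASS_LABELS",
    "FormulaIndices",
    "SampleMolecularSummary",
    "dbe",
    "nosc",
    "ai_mod",
    "classify",
    "compute_indices",
    "summarize_sample",
]

CLASS_LABELS = ("CA", "Pol", "Uns", "Ali", "Other")


def dbe(f: MolecularFormula) -> float:
    return 1.0 + (2 * f.c - f.h + f.n) / 2.0


def nosc(f: MolecularFormula) -> float:
    return 4.0 - (4 * f.c + f.h - 3 * f.n - 2 * f.o - 2 * f.s) / f.c


def ai_mod(f: MolecularFormula) -> float:
    value, _ = _ai_mod_flagged(f)
    return value


def _ai_mod_flagged(f: MolecularFormula) -> tuple[float, str | None]:
    num = 1.0 + f.c - f.o / 2.0 - f.s - (f.n + f.h) / 2.0
    den = f.c - f.o / 2.0 - f.n - f.s
    if den <= 0 or num <= 0:
        return 0.0, "undefined_clamped_to_0"
    value = num / den
    if value > 1.0:
        return value, "above_1"
    return value, None


def classify(f: MolecularFormula) -> str:
    """Assign the compound class from AI_mod and H/C (precedence CA > Pol > Uns > Ali)."""
    ai = ai_mod(f)
    hc = f.hc
    if ai > 0.66:
        return "CA"
    if ai > 0.50:
        return "Pol"
    if ai <= 0.50 and hc < 1.5:
        return "Uns"
    if 1.5 <= hc <= 2.0:
        return "Ali"
    return "Other"


@dataclass(frozen=True)
class FormulaIndices:
    """Derived indices for one assigned formula."""

    dbe: float
    nosc: float
    ai_mod: float
    hc: float
    oc: float
    compound_class: str
    ai_flag: str | None = None


def compute_indices(f: MolecularFormula) -> FormulaIndices:
    ai, flag = _ai_mod_flagged(f)
    return FormulaIndices(
        dbe=dbe(f),
        nosc=nosc(f),
        ai_mod=ai,
        hc=f.hc,
        oc=f.oc,
        compound_class=classify(f),
        ai_flag=flag,
    )


@dataclass
class SampleMolecularSummary:
    """Molecular-level summary of one annotated sample or formula subset."""

    n_formulas: int
    mean: dict[str, float]
    median: dict[str, float]
    class_shares: dict[str, float]
    class_ratios: dict[str, float]
    weighting: str


def summarize_sample(sample, weighting: Literal["none", "intensity"] = "none") -> SampleMolecularSummary:
    """Summarise the index distribution of an annotated sample.

    ``weighting="intensity"`` weights the mean/median of each index by
    relative intensity; class shares are always relative abundances
    (intensity-weighted shares of total signal) under intensity weighting
    and simple count fractions otherwise.  Class ratios (Uns/Ali, Pol/Ali,
    CA/Ali) are computed on those shares; a zero Ali share yields NaN.
    """
    formulas = list(sample.intensities)
    if not formulas:
        raise ValueError("no formulas: cannot summarise an empty sample")
    w = np.array([sample.intensities[f] for f in formulas], dtype=float)
    if weighting == "intensity":
        w = w / w.sum()
    elif weighting == "none":
        w = np.full(len(formulas), 1.0 / len(formulas))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    idx = [sample.indices[f] for f in formulas]
    values = {
        "dbe": np.array([i.dbe for i in idx]),
        "nosc": np.array([i.nosc for i in idx]),
        "ai_mod": np.array([i.ai_mod for i in idx]),
        "hc": np.array([i.hc for i in idx]),
    }
    mean = {k: float(np.sum(w * v)) for k, v in values.items()}
    median = {k: _weighted_median(v, w) for k, v in values.items()}

    shares = {}
    labels = np.array([i.compound_class for i in idx])
    for label in CLASS_LABELS:
        shares[label] = float(w[labels == label].sum())

    ratios = {}
    ali = shares["Ali"]
    for label in ("Uns", "Pol", "CA"):
        ratios[f"{label}/Ali"] = shares[label] / ali if ali > 0 else float("nan")

    return SampleMolecularSummary(
        n_formulas=len(formulas),
        mean=mean,
        median=median,
        class_shares=shares,
        class_ratios=ratios,
        weighting=weighting,
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Median of values under normalised weights (interpolating convention).

    With equal weights this reduces to the ordinary sample median.
    """
    order = np.argsort(values)
    v = values[order]
    cw = np.cumsum(weights[order])
    cw = cw / cw[-1]
    # position of cumulative weight 0.5 among the sorted values
    lo = np.searchsorted(cw, 0.5, side="left")
    if lo < len(v) and np.isclose(cw[lo], 0.5):
        return float((v[lo] + v[min(lo + 1, len(v) - 1)]) / 2.0)
    return float(v[min(lo, len(v) - 1)])


def indices_frame(sample):
    """Per-formula index table (pandas DataFrame) for an annotated sample."""
    import pandas as pd

    rows = []
    for f, inten in sample.intensities.items():
        i = sample.indices[f]
        rows.append(
            {
                "formula": str(f),
                "c": f.c, "h": f.h, "o": f.o, "n": f.n, "s": f.s,
                "neutral_mass": f.neutral_mass_Da,
                "intensity": inten,
                "dbe": i.dbe,
                "nosc": i.nosc,
                "ai_mod": i.ai_mod,
                "hc": i.hc,
                "oc": i.oc,
                "class": i.compound_class,
            }
        )
    return pd.DataFrame(rows).sort_values("neutral_mass").reset_index(drop=True)
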