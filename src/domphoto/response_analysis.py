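"""Respiration arithmetic, response ratios and the regression/ANOVA layer.

The study design behind these routines: water from each lake is split into a
UV-exposed (light) treatment and a dark control, then incubated with a
microbial inoculum; cumulative headspace CO2 is measured on days 0, 7 and
28, with blanks tracking bottle drift.  The response ratio (RR) of any
quantity is ln(light/dark); CO2-RR is the RR of blank-corrected microbial
CO2 production.  A single DOM-content gradient is summarised as PC1 of
standardised DOC and DON, and relationships between RRs and chemistry are
quantified with standardised regression coefficients (equal to Pearson r),
factorial ANOVA (type-II sums of squares) and two-sided Wilcoxon rank-sum
tests, with Benjamini-Hochberg FDR across families of comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import SampleRecord

__all__ = [
    "LakeSummary",
    "co2_production",
    "response_ratio",
    "dom_pc1",
    "standardized_coef",
    "factorial_anova",
    "group_rank_test",
    "fdr_adjust",
    "lake_co2_response",
]

logger = logging.getLogger(__name__)


def co2_production(
    record: SampleRecord, blank: SampleRecord | None, day: int
) -> float:
    """Blank-corrected cumulative CO2 production (umol) after ``day`` days.

    Production is the rise in cumulative headspace CO2 from day 0 (the
    background dissolved-inorganic-carbon signal), minus the same rise in
    the blank.  Negative values are retained (and flagged in the log), as
    they carry real information about drift.  Without a blank the
    uncorrected rise is returned with a warning.
    """
    if day not in (7, 28):
        raise ValueError("day must be 7 or 28")
    for rec, name in ((record, "sample"), (blank, "blank")):
        if rec is None:
            continue
        if day not in rec.co2_umol or 0 not in rec.co2_umol:
            raise ValueError(f"{name} is missing day-0 or day-{day} CO2")
    rise = record.co2_umol[day] - record.co2_umol[0]
    if blank is None:
        logger.warning("no blank provided; returning uncorrected CO2 rise")
        return rise
    value = rise - (blank.co2_umol[day] - blank.co2_umol[0])
    if value < 0:
        logger.warning(
            "%s: negative blank-corrected CO2 production (%.3f umol)",
            record.lake_id, value,
        )
    return value


def response_ratio(treatment_mean: float, control_mean: float, log: bool = True) -> float:
    """RR = ln(treatment/control); ``log=False`` gives the plain ratio."""
    if not (treatment_mean > 0 and control_mean > 0):
        raise ValueError("response ratio requires positive means")
    ratio = treatment_mean / control_mean
    return math.log(ratio) if log else ratio


def dom_pc1(
    doc_values: Sequence[float], don_values: Sequence[float]
) -> tuple[np.ndarray, float]:
    """DOM-content gradient: PC1 of standardised DOC and DON.

    Both variables are z-scored, the 2x2 correlation matrix is
    eigen-decomposed, and the leading component's scores are returned with
    the sign fixed so the DOC loading is positive.  Also returns the
    fraction of variance explained, which for two variables is
    (1 + |r|) / 2.
    """
    doc = np.asarray(doc_values, dtype=float)
    don = np.asarray(don_values, dtype=float)
    if doc.size != don.size or doc.size < 3:
        raise ValueError("need >= 3 paired DOC/DON values")
    if np.std(doc) == 0 or np.std(don) == 0:
        raise ValueError("DOC and DON must both vary across lakes")
    z = np.column_stack([_zscore(doc), _zscore(don)])
    corr = np.corrcoef(z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)  # ascending
    v = eigvec[:, -1]
    if v[0] < 0:
        v = -v
    scores = z @ v
    explained = float(eigval[-1] / eigval.sum())
    return scores, explained


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


@dataclass
class RegressionResult:
    coef: float
    p_value: float
    r2: float
    n: int


def standardized_coef(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """OLS slope of z(y) on z(x): the standardised regression coefficient.

    For simple regression this equals the Pearson correlation; the two-sided
    p-value comes from the t distribution with n - 2 df and R^2 = r^2.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need >= 3 paired finite values")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise ValueError("inputs must be finite")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise ValueError("zero variance in x or y")
    res = stats.linregress(_zscore(xa), _zscore(ya))
    return RegressionResult(
        coef=float(res.slope),
        p_value=float(res.pvalue),
        r2=float(res.rvalue**2),
        n=int(xa.size),
    )


_FACTOR_COLS = {"treatment": "treatment", "temperature": "temperature_C", "lake": "lake_id"}


def factorial_anova(
    table: pd.DataFrame,
    response: str = "co2_production",
    factors: Sequence[str] = ("treatment", "temperature", "lake"),
) -> pd.DataFrame:
    """Factorial ANOVA (type-II SS) of a response on up to three factors.

    ``table`` is long format with one row per microcosm; factors are any
    subset of {treatment, temperature, lake} mapped onto the columns
    ``treatment``, ``temperature_C`` and ``lake_id``.  All interactions are
    included.  The returned effect table is indexed by friendly term names:
    main effects by factor name and interactions like ``treatment:lake``
    (the sunlight-by-lake S x L term) or ``treatment:temperature`` (S x T).
    A response with zero variance yields NaN F statistics with a warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    unknown = [f for f in factors if f not in _FACTOR_COLS]
    if unknown:
        raise ValueError(f"unknown factor(s) {unknown}")
    for f in factors:
        if table[_FACTOR_COLS[f]].nunique() < 2:
            raise ValueError(f"factor {f!r} has a single level")
    if float(np.std(table[response])) == 0:
        logger.warning("response %r has zero variance; F undefined", response)

    terms = [f"C({_FACTOR_COLS[f]})" for f in factors]
    formula = f"{response} ~ " + " * ".join(terms)
    model = smf.ols(formula, data=table).fit()
    aov = sm.stats.anova_lm(model, typ=2)

    rename = {}
    for raw in aov.index:
        name = raw
        for f, col in _FACTOR_COLS.items():
            name = name.replace(f"C({col})", f)
        rename[raw] = name
    aov = aov.rename(index=rename)
    return aov


def group_rank_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (W, p) where W is the rank-sum statistic of the first group.
    The exact null distribution is used for small samples (both n <= 20,
    no ties); otherwise the normal approximation with tie correction.
    """
    aa = np.asarray(a, dtype=float)
    bb = np.asarray(b, dtype=float)
    if aa.size < 2 or bb.size < 2:
        raise ValueError("each group needs >= 2 values")
    ties = np.unique(np.concatenate([aa, bb])).size < aa.size + bb.size
    method = "exact" if (max(aa.size, bb.size) <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(aa, bb, alternative="two-sided", method=method)
    w = float(res.statistic + aa.size * (aa.size + 1) / 2)  # U -> rank sum
    return w, float(res.pvalue)


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


@dataclass
class LakeSummary:
    """Per-lake outcome of the response analysis."""

    lake_id: str
    co2_production_light: float
    co2_production_dark: float
    co2_rr: float
    chem_rr: dict[str, float] = field(default_factory=dict)
    dom_pc1: float = math.nan


def lake_co2_response(
    records: Sequence[SampleRecord],
    day: int = 28,
    log: bool = True,
) -> tuple[pd.DataFrame, list[LakeSummary]]:
    """CO2 production and response ratios per lake from the sample table.

    Blank corrections use the blank record matching each sample's
    temperature (the mean of matching blanks).  Treatment means pool the
    two incubation temperatures and the replicates, following the design's
    non-significant sunlight-by-temperature interaction.  Returns the
    long-format microcosm production table (for ANOVA) and per-lake
    summaries with CO2-RR.
    """
    blanks = [r for r in records if r.is_blank]
    samples = [r for r in records if not r.is_blank]

    def blank_for(temp: float) -> SampleRecord | None:
        match = [b for b in blanks if b.temperature_C == temp] or blanks
        if not match:
            return None
        co2: dict[int, float] = {}
        for d in (0, 7, 28):
            vals = [b.co2_umol[d] for b in match if d in b.co2_umol]
            if vals:
                co2[d] = float(np.mean(vals))
        proto = match[0]
        return SampleRecord(
            lake_id="blank_mean", treatment=proto.treatment,
            temperature_C=temp, replicate=0, doc_mgC_L=proto.doc_mgC_L,
            don_mg_L=proto.don_mg_L, co2_umol=co2, is_blank=True,
        )

    rows = []
    for r in samples:
        prod = co2_production(r, blank_for(r.temperature_C), day)
        rows.append(
            {
                "lake_id": r.lake_id,
                "treatment": r.treatment,
                "temperature_C": r.temperature_C,
                "replicate": r.replicate,
                "co2_production": prod,
            }
        )
    table = pd.DataFrame(rows)

    summaries = []
    for lake, g in table.groupby("lake_id", sort=True):
        mean_light = float(g.loc[g.treatment == "light", "co2_production"].mean())
        mean_dark = float(g.loc[g.treatment == "dark", "co2_production"].mean())
        rr = math.nan
        if mean_light > 0 and mean_dark > 0:
            rr = response_ratio(mean_light, mean_dark, log=log)
        else:
            logger.warning("%s: non-positive mean CO2 production; RR undefined", lake)
        summaries.append(
            LakeSummary(
                lake_id=str(lake),
                co2_production_light=mean_light,
                co2_production_dark=mean_dark,
                co2_rr=rr,
            )
        )
    return table, summaries
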