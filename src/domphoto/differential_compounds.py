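"""Photo-produced / photo-degraded / bio-degraded compound detection.

A pair of annotated samples (reference vs treated — dark vs light for the
photochemical step, pre- vs post-incubation for the microbial step) is
partitioned into produced / degraded / unchanged formula sets by one of two
methods:

* ``threshold20`` — a formula present in both samples is *produced* when
  both its raw-intensity relative change and its total-normalised
  (relative-intensity) relative change exceed +20 %, *degraded* when both
  fall below -20 %; formulas present in only one sample are produced or
  degraded by presence/absence.  The dual raw/normalised condition guards
  against total-signal drift between runs; the 20 % cut is a fixed
  effect-size threshold, not a statistical test.
* ``presence_absence`` — the stricter cross-validation variant: only
  appearance or disappearance counts; shared formulas are unchanged.

Concordance between the two methods (per-set Jaccard indices and
correlations of set-level chemistry across sample pairs) quantifies how much
the conclusions depend on the thresholding rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .formula_assignment import Assignment, MolecularFormula
from .molecular_indices import (
    FormulaIndices,
    SampleMolecularSummary,
    compute_indices,
    summarize_sample,
)

__all__ = [
    "AnnotatedSample",
    "DifferentialSet",
    "ConcordanceReport",
    "OverlapReport",
    "compare_threshold",
    "compare_presence_absence",
    "method_concordance",
    "set_overlap_analysis",
    "differential_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class AnnotatedSample:
    """Formula-resolved intensity table for one sample.

    ``intensities`` maps each assigned formula to its (summed) peak
    intensity; ``indices`` carries the derived molecular indices.  Relative
    intensity of a formula is its share of ``total_intensity``.
    """

    sample_id: str
    intensities: dict[MolecularFormula, float]
    indices: dict[MolecularFormula, FormulaIndices]
    assignments: list[Assignment] | None = None

    def __post_init__(self) -> None:
        for f, v in self.intensities.items():
            if not v > 0:
                raise ValueError(f"{self.sample_id}: non-positive intensity for {f}")

    @classmethod
    def from_intensities(
        cls,
        sample_id: str,
        intensities: Mapping[MolecularFormula, float],
        assignments: list[Assignment] | None = None,
    ) -> "AnnotatedSample":
        ints = {f: v for f, v in intensities.items() if v > 0}
        return cls(
            sample_id=sample_id,
            intensities=dict(ints),
            indices={f: compute_indices(f) for f in ints},
            assignments=assignments,
        )

    @property
    def total_intensity(self) -> float:
        return float(sum(self.intensities.values()))

    def relative_intensity(self, f: MolecularFormula) -> float:
        return self.intensities[f] / self.total_intensity

    def formulas(self) -> set[MolecularFormula]:
        return set(self.intensities)

    def subset(self, formulas: Iterable[MolecularFormula], sample_id: str | None = None) -> "AnnotatedSample":
        fs = [f for f in formulas if f in self.intensities]
        return AnnotatedSample(
            sample_id=sample_id or self.sample_id,
            intensities={f: self.intensities[f] for f in fs},
            indices={f: self.indices[f] for f in fs},
        )


@dataclass
class DifferentialSet:
    """Produced / degraded / unchanged partition for one sample pair."""

    reference_id: str
    treated_id: str
    method: str
    produced: set[MolecularFormula]
    degraded: set[MolecularFormula]
    unchanged: set[MolecularFormula]
    summaries: dict[str, SampleMolecularSummary] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.produced & self.degraded or self.produced & self.unchanged or (
            self.degraded & self.unchanged
        ):
            raise ValueError("produced/degraded/unchanged sets must be disjoint")


def _summaries(
    reference: AnnotatedSample,
    treated: AnnotatedSample,
    produced: set,
    degraded: set,
    unchanged: set,
) -> dict[str, SampleMolecularSummary]:
    out: dict[str, SampleMolecularSummary] = {}
    # produced compounds exist in the treated sample, degraded in the reference
    for label, sample, fs in (
        ("produced", treated, produced),
        ("degraded", reference, degraded),
        ("unchanged", reference, unchanged),
    ):
        sub = sample.subset(fs, f"{sample.sample_id}:{label}")
        if sub.intensities:
            out[label] = summarize_sample(sub, weighting="none")
    return out


def compare_threshold(
    reference: AnnotatedSample,
    treated: AnnotatedSample,
    frac: float = 0.20,
) -> DifferentialSet:
    """Partition formulas by the dual 20 % intensity-change rule.

    A shared formula is produced when both its raw-intensity ratio I_t/I_r
    and its relative-intensity (total-normalised) ratio exceed 1 + ``frac``;
    degraded when both fall below 1/(1 + ``frac``); otherwise unchanged.
    The reciprocal down-threshold (rather than a plain -20% change) makes
    "degraded under light" identical to "produced under the swapped
    comparison", so exchanging the reference and treated roles swaps the
    produced and degraded sets exactly -- a property the presence/absence
    cross-validation relies on.  Formulas present in only one sample are
    produced/degraded by presence.
    """
    if reference.sample_id == treated.sample_id:
        raise ValueError("reference and treated samples must differ")
    if not 0 < frac:
        raise ValueError("frac must be positive")
    produced: set[MolecularFormula] = set()
    degraded: set[MolecularFormula] = set()
    unchanged: set[MolecularFormula] = set()
    tot_r = reference.total_intensity
    tot_t = treated.total_intensity
    for f in reference.formulas() | treated.formulas():
        in_r = f in reference.intensities
        in_t = f in treated.intensities
        if in_t and not in_r:
            produced.add(f)
        elif in_r and not in_t:
            degraded.add(f)
        else:
            ir = reference.intensities[f]
            it = treated.intensities[f]
            r_raw = it / ir
            r_rel = (it / tot_t) / (ir / tot_r)
            if r_raw > 1 + frac and r_rel > 1 + frac:
                produced.add(f)
            elif r_raw < 1 / (1 + frac) and r_rel < 1 / (1 + frac):
                degraded.add(f)
            else:
                unchanged.add(f)
    return DifferentialSet(
        reference_id=reference.sample_id,
        treated_id=treated.sample_id,
        method="threshold20",
        produced=produced,
        degraded=degraded,
        unchanged=unchanged,
        summaries=_summaries(reference, treated, produced, degraded, unchanged),
    )


def compare_presence_absence(
    reference: AnnotatedSample, treated: AnnotatedSample
) -> DifferentialSet:
    """Partition formulas by appearance/disappearance only."""
    fr = reference.formulas()
    ft = treated.formulas()
    produced = ft - fr
    degraded = fr - ft
    unchanged = fr & ft
    return DifferentialSet(
        reference_id=reference.sample_id,
        treated_id=treated.sample_id,
        method="presence_absence",
        produced=produced,
        degraded=degraded,
        unchanged=unchanged,
        summaries=_summaries(reference, treated, produced, degraded, unchanged),
    )


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


@dataclass
class ConcordanceReport:
    """Agreement between the threshold and presence/absence methods."""

    jaccard: dict[str, list[float]]          # per set label, per pair
    mean_jaccard: dict[str, float]
    correlations: dict[str, dict[str, float]] | None  # label -> index -> Pearson r


def method_concordance(
    sets_a: Sequence[DifferentialSet], sets_b: Sequence[DifferentialSet]
) -> ConcordanceReport:
    """Compare two differential methods across a collection of sample pairs.

    For each set label the per-pair Jaccard index of formula sets is
    reported; with at least 3 pairs, Pearson correlations of per-set summary
    chemistry (mean AI_mod, DBE, NOSC, H/C and class shares) between methods
    are added.
    """
    if len(sets_a) != len(sets_b):
        raise ValueError("need the same sample pairs under both methods")
    for a, b in zip(sets_a, sets_b):
        if (a.reference_id, a.treated_id) != (b.reference_id, b.treated_id):
            raise ValueError(
                f"pair mismatch: {a.reference_id}/{a.treated_id} vs "
                f"{b.reference_id}/{b.treated_id}"
            )
    labels = ("produced", "degraded", "unchanged")
    jac = {
        lab: [_jaccard(getattr(a, lab), getattr(b, lab)) for a, b in zip(sets_a, sets_b)]
        for lab in labels
    }
    mean_jac = {lab: float(np.mean(v)) for lab, v in jac.items()}

    correlations: dict[str, dict[str, float]] | None = None
    if len(sets_a) >= 3:
        correlations = {}
        stats_keys = ["ai_mod", "dbe", "nosc", "hc"]
        for lab in labels:
            per_stat: dict[str, float] = {}
            for key in stats_keys + [f"share_{c}" for c in ("CA", "Pol", "Uns", "Ali")]:
                xs, ys = [], []
                for a, b in zip(sets_a, sets_b):
                    sa = a.summaries.get(lab)
                    sb = b.summaries.get(lab)
                    if sa is None or sb is None:
                        continue
                    if key.startswith("share_"):
                        cls = key.split("_", 1)[1]
                        xs.append(sa.class_shares[cls])
                        ys.append(sb.class_shares[cls])
                    else:
                        xs.append(sa.mean[key])
                        ys.append(sb.mean[key])
                if len(xs) >= 3 and np.std(xs) > 0 and np.std(ys) > 0:
                    per_stat[key] = float(stats.pearsonr(xs, ys)[0])
            correlations[lab] = per_stat
    return ConcordanceReport(jaccard=jac, mean_jaccard=mean_jac, correlations=correlations)


@dataclass
class OverlapReport:
    """Which compound pool (photo-produced or photo-degraded) a lake's
    bio-degraded compounds resemble most, judged on AI_mod."""

    medians: dict[str, dict[str, float]]        # lake -> set label -> median AI_mod
    rank_p: dict[str, dict[str, float]]         # lake -> pair -> two-sided p
    closest_to_bd: dict[str, str]               # lake -> "PP" or "PD"
    skipped: list[str]


def set_overlap_analysis(
    pp: Mapping[str, Sequence[float]],
    pd_: Mapping[str, Sequence[float]],
    bd: Mapping[str, Sequence[float]],
) -> OverlapReport:
    """Per-lake overlap diagnostic on AI_mod distributions.

    Inputs map lake id to the per-formula AI_mod values of the
    photo-produced (PP), photo-degraded (PD) and bio-degraded (BD) sets.
    For each lake the set medians, pairwise two-sided Wilcoxon rank-sum
    p-values, and the pool (PP or PD) whose median lies closer to BD are
    reported.  Lakes with an empty set are skipped with a warning; rank-sum
    tests are omitted when a set has fewer than 2 values.
    """
    medians: dict[str, dict[str, float]] = {}
    rank_p: dict[str, dict[str, float]] = {}
    closest: dict[str, str] = {}
    skipped: list[str] = []
    for lake in pp:
        sets = {
            "PP": np.asarray(pp[lake], dtype=float),
            "PD": np.asarray(pd_.get(lake, []), dtype=float),
            "BD": np.asarray(bd.get(lake, []), dtype=float),
        }
        if any(v.size == 0 for v in sets.values()):
            logger.warning("lake %s skipped: empty compound set", lake)
            skipped.append(lake)
            continue
        med = {k: float(np.median(v)) for k, v in sets.items()}
        medians[lake] = med
        pvals: dict[str, float] = {}
        for x, y in (("PP", "BD"), ("PD", "BD"), ("PP", "PD")):
            if sets[x].size >= 2 and sets[y].size >= 2:
                res = stats.mannwhitneyu(
                    sets[x], sets[y], alternative="two-sided",
                    method="exact" if max(sets[x].size, sets[y].size) <= 20 else "asymptotic",
                )
                pvals[f"{x}-{y}"] = float(res.pvalue)
        rank_p[lake] = pvals
        gap_pp = abs(med["PP"] - med["BD"])
        gap_pd = abs(med["PD"] - med["BD"])
        closest[lake] = "PP" if gap_pp <= gap_pd else "PD"
    return OverlapReport(medians=medians, rank_p=rank_p, closest_to_bd=closest, skipped=skipped)


def differential_frame(diff: DifferentialSet, reference: AnnotatedSample, treated: AnnotatedSample):
    """Long-format per-formula table for a differential partition."""
    import pandas as pd

    tot_r = reference.total_intensity
    tot_t = treated.total_intensity
    rows = []
    for status, fs in (
        ("produced", diff.produced),
        ("degraded", diff.degraded),
        ("unchanged", diff.unchanged),
    ):
        for f in sorted(fs):
            in_r = f in reference.intensities
            in_t = f in treated.intensities
            d_raw = d_rel = np.nan
            if in_r and in_t:
                ir, it = reference.intensities[f], treated.intensities[f]
                d_raw = (it - ir) / ir
                d_rel = (it / tot_t - ir / tot_r) / (ir / tot_r)
            idx = (treated if in_t else reference).indices[f]
            rows.append(
                {
                    "formula": str(f),
                    "status": status,
                    "delta_raw_frac": d_raw,
                    "delta_rel_frac": d_rel,
                    "class": idx.compound_class,
                    "ai_mod": idx.ai_mod,
                    "dbe": idx.dbe,
                    "nosc": idx.nosc,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["formula", "status", "delta_raw_frac", "delta_rel_frac",
                 "class", "ai_mod", "dbe", "nosc"],
    )
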