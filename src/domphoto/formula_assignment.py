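"""CHONS molecular-formula assignment for negative-ESI FT-ICR MS peak lists.

Every peak is treated as a singly charged deprotonated ion [M-H]-, so the
neutral monoisotopic mass is m/z plus one proton mass.  For each neutral
mass the full space of C(1..)H(0..)O(0..)N(0-1)S(0-1) formulas within a ppm
tolerance is enumerated by solving the hydrogen count from the mass balance,
then filtered to the chemically plausible region for natural organic matter
(0.3 < H/C < 2.2, O/C < 1.2, 100-800 Da neutral mass) and disambiguated by
the least-heteroatom rule: among surviving candidates, keep the formula with
the fewest N+S atoms, breaking ties by smallest absolute mass error.

Monoisotopic masses are IUPAC/CODATA values; 12C is exactly 12 Da by
definition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core_io import Peak, PeakList

__all__ = [
    "MASS_C",
    "MASS_H",
    "MASS_O",
    "MASS_N",
    "MASS_S",
    "MASS_PROTON",
    "MolecularFormula",
    "Assignment",
    "FilterRules",
    "neutral_mass_from_mz",
    "formula_mass",
    "enumerate_candidates",
    "filter_candidates",
    "disambiguate",
    "assign_peaklist",
    "replicate_consistency_filter",
]

logger = logging.getLogger(__name__)

MASS_C = 12.0
MASS_H = 1.00782503207
MASS_O = 15.99491461956
MASS_N = 14.0030740048
MASS_S = 31.97207100
MASS_PROTON = 1.00727646677


def formula_mass(c: int, h: int, o: int, n: int, s: int) -> float:
    """Neutral monoisotopic mass of C_c H_h O_o N_n S_s in Da.

    The summation order is fixed (C, H, O, N, S) so that every code path in
    the package computes bit-identical masses.
    """
    return MASS_C * c + MASS_H * h + MASS_O * o + MASS_N * n + MASS_S * s


@dataclass(frozen=True, order=True)
class MolecularFormula:
    """A neutral CHONS elemental composition with derived ratios."""

    c: int
    h: int
    o: int = 0
    n: int = 0
    s: int = 0

    def __post_init__(self) -> None:
        if self.c < 1:
            raise ValueError("formula must contain at least one carbon")
        if min(self.h, self.o, self.n, self.s) < 0:
            raise ValueError("atom counts must be non-negative")
        if self.n > 1 or self.s > 1:
            raise ValueError("at most one N and one S are allowed")

    @property
    def neutral_mass_Da(self) -> float:
        return formula_mass(self.c, self.h, self.o, self.n, self.s)

    @property
    def hc(self) -> float:
        return self.h / self.c

    @property
    def oc(self) -> float:
        return self.o / self.c

    @property
    def heteroatoms(self) -> int:
        """Number of non-oxygen heteroatoms (N + S)."""
        return self.n + self.s

    def __str__(self) -> str:  # Hill order: C, H, then alphabetical N, O, S
        parts = [f"C{self.c}", f"H{self.h}"]
        for sym, cnt in (("N", self.n), ("O", self.o), ("S", self.s)):
            if cnt == 1:
                parts.append(sym)
            elif cnt > 1:
                parts.append(f"{sym}{cnt}")
        return "".join(parts)


@dataclass(frozen=True)
class FilterRules:
    """Plausibility window for assigned DOM formulas.

    H/C and O/C bounds are exclusive; the neutral-mass window is inclusive.
    """

    hc_min: float = 0.3
    hc_max: float = 2.2
    oc_max: float = 1.2
    mass_min: float = 100.0
    mass_max: float = 800.0

    def passes(self, f: MolecularFormula) -> bool:
        return (
            self.hc_min < f.hc < self.hc_max
            and f.oc < self.oc_max
            and self.mass_min <= f.neutral_mass_Da <= self.mass_max
        )


@dataclass
class Assignment:
    """Outcome of assigning one peak: a formula or a rejection reason."""

    peak: Peak
    formula: MolecularFormula | None
    mass_error_ppm: float = math.nan
    candidates_considered: int = 0
    rejection_reason: str | None = None

    def __post_init__(self) -> None:
        if (self.formula is None) == (self.rejection_reason is None):
            raise ValueError("exactly one of formula / rejection_reason must be set")


def neutral_mass_from_mz(mz: float, charge: int = 1) -> float:
    """Neutral monoisotopic mass of M for an [M-H]- ion at the given m/z."""
    if charge != 1:
        raise NotImplementedError("only singly charged [M-H]- ions are supported")
    if not mz > 0:
        raise ValueError("m/z must be positive")
    return mz + MASS_PROTON


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------

# Pre-built (n, s, o, c) grid covering neutral masses up to ~1000 Da.  The
# hydrogen count is solved per query mass; one grid serves every call.
_GRID_MASS_MAX = 1000.0
_O_MAX = int(_GRID_MASS_MAX / 15.994)
_C_MAX = int(_GRID_MASS_MAX / MASS_C)


def _build_grid() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    n, s, o, c = np.meshgrid(
        np.arange(2), np.arange(2), np.arange(_O_MAX + 1), np.arange(1, _C_MAX + 1),
        indexing="ij",
    )
    n, s, o, c = (a.ravel() for a in (n, s, o, c))
    base = MASS_C * c + MASS_O * o + MASS_N * n + MASS_S * s
    keep = base <= _GRID_MASS_MAX
    return n[keep], s[keep], o[keep], c[keep], base[keep]


_GN, _GS, _GO, _GC, _GBASE = _build_grid()


def _enumerate_arrays(
    neutral_mass: float, tol_ppm: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised candidate search; returns (c, h, o, n, s, err_ppm) arrays."""
    h_float = (neutral_mass - _GBASE) / MASS_H
    h = np.rint(h_float)
    valid = h >= 0
    # recompute in the canonical summation order to match formula_mass()
    mass = (
        MASS_C * _GC + MASS_H * h + MASS_O * _GO + MASS_N * _GN + MASS_S * _GS
    )
    err_ppm = (mass - neutral_mass) / neutral_mass * 1e6
    keep = valid & (np.abs(err_ppm) <= tol_ppm)
    return (
        _GC[keep],
        h[keep].astype(int),
        _GO[keep],
        _GN[keep],
        _GS[keep],
        err_ppm[keep],
    )


def enumerate_candidates(neutral_mass: float, tol_ppm: float = 1.0) -> list[MolecularFormula]:
    """All CHONS formulas (N<=1, S<=1) within ``tol_ppm`` of a neutral mass.

    The search is exhaustive over c >= 1, o >= 0, n, s in {0, 1}; the
    hydrogen count is the unique integer solving the residual mass balance
    (within any tolerance <= 2 ppm at <= 1000 Da, at most one H count can
    match, since one hydrogen weighs ~1.008 Da).
    """
    if not 0 < tol_ppm <= 2:
        raise ValueError("tol_ppm must be in (0, 2]")
    if not 50 < neutral_mass < 1000:
        raise ValueError("neutral mass must be in (50, 1000) Da")
    c, h, o, n, s, _ = _enumerate_arrays(neutral_mass, tol_ppm)
    return [
        MolecularFormula(int(ci), int(hi), int(oi), int(ni), int(si))
        for ci, hi, oi, ni, si in zip(c, h, o, n, s)
    ]


def filter_candidates(
    candidates: Iterable[MolecularFormula], rules: FilterRules = FilterRules()
) -> list[MolecularFormula]:
    """Keep candidates inside the H/C, O/C and neutral-mass plausibility window."""
    return [f for f in candidates if rules.passes(f)]


def disambiguate(
    candidates: Sequence[MolecularFormula], neutral_mass: float | None = None
) -> tuple[MolecularFormula | None, str | None]:
    """Resolve multiple candidates by the least-heteroatom rule.

    Returns ``(formula, None)`` on success or ``(None, reason)`` with reason
    ``"no_candidate"`` (empty input) or ``"ambiguous"`` (residual exact tie
    on both N+S count and absolute mass error).
    """
    if not candidates:
        return None, "no_candidate"
    if len(candidates) == 1:
        return candidates[0], None

    def err(f: MolecularFormula) -> float:
        if neutral_mass is None:
            return 0.0
        return abs(f.neutral_mass_Da - neutral_mass) / neutral_mass * 1e6

    min_het = min(f.heteroatoms for f in candidates)
    pool = [f for f in candidates if f.heteroatoms == min_het]
    if len(pool) == 1:
        return pool[0], None
    errs = [err(f) for f in pool]
    best = min(errs)
    winners = [f for f, e in zip(pool, errs) if e == best]
    if len(winners) == 1:
        return winners[0], None
    return None, "ambiguous"


def assign_peaklist(
    pl: PeakList,
    tol_ppm: float = 1.0,
    snr_min: float = 4.0,
    rules: FilterRules = FilterRules(),
):
    """Assign formulas to all S/N-qualifying peaks of a peak list.

    Peaks with S/N <= ``snr_min`` are skipped (reason ``"low_snr"``).  The
    remaining peaks run through neutral-mass conversion, exhaustive candidate
    enumeration, plausibility filtering and least-heteroatom disambiguation.
    Returns an :class:`~domphoto.differential_compounds.AnnotatedSample`
    keyed by formula; if two peaks resolve to the same formula their
    intensities are summed and a warning is logged.
    """
    from .differential_compounds import AnnotatedSample  # deferred: avoids cycle

    assignments: list[Assignment] = []
    intensities: dict[MolecularFormula, float] = {}
    for peak in pl.peaks:
        if peak.snr <= snr_min:
            assignments.append(
                Assignment(peak, None, rejection_reason="low_snr")
            )
            continue
        neutral = neutral_mass_from_mz(peak.mz)
        c, h, o, n, s, err = _enumerate_arrays(neutral, tol_ppm)
        hc = h / c
        oc = o / c
        mass = neutral * (1.0 + err * 1e-6)
        keep = (
            (hc > rules.hc_min)
            & (hc < rules.hc_max)
            & (oc < rules.oc_max)
            & (mass >= rules.mass_min)
            & (mass <= rules.mass_max)
        )
        n_cand = int(keep.sum())
        if n_cand == 0:
            assignments.append(
                Assignment(peak, None, candidates_considered=int(c.size),
                           rejection_reason="no_candidate")
            )
            continue
        het = n[keep] + s[keep]
        aerr = np.abs(err[keep])
        order = np.lexsort((aerr, het))
        i0 = order[0]
        if n_cand > 1:
            i1 = order[1]
            if het[i1] == het[i0] and aerr[i1] == aerr[i0]:
                assignments.append(
                    Assignment(peak, None, candidates_considered=n_cand,
                               rejection_reason="ambiguous")
                )
                continue
        idx = np.nonzero(keep)[0][i0]
        f = MolecularFormula(int(c[idx]), int(h[idx]), int(o[idx]),
                             int(n[idx]), int(s[idx]))
        assignments.append(
            Assignment(peak, f, mass_error_ppm=float(err[idx]),
                       candidates_considered=n_cand)
        )
        if f in intensities:
            logger.warning(
                "%s: peaks at distinct m/z both assigned to %s; intensities summed",
                pl.sample_id, f,
            )
        intensities[f] = intensities.get(f, 0.0) + peak.intensity

    return AnnotatedSample.from_intensities(pl.sample_id, intensities,
                                            assignments=assignments)


def replicate_consistency_filter(
    replicate_formula_sets: Sequence[set[MolecularFormula]], k: int = 2
) -> set[MolecularFormula]:
    """Formulas present in at least ``k`` of the replicate assignments.

    Optional post-filter mirroring the common replicate-overlap QC step for
    FT-ICR DOM data (a formula seen in only one of three replicates is
    likely noise).
    """
    counts: dict[MolecularFormula, int] = {}
    for fs in replicate_formula_sets:
        for f in fs:
            counts[f] = counts.get(f, 0) + 1
    return {f for f, cnt in counts.items() if cnt >= k}
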