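"""Synthetic study generator with exact ground truth.

Emulates a 10-lake, 2-light-treatment (UV vs dark), 2-temperature,
3-replicate DOM photo/bio-degradation experiment end to end: CHONS formula
populations over 100-800 Da with lognormal intensities, paired dark/light
peak lists in which a controlled, class-stratified fraction of compounds is
removed or newly produced by light, piecewise-exponential absorbance
spectra with known slopes, Gaussian-component EEMs, and CO2 respiration
series generated from a stated log-linear model: the lake's respiration
response ratio is ``beta_co2`` times the (centred) aromatic share of its
photo-produced compounds plus Gaussian noise.  Every random draw descends
from a single seed through per-lake substreams, so adding lakes does not
perturb existing lakes, and truth records are sufficient to score every
pipeline stage.

Three intentional departures from real instrument output, chosen for
scorability: peaks are emitted only for true library formulas (no chemical
noise peaks); ions closer than ~3 ppm are not emitted in one list (a 15 T
instrument would not resolve them, and the peak-list contract rejects
near-duplicate m/z); and the planted formulas are restricted to the
unambiguously assignable part of the CHONS space — those with no
equal-or-fewer-heteroatom alternative within ``isolation_ppm`` of their own
mass.  The full space contains near-degenerate substitutions (e.g. swapping
N+S for C7H2O8 shifts the mass by only ~0.2 mDa) that no mass-based rule
can resolve at 1 ppm; planting such formulas would measure an
identifiability limit of exact-mass assignment itself rather than the
pipeline's correctness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core_io import (
    EEM,
    AbsorbanceSpectrum,
    PeakList,
    Peak,
    SampleRecord,
    write_eem,
    write_peaklist,
    write_samples,
    write_spectrum,
)
from .formula_assignment import MASS_PROTON, MolecularFormula, formula_mass

__all__ = [
    "GeneratorConfig",
    "PhotoEffect",
    "FormulaLibrary",
    "LakePair",
    "Study",
    "build_formula_library",
    "synthesize_peaklist",
    "synthesize_lake_pair",
    "synthesize_study",
    "write_study",
]

#: minimum ion spacing emitted within one synthetic peak list
MIN_ION_SPACING_PPM = 3.0

CLASSES = ("CA", "Pol", "Uns", "Ali", "Other")


@dataclass(frozen=True)
class PhotoEffect:
    """Class-stratified photo-production / photo-removal fractions.

    For a lake at normalised DOM-gradient position ``u`` in [0, 1], the
    fraction of class-k dark compounds removed by light is
    ``remove_base[k] + remove_slope[k] * u`` and the number of new class-k
    compounds produced is the analogous produce fraction times the dark
    class count.  The positive slopes on CA and Pol encode the study
    structure under test: high-DOM lakes photo-produce more aromatic-like
    compounds.
    """

    produce_base: Mapping[str, float] = field(
        default_factory=lambda: {"CA": 0.05, "Pol": 0.08, "Uns": 0.08, "Ali": 0.10, "Other": 0.05}
    )
    produce_slope: Mapping[str, float] = field(
        default_factory=lambda: {"CA": 0.30, "Pol": 0.25, "Uns": 0.0, "Ali": 0.0, "Other": 0.0}
    )
    remove_base: Mapping[str, float] = field(
        default_factory=lambda: {"CA": 0.05, "Pol": 0.05, "Uns": 0.10, "Ali": 0.15, "Other": 0.05}
    )
    remove_slope: Mapping[str, float] = field(
        default_factory=lambda: {"CA": 0.0, "Pol": 0.0, "Uns": 0.0, "Ali": 0.0, "Other": 0.0}
    )

    def fractions(self, u: float) -> tuple[dict[str, float], dict[str, float]]:
        produce = {
            k: float(np.clip(self.produce_base.get(k, 0.0) + self.produce_slope.get(k, 0.0) * u, 0, 1))
            for k in CLASSES
        }
        remove = {
            k: float(np.clip(self.remove_base.get(k, 0.0) + self.remove_slope.get(k, 0.0) * u, 0, 1))
            for k in CLASSES
        }
        return produce, remove


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-level generator parameters.

    Sample sizes follow the emulated design (10 lakes x 2 light treatments
    x 2 incubation temperatures x 3 replicates); DOC/DON/a300 spans mirror
    the field ranges of the emulated lake set.  ``formulas_per_lake`` is a
    desk-scale stand-in for the thousands of formulas a real FT-ICR DOM
    spectrum yields.
    """

    n_lakes: int = 10
    n_replicates: int = 3
    temperatures: tuple[float, float] = (10.0, 20.0)
    formulas_per_lake: int = 500
    library_size: int = 5000
    mass_range: tuple[float, float] = (100.0, 800.0)
    ppm_noise_sd: float = 0.3
    intensity_lognormal: tuple[float, float] = (11.5, 1.0)
    intensity_cv: float = 0.05
    snr_below4_frac: float = 0.05
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: {"Uns": 0.55, "Ali": 0.25, "Pol": 0.12, "CA": 0.05, "Other": 0.03}
    )
    photo_effect: PhotoEffect = field(default_factory=PhotoEffect)
    doc_range: tuple[float, float] = (5.69, 16.76)
    don_range: tuple[float, float] = (0.33, 1.35)
    a300_range: tuple[float, float] = (8.44, 65.87)
    path_length_m: float = 0.01
    beta_co2: float = 4.0
    noise_sd_co2: float = 0.15
    #: minimum ppm distance to any equal-or-fewer-heteroatom alternative for
    #: a formula to be planted (working tolerance 1 ppm + 4 sd of m/z noise)
    isolation_ppm: float = 2.2
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix probabilities must sum to 1, got {total}")
        for k, v in self.class_mix.items():
            if k not in CLASSES or v < 0:
                raise ValueError(f"bad class_mix entry {k}={v}")


# ---------------------------------------------------------------------------
# formula library
# ---------------------------------------------------------------------------


@dataclass
class FormulaLibrary:
    """Sampled pool of assignable formulas with class labels (array-backed)."""

    c: np.ndarray
    h: np.ndarray
    o: np.ndarray
    n: np.ndarray
    s: np.ndarray
    mass: np.ndarray
    label: np.ndarray  # unicode class labels

    def __len__(self) -> int:
        return int(self.c.size)

    def formula(self, i: int) -> MolecularFormula:
        return MolecularFormula(
            int(self.c[i]), int(self.h[i]), int(self.o[i]), int(self.n[i]), int(self.s[i])
        )

    def class_indices(self) -> dict[str, np.ndarray]:
        return {k: np.nonzero(self.label == k)[0] for k in CLASSES}


@lru_cache(maxsize=4)
def _full_space(mass_lo: float, mass_hi: float) -> tuple[np.ndarray, ...]:
    """Exhaustive assignable CHONS space (0.3<H/C<2.2, O/C<1.2, mass window)."""
    cs, hs, os_, ns, ss = [], [], [], [], []
    c_max = int(mass_hi / 12.0)
    for c in range(1, c_max + 1):
        h_lo = int(np.floor(0.3 * c)) + 1          # H/C > 0.3, exclusive
        h_hi = int(np.ceil(2.2 * c)) - 1           # H/C < 2.2, exclusive
        if h_hi < h_lo:
            continue
        o_hi = int(np.floor(1.2 * c - 1e-9))       # O/C < 1.2, exclusive
        h, o, n, s = np.meshgrid(
            np.arange(h_lo, h_hi + 1),
            np.arange(0, o_hi + 1),
            np.arange(2),
            np.arange(2),
            indexing="ij",
        )
        h, o, n, s = (a.ravel() for a in (h, o, n, s))
        mass = formula_mass(c, 0, 0, 0, 0) + 1.00782503207 * h + 15.99491461956 * o \
            + 14.0030740048 * n + 31.97207100 * s
        keep = (mass >= mass_lo) & (mass <= mass_hi)
        cs.append(np.full(int(keep.sum()), c))
        hs.append(h[keep])
        os_.append(o[keep])
        ns.append(n[keep])
        ss.append(s[keep])
    c = np.concatenate(cs)
    h = np.concatenate(hs)
    o = np.concatenate(os_)
    n = np.concatenate(ns)
    s = np.concatenate(ss)
    mass = 12.0 * c + 1.00782503207 * h + 15.99491461956 * o + 14.0030740048 * n \
        + 31.97207100 * s
    label = _classify_arrays(c, h, o, n, s)
    return c, h, o, n, s, mass, label


def _classify_arrays(c, h, o, n, s) -> np.ndarray:
    num = 1.0 + c - o / 2.0 - s - (n + h) / 2.0
    den = c - o / 2.0 - n - s
    ai = np.where((num > 0) & (den > 0), num / np.where(den > 0, den, 1.0), 0.0)
    hc = h / c
    return np.select(
        [ai > 0.66, ai > 0.50, (ai <= 0.50) & (hc < 1.5), (hc >= 1.5) & (hc <= 2.0)],
        ["CA", "Pol", "Uns", "Ali"],
        default="Other",
    ).astype("U5")


@lru_cache(maxsize=4)
def _isolated_space(
    mass_lo: float, mass_hi: float, isolation_ppm: float
) -> tuple[np.ndarray, ...]:
    """The sub-space of formulas with no het<=self competitor within ``isolation_ppm``.

    A planted formula is only recoverable by the least-heteroatom rule when
    every other in-filter formula inside the tolerance window around its
    observed mass has strictly more N+S atoms; this mask enforces that with
    margin for m/z noise.
    """
    c, h, o, n, s, mass, label = _full_space(mass_lo, mass_hi)
    order = np.argsort(mass)
    m = mass[order]
    het = (n + s)[order]
    lo = np.searchsorted(m, m * (1 - isolation_ppm * 1e-6), side="left")
    hi = np.searchsorted(m, m * (1 + isolation_ppm * 1e-6), side="right")
    rec = np.ones(m.size, dtype=bool)
    idx = np.arange(m.size)
    for k in range(1, int((hi - lo).max())):
        for sign in (-1, 1):
            j = idx + sign * k
            jj = np.clip(j, 0, m.size - 1)
            inwin = (j >= 0) & (j < m.size) & (jj >= lo) & (jj < hi)
            rec &= ~(inwin & (het[jj] <= het))
    keep = order[rec]
    keep.sort()
    return tuple(a[keep] for a in (c, h, o, n, s, mass, label))


def build_formula_library(cfg: GeneratorConfig) -> FormulaLibrary:
    """Sample ``cfg.library_size`` formulas matching ``cfg.class_mix``.

    The unambiguously assignable space (see :func:`_isolated_space`) is
    enumerated, classified, and sampled per class without replacement
    (counts are the largest-remainder apportionment of the mix).
    Deterministic given ``cfg.seed``.
    """
    c, h, o, n, s, mass, label = _isolated_space(*cfg.mass_range, cfg.isolation_ppm)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))
    counts = _apportion(cfg.class_mix, cfg.library_size)
    chosen: list[np.ndarray] = []
    for k in CLASSES:
        want = counts.get(k, 0)
        if want == 0:
            continue
        pool = np.nonzero(label == k)[0]
        if pool.size == 0:
            raise ValueError(f"no formulas available for class {k} in the mass window")
        if pool.size < want:
            raise ValueError(
                f"class {k} has only {pool.size} formulas, {want} requested"
            )
        chosen.append(rng.choice(pool, size=want, replace=False))
    idx = np.sort(np.concatenate(chosen))
    return FormulaLibrary(
        c=c[idx], h=h[idx], o=o[idx], n=n[idx], s=s[idx],
        mass=mass[idx], label=label[idx],
    )


def _apportion(mix: Mapping[str, float], total: int) -> dict[str, int]:
    raw = {k: mix.get(k, 0.0) * total for k in CLASSES}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = total - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


# ---------------------------------------------------------------------------
# peak lists
# ---------------------------------------------------------------------------


def synthesize_peaklist(
    library: FormulaLibrary,
    indices: Sequence[int],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    sample_id: str = "synthetic",
    intensities: Mapping[int, float] | None = None,
) -> tuple[PeakList, dict[float, MolecularFormula]]:
    """Emit one peak per library formula, with ppm noise on m/z.

    Each formula appears at its [M-H]- ion m/z perturbed by Gaussian
    relative error (sd ``cfg.ppm_noise_sd`` ppm), with a lognormal intensity
    (or the supplied per-index intensity), and an S/N drawn so that
    ``cfg.snr_below4_frac`` of peaks fall below the S/N > 4 cut.  Returns
    the peak list and an exact m/z -> generating-formula truth map.
    """
    idx = np.asarray(indices, dtype=int)
    ion = library.mass[idx] - MASS_PROTON
    mz = ion * (1.0 + rng.normal(0.0, cfg.ppm_noise_sd, size=idx.size) * 1e-6)
    if intensities is None:
        mu, sigma = cfg.intensity_lognormal
        inten = rng.lognormal(mu, sigma, size=idx.size)
    else:
        inten = np.array([intensities[int(i)] for i in idx], dtype=float)
    low = rng.random(idx.size) < cfg.snr_below4_frac
    snr = np.where(low, rng.uniform(0.5, 3.9, size=idx.size), rng.uniform(4.5, 60.0, size=idx.size))
    peaks = [Peak(float(m), float(v), float(q)) for m, v, q in zip(mz, inten, snr)]
    truth = {float(m): library.formula(int(i)) for m, i in zip(mz, idx)}
    return PeakList(sample_id=sample_id, peaks=peaks), truth


def _draw_spaced(
    rng: np.random.Generator,
    pool: np.ndarray,
    count: int,
    masses: np.ndarray,
    taken_masses: list[float],
) -> list[int]:
    """Draw ``count`` pool indices whose ion masses keep >= 3 ppm spacing."""
    accepted: list[int] = []
    order = rng.permutation(pool)
    sorted_taken = sorted(taken_masses)

    def ok(m: float) -> bool:
        import bisect

        j = bisect.bisect_left(sorted_taken, m)
        for k in (j - 1, j):
            if 0 <= k < len(sorted_taken):
                if abs(m - sorted_taken[k]) / m * 1e6 < MIN_ION_SPACING_PPM:
                    return False
        return True

    import bisect

    for i in order:
        if len(accepted) == count:
            break
        m = float(masses[i])
        if ok(m):
            accepted.append(int(i))
            bisect.insort(sorted_taken, m)
    if len(accepted) < count:
        raise ValueError(
            f"library too sparse: only {len(accepted)}/{count} spaced formulas"
        )
    taken_masses[:] = sorted_taken
    return accepted


# ---------------------------------------------------------------------------
# lake pairs and the full study
# ---------------------------------------------------------------------------


@dataclass
class LakePairTruth:
    """Exact bookkeeping of what light did to one lake's formula pool."""

    lake_id: str
    u: float
    produced: set[MolecularFormula]
    removed: set[MolecularFormula]
    shared: set[MolecularFormula]
    produced_class_counts: dict[str, int]
    dark_class_counts: dict[str, int]
    aromatic_share_produced: float  # (CA + Pol) count share of produced set
    mean_ai_produced: float


@dataclass
class LakePair:
    lake_id: str
    dark: PeakList
    light: PeakList
    dark_truth: dict[float, MolecularFormula]
    light_truth: dict[float, MolecularFormula]
    truth: LakePairTruth


def _lake_rng(cfg: GeneratorConfig, lake_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1, lake_index)))


def synthesize_lake_pair(
    lake_index: int,
    cfg: GeneratorConfig,
    library: FormulaLibrary | None = None,
) -> LakePair:
    """Generate the dark/light peak-list pair for one lake.

    The dark list draws ``cfg.formulas_per_lake`` formulas from the library
    by class mix; the light list removes a per-class fraction and injects a
    per-class fraction of new formulas, with CA/Pol production increasing
    along the DOM gradient (``u = lake_index / (n_lakes - 1)``).  Shared
    formulas keep a common base intensity with multiplicative replicate
    noise (CV ``cfg.intensity_cv``) so that, absent a true change, the
    20 %-rule calls them unchanged.
    """
    if library is None:
        library = build_formula_library(cfg)
    rng = _lake_rng(cfg, lake_index)
    u = lake_index / max(cfg.n_lakes - 1, 1)
    lake_id = f"L{lake_index + 1:02d}"

    by_class = library.class_indices()
    counts = _apportion(cfg.class_mix, cfg.formulas_per_lake)
    taken: list[float] = []
    dark_idx: list[int] = []
    for k in CLASSES:
        if counts.get(k, 0):
            dark_idx += _draw_spaced(rng, by_class[k], counts[k], library.mass, taken)

    produce, remove = cfg.photo_effect.fractions(u)
    removed_idx: list[int] = []
    kept_idx: list[int] = []
    dark_by_class = {k: [i for i in dark_idx if library.label[i] == k] for k in CLASSES}
    for k in CLASSES:
        pool = dark_by_class[k]
        n_remove = int(round(remove[k] * len(pool)))
        sel = list(rng.choice(len(pool), size=n_remove, replace=False)) if n_remove else []
        removed_idx += [pool[j] for j in sel]
        kept_idx += [pool[j] for j in range(len(pool)) if j not in set(sel)]

    injected_idx: list[int] = []
    dark_set = set(dark_idx)
    for k in CLASSES:
        n_new = int(round(produce[k] * len(dark_by_class[k])))
        if n_new:
            pool = np.array([i for i in by_class[k] if i not in dark_set], dtype=int)
            injected_idx += _draw_spaced(rng, pool, n_new, library.mass, taken)

    mu, sigma = cfg.intensity_lognormal
    base = {int(i): float(v) for i, v in zip(
        dark_idx + injected_idx,
        rng.lognormal(mu, sigma, size=len(dark_idx) + len(injected_idx)),
    )}

    def noisy(indices: list[int]) -> dict[int, float]:
        factors = np.maximum(rng.normal(1.0, cfg.intensity_cv, size=len(indices)), 0.05)
        return {int(i): base[int(i)] * float(f) for i, f in zip(indices, factors)}

    dark_pl, dark_truth = synthesize_peaklist(
        library, dark_idx, cfg, rng, sample_id=f"{lake_id}_dark",
        intensities=noisy(dark_idx),
    )
    light_indices = kept_idx + injected_idx
    light_pl, light_truth = synthesize_peaklist(
        library, light_indices, cfg, rng, sample_id=f"{lake_id}_light",
        intensities=noisy(light_indices),
    )

    produced_set = {library.formula(i) for i in injected_idx}
    removed_set = {library.formula(i) for i in removed_idx}
    shared_set = {library.formula(i) for i in kept_idx}
    prod_counts = {k: sum(1 for i in injected_idx if library.label[i] == k) for k in CLASSES}
    n_prod = max(sum(prod_counts.values()), 1)
    from .molecular_indices import ai_mod

    mean_ai = float(np.mean([ai_mod(f) for f in produced_set])) if produced_set else 0.0
    truth = LakePairTruth(
        lake_id=lake_id,
        u=u,
        produced=produced_set,
        removed=removed_set,
        shared=shared_set,
        produced_class_counts=prod_counts,
        dark_class_counts={k: len(dark_by_class[k]) for k in CLASSES},
        aromatic_share_produced=(prod_counts["CA"] + prod_counts["Pol"]) / n_prod,
        mean_ai_produced=mean_ai,
    )
    return LakePair(
        lake_id=lake_id, dark=dark_pl, light=light_pl,
        dark_truth=dark_truth, light_truth=light_truth, truth=truth,
    )


@dataclass
class StudyTruth:
    """Study-level ground truth for scoring the full pipeline."""

    u: dict[str, float]
    doc: dict[str, float]
    don: dict[str, float]
    a300: dict[str, float]
    s_short: dict[str, float]
    s_long: dict[str, float]
    rr_co2: dict[str, float]
    aromatic_share_produced: dict[str, float]
    mean_ai_produced: dict[str, float]


@dataclass
class Study:
    """Complete synthetic input bundle plus ground truth."""

    cfg: GeneratorConfig
    pairs: list[LakePair]
    spectra: dict[tuple[str, str], AbsorbanceSpectrum]
    eems: dict[tuple[str, str], EEM]
    records: list[SampleRecord]
    truth: StudyTruth

    @property
    def lake_ids(self) -> list[str]:
        return [p.lake_id for p in self.pairs]


def _gauss(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sd) ** 2)


def _make_spectrum(
    sample_id: str, a300: float, s_short: float, s_long: float, path_m: float
) -> AbsorbanceSpectrum:
    """Piecewise-exponential Napierian profile, continuous at 320 nm."""
    wl = np.arange(240.0, 601.0)
    a320 = a300 * np.exp(-s_short * 20.0)
    a = np.where(
        wl < 320.0,
        a320 * np.exp(-s_short * (wl - 320.0)),
        a320 * np.exp(-s_long * (wl - 320.0)),
    )
    absorbance = a * path_m / 2.303  # decadic, as a spectrophotometer reports
    return AbsorbanceSpectrum(
        sample_id=sample_id, wavelength_nm=wl, absorbance=absorbance,
        path_length_m=path_m,
    )


def _make_eem(sample_id: str, u: float, treatment: str) -> EEM:
    ex = np.arange(240.0, 451.0, 5.0)
    em = np.arange(280.0, 561.0, 4.0)
    exg, emg = np.meshgrid(ex, em, indexing="ij")
    humic = 0.8 + 1.5 * u
    protein = 1.2 - 0.6 * u
    if treatment == "light":
        humic *= 0.80   # photobleaching preferentially removes humic signal
        protein *= 0.95
    intensity = 100.0 * (
        humic * _gauss(exg, 320, 45) * _gauss(emg, 430, 55)
        + 0.6 * humic * _gauss(exg, 255, 25) * _gauss(emg, 440, 60)
        + protein * _gauss(exg, 275, 15) * _gauss(emg, 340, 25)
    )
    return EEM(sample_id=sample_id, excitation_nm=ex, emission_nm=em, intensity=intensity)


def synthesize_study(cfg: GeneratorConfig = GeneratorConfig()) -> Study:
    """Generate the complete study bundle.

    Per lake: the dark/light peak-list pair; absorbance spectra and EEMs for
    both treatments (a300 increasing along the DOM gradient, light samples
    mildly photobleached); and 2 treatments x 2 temperatures x 3 replicates
    of CO2 series in which the lake's respiration response ratio equals
    ``beta_co2`` times its centred photo-produced aromatic share plus
    N(0, noise_sd_co2) noise.  Blank microcosms carry the bottle drift that
    the blank correction is meant to remove.
    """
    library = build_formula_library(cfg)
    pairs = [synthesize_lake_pair(i, cfg, library) for i in range(cfg.n_lakes)]

    study_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(2,)))
    f_arom = np.array([p.truth.aromatic_share_produced for p in pairs])
    rr_true = cfg.beta_co2 * (f_arom - f_arom.mean()) + study_rng.normal(
        0.0, cfg.noise_sd_co2, size=cfg.n_lakes
    )

    spectra: dict[tuple[str, str], AbsorbanceSpectrum] = {}
    eems: dict[tuple[str, str], EEM] = {}
    records: list[SampleRecord] = []
    truth = StudyTruth(
        u={}, doc={}, don={}, a300={}, s_short={}, s_long={}, rr_co2={},
        aromatic_share_produced={}, mean_ai_produced={},
    )

    drift = {7: 1.5, 28: 3.0}  # umol of bottle CO2 drift shared with blanks
    for i, pair in enumerate(pairs):
        lake = pair.lake_id
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(3, i)))
        u = pair.truth.u
        doc = cfg.doc_range[0] + (cfg.doc_range[1] - cfg.doc_range[0]) * float(
            np.clip(u + rng.normal(0.0, 0.03), 0.0, 1.0)
        )
        don = cfg.don_range[0] + (cfg.don_range[1] - cfg.don_range[0]) * float(
            np.clip(u + rng.normal(0.0, 0.05), 0.0, 1.0)
        )
        a300 = cfg.a300_range[0] + (cfg.a300_range[1] - cfg.a300_range[0]) * u
        s_short = 0.020 - 0.006 * u
        sr = 1.8 - 0.6 * u
        s_long = s_short / sr
        for trt in ("dark", "light"):
            bleach = 0.85 if trt == "light" else 1.0
            steep = 1.05 if trt == "light" else 1.0
            spectra[(lake, trt)] = _make_spectrum(
                f"{lake}_{trt}", a300 * bleach, s_short * steep, s_long * steep,
                cfg.path_length_m,
            )
            eems[(lake, trt)] = _make_eem(f"{lake}_{trt}", u, trt)

        for trt in ("dark", "light"):
            for temp in cfg.temperatures:
                tempfactor = 2.0 ** ((temp - 20.0) / 10.0)  # Q10 = 2
                for rep in range(1, cfg.n_replicates + 1):
                    p28 = 3.0 * doc * tempfactor
                    if trt == "light":
                        p28 *= float(np.exp(rr_true[i]))
                    p28 *= float(np.maximum(rng.normal(1.0, 0.05), 0.05))
                    p7 = 0.45 * p28 * float(np.maximum(rng.normal(1.0, 0.05), 0.05))
                    d0 = 10.0 + 0.8 * doc + float(rng.normal(0.0, 0.3))
                    records.append(
                        SampleRecord(
                            lake_id=lake, treatment=trt, temperature_C=temp,
                            replicate=rep, doc_mgC_L=doc, don_mg_L=don,
                            co2_umol={
                                0: d0,
                                7: d0 + p7 + drift[7],
                                28: d0 + p28 + drift[28],
                            },
                        )
                    )
        truth.u[lake] = u
        truth.doc[lake] = doc
        truth.don[lake] = don
        truth.a300[lake] = a300
        truth.s_short[lake] = s_short
        truth.s_long[lake] = s_long
        truth.rr_co2[lake] = float(rr_true[i])
        truth.aromatic_share_produced[lake] = float(f_arom[i])
        truth.mean_ai_produced[lake] = pair.truth.mean_ai_produced

    blank_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(4,)))
    for temp in cfg.temperatures:
        for rep in range(1, cfg.n_replicates + 1):
            d0 = 5.0 + float(blank_rng.normal(0.0, 0.1))
            records.append(
                SampleRecord(
                    lake_id="blank", treatment="dark", temperature_C=temp,
                    replicate=rep, doc_mgC_L=0.0, don_mg_L=0.0,
                    co2_umol={
                        0: d0,
                        7: d0 + drift[7] * float(blank_rng.normal(1.0, 0.03)),
                        28: d0 + drift[28] * float(blank_rng.normal(1.0, 0.03)),
                    },
                    is_blank=True,
                )
            )

    return Study(cfg=cfg, pairs=pairs, spectra=spectra, eems=eems,
                 records=records, truth=truth)


def write_study(study: Study, out_dir: str | Path) -> None:
    """Write the full bundle in the package's delimited-text schemas.

    Layout: ``samples.csv``, ``truth.json`` and per lake x treatment
    ``peaks_<lake>_<trt>.csv``, ``spectrum_<lake>_<trt>.csv``,
    ``eem_<lake>_<trt>.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_samples(study.records, out / "samples.csv")
    for pair in study.pairs:
        write_peaklist(pair.dark, out / f"peaks_{pair.lake_id}_dark.csv")
        write_peaklist(pair.light, out / f"peaks_{pair.lake_id}_light.csv")
    for (lake, trt), spec in study.spectra.items():
        write_spectrum(spec, out / f"spectrum_{lake}_{trt}.csv")
    for (lake, trt), eem in study.eems.items():
        write_eem(eem, out / f"eem_{lake}_{trt}.csv")

    payload = {
        "u": study.truth.u,
        "doc": study.truth.doc,
        "don": study.truth.don,
        "a300": study.truth.a300,
        "s_short": study.truth.s_short,
        "s_long": study.truth.s_long,
        "rr_co2": study.truth.rr_co2,
        "aromatic_share_produced": study.truth.aromatic_share_produced,
        "mean_ai_produced": study.truth.mean_ai_produced,
        "produced": {p.lake_id: sorted(str(f) for f in p.truth.produced) for p in study.pairs},
        "removed": {p.lake_id: sorted(str(f) for f in p.truth.removed) for p in study.pairs},
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
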