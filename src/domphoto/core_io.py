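"""Data model and delimited-text IO for DOM photo/bio-degradation studies.

The exchange formats are deliberately plain: UTF-8 delimited text with a
header row (comma by default, tab via ``sep="\\t"``).  Peak picking,
centroiding and instrument calibration happen upstream in vendor software;
this package consumes centroided peak lists, decadic absorbance spectra,
scatter-corrected fluorescence excitation-emission matrices (EEMs) and a
sample metadata table.

Schemas
-------
peaks:    ``mz,intensity,snr``
spectrum: ``wavelength_nm,absorbance`` (+ ``path_length_m`` column or argument)
eem:      long format ``excitation_nm,emission_nm,intensity``
samples:  ``lake_id,treatment,temperature_C,replicate,doc_mgC_L,don_mg_L,
          co2_d0,co2_d7,co2_d28,is_blank``
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "PeakList",
    "AbsorbanceSpectrum",
    "EEM",
    "SampleRecord",
    "FormatError",
    "ValidationError",
    "read_peaklist",
    "write_peaklist",
    "read_spectrum",
    "write_spectrum",
    "read_eem",
    "write_eem",
    "read_samples",
    "write_samples",
    "write_table",
]

#: relative m/z separation below which two peaks are considered duplicates
DUPLICATE_MZ_PPM = 0.1

#: text encoding precision used for lossless numeric round-trips
_FLOAT_FMT = "%.12g"

TREATMENTS = ("light", "dark")


class FormatError(ValueError):
    """A file does not follow the expected delimited-text schema."""


class ValidationError(ValueError):
    """A parsed value violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Peak:
    """One centroided ion: m/z (Th), intensity (arbitrary units), S/N."""

    mz: float
    intensity: float
    snr: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValidationError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValidationError(
                f"peak intensity must be non-negative, got {self.intensity}"
            )
        if self.snr < 0:
            raise ValidationError(f"peak S/N must be non-negative, got {self.snr}")


@dataclass
class PeakList:
    """Centroided negative-ESI peak list for one sample, sorted by m/z."""

    sample_id: str
    peaks: list[Peak]
    polarity: str = "negative"

    def __post_init__(self) -> None:
        if self.polarity != "negative":
            raise ValidationError(
                f"only negative-ESI peak lists are supported, got {self.polarity!r}"
            )
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)
        mz = np.array([p.mz for p in self.peaks])
        if len(mz) > 1:
            rel = np.diff(mz) / mz[:-1] * 1e6
            bad = np.nonzero(rel < DUPLICATE_MZ_PPM)[0]
            if bad.size:
                raise ValidationError(
                    f"{self.sample_id}: duplicate m/z within "
                    f"{DUPLICATE_MZ_PPM} ppm at index {bad[0]} "
                    f"({mz[bad[0]]:.6f} / {mz[bad[0] + 1]:.6f})"
                )

    def __len__(self) -> int:
        return len(self.peaks)

    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])


@dataclass
class AbsorbanceSpectrum:
    """Decadic UV-Vis absorbance spectrum on an increasing wavelength grid.

    Absorbance is stored decadic, exactly as measured; the Napierian
    conversion (factor ln 10 ~ 2.303) is applied only when computing
    absorption coefficients.
    """

    sample_id: str
    wavelength_nm: np.ndarray
    absorbance: np.ndarray
    path_length_m: float

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelength_nm.shape != self.absorbance.shape:
            raise ValidationError("wavelength and absorbance lengths differ")
        if not self.path_length_m > 0:
            raise ValidationError("path length must be positive")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if np.any(self.absorbance < 0):
            raise ValidationError("absorbance values must be non-negative")


@dataclass
class EEM:
    """Fluorescence excitation-emission matrix (rows = excitation)."""

    sample_id: str
    excitation_nm: np.ndarray
    emission_nm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.excitation_nm = np.asarray(self.excitation_nm, dtype=float)
        self.emission_nm = np.asarray(self.emission_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.excitation_nm) <= 0) or np.any(
            np.diff(self.emission_nm) <= 0
        ):
            raise ValidationError("EEM grids must be strictly increasing")
        if self.intensity.shape != (
            self.excitation_nm.size,
            self.emission_nm.size,
        ):
            raise ValidationError(
                f"EEM matrix shape {self.intensity.shape} does not match grids "
                f"({self.excitation_nm.size}, {self.emission_nm.size})"
            )
        if np.any(self.intensity < 0):
            raise ValidationError("EEM intensities must be non-negative")


@dataclass
class SampleRecord:
    """Metadata and respiration series for one incubation microcosm.

    ``co2_umol`` maps incubation day (0, 7, 28) to the cumulative headspace
    CO2 (umol) measured on that day; day 0 is the background dissolved
    inorganic carbon and must be present whenever a later day is.
    """

    lake_id: str
    treatment: str
    temperature_C: float
    replicate: int
    doc_mgC_L: float
    don_mg_L: float
    co2_umol: dict[int, float] = field(default_factory=dict)
    is_blank: bool = False

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"unknown treatment {self.treatment!r}; allowed: {TREATMENTS}"
            )
        if not self.is_blank and not self.doc_mgC_L > 0:
            raise ValidationError(
                f"{self.lake_id}: DOC must be positive for non-blank samples"
            )
        for day, v in self.co2_umol.items():
            if v < 0:
                raise ValidationError(f"{self.lake_id}: CO2 on day {day} negative")
        if (7 in self.co2_umol or 28 in self.co2_umol) and 0 not in self.co2_umol:
            raise ValidationError(
                f"{self.lake_id}: day-0 CO2 required when day 7/28 present"
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_frame(path: str | Path, required: Sequence[str], sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def _require_numeric(df: pd.DataFrame, cols: Sequence[str], path: str | Path) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        vals = pd.to_numeric(out[c], errors="coerce")
        bad = vals.isna() & out[c].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise FormatError(
                f"{path}: column {c!r} row {row} is not numeric: {out[c][row]!r}"
            )
        out[c] = vals
    return out


def read_peaklist(path: str | Path, sample_id: str | None = None, sep: str = ",") -> PeakList:
    """Read a ``mz,intensity,snr`` table into a validated :class:`PeakList`.

    Rows failing numeric parse or domain invariants raise, naming the row;
    malformed input is never silently coerced.
    """
    df = _read_frame(path, ["mz", "intensity", "snr"], sep)
    df = _require_numeric(df, ["mz", "intensity", "snr"], path)
    peaks = []
    for row, rec in enumerate(df.itertuples(index=False)):
        try:
            peaks.append(Peak(float(rec.mz), float(rec.intensity), float(rec.snr)))
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {row}: {exc}") from exc
    sid = sample_id if sample_id is not None else Path(path).stem
    return PeakList(sample_id=sid, peaks=peaks)


def write_peaklist(pl: PeakList, path: str | Path, sep: str = ",") -> None:
    df = pd.DataFrame(
        {
            "mz": [p.mz for p in pl.peaks],
            "intensity": [p.intensity for p in pl.peaks],
            "snr": [p.snr for p in pl.peaks],
        }
    )
    write_table(df, path, sep=sep)


def read_spectrum(
    path: str | Path,
    sample_id: str | None = None,
    path_length_m: float | None = None,
    sep: str = ",",
) -> AbsorbanceSpectrum:
    """Read a ``wavelength_nm,absorbance`` table.

    The cuvette path length comes either from a ``path_length_m`` column
    (constant over rows) or from the argument; the argument wins.
    """
    df = _read_frame(path, ["wavelength_nm", "absorbance"], sep)
    cols = ["wavelength_nm", "absorbance"]
    if "path_length_m" in df.columns:
        cols.append("path_length_m")
    df = _require_numeric(df, cols, path)
    if path_length_m is None:
        if "path_length_m" not in df.columns:
            raise FormatError(f"{path}: no path_length_m column and none supplied")
        path_length_m = float(df["path_length_m"].iloc[0])
    sid = sample_id if sample_id is not None else Path(path).stem
    return AbsorbanceSpectrum(
        sample_id=sid,
        wavelength_nm=df["wavelength_nm"].to_numpy(),
        absorbance=df["absorbance"].to_numpy(),
        path_length_m=path_length_m,
    )


def write_spectrum(spec: AbsorbanceSpectrum, path: str | Path, sep: str = ",") -> None:
    df = pd.DataFrame(
        {
            "wavelength_nm": spec.wavelength_nm,
            "absorbance": spec.absorbance,
            "path_length_m": spec.path_length_m,
        }
    )
    write_table(df, path, sep=sep)


def read_eem(path: str | Path, sample_id: str | None = None, sep: str = ",") -> EEM:
    """Read a long-format ``excitation_nm,emission_nm,intensity`` EEM."""
    df = _read_frame(path, ["excitation_nm", "emission_nm", "intensity"], sep)
    df = _require_numeric(df, ["excitation_nm", "emission_nm", "intensity"], path)
    ex = np.unique(df["excitation_nm"].to_numpy())
    em = np.unique(df["emission_nm"].to_numpy())
    mat = (
        df.pivot_table(index="excitation_nm", columns="emission_nm", values="intensity")
        .reindex(index=ex, columns=em)
        .to_numpy()
    )
    if np.any(np.isnan(mat)):
        raise FormatError(f"{path}: EEM long format does not cover the full grid")
    sid = sample_id if sample_id is not None else Path(path).stem
    return EEM(sample_id=sid, excitation_nm=ex, emission_nm=em, intensity=mat)


def write_eem(eem: EEM, path: str | Path, sep: str = ",") -> None:
    ex, em = np.meshgrid(eem.excitation_nm, eem.emission_nm, indexing="ij")
    df = pd.DataFrame(
        {
            "excitation_nm": ex.ravel(),
            "emission_nm": em.ravel(),
            "intensity": eem.intensity.ravel(),
        }
    )
    write_table(df, path, sep=sep)


_SAMPLE_COLS = [
    "lake_id",
    "treatment",
    "temperature_C",
    "replicate",
    "doc_mgC_L",
    "don_mg_L",
    "co2_d0",
    "co2_d7",
    "co2_d28",
    "is_blank",
]


def read_samples(path: str | Path, sep: str = ",") -> list[SampleRecord]:
    """Read the sample metadata table into validated :class:`SampleRecord` s."""
    df = _read_frame(path, ["lake_id", "treatment"], sep)
    records: list[SampleRecord] = []
    for row, rec in df.iterrows():
        co2: dict[int, float] = {}
        for day in (0, 7, 28):
            col = f"co2_d{day}"
            if col in df.columns and pd.notna(rec.get(col)):
                co2[day] = float(rec[col])
        try:
            records.append(
                SampleRecord(
                    lake_id=str(rec["lake_id"]),
                    treatment=str(rec["treatment"]),
                    temperature_C=float(rec.get("temperature_C", np.nan)),
                    replicate=int(rec.get("replicate", 1)),
                    doc_mgC_L=float(rec.get("doc_mgC_L", np.nan)),
                    don_mg_L=float(rec.get("don_mg_L", np.nan)),
                    co2_umol=co2,
                    is_blank=bool(rec.get("is_blank", False)),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {row}: {exc}") from exc
    return records


def write_samples(records: Iterable[SampleRecord], path: str | Path, sep: str = ",") -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "lake_id": r.lake_id,
                "treatment": r.treatment,
                "temperature_C": r.temperature_C,
                "replicate": r.replicate,
                "doc_mgC_L": r.doc_mgC_L,
                "don_mg_L": r.don_mg_L,
                "co2_d0": r.co2_umol.get(0, np.nan),
                "co2_d7": r.co2_umol.get(7, np.nan),
                "co2_d28": r.co2_umol.get(28, np.nan),
                "is_blank": r.is_blank,
            }
        )
    write_table(pd.DataFrame(rows, columns=_SAMPLE_COLS), path, sep=sep)


def write_table(records: pd.DataFrame | Mapping | Sequence, path: str | Path, sep: str = ",") -> None:
    """Write any tabular result as delimited text that round-trips losslessly.

    Floats are encoded with 12 significant digits so write->read reproduces
    every numeric field to full practical precision.  An empty frame still
    writes its header (schema-preserving).
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    df.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)
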