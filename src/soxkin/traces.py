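"""Kinetic-trace, absorbance and emission-spectrum containers plus text I/O.

All time axes are in microseconds (µs); every lifetime the package reports is
in µs as well.  Traces are photon-counting histograms: ``time`` holds bin
centers, ``counts`` the photons per bin.  Raw instrument traces carry integer
counts; processed traces (e.g. after off-band background subtraction) may
carry real-valued counts, but counts are always nonnegative.

File dialect (documented, stable):

* comma separator, ``.`` decimal;
* leading comment lines ``# key: value`` carry free-form metadata;
* a ``time_unit`` metadata key of ``ns`` or ``s`` triggers conversion to µs
  on read (the in-memory unit is always µs);
* trace columns ``time_us,counts``; absorbance columns
  ``wavelength_nm,absorbance``; spectrum columns ``wavelength_nm,intensity``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import TraceFormatError, ValidationError

__all__ = [
    "KineticTrace",
    "AbsorbanceRecord",
    "EmissionSpectrum",
    "read_trace",
    "write_trace",
    "read_absorbance",
    "read_spectrum",
    "write_spectrum",
]

_TIME_UNIT_TO_US = {"us": 1.0, "µs": 1.0, "ns": 1e-3, "s": 1e6, "ms": 1e3}


@dataclass
class KineticTrace:
    """One photon-counting decay for a single detection channel.

    Parameters
    ----------
    time : array
        Bin centers in µs, strictly increasing.
    counts : array
        Photons per bin, nonnegative.  Integer for raw data; real-valued
        allowed for processed traces.
    channel_nm : float, optional
        Detection wavelength (1270 nm on-band; 1250/1300 nm off-band).
    excitation_nm : float, optional
        Excitation wavelength.
    meta : dict
        Free-form string metadata (solvent, sample id, pulse energy, ...).
    """

    time: np.ndarray
    counts: np.ndarray
    channel_nm: float | None = None
    excitation_nm: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.dtype.kind not in "iuf":
            raise ValidationError("counts must be numeric")
        if self.time.ndim != 1 or self.counts.ndim != 1:
            raise ValidationError("time and counts must be 1-D arrays")
        if len(self.time) != len(self.counts):
            raise ValidationError(
                f"length mismatch: {len(self.time)} times vs {len(self.counts)} counts"
            )
        if len(self.time) == 0:
            raise ValidationError("empty trace")
        if not np.all(np.isfinite(self.time)) or not np.all(np.isfinite(self.counts)):
            raise ValidationError("non-finite values in trace")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValidationError("time must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be nonnegative")

    def __len__(self) -> int:
        return len(self.time)

    def __eq__(self, other) -> bool:
        if not isinstance(other, KineticTrace):
            return NotImplemented
        return (
            len(self) == len(other)
            and np.allclose(self.time, other.time, rtol=1e-9, atol=0.0)
            and np.array_equal(np.asarray(self.counts, float), np.asarray(other.counts, float))
            and self.channel_nm == other.channel_nm
            and self.excitation_nm == other.excitation_nm
            and self.meta == other.meta
        )

    @property
    def bin_width(self) -> float | None:
        """Uniform bin width in µs, or None for non-uniform binning."""
        if len(self.time) < 2:
            return None
        d = np.diff(self.time)
        if np.allclose(d, d[0], rtol=1e-9, atol=0.0):
            return float(d[0])
        return None

    @property
    def is_uniform(self) -> bool:
        return self.bin_width is not None

    def with_meta(self, **kv) -> "KineticTrace":
        meta = dict(self.meta)
        meta.update({k: str(v) for k, v in kv.items()})
        return replace(self, meta=meta)


@dataclass
class AbsorbanceRecord:
    """Decadic absorbance A(λ), optionally with the sample concentration."""

    wavelength_nm: float
    absorbance: float
    concentration_uM: float | None = None

    def __post_init__(self):
        if self.wavelength_nm <= 0:
            raise ValidationError("wavelength must be positive")
        if self.absorbance < 0:
            raise ValidationError("absorbance must be nonnegative")


@dataclass
class EmissionSpectrum:
    """NIR emission spectrum used for spectral validation of the 1270 nm band."""

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    atmosphere: str = "air"  # air | O2 | inert

    def __post_init__(self):
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.wavelength_nm) != len(self.intensity):
            raise ValidationError("wavelength/intensity length mismatch")
        if len(self.wavelength_nm) > 1 and not np.all(np.diff(self.wavelength_nm) > 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValidationError("intensities must be finite")
        if self.atmosphere not in ("air", "O2", "inert"):
            raise ValidationError(f"unknown atmosphere tag {self.atmosphere!r}")


# ---------------------------------------------------------------------------
# I/O


def _split_comments(text: str) -> tuple[dict, str]:
    meta: dict[str, str] = {}
    body_lines = []
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("#"):
            payload = stripped.lstrip("#").strip()
            if ":" in payload:
                key, _, value = payload.partition(":")
                meta[key.strip()] = value.strip()
        elif stripped:
            body_lines.append(line)
    return meta, "\n".join(body_lines)


def _read_two_columns(path, colnames: tuple[str, str], columns=None):
    try:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    except OSError as exc:
        raise TraceFormatError(f"cannot read {path}: {exc}") from exc
    meta, body = _split_comments(text)
    if not body.strip():
        raise TraceFormatError(f"{path}: no data rows")
    first = body.splitlines()[0]
    has_header = any(c.isalpha() for c in first.split(",")[0])
    try:
        df = pd.read_csv(io.StringIO(body), header=0 if has_header else None)
    except Exception as exc:
        raise TraceFormatError(f"{path}: cannot parse CSV body: {exc}") from exc
    if columns is not None:
        # column-mapping hook for foreign exports
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise TraceFormatError(f"{path}: mapped columns {missing} not found")
        df = df[list(columns)]
    if df.shape[1] < 2:
        raise TraceFormatError(f"{path}: expected two columns, found {df.shape[1]}")
    df = df.iloc[:, :2]
    df.columns = list(colnames)
    for c in colnames:
        if not np.issubdtype(np.asarray(df[c]).dtype, np.number):
            raise TraceFormatError(f"{path}: non-numeric values in column {c!r}")
    if df.isna().any().any():
        raise TraceFormatError(f"{path}: missing/non-numeric values")
    return meta, df


def read_trace(path, channel_nm: float | None = None, columns=None) -> KineticTrace:
    """Read a kinetic trace from a two-column CSV.

    ``columns`` optionally names the (time, counts) columns of a foreign
    export with a header row.  A ``time_unit`` metadata key of ``ns``/``s``
    converts the axis to µs.  Raises :class:`TraceFormatError` on
    non-monotonic time, negative counts or an empty body.
    """
    meta, df = _read_two_columns(path, ("time_us", "counts"), columns=columns)
    time = df["time_us"].to_numpy(dtype=float)
    counts = df["counts"].to_numpy()
    unit = meta.pop("time_unit", "us").lower()
    if unit not in _TIME_UNIT_TO_US:
        raise TraceFormatError(f"unknown time_unit {unit!r}")
    time = time * _TIME_UNIT_TO_US[unit]
    if np.all(counts == np.round(counts)):
        counts = counts.astype(np.int64)
    chan = channel_nm
    if chan is None and "channel_nm" in meta:
        chan = float(meta.pop("channel_nm"))
    elif "channel_nm" in meta:
        meta.pop("channel_nm")
    exc_nm = float(meta.pop("excitation_nm")) if "excitation_nm" in meta else None
    try:
        return KineticTrace(time, counts, channel_nm=chan, excitation_nm=exc_nm, meta=meta)
    except ValidationError as exc:
        raise TraceFormatError(f"{path}: {exc}") from exc


def write_trace(trace: KineticTrace, path) -> None:
    """Write a trace in the package CSV dialect; re-reading round-trips."""
    lines = []
    if trace.channel_nm is not None:
        lines.append(f"# channel_nm: {trace.channel_nm:g}")
    if trace.excitation_nm is not None:
        lines.append(f"# excitation_nm: {trace.excitation_nm:g}")
    for key, value in trace.meta.items():
        lines.append(f"# {key}: {value}")
    lines.append("time_us,counts")
    integral = trace.counts.dtype.kind in "iu" or np.all(
        trace.counts == np.round(trace.counts)
    )
    for t, c in zip(trace.time, trace.counts):
        cs = f"{int(round(c))}" if integral else repr(float(c))
        lines.append(f"{float(t)!r},{cs}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_absorbance(path) -> list[AbsorbanceRecord]:
    """Read wavelength_nm,absorbance[,concentration_uM] rows."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    except OSError as exc:
        raise TraceFormatError(f"cannot read {path}: {exc}") from exc
    _, body = _split_comments(text)
    if not body.strip():
        raise TraceFormatError(f"{path}: no data rows")
    first = body.splitlines()[0]
    has_header = any(c.isalpha() for c in first.split(",")[0])
    df = pd.read_csv(io.StringIO(body), header=0 if has_header else None)
    records = []
    for row in df.itertuples(index=False):
        vals = list(row)
        conc = float(vals[2]) if len(vals) > 2 and pd.notna(vals[2]) else None
        records.append(AbsorbanceRecord(float(vals[0]), float(vals[1]), conc))
    return records


def read_spectrum(path, atmosphere: str = "air") -> EmissionSpectrum:
    meta, df = _read_two_columns(path, ("wavelength_nm", "intensity"))
    atmos = meta.get("atmosphere", atmosphere)
    return EmissionSpectrum(
        df["wavelength_nm"].to_numpy(float), df["intensity"].to_numpy(float), atmos
    )


def write_spectrum(spectrum: EmissionSpectrum, path) -> None:
    lines = [f"# atmosphere: {spectrum.atmosphere}", "wavelength_nm,intensity"]
    for w, y in zip(spectrum.wavelength_nm, spectrum.intensity):
        lines.append(f"{float(w)!r},{float(y)!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
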