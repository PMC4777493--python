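"""Recording I/O and windowing primitives.

Overnight sleep recordings arrive as European Data Format (EDF/EDF+) files
holding three channels: nasal-cannula airflow, thoracic belt excursion and
pulse-oximetry SpO2. This module reads and writes those files, slices
analysis windows out of a channel, and performs the plain every-k-th-sample
decimation that defines the "f2" family of flow features.

Conventions
-----------
* Sample indexing is 0-based; windows are half-open ``[start, start+duration)``
  in seconds.
* Decimation keeps raw samples (no anti-alias filtering) and divides the
  sampling rate by ``k``.
* EDF and continuous EDF+ (``EDF+C``) are accepted; discontinuous ``EDF+D``
  files are rejected because the downstream analysis assumes contiguous time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Series",
    "SleepRecording",
    "read_recording",
    "write_recording",
    "extract_window",
    "decimate_keep_kth",
]

#: Default native sampling rates (Hz) per channel. Flow is specified by the
#: acquisition hardware; belt and oximeter rates are typical polysomnograph
#: values and can be overridden everywhere they are used.
DEFAULT_RATES = {"flow": 200.0, "thoracic": 10.0, "spo2": 1.0}


@dataclass(frozen=True)
class Series:
    """A uniformly sampled 1-D signal.

    Parameters
    ----------
    values : array-like of float
        Ordered samples in the channel's physical units.
    rate : float
        Sampling rate in Hz; must be positive.
    label : str
        Channel name.
    """

    values: np.ndarray
    rate: float
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("Series requires a non-empty 1-D sample array")
        if not (self.rate > 0):
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Length of the series in seconds (``n / rate``, exact)."""
        return self.values.size / self.rate


@dataclass(frozen=True)
class SleepRecording:
    """One subject-night: airflow, thoracic belt and SpO2 channels.

    All three channels must span the same time interval to within one sample
    period of the coarsest channel; SpO2 values are percent saturation in
    ``[0, 100]``.
    """

    flow: Series
    thoracic: Series
    spo2: Series
    start_offset: float = 0.0

    def __post_init__(self) -> None:
        durs = [self.flow.duration, self.thoracic.duration, self.spo2.duration]
        tol = max(1.0 / s.rate for s in (self.flow, self.thoracic, self.spo2))
        if max(durs) - min(durs) > tol:
            raise ValueError(
                f"channel durations differ by more than one sample period: {durs}"
            )
        s = self.spo2.values
        if s.min() < 0 or s.max() > 100:
            raise ValueError("SpO2 values must lie in [0, 100]")

    @property
    def total_duration(self) -> float:
        return self.flow.duration

    def channels(self) -> dict[str, Series]:
        return {"flow": self.flow, "thoracic": self.thoracic, "spo2": self.spo2}


# ---------------------------------------------------------------------------
# Windowing and decimation
# ---------------------------------------------------------------------------

def extract_window(s: Series, start: float, duration: float) -> Series:
    """Return the contiguous slice ``[start, start+duration)`` of a series.

    The slice begins at sample index ``floor(start * rate)`` and contains
    ``round(duration * rate)`` samples at the original rate.
    """
    if start < 0:
        raise ValueError(f"window start must be >= 0, got {start}")
    i0 = math.floor(start * s.rate)
    n = round(duration * s.rate)
    if i0 + n > len(s):
        raise ValueError(
            f"window [{start}, {start + duration}) s exceeds signal extent: "
            f"only {s.duration:g} s available"
        )
    return replace(s, values=s.values[i0 : i0 + n])


def decimate_keep_kth(s: Series, k: int) -> Series:
    """Keep every ``k``-th sample (indices 0, k, 2k, ...), rate divided by k.

    No anti-alias filter is applied: the operation is literal value-keeping,
    which is what defines the decimated ("f2") flow features.
    """
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise ValueError(f"decimation factor must be a positive integer, got {k!r}")
    return replace(s, values=s.values[::k], rate=s.rate / k)


# ---------------------------------------------------------------------------
# Minimal EDF / EDF+C layer (16-bit)
# ---------------------------------------------------------------------------
# EDF stores an ASCII header (256 bytes + 256 per signal) followed by fixed
# duration data records of little-endian int16 samples, one block per signal
# per record. Physical values are recovered by a per-signal affine map from
# the digital to the physical range.

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(field_val: str, width: int) -> bytes:
    b = field_val.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {field_val!r}")
    return b.ljust(width)


def _record_layout(rates: list[float], durations: list[float]) -> tuple[float, list[int]]:
    """Choose a record duration giving an integer sample count per record."""
    for rec_dur in (1.0, 2.0, 5.0, 10.0, 0.5, 0.1):
        spr = [r * rec_dur for r in rates]
        if all(abs(x - round(x)) < 1e-9 and round(x) >= 1 for x in spr):
            n_rec = durations[0] / rec_dur
            if abs(n_rec - round(n_rec)) < 1e-9:
                return rec_dur, [int(round(x)) for x in spr]
    raise ValueError(
        f"cannot lay out EDF records for rates {rates} and duration {durations[0]} s"
    )


def write_recording(rec: SleepRecording, path) -> str:
    """Write a recording as a 16-bit EDF file; returns the path written.

    Round-tripping through :func:`read_recording` preserves labels, rates and
    durations exactly and sample values to within one quantization step of
    the per-channel physical range.
    """
    series = [rec.flow, rec.thoracic, rec.spo2]
    rates = [s.rate for s in series]
    rec_dur, spr = _record_layout(rates, [s.duration for s in series])
    n_records = int(round(series[0].duration / rec_dur))

    def _fit8(v: float) -> str:
        # most precise representation that fits the 8-char header field
        for p in range(8, 0, -1):
            txt = f"{v:.{p}g}"
            if len(txt) <= 8:
                return txt
        return f"{v:.0e}"[:8]

    def _fit8_outward(v: float, direction: int) -> str:
        # 8-char representation at or beyond v in the given direction, so
        # the written physical range always covers the data; bounded search
        pad = max(abs(v), 1.0) * 1e-6
        for k in range(200):
            txt = _fit8(v + direction * k * pad)
            val = float(txt)
            if direction * (val - v) >= 0:
                return txt
        raise ValueError(f"cannot encode physical bound {v} in 8 characters")

    pmins, pmaxs, digital = [], [], []
    for s in series:
        lo, hi = float(s.values.min()), float(s.values.max())
        if hi <= lo:  # constant channel: give the map a nonzero span
            hi = lo + 1.0
        # digitize against the bounds as actually written in the 8-char
        # header fields, so the read-back affine map matches this one
        pmin = float(_fit8_outward(lo, -1))
        pmax = float(_fit8_outward(hi, +1))
        scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
        d = np.round((s.values - pmin) * scale + _DIG_MIN).astype("<i2")
        pmins.append(pmin)
        pmaxs.append(pmax)
        digital.append(d)

    ns = len(series)
    header_bytes = 256 + 256 * ns
    head = b"".join(
        [
            _ascii("0", 8),
            _ascii("X X X X", 80),
            _ascii("Startdate X X X X", 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(str(header_bytes), 8),
            _ascii("EDF+C", 44),
            _ascii(str(n_records), 8),
            _ascii(f"{rec_dur:g}", 8),
            _ascii(str(ns), 4),
        ]
    )

    def sig_field(vals, width):
        return b"".join(_ascii(v, width) for v in vals)

    labels = [s.label or name for s, name in zip(series, ("Flow", "Thorax", "SpO2"))]
    head += sig_field(labels, 16)
    head += sig_field([""] * ns, 80)  # transducer
    head += sig_field([""] * ns, 8)  # physical dimension
    head += sig_field([_fit8(p) for p in pmins], 8)
    head += sig_field([_fit8(p) for p in pmaxs], 8)
    head += sig_field([str(_DIG_MIN)] * ns, 8)
    head += sig_field([str(_DIG_MAX)] * ns, 8)
    head += sig_field([""] * ns, 80)  # prefiltering
    head += sig_field([str(n) for n in spr], 8)
    head += sig_field([""] * ns, 32)  # reserved

    with open(path, "wb") as fh:
        fh.write(head)
        for r in range(n_records):
            for d, n in zip(digital, spr):
                fh.write(d[r * n : (r + 1) * n].tobytes())
    return str(path)


def _read_edf(path) -> dict[str, Series]:
    with open(path, "rb") as fh:
        fixed = fh.read(256)
        if len(fixed) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        reserved = fixed[192:236].decode("ascii", errors="replace").strip()
        if reserved.startswith("EDF+D"):
            raise ValueError(
                f"{path}: discontinuous EDF+D recordings are not supported; "
                "the analysis assumes contiguous time"
            )
        n_records = int(fixed[236:244].decode())
        rec_dur = float(fixed[244:252].decode())
        ns = int(fixed[252:256].decode())

        def read_fields(width):
            raw = fh.read(width * ns)
            return [raw[i * width : (i + 1) * width].decode("ascii").strip() for i in range(ns)]

        labels = read_fields(16)
        read_fields(80)  # transducer
        read_fields(8)  # dimension
        pmin = [float(x) for x in read_fields(8)]
        pmax = [float(x) for x in read_fields(8)]
        dmin = [int(x) for x in read_fields(8)]
        dmax = [int(x) for x in read_fields(8)]
        read_fields(80)  # prefiltering
        spr = [int(x) for x in read_fields(8)]
        read_fields(32)  # reserved

        raw = np.frombuffer(fh.read(2 * sum(spr) * n_records), dtype="<i2")

    if raw.size != sum(spr) * n_records:
        raise ValueError(f"{path}: EDF data section shorter than header declares")

    out: dict[str, Series] = {}
    rec_len = sum(spr)
    offsets = np.cumsum([0] + spr)
    for i, label in enumerate(labels):
        blocks = raw.reshape(n_records, rec_len)[:, offsets[i] : offsets[i + 1]]
        scale = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        phys = (blocks.ravel().astype(np.float64) - dmin[i]) * scale + pmin[i]
        out[label] = Series(values=phys, rate=spr[i] / rec_dur, label=label)
    return out


def read_recording(path, channel_map: dict[str, str] | None = None) -> SleepRecording:
    """Read an EDF/EDF+C file into a :class:`SleepRecording`.

    Parameters
    ----------
    path : path-like
        EDF file to read.
    channel_map : dict, optional
        Maps the roles ``flow``/``thoracic``/``spo2`` to channel labels in
        the file. Defaults to ``{"flow": "Flow", "thoracic": "Thorax",
        "spo2": "SpO2"}``.
    """
    channel_map = channel_map or {"flow": "Flow", "thoracic": "Thorax", "spo2": "SpO2"}
    channels = _read_edf(path)
    picked = {}
    for role in ("flow", "thoracic", "spo2"):
        name = channel_map.get(role)
        if name is None:
            raise ValueError(f"channel_map must name the {role!r} channel")
        if name not in channels:
            raise KeyError(
                f"channel {name!r} (role {role!r}) not present in {path}; "
                f"available: {sorted(channels)}"
            )
        picked[role] = channels[name]
    return SleepRecording(flow=picked["flow"], thoracic=picked["thoracic"], spo2=picked["spo2"])
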