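"""Nonlinear respiratory-signal features.

Three estimators quantify the dynamics of overnight breathing signals:

* **Detrended fluctuation analysis (DFA)** — the scaling exponent alpha of
  the RMS fluctuation F(n) of the integrated, box-wise linearly detrended
  series versus box size n, on a log-log scale. alpha ~ 0.5 indicates an
  uncorrelated series, alpha ~ 1 long-range correlation. Two band slopes
  are reported: *fast* over boxes of 8-30 s (roughly 2-6 breaths) and
  *slow* over 30-100 s (6-24 breaths).
* **Approximate entropy ApEn(m, r, N)** — the negative mean log conditional
  probability that epochs similar for m points (within Chebyshev tolerance
  r) remain similar at the next point; low values mean regularity. The
  conventional parameters m = 2 and r = 0.2 x SD are the defaults.
* **Largest Lyapunov exponent (LLE)** — the mean exponential divergence
  rate of initially close trajectories in a delay-embedded phase space,
  estimated by the Rosenstein nearest-neighbor method: track the log
  distance between each point and its nearest (temporally separated)
  neighbor as both evolve, and fit a line to the initial rise of the mean
  log-divergence curve.

plus **T90**, the percentage of the night spent with SpO2 below 90%.

:func:`extract_features` applies these over the windowing scheme used for
overnight studies (analysis windows start one hour into the recording;
airflow is analyzed over 20 min, the belt signal over 240 min for DFA and
170 min for LLE; a 4x-decimated airflow copy over 80 min yields the "f2"
family) and assembles the derived difference/mean parameter set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial import cKDTree

from .signal_io import Series, decimate_keep_kth, extract_window

__all__ = [
    "DFAResult",
    "ApEnResult",
    "LLEResult",
    "FeatureVector",
    "dfa",
    "apen",
    "lle_rosenstein",
    "t90",
    "extract_features",
    "FEATURE_COLUMNS",
]


# ---------------------------------------------------------------------------
# Detrended fluctuation analysis
# ---------------------------------------------------------------------------

#: Band edges in seconds: fast = medium-to-fast scales, slow = slow-to-medium.
DFA_FAST_BAND = (8.0, 30.0)
DFA_SLOW_BAND = (30.0, 100.0)


@dataclass(frozen=True)
class DFAResult:
    box_seconds: np.ndarray  # box sizes in seconds, strictly increasing
    box_samples: np.ndarray  # the same boxes in samples
    fluctuations: np.ndarray  # F(n) per box
    alpha_fast: float  # slope of log F vs log n over the fast band
    alpha_slow: float  # slope over the slow band
    alpha_overall: float  # slope over all boxes
    degenerate: bool = False  # True when the series had zero variance

    def alpha(self, band: tuple[float, float]) -> float:
        """Slope of log F(n) vs log n restricted to ``band`` (seconds)."""
        return _band_slope(self.box_seconds, self.fluctuations, band)


def _band_slope(sec: np.ndarray, fl: np.ndarray, band: tuple[float, float]) -> float:
    sel = (sec >= band[0] - 1e-9) & (sec <= band[1] + 1e-9) & (fl > 0)
    if sel.sum() < 3:
        return float("nan")
    return float(np.polyfit(np.log(sec[sel]), np.log(fl[sel]), 1)[0])


def default_box_sizes(n_per_band: int = 7) -> np.ndarray:
    """Log-spaced box sizes (seconds) covering both bands, >= 6 per band."""
    fast = np.geomspace(*DFA_FAST_BAND, n_per_band)
    slow = np.geomspace(*DFA_SLOW_BAND, n_per_band)
    return np.unique(np.concatenate([fast, slow]))


def dfa(s: Series, box_sizes_seconds=None) -> DFAResult:
    """Detrended fluctuation analysis of a series.

    The series is mean-subtracted and integrated; the profile is split into
    non-overlapping boxes of n samples (trailing partial box discarded), a
    least-squares line is removed per box, and F(n) is the RMS of the
    residuals. Band slopes of log F vs log n give the scaling exponents.
    """
    x = s.values
    boxes_sec = np.asarray(
        default_box_sizes() if box_sizes_seconds is None else box_sizes_seconds, dtype=float
    )
    boxes_sec = np.unique(boxes_sec)
    box_n = np.unique(np.round(boxes_sec * s.rate).astype(int))
    box_n = box_n[box_n >= 4]
    if box_n.size == 0 or len(x) < 4 * box_n.max():
        raise ValueError(
            f"series too short for DFA: {len(x)} samples, "
            f"largest box {box_n.max() if box_n.size else '?'} samples needs 4x coverage"
        )

    y = np.cumsum(x - x.mean())
    fl = np.empty(box_n.size)
    for i, n in enumerate(box_n):
        cnt = len(y) // n
        segs = y[: cnt * n].reshape(cnt, n)
        t = np.arange(n, dtype=float)
        a = np.vstack([t, np.ones(n)]).T  # (n, 2)
        coef = segs @ np.linalg.pinv(a).T  # (cnt, 2)
        resid = segs - coef @ a.T
        fl[i] = math.sqrt(np.mean(resid**2))

    sec = box_n / s.rate
    degenerate = bool(np.all(fl <= 1e-300))
    return DFAResult(
        box_seconds=sec,
        box_samples=box_n,
        fluctuations=fl,
        alpha_fast=_band_slope(sec, fl, DFA_FAST_BAND),
        alpha_slow=_band_slope(sec, fl, DFA_SLOW_BAND),
        alpha_overall=_band_slope(sec, fl, (sec[0], sec[-1])),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Approximate entropy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ApEnResult:
    m: int
    r: float  # absolute tolerance used
    n_samples: int
    apen: float
    apen_high: float  # max of the first-difference sequence of sub-window ApEn
    apen_low: float  # min of that sequence
    subwindow_apen: np.ndarray = field(default_factory=lambda: np.empty(0))


def _phi(x: np.ndarray, mm: int, r: float) -> float:
    templates = sliding_window_view(x, mm)
    tree = cKDTree(templates)
    counts = tree.query_ball_point(templates, r, p=np.inf, return_length=True)
    return float(np.mean(np.log(counts / templates.shape[0])))


def _apen_value(x: np.ndarray, m: int, r: float) -> float:
    if len(x) < m + 2:
        raise ValueError(f"need at least {m + 2} samples for ApEn(m={m})")
    if r <= 0:  # zero spread: every epoch matches every other exactly
        return 0.0
    return _phi(x, m, r) - _phi(x, m + 1, r)


def apen(
    s: Series,
    m: int = 2,
    r_factor: float = 0.2,
    subwindow_seconds: float = 300.0,
) -> ApEnResult:
    """Approximate entropy with self-matches included (Pincus convention).

    ``r`` is ``r_factor`` times the SD of the whole series; the same r is
    used for the sub-window sequence. ``apen_high``/``apen_low`` are the
    max/min of the first differences of ApEn computed on successive
    non-overlapping sub-windows (default 5 min), a signed measure of how
    abruptly regularity changes across the night.
    """
    if r_factor <= 0:
        raise ValueError("r_factor must be positive")
    x = s.values
    if len(x) < 50:
        raise ValueError(f"need at least 50 samples, got {len(x)}")
    sd = float(np.std(x))
    r = r_factor * sd
    value = _apen_value(x, m, r) if sd > 0 else 0.0

    wlen = int(round(subwindow_seconds * s.rate))
    sub = []
    if wlen >= m + 2:
        for lo in range(0, len(x) - wlen + 1, wlen):
            w = x[lo : lo + wlen]
            sub.append(_apen_value(w, m, r) if sd > 0 else 0.0)
    sub = np.asarray(sub)
    if sub.size >= 2:
        diffs = np.diff(sub)
        high, low = float(diffs.max()), float(diffs.min())
    else:
        high = low = 0.0
    return ApEnResult(
        m=m, r=r, n_samples=len(x), apen=float(value),
        apen_high=high, apen_low=low, subwindow_apen=sub,
    )


# ---------------------------------------------------------------------------
# Largest Lyapunov exponent (Rosenstein method)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LLEResult:
    lyapunov: float  # per second (per iteration when rate = 1)
    divergence_curve: np.ndarray  # mean log separation vs step
    steps: np.ndarray  # elapsed steps for the curve
    embed_dim: int
    delay: int  # samples
    theiler_window: int
    fit_range: tuple[float, float]  # seconds
    rate: float


def _autocorr_zero_crossing(x: np.ndarray, max_lag: int) -> int:
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        return 1
    for lag in range(1, max_lag):
        c = float(x[:-lag] @ x[lag:]) / denom
        if c <= 0:
            return lag
    return max_lag


def _nearest_neighbors(emb: np.ndarray, theiler: int, eps: float) -> np.ndarray:
    """Index of the nearest neighbor of each point with temporal separation
    greater than the Theiler window and distance above the numerical noise
    floor ``eps`` (pairs closer than rounding error carry no dynamics)."""
    m = emb.shape[0]
    tree = cKDTree(emb)
    nn = np.full(m, -1, dtype=np.int64)
    unresolved = np.arange(m)
    k = min(m, 2 * theiler + 4)
    while unresolved.size:
        d, idx = tree.query(emb[unresolved], k=k)
        if k == 1:
            d, idx = d[:, None], idx[:, None]
        ok = (np.abs(idx - unresolved[:, None]) > theiler) & (d > eps)
        first = np.argmax(ok, axis=1)
        found = ok[np.arange(len(unresolved)), first]
        nn[unresolved[found]] = idx[np.arange(len(unresolved)), first][found]
        unresolved = unresolved[~found]
        if k >= m:
            break
        k = min(m, k * 4)
    if unresolved.size:
        raise ValueError(
            "no admissible nearest neighbors outside the Theiler window; "
            "the series may be constant or too short"
        )
    return nn


def lle_rosenstein(
    s: Series,
    embed_dim: int = 5,
    delay: int | None = None,
    theiler_window: int | None = None,
    fit_seconds: tuple[float, float] | None = None,
    max_steps: int | None = None,
) -> LLEResult:
    """Largest Lyapunov exponent by the Rosenstein nearest-neighbor method.

    The series is delay-embedded; each point is paired with its nearest
    neighbor at temporal separation beyond the Theiler window; the mean log
    distance between pairs after k steps forms the divergence curve, whose
    initial slope (least squares over ``fit_seconds``, or over the initial
    rise up to half the curve's total climb when not given) is the exponent
    in nats per step, converted to per-second units via the sampling rate.
    """
    x = s.values
    if np.ptp(x) == 0:
        raise ValueError("constant series has no phase-space structure")
    if delay is None:
        delay = _autocorr_zero_crossing(x, max_lag=max(2, len(x) // 4))
    if theiler_window is None:
        theiler_window = max(1, embed_dim * delay)

    m_pts = len(x) - (embed_dim - 1) * delay
    if m_pts < 100:
        raise ValueError(
            f"embedding leaves {m_pts} points; need >= 100 "
            f"(n={len(x)}, embed_dim={embed_dim}, delay={delay})"
        )
    emb = sliding_window_view(x, (embed_dim - 1) * delay + 1)[:, :: delay]
    eps = 1e-8 * float(np.std(x))
    nn = _nearest_neighbors(np.ascontiguousarray(emb), theiler_window, eps)

    if max_steps is None:
        if fit_seconds is not None:
            max_steps = max(3, int(math.ceil(fit_seconds[1] * s.rate)))
        else:
            max_steps = min(200, m_pts // 4)
    i_idx = np.arange(m_pts)
    curve, steps = [], []
    for k in range(max_steps + 1):
        valid = (i_idx + k < m_pts) & (nn + k < m_pts)
        if valid.sum() < 10:
            break
        diff = emb[i_idx[valid] + k] - emb[nn[valid] + k]
        d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        d = d[d > 0]
        if d.size < 10:
            break
        curve.append(float(np.mean(np.log(d))))
        steps.append(k)
    curve = np.asarray(curve)
    steps = np.asarray(steps)
    if curve.size < 3:
        raise ValueError("divergence curve too short to fit a slope")

    if fit_seconds is None:
        # initial linear region: steps before the curve climbs half of its
        # total rise above the starting value (at least 4 points)
        rise = curve.max() - curve[0]
        if rise <= 0:
            k_end = curve.size - 1
        else:
            above = np.nonzero(curve - curve[0] >= 0.5 * rise)[0]
            k_end = max(3, int(above[0])) if above.size else curve.size - 1
        k_start = 0
    else:
        k_start = int(math.floor(fit_seconds[0] * s.rate))
        k_end = int(math.ceil(fit_seconds[1] * s.rate))
    sel = (steps >= k_start) & (steps <= k_end)
    if sel.sum() < 2:
        raise ValueError("fit range contains fewer than 2 divergence-curve points")
    slope = float(np.polyfit(steps[sel], curve[sel], 1)[0])
    return LLEResult(
        lyapunov=slope * s.rate,
        divergence_curve=curve,
        steps=steps,
        embed_dim=embed_dim,
        delay=int(delay),
        theiler_window=int(theiler_window),
        fit_range=(steps[sel][0] / s.rate, steps[sel][-1] / s.rate),
        rate=s.rate,
    )


# ---------------------------------------------------------------------------
# T90
# ---------------------------------------------------------------------------

def t90(spo2: Series) -> float:
    """Percentage of samples with SpO2 strictly below 90%."""
    v = spo2.values
    if v.size == 0:
        raise ValueError("empty SpO2 series")
    if v.min() < 0 or v.max() > 100:
        raise ValueError("SpO2 values must lie in [0, 100]")
    return 100.0 * float(np.count_nonzero(v < 90.0)) / v.size


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureVector:
    """Per-subject feature set: nonlinear indices, derived difference/mean
    parameters, T90 and demographics.

    For every difference/mean pair derived from components (X, Y):
    d = X - Y and m = (X + Y)/2, so X = m + d/2 and Y = m - d/2 exactly.
    The ApEn-derived pair instead combines the signed sub-window extremes:
    dAPEN = high + low, mAPEN = (high + low)/2.
    """

    LLEf: float
    LLEt: float
    dLLE: float
    mLLE: float
    LLEf2: float
    dLLE2: float
    mLLE2: float
    DFAslow_f: float
    DFAfast_f: float
    dDFA_f: float
    mDFA_f: float
    DFAslow_f2: float
    DFAfast_f2: float
    dDFA_f2: float
    mDFA_f2: float
    DFAslow_t: float
    DFAfast_t: float
    dDFA_t: float
    mDFA_t: float
    dmDFA_t2: float
    mmDFA_t2: float
    APEN_low_f: float
    APEN_high_f: float
    dAPEN_f: float
    mAPEN_f: float
    APEN_low_t: float
    APEN_high_t: float
    dAPEN_t: float
    mAPEN_t: float
    T90: float
    age: float | None = None
    sex: str | None = None
    bmi: float | None = None
    epworth: float | None = None

    #: difference/mean pairs: d_name, m_name -> (X, Y) with d = X - Y
    DIFF_MEAN_PAIRS = {
        ("dDFA_f", "mDFA_f"): ("DFAfast_f", "DFAslow_f"),
        ("dDFA_f2", "mDFA_f2"): ("DFAfast_f2", "DFAslow_f2"),
        ("dDFA_t", "mDFA_t"): ("DFAfast_t", "DFAslow_t"),
        ("dLLE", "mLLE"): ("LLEf", "LLEt"),
        ("dLLE2", "mLLE2"): ("LLEf2", "LLEt"),
        ("dmDFA_t2", "mmDFA_t2"): ("mDFA_f2", "mDFA_t"),
    }

    def to_dict(self) -> dict:
        out = {col: getattr(self, attr) for col, attr in FEATURE_COLUMNS.items()}
        return out


#: CSV column name -> attribute name, following the conventional table layout
FEATURE_COLUMNS = {
    "LLEf": "LLEf", "LLEt": "LLEt", "dLLE": "dLLE", "mLLE": "mLLE",
    "LLEf2": "LLEf2", "dLLE2": "dLLE2", "mLLE2": "mLLE2",
    "DFA slow_f": "DFAslow_f", "DFA fast_f": "DFAfast_f",
    "dDFA_f": "dDFA_f", "mDFA_f": "mDFA_f",
    "DFA slow_f2": "DFAslow_f2", "DFA fast_f2": "DFAfast_f2",
    "dDFA_f2": "dDFA_f2", "mDFA_f2": "mDFA_f2",
    "DFA slow_t": "DFAslow_t", "DFA fast_t": "DFAfast_t",
    "dDFA_t": "dDFA_t", "mDFA_t": "mDFA_t",
    "APEN low_f": "APEN_low_f", "APEN high_f": "APEN_high_f",
    "dAPEN_f": "dAPEN_f", "mAPEN_f": "mAPEN_f",
    "APEN low_t": "APEN_low_t", "APEN high_t": "APEN_high_t",
    "dAPEN_t": "dAPEN_t", "mAPEN_t": "mAPEN_t",
    "dmDFAt2": "dmDFA_t2", "mmDFAt2": "mmDFA_t2",
    "T90": "T90",
    "AGE": "age", "SEX": "sex", "BMI": "bmi", "EPWORTH": "epworth",
}

#: Analysis window scheme (seconds). Windows start one hour into the study.
WINDOW_SCHEME = {
    "offset": 3600.0,
    "dfa_flow": 20 * 60.0,
    "dfa_flow2": 80 * 60.0,  # 4x-decimated airflow
    "dfa_thoracic": 240 * 60.0,
    "lle_flow": 20 * 60.0,
    "lle_flow2": 80 * 60.0,
    "lle_thoracic": 170 * 60.0,
}


def _resample_1hz(s: Series) -> Series:
    """Mean within each second; identity for a 1 Hz series."""
    spr = s.rate
    if abs(spr - round(spr)) > 1e-9:
        raise ValueError(f"1 Hz resampling requires an integer rate, got {spr}")
    spr = int(round(spr))
    if spr == 1:
        return s
    n_sec = len(s) // spr
    v = s.values[: n_sec * spr].reshape(n_sec, spr).mean(axis=1)
    return Series(values=v, rate=1.0, label=s.label)


def _window(s: Series, name: str, start: float, dur: float) -> Series:
    try:
        return extract_window(s, start, dur)
    except ValueError as exc:
        raise ValueError(f"cannot compute feature {name}: {exc}") from exc


def _dm(x: float, y: float) -> tuple[float, float]:
    return x - y, (x + y) / 2.0


def extract_features(
    rec,
    demographics: dict | None = None,
    *,
    dfa_diff_sign: int = 1,
    lle_embed_dim: int = 5,
    breath_period: float = 4.0,
    apen_subwindow_seconds: float = 300.0,
) -> FeatureVector:
    """Compute the full per-subject feature vector from one recording.

    ``dfa_diff_sign=+1`` defines dDFA = DFAfast - DFAslow (the default);
    ``-1`` flips the convention. LLE uses embedding dimension
    ``lle_embed_dim`` with the delay chosen at the first zero crossing of
    the autocorrelation and a Theiler window of one breath period.
    """
    off = WINDOW_SCHEME["offset"]
    demographics = demographics or {}

    f20 = _window(rec.flow, "DFA/LLE flow 20 min", off, WINDOW_SCHEME["dfa_flow"])
    flow_dec = decimate_keep_kth(rec.flow, 4)
    f2_80 = _window(flow_dec, "DFA/LLE decimated flow 80 min", off, WINDOW_SCHEME["dfa_flow2"])
    t240 = _window(rec.thoracic, "DFA thoracic 240 min", off, WINDOW_SCHEME["dfa_thoracic"])
    t170 = _window(rec.thoracic, "LLE thoracic 170 min", off, WINDOW_SCHEME["lle_thoracic"])

    dfa_f = dfa(f20)
    dfa_f2 = dfa(f2_80)
    dfa_t = dfa(t240)

    def _lle(series: Series, name: str) -> float:
        theiler = max(1, int(round(breath_period * series.rate)))
        try:
            return lle_rosenstein(series, embed_dim=lle_embed_dim, theiler_window=theiler).lyapunov
        except ValueError as exc:
            raise ValueError(f"cannot compute feature {name}: {exc}") from exc

    lle_f = _lle(f20, "LLEf")
    lle_f2 = _lle(f2_80, "LLEf2")
    lle_t = _lle(t170, "LLEt")

    ap_f = apen(_resample_1hz(rec.flow), subwindow_seconds=apen_subwindow_seconds)
    ap_t = apen(_resample_1hz(rec.thoracic), subwindow_seconds=apen_subwindow_seconds)

    sgn = 1 if dfa_diff_sign >= 0 else -1
    d_f, m_f = _dm(dfa_f.alpha_fast, dfa_f.alpha_slow)
    d_f2, m_f2 = _dm(dfa_f2.alpha_fast, dfa_f2.alpha_slow)
    d_t, m_t = _dm(dfa_t.alpha_fast, dfa_t.alpha_slow)
    d_lle, m_lle = _dm(lle_f, lle_t)
    d_lle2, m_lle2 = _dm(lle_f2, lle_t)
    d_mt2, m_mt2 = _dm(m_f2, m_t)

    return FeatureVector(
        LLEf=lle_f, LLEt=lle_t, dLLE=d_lle, mLLE=m_lle,
        LLEf2=lle_f2, dLLE2=d_lle2, mLLE2=m_lle2,
        DFAslow_f=dfa_f.alpha_slow, DFAfast_f=dfa_f.alpha_fast,
        dDFA_f=sgn * d_f, mDFA_f=m_f,
        DFAslow_f2=dfa_f2.alpha_slow, DFAfast_f2=dfa_f2.alpha_fast,
        dDFA_f2=sgn * d_f2, mDFA_f2=m_f2,
        DFAslow_t=dfa_t.alpha_slow, DFAfast_t=dfa_t.alpha_fast,
        dDFA_t=sgn * d_t, mDFA_t=m_t,
        dmDFA_t2=d_mt2, mmDFA_t2=m_mt2,
        APEN_low_f=ap_f.apen_low, APEN_high_f=ap_f.apen_high,
        dAPEN_f=ap_f.apen_high + ap_f.apen_low,
        mAPEN_f=(ap_f.apen_high + ap_f.apen_low) / 2.0,
        APEN_low_t=ap_t.apen_low, APEN_high_t=ap_t.apen_high,
        dAPEN_t=ap_t.apen_high + ap_t.apen_low,
        mAPEN_t=(ap_t.apen_high + ap_t.apen_low) / 2.0,
        T90=t90(rec.spo2),
        age=demographics.get("age"),
        sex=demographics.get("sex"),
        bmi=demographics.get("bmi"),
        epworth=demographics.get("epworth"),
    )
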