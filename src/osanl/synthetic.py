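"""Synthetic overnight recordings and reference series.

Two kinds of simulated data back the analysis pipeline:

* **Overnight recordings** with a controlled true apnea-hypopnea index (AHI)
  and a ground-truth event list, so that feature extraction, the AHI
  regression and the severity classifiers can be exercised and validated
  end-to-end without patient data. The generator emulates quasi-periodic
  breathing (~4 s breaths) in the airflow and thoracic channels, apneas
  (airflow collapse with persisting paradoxical belt excursion) and
  hypopneas (partial airflow reduction), SpO2 desaturation ramps that lag
  event onset, measurement noise, and a severity-dependent slow amplitude
  modulation that induces longer-range correlation structure in more
  severe subjects.
* **Reference series** with known nonlinear properties (fractional Gaussian
  noise with prescribed Hurst exponent, the logistic map, the Lorenz-x
  coordinate, sinusoids, white noise) used to validate the DFA, ApEn and
  Lyapunov estimators against analytic ground truth.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .signal_io import Series, SleepRecording

__all__ = [
    "SyntheticSpec",
    "Event",
    "EventList",
    "generate_recording",
    "spo2_with_target_t90",
    "generate_reference_series",
    "generate_cohort",
    "CohortSubject",
]

#: Channel rates used for simulation-scale cohorts (Hz). Full acquisition
#: rates (200/10/1) remain the defaults for real recordings in signal_io;
#: the estimators are rate-aware, so reduced rates keep simulated cohorts
#: tractable without changing any algorithm.
SIMULATION_RATES = {"flow": 8.0, "thoracic": 2.0, "spo2": 1.0}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one simulated subject-night."""

    duration: float = 6 * 3600.0  # seconds
    true_ahi: float = 0.0  # events per hour
    apnea_fraction: float = 0.6  # proportion of events that are apneas
    breath_period: float = 4.0  # seconds per breath
    event_duration_mean: float = 25.0  # seconds
    event_duration_sd: float = 5.0
    desat_depth_mean: float = 10.0  # % SpO2 drop per event
    desat_depth_sd: float = 3.0
    noise_sd: float = 0.05  # relative to breathing amplitude
    seed: int = 0
    flow_rate: float = SIMULATION_RATES["flow"]
    thoracic_rate: float = SIMULATION_RATES["thoracic"]
    spo2_rate: float = SIMULATION_RATES["spo2"]

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.breath_period <= 0:
            raise ValueError("duration and breath_period must be positive")
        if self.true_ahi < 0:
            raise ValueError("true_ahi must be >= 0")
        if not 0 <= self.apnea_fraction <= 1:
            raise ValueError("apnea_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class Event:
    start: float  # seconds from recording start
    duration: float  # seconds
    kind: str  # "apnea" | "hypopnea"

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class EventList:
    """Ground-truth respiratory events, non-overlapping and sorted."""

    events: tuple[Event, ...]
    total_duration: float  # seconds of recording

    def __post_init__(self) -> None:
        ev = tuple(self.events)
        for a, b in zip(ev, ev[1:]):
            if b.start < a.end:
                raise ValueError("events must be sorted and non-overlapping")
        object.__setattr__(self, "events", ev)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def ahi(self) -> float:
        return len(self.events) / (self.total_duration / 3600.0)

    @property
    def ai(self) -> float:
        n = sum(1 for e in self.events if e.kind == "apnea")
        return n / (self.total_duration / 3600.0)

    @property
    def hi(self) -> float:
        n = sum(1 for e in self.events if e.kind == "hypopnea")
        return n / (self.total_duration / 3600.0)


# ---------------------------------------------------------------------------
# Event placement
# ---------------------------------------------------------------------------

def _place_events(spec: SyntheticSpec, rng: np.random.Generator) -> EventList:
    n = int(round(spec.true_ahi * spec.duration / 3600.0))
    if n == 0:
        return EventList(events=(), total_duration=spec.duration)

    durations = np.clip(
        rng.normal(spec.event_duration_mean, spec.event_duration_sd, size=n), 10.0, 90.0
    )
    kinds = np.where(rng.random(n) < spec.apnea_fraction, "apnea", "hypopnea")

    gap = spec.breath_period  # minimum inter-event gap: one breath
    margin = 120.0  # event-free head/tail so windows see stable breathing
    leftover = spec.duration - 2 * margin - durations.sum() - gap * (n + 1)
    if leftover < 0:
        raise ValueError(
            f"cannot place {n} events of mean duration "
            f"{spec.event_duration_mean:g} s without overlap in "
            f"{spec.duration:g} s"
        )
    # Dirichlet spacings; a smaller concentration makes inter-event gaps
    # burstier, so severe subjects get the clustered event trains that carry
    # long-range correlation into the respiratory envelope.
    conc = 1.0 / (1.0 + spec.true_ahi / 30.0)
    w = rng.dirichlet(np.full(n + 1, conc))
    extra = leftover * w
    starts = np.empty(n)
    t = margin + extra[0] + gap
    for i in range(n):
        starts[i] = t
        t += durations[i] + gap + extra[i + 1]
    events = tuple(
        Event(start=float(s), duration=float(d), kind=str(k))
        for s, d, k in zip(starts, durations, kinds)
    )
    return EventList(events=events, total_duration=spec.duration)


# ---------------------------------------------------------------------------
# Channel synthesis
# ---------------------------------------------------------------------------

def _smooth_gate(t: np.ndarray, ev: Event, floor: float, edge: float = 1.5) -> np.ndarray:
    """Multiplicative envelope dipping to ``floor`` over the event, with
    raised-cosine edges of width ``edge`` seconds."""
    g = np.ones_like(t)
    rise = np.clip((t - ev.start) / edge, 0.0, 1.0)
    fall = np.clip((ev.end - t) / edge, 0.0, 1.0)
    depth = 0.5 * (1 - np.cos(np.pi * np.minimum(rise, fall)))
    inside = (t > ev.start) & (t < ev.end)
    g[inside] = 1.0 - (1.0 - floor) * depth[inside]
    return g


def _slow_modulation(t: np.ndarray, depth: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth random amplitude modulation (30 s knots, linear interpolation)."""
    if depth <= 0:
        return np.ones_like(t)
    knots_t = np.arange(0.0, t[-1] + 60.0, 30.0)
    knots = rng.standard_normal(knots_t.size)
    # 3-point moving average smooths the knot sequence
    k = np.convolve(knots, np.ones(3) / 3.0, mode="same")
    return 1.0 + depth * np.interp(t, knots_t, k)


def _breathing_channel(
    spec: SyntheticSpec,
    rate: float,
    events: EventList,
    rng: np.random.Generator,
    amplitude: float,
    phase: float,
    apnea_floor: float,
    hypopnea_floor_range: tuple[float, float],
    label: str,
) -> Series:
    n = int(round(spec.duration * rate))
    t = np.arange(n) / rate
    x = amplitude * np.sin(2 * np.pi * t / spec.breath_period + phase)
    mod_depth = min(0.5, 0.006 * spec.true_ahi)
    x = x * _slow_modulation(t, mod_depth, rng)
    for ev in events.events:
        if ev.kind == "apnea":
            floor = apnea_floor
        else:
            floor = rng.uniform(*hypopnea_floor_range)
        x *= _smooth_gate(t, ev, floor)
    if spec.noise_sd > 0:
        x = x + rng.normal(0.0, spec.noise_sd * amplitude, size=n)
    return Series(values=x, rate=rate, label=label)


def _spo2_channel(spec: SyntheticSpec, events: EventList, rng: np.random.Generator) -> Series:
    rate = spec.spo2_rate
    n = int(round(spec.duration * rate))
    t = np.arange(n) / rate
    base = 96.0
    x = np.full(n, base)
    lag, tau = 10.0, 15.0  # onset lag and recovery time constant, seconds
    for ev in events.events:
        depth = float(np.clip(rng.normal(spec.desat_depth_mean, spec.desat_depth_sd), 2.0, 30.0))
        nadir_t = ev.end + 5.0
        prof = np.full(n, base)
        ramp = (t >= ev.start + lag) & (t <= nadir_t)
        span = max(nadir_t - (ev.start + lag), 1.0)
        prof[ramp] = base - depth * (t[ramp] - (ev.start + lag)) / span
        rec = t > nadir_t
        prof[rec] = base - depth * np.exp(-(t[rec] - nadir_t) / tau)
        np.minimum(x, prof, out=x)
    if spec.noise_sd > 0:
        x = x + rng.normal(0.0, 2.0 * spec.noise_sd, size=n)
    return Series(values=np.clip(x, 0.0, 100.0), rate=rate, label="SpO2")


def generate_recording(spec: SyntheticSpec) -> tuple[SleepRecording, EventList]:
    """Simulate one subject-night.

    Returns the three-channel recording and the ground-truth event list.
    Identical specs (including seed) produce bitwise-identical output; with
    ``true_ahi=0`` and ``noise_sd=0`` the airflow channel is exactly periodic.
    """
    rng = np.random.default_rng(spec.seed)
    events = _place_events(spec, rng)
    flow = _breathing_channel(
        spec, spec.flow_rate, events, rng,
        amplitude=1.0, phase=0.0, apnea_floor=0.05,
        hypopnea_floor_range=(0.3, 0.7), label="Flow",
    )
    thoracic = _breathing_channel(
        spec, spec.thoracic_rate, events, rng,
        amplitude=0.8, phase=0.3, apnea_floor=0.6,
        hypopnea_floor_range=(0.65, 0.85), label="Thorax",
    )
    spo2 = _spo2_channel(spec, events, rng)
    return SleepRecording(flow=flow, thoracic=thoracic, spo2=spo2), events


def spo2_with_target_t90(spec: SyntheticSpec, target_t90: float) -> Series:
    """Generate an SpO2 series whose fraction of time below 90% saturation
    matches ``target_t90`` (percent) to within one percentage point.

    Desaturated time is laid out in contiguous ~60 s blocks at a seeded
    random set of positions; the block count is chosen so the below-90
    sample count is exact up to rounding.
    """
    if not 0 <= target_t90 <= 100:
        raise ValueError(f"target_t90 must lie in [0, 100], got {target_t90}")
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.spo2_rate))
    k = int(round(target_t90 / 100.0 * n))  # samples below 90

    block = max(1, int(round(60.0 * spec.spo2_rate)))
    n_blocks = math.ceil(n / block)
    starts = np.arange(n_blocks) * block
    order = rng.permutation(n_blocks)
    below = np.zeros(n, dtype=bool)
    remaining = k
    for b in order:
        if remaining <= 0:
            break
        lo = starts[b]
        hi = min(lo + block, n)
        take = min(remaining, hi - lo)
        below[lo : lo + take] = True
        remaining -= take

    x = np.where(below, rng.uniform(84.0, 89.5, size=n), rng.uniform(93.0, 97.0, size=n))
    return Series(values=x, rate=spec.spo2_rate, label="SpO2")


# ---------------------------------------------------------------------------
# Reference series with known nonlinear properties
# ---------------------------------------------------------------------------

def _fgn_davies_harte(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Exact synthesis of fractional Gaussian noise by circulant embedding.

    The autocovariance gamma(k) = 0.5(|k+1|^2H - 2|k|^2H + |k-1|^2H) is
    embedded in a circulant of size 2n whose eigenvalues are nonnegative for
    fGn, giving a draw with exactly the target covariance.
    """
    k = np.arange(n + 1, dtype=np.float64)
    g = 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst) + np.abs(k - 1) ** (2 * hurst))
    row = np.concatenate([g, g[-2:0:-1]])  # length 2n
    lam = np.fft.fft(row).real
    lam = np.clip(lam, 0.0, None)  # guard tiny negative round-off
    m = 2 * n
    w = np.zeros(m, dtype=np.complex128)
    w[0] = math.sqrt(lam[0] / m) * rng.standard_normal()
    w[n] = math.sqrt(lam[n] / m) * rng.standard_normal()
    a = rng.standard_normal(n - 1)
    b = rng.standard_normal(n - 1)
    w[1:n] = np.sqrt(lam[1:n] / (2 * m)) * (a + 1j * b)
    w[n + 1 :] = np.conj(w[1:n][::-1])
    return np.fft.fft(w).real[:n]


def generate_reference_series(
    kind: str,
    n: int,
    seed: int = 0,
    *,
    hurst: float = 0.5,
    r: float = 4.0,
    period: float = 100.0,
    rate: float = 1.0,
) -> Series:
    """Deterministic reference signals for estimator validation.

    Parameters
    ----------
    kind : {"constant", "sine", "white_noise", "fgn", "logistic_map", "lorenz_x"}
        ``fgn`` takes ``hurst`` (0 < H < 1); ``logistic_map`` takes ``r`` in
        (3.57, 4]; ``sine`` takes ``period`` in samples.
    n : int
        Number of samples, at least 64.
    """
    if n < 64:
        raise ValueError(f"n must be >= 64, got {n}")
    rng = np.random.default_rng(seed)
    if kind == "constant":
        v = np.full(n, 1.0)
    elif kind == "sine":
        v = np.sin(2 * np.pi * np.arange(n) / period)
    elif kind == "white_noise":
        v = rng.standard_normal(n)
    elif kind == "fgn":
        if not 0 < hurst < 1:
            raise ValueError(f"Hurst exponent must lie in (0, 1), got {hurst}")
        v = _fgn_davies_harte(n, hurst, rng)
    elif kind == "logistic_map":
        if not 3.57 < r <= 4.0:
            raise ValueError(f"logistic r must lie in (3.57, 4], got {r}")
        v = np.empty(n)
        x = rng.uniform(0.05, 0.95)
        for _ in range(100):  # transient
            x = r * x * (1 - x)
        for i in range(n):
            x = r * x * (1 - x)
            v[i] = x
    elif kind == "lorenz_x":
        y0 = np.array([1.0, 1.0, 1.0]) + 0.01 * rng.standard_normal(3)
        dt = 0.02
        t_eval = 10.0 + dt * np.arange(n)  # discard a 10 s transient

        def lorenz(_t, s):
            x, y, z = s
            return [10.0 * (y - x), x * (28.0 - z) - y, x * y - 8.0 / 3.0 * z]

        sol = solve_ivp(lorenz, (0.0, t_eval[-1]), y0, t_eval=t_eval, rtol=1e-9, atol=1e-9)
        v = sol.y[0]
        rate = 1.0 / dt
    else:
        raise ValueError(f"unknown reference series kind {kind!r}")
    return Series(values=v, rate=rate, label=kind)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortSubject:
    """One simulated subject: demographics plus the generated night."""

    id: str
    age: float
    sex: str
    bmi: float
    epworth: int
    ahi_true: float
    ai: float
    hi: float
    recording: SleepRecording | None
    events: EventList | None


def _default_ahi_distribution(n: int, rng: np.random.Generator) -> np.ndarray:
    """Severity mixture emulating a sleep-clinic referral population:
    24% normal, 15% mild, 18% moderate, 43% severe."""
    cat = rng.choice(4, size=n, p=[0.24, 0.15, 0.18, 0.43])
    ahi = np.empty(n)
    ahi[cat == 0] = rng.uniform(0.0, 5.0, size=(cat == 0).sum())
    ahi[cat == 1] = rng.uniform(5.0, 15.0, size=(cat == 1).sum())
    ahi[cat == 2] = rng.uniform(15.0, 30.0, size=(cat == 2).sum())
    # severe tail capped at 110/h: with ~25 s events plus a one-breath gap,
    # higher rates cannot be placed without overlap in a 6 h night
    ahi[cat == 3] = np.clip(30.0 + rng.exponential(25.0, size=(cat == 3).sum()), 30.0, 110.0)
    return ahi


def generate_cohort(
    n_subjects: int,
    ahi_distribution=None,
    seed: int = 0,
    *,
    duration: float = 6 * 3600.0,
    with_recordings: bool = True,
    target_r_bmi: float = 0.58,
    target_r_epworth: float = 0.47,
    noise_sd: float = 0.05,
) -> list[CohortSubject]:
    """Simulate a referral cohort with AHI-coupled demographics.

    BMI and Epworth score are generated from the standardized AHI through a
    Gaussian-copula-style linear coupling targeting the stated population
    correlations (defaults 0.58 and 0.47). ``ahi_distribution`` may be a
    callable ``(n, rng) -> array`` of true AHI values; the default mixture
    mimics a sleep-clinic referral population.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    draw = ahi_distribution or _default_ahi_distribution
    ahi = np.asarray(draw(n_subjects, rng), dtype=np.float64)
    if ahi.min() < 0:
        raise ValueError("ahi_distribution produced negative AHI")

    sd = ahi.std()
    z = (ahi - ahi.mean()) / sd if sd > 0 else np.zeros_like(ahi)
    bmi = 31.94 + 6.89 * (
        target_r_bmi * z + math.sqrt(1 - target_r_bmi**2) * rng.standard_normal(n_subjects)
    )
    bmi = np.clip(bmi, 17.0, 53.0)
    epw = 7.8 + 5.1 * (
        target_r_epworth * z
        + math.sqrt(1 - target_r_epworth**2) * rng.standard_normal(n_subjects)
    )
    epw = np.clip(np.round(epw), 0, 24).astype(int)
    age = np.clip(rng.normal(48.4, 13.6, size=n_subjects), 16.0, 83.0)
    sex = np.where(rng.random(n_subjects) < 0.74, "M", "F")
    apnea_frac = rng.uniform(0.5, 0.8, size=n_subjects)

    subjects: list[CohortSubject] = []
    for i in range(n_subjects):
        spec = SyntheticSpec(
            duration=duration,
            true_ahi=float(ahi[i]),
            apnea_fraction=float(apnea_frac[i]),
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        if with_recordings:
            recording, events = generate_recording(spec)
            realized_ahi = events.ahi
            ai, hi = events.ai, events.hi
        else:
            recording, events = None, None
            realized_ahi = float(ahi[i])
            ai = realized_ahi * float(apnea_frac[i])
            hi = realized_ahi - ai
        subjects.append(
            CohortSubject(
                id=f"S{i + 1:03d}",
                age=float(age[i]),
                sex=str(sex[i]),
                bmi=float(bmi[i]),
                epworth=int(epw[i]),
                ahi_true=float(realized_ahi),
                ai=float(ai),
                hi=float(hi),
                recording=recording,
                events=events,
            )
        )
    return subjects
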