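"""Synthetic fixational eye-movement traces with ground truth.

Emulates 15 s point-fixation recordings at 1 kHz as the additive
superposition of four components:

* a microsaccade train — Poisson arrivals of small fast events
  (amplitudes around 12 arcmin = 0.2 deg) with a smooth bell-shaped
  speed profile; a fraction are "double" (out-and-back) events whose
  endpoints nearly coincide;
* drift — band-limited noise with power in 0-40 Hz, rescaled to a
  target mean speed (~4 arcmin/s);
* tremor — band-limited noise in 70-103 Hz at a small target RMS;
* i.i.d. Gaussian sensor noise.

Each simulated person has a profile of generation parameters drawn
from configurable ranges, so different persons have genuinely
different microsaccade feature distributions while repeated fixations
of one person are exchangeable.  Every trace carries the ground-truth
event intervals (0-based, half-open) for detector validation.

All randomness is driven by explicit integer seeds; identical seeds
reproduce bit-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np

from .core import GazeTrace, MsaccidError, ParameterError


class GenerationError(MsaccidError, RuntimeError):
    """The requested trace could not be generated (e.g. rate too high)."""


class ProtocolError(MsaccidError, ValueError):
    """Cohort request violates the study protocol (too few persons/fixations)."""


@dataclass
class SimConfig:
    """Uniform sampling ranges (min, max) for person-profile fields.

    Units: msacc_rate events/s; amp_mean, amp_sd degrees; peak_vel_scale
    deg/s; double_fraction probability; drift_speed arcmin/s; tremor_rms
    and noise_sd degrees.
    """

    msacc_rate: tuple = (1.0, 2.0)
    amp_mean: tuple = (0.15, 0.25)       # centered on 12 arcmin = 0.2 deg
    amp_sd: tuple = (0.02, 0.06)
    peak_vel_scale: tuple = (25.0, 60.0)
    double_fraction: tuple = (0.0, 0.3)
    drift_speed: tuple = (2.0, 6.0)      # mean ~4 arcmin/s
    tremor_rms: tuple = (0.002, 0.006)
    noise_sd: tuple = (0.0005, 0.002)

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            lo, hi = getattr(self, f.name)
            if not lo < hi:
                raise ParameterError(f"SimConfig.{f.name}: need min < max")
            if f.name != "double_fraction" and lo <= 0:
                raise ParameterError(f"SimConfig.{f.name}: scales must be > 0")
            if f.name == "double_fraction" and not (0 <= lo and hi <= 1):
                raise ParameterError("double_fraction range must be in [0, 1]")


@dataclass
class PersonProfile:
    """Generation parameters for one simulated person."""

    person_id: str
    msacc_rate: float
    amp_mean: float
    amp_sd: float
    peak_vel_scale: float
    double_fraction: float
    drift_speed: float
    tremor_rms: float
    noise_sd: float
    seed: int = 0


@dataclass
class LabeledTrace:
    """A synthetic trace plus the ground-truth event intervals.

    ``truth_intervals`` are (start, end) index pairs, 0-based and
    half-open, sorted and non-overlapping.
    """

    trace: GazeTrace
    truth_intervals: list
    profile: PersonProfile

    def __post_init__(self) -> None:
        n = len(self.trace)
        prev_end = 0
        for s, e in self.truth_intervals:
            if not (0 <= s < e <= n) or s < prev_end:
                raise ParameterError("truth intervals must be sorted, "
                                     "non-overlapping and within bounds")
            prev_end = e


@dataclass
class CohortPerson:
    """One simulated person: profile plus one labeled trace per fixation."""

    profile: PersonProfile
    traces: list = field(default_factory=list)

    @property
    def person_id(self) -> str:
        return self.profile.person_id


_PROFILE_FIELDS = (
    "msacc_rate", "amp_mean", "amp_sd", "peak_vel_scale",
    "double_fraction", "drift_speed", "tremor_rms", "noise_sd",
)


def make_person_profile(
    seed: int, config: SimConfig | None = None, person_id: str | None = None
) -> PersonProfile:
    """Draw a profile uniformly from the config ranges; deterministic per seed."""
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    values = {
        name: float(rng.uniform(*getattr(config, name)))
        for name in _PROFILE_FIELDS
    }
    return PersonProfile(
        person_id=person_id if person_id is not None else f"P{seed}",
        seed=seed,
        **values,
    )


def make_separated_profiles(
    n: int, seed: int, config: SimConfig | None = None
) -> list:
    """Profiles spread evenly across the config ranges.

    Each field takes the grid values min + (k + 1/2)/n * (max - min)
    with an independent seeded permutation per field (a latin-hypercube
    layout), so any two persons differ in every generation parameter.
    Used where the study calls for clearly distinct persons.
    """
    if n < 1:
        raise ProtocolError("need at least one person")
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    grid = (np.arange(n) + 0.5) / n
    columns = {}
    for name in _PROFILE_FIELDS:
        lo, hi = getattr(config, name)
        columns[name] = lo + rng.permutation(grid) * (hi - lo)
    out = []
    for p in range(n):
        out.append(
            PersonProfile(
                person_id=f"P{p + 1}",
                seed=int(rng.integers(0, 2**31 - 1)),
                **{name: float(columns[name][p]) for name in _PROFILE_FIELDS},
            )
        )
    return out


def synth_microsaccade(
    profile: PersonProfile,
    rng: np.random.Generator,
    direction: float | None = None,
    amplitude: float | None = None,
    duration_ms: int | None = None,
    fs: float = 1000.0,
) -> np.ndarray:
    """One event as an (n, 2) point array starting at the origin.

    The speed along a straight path follows a Gaussian bell
    (sigma = duration/6), giving a single realistic velocity peak.
    Amplitude ~ Normal(amp_mean, amp_sd) truncated positive; duration
    follows from the profile's peak-velocity scale.  With probability
    ``double_fraction`` a mirrored return stroke is appended and the
    endpoint offset is kept below half the mono/double threshold, so
    the event classifies as double.
    """
    if direction is None:
        direction = float(rng.uniform(0.0, 2.0 * np.pi))
    if amplitude is None:
        amplitude = -1.0
        for _ in range(100):
            amplitude = float(rng.normal(profile.amp_mean, profile.amp_sd))
            if amplitude > 0.02:
                break
        if amplitude <= 0:
            amplitude = profile.amp_mean
    if amplitude == 0.0:
        n = (duration_ms or 20) + 1
        return np.zeros((n, 2))
    if duration_ms is None:
        # peak speed of the Gaussian profile ~ 2.39 * A / T
        t_s = 2.394 * amplitude / profile.peak_vel_scale
        duration_ms = int(np.clip(round(t_s * 1000.0), 8, 80))
    n_steps = max(int(round(duration_ms * fs / 1000.0)), 2)

    def stroke(amp: float, ang: float, steps: int) -> np.ndarray:
        t = np.arange(steps) + 0.5
        sigma = steps / 6.0
        prof = np.exp(-0.5 * ((t - steps / 2.0) / sigma) ** 2)
        prof *= amp / prof.sum()
        return np.outer(prof, [np.cos(ang), np.sin(ang)])

    steps = stroke(amplitude, direction, n_steps)
    is_double = rng.uniform() < profile.double_fraction
    if is_double:
        total_ms = 2 * n_steps * 1000.0 / fs
        offset = float(rng.uniform(0.0, 0.4)) * 0.01 * total_ms  # < half threshold
        back = stroke(amplitude - offset, direction + np.pi, n_steps)
        steps = np.vstack([steps, back])
    pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return pts


def _bandlimited_noise(
    n: int, fs: float, lo_hz: float, hi_hz: float, rng: np.random.Generator
) -> np.ndarray:
    """(n, 2) white noise restricted to [lo_hz, hi_hz] (DC excluded)."""
    out = np.empty((n, 2))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= lo_hz) & (freqs <= hi_hz) & (freqs > 0)
    for ax in range(2):
        spec = np.fft.rfft(rng.standard_normal(n))
        spec[~mask] = 0.0
        out[:, ax] = np.fft.irfft(spec, n)
    return out


def synth_fixation_trace(
    profile: PersonProfile,
    duration_s: float = 15.0,
    fs: float = 1000.0,
    seed: int | None = None,
) -> LabeledTrace:
    """One labeled fixation trace (default 15 s at 1 kHz).

    The four components (event train, drift, tremor, sensor noise) are
    generated independently and summed.  Event arrivals follow a
    Poisson process at the profile rate; events that would overlap are
    re-drawn, and a rate too high to place is an error.
    """
    if duration_s <= 0:
        raise ParameterError("duration_s must be positive")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(profile.seed if seed is None else seed)

    # --- microsaccade train -------------------------------------------------
    margin = int(0.010 * fs)  # >= 10 ms between events
    if profile.msacc_rate * 0.1 > 0.9:
        raise GenerationError(
            f"microsaccade rate {profile.msacc_rate}/s too high to place "
            "non-overlapping events"
        )
    events = []  # (start_idx, points)
    t = 0.0
    while True:
        t += rng.exponential(1.0 / profile.msacc_rate)
        start = int(round(t * fs))
        if start >= n:
            break
        pts = synth_microsaccade(profile, rng, fs=fs)
        end = start + pts.shape[0]
        if events and start < events[-1][0] + len(events[-1][1]) + margin:
            continue  # too close to the previous event: drop this arrival
        if end > n:
            break
        events.append((start, pts))

    train = np.zeros((n, 2))
    truth = []
    for start, pts in events:
        end = start + pts.shape[0]
        disp = pts - pts[0]
        train[start:end] += disp
        train[end:] += disp[-1]  # gaze stays where the event left it
        truth.append((start, end))

    # --- drift, tremor, sensor noise ---------------------------------------
    drift = _bandlimited_noise(n, fs, 0.0, 40.0, rng)
    speed = np.mean(np.linalg.norm(np.diff(drift, axis=0), axis=1))
    target = profile.drift_speed / 60.0 / fs  # arcmin/s -> deg/sample
    if speed > 0:
        drift *= target / speed

    tremor = _bandlimited_noise(n, fs, 70.0, 103.0, rng)
    rms = np.sqrt(np.mean(np.sum(tremor**2, axis=1)))
    if rms > 0:
        tremor *= profile.tremor_rms / rms

    noise = rng.normal(0.0, profile.noise_sd, (n, 2))

    xy = train + drift + tremor + noise
    trace = GazeTrace(
        x=xy[:, 0], y=xy[:, 1], rate_hz=fs,
        meta={"person_id": profile.person_id},
    )
    return LabeledTrace(trace=trace, truth_intervals=truth, profile=profile)


def synth_cohort(
    n_persons: int,
    n_fixations: int,
    seed: int,
    config: SimConfig | None = None,
    duration_s: float = 15.0,
    fs: float = 1000.0,
    separated: bool = True,
) -> list:
    """Simulate a cohort: ``n_persons`` profiles x ``n_fixations`` traces.

    With ``separated=True`` (default) profiles are spread across the
    config ranges (clearly distinct persons, the identification study
    condition); otherwise each profile is an independent uniform draw.
    Deterministic per seed.
    """
    if n_persons < 2 or n_fixations < 2:
        raise ProtocolError("need at least 2 persons and 2 fixations each")
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    if separated:
        profiles = make_separated_profiles(n_persons, seed, config)
    else:
        profiles = [
            make_person_profile(int(rng.integers(0, 2**31 - 1)), config,
                                person_id=f"P{p + 1}")
            for p in range(n_persons)
        ]
    cohort = []
    for prof in profiles:
        person = CohortPerson(profile=prof)
        for j in range(n_fixations):
            trace_seed = int(
                np.random.default_rng([prof.seed, j]).integers(0, 2**31 - 1)
            )
            lt = synth_fixation_trace(prof, duration_s=duration_s, fs=fs,
                                      seed=trace_seed)
            lt.trace.meta["fixation_id"] = f"F{j + 1}"
            person.traces.append(lt)
        cohort.append(person)
    return cohort
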