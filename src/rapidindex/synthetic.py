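"""Seeded generator of stable and deteriorating paediatric vital-sign sessions.

No real monitoring data ships with this package, so studies of the index
run on synthetic sessions that emulate the salient structure of wireless
ward monitoring: per-minute cadence, age-dependent baselines, circadian
rhythm, cross-channel coupling through a latent "stress" factor (heart
and respiratory rate rise while oxygen saturation falls), per-sensor
dropout, out-of-range artifact, and deterioration trajectories in which
the latent stress ramps from a therapy-escalation onset to a significant
event.  The generator is deterministic given its seed and records exactly
which minutes it corrupted, so the validity filter can be checked against
ground truth.

These are structural surrogates: no claim of clinical fidelity is made
for any particular child.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .vitals import CHANNELS, SENSOR_CHANNELS, DeteriorationEvent, MonitoringSession

#: (max_age_months, {channel: baseline mean}) — coarse paediatric bands
AGE_BANDS = [
    (3, {"hr": 140.0, "rr": 45.0, "spo2": 98.0, "pr": 140.0}),
    (12, {"hr": 130.0, "rr": 35.0, "spo2": 98.0, "pr": 130.0}),
    (36, {"hr": 115.0, "rr": 28.0, "spo2": 98.0, "pr": 115.0}),
    (72, {"hr": 100.0, "rr": 24.0, "spo2": 98.0, "pr": 100.0}),
    (144, {"hr": 90.0, "rr": 20.0, "spo2": 98.0, "pr": 90.0}),
    (10**9, {"hr": 75.0, "rr": 16.0, "spo2": 98.0, "pr": 75.0}),
]

DEFAULT_SD = {"hr": 8.0, "rr": 4.0, "spo2": 1.5, "pr": 8.0}
DEFAULT_CIRCADIAN = {"hr": 5.0, "rr": 2.0, "spo2": 0.5, "pr": 5.0}

#: per-unit-latent-stress loading (HR/RR up, SpO2 down)
STRESS_LOADING = {"hr": 6.0, "rr": 3.0, "spo2": -1.5, "pr": 6.0}

#: pre-artifact physiologic clip range per channel
PHYSIOLOGIC_RANGE = {
    "hr": (30.0, 250.0),
    "rr": (8.0, 150.0),
    "spo2": (60.0, 100.0),
    "pr": (30.0, 250.0),
}

#: out-of-range replacement values used for injected artifact (strictly
#: outside the default validity bounds, which are exclusive-as-printed)
ARTIFACT_VALUES = {"hr": (5.0, 350.0), "rr": (2.0, 250.0), "spo2": (10.0, 10.0), "pr": (5.0, 350.0)}

#: sensor capture fractions observed for the wireless devices: chest ECG
#: captured ~93% of intended time, wrist oximeter ~55%
DEFAULT_DROPOUT = {"chest_ecg": 0.07, "pulse_ox": 0.45}

#: fraction of *captured* sensor-minutes replaced by technical noise,
#: calibrated so valid data is ~63% (chest) / ~50% (oximeter) of intended
DEFAULT_ARTIFACT = {"chest_ecg": 0.32, "pulse_ox": 0.09}

CIRCADIAN_PERIOD_MIN = 1440.0
STRESS_PHI = 0.95
CHANNEL_PHI = 0.9

#: mean burst lengths (minutes) of the two-state loss processes: sensors
#: detach and recover in stretches, they do not flicker minute-to-minute
DROPOUT_BURST_MIN = 10.0
ARTIFACT_BURST_MIN = 8.0


def _burst_mask(rng: np.random.Generator, n: int, p: float, mean_burst: float) -> np.ndarray:
    """Stationary two-state Markov indicator with P(on) = p.

    Alternates geometric off/on runs; the on-run mean is ``mean_burst``
    so the marginal on-fraction converges to ``p`` while preserving the
    bursty temporal structure of wireless data loss.
    """
    if p <= 0:
        return np.zeros(n, dtype=bool)
    if p >= 1:
        return np.ones(n, dtype=bool)
    exit_on = 1.0 / mean_burst
    exit_off = min(exit_on * p / (1.0 - p), 1.0)
    mask = np.empty(n, dtype=bool)
    state = rng.random() < p
    pos = 0
    while pos < n:
        run = rng.geometric(exit_on if state else exit_off)
        mask[pos : pos + run] = state
        pos += run
        state = not state
    return mask


def age_baseline(age_months: float) -> dict[str, float]:
    """Default per-channel baseline means for a patient age."""
    for limit, base in AGE_BANDS:
        if age_months < limit:
            return dict(base)
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class DeteriorationSpec:
    """Latent-stress ramp from therapy-escalation onset to a significant event.

    From ``onset_minute`` the latent stress mean rises linearly to
    ``stress_at_event`` at ``event_minute``; optional explicit per-channel
    drifts (units/min) are added on top.
    """

    onset_minute: int
    event_minute: int
    stress_at_event: float = 6.0
    drift_per_min: dict[str, float] = field(default_factory=dict)
    event_type: str = "unplanned_picu"

    def __post_init__(self) -> None:
        if not self.onset_minute < self.event_minute:
            raise ValueError("onset_minute must be < event_minute")


@dataclass(frozen=True)
class SyntheticScenario:
    """Full description of one synthetic monitoring session."""

    patient_age_months: float = 27.0
    duration_minutes: int = 2880
    baseline: dict[str, float] | None = None
    baseline_sd: dict[str, float] | None = None
    circadian_amplitude: dict[str, float] | None = None
    deterioration: DeteriorationSpec | None = None
    dropout_rate: dict[str, float] | None = None
    artifact_rate: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for rates in (self.dropout_rate, self.artifact_rate):
            if rates:
                for k, v in rates.items():
                    if not 0 <= v <= 1:
                        raise ValueError(f"rate {k}={v} outside [0, 1]")
        d = self.deterioration
        if d is not None and d.event_minute > self.duration_minutes:
            raise ValueError("event_minute beyond session duration")

    def resolved(self) -> dict:
        base = self.baseline or age_baseline(self.patient_age_months)
        return {
            "baseline": base,
            "sd": self.baseline_sd or dict(DEFAULT_SD),
            "circadian": self.circadian_amplitude or dict(DEFAULT_CIRCADIAN),
            "dropout": dict(DEFAULT_DROPOUT) | (self.dropout_rate or {}),
            "artifact": dict(DEFAULT_ARTIFACT) | (self.artifact_rate or {}),
        }


@dataclass(frozen=True)
class GeneratedSession:
    """A generated session plus its ground truth."""

    session: MonitoringSession
    event: DeteriorationEvent | None
    #: sensor -> number of captured minutes corrupted with out-of-range values
    artifact_minutes: dict[str, int]
    #: latent stress trace (one value per minute) driving all channels
    stress: np.ndarray | None = None


def _ar1(rng: np.random.Generator, n: int, phi: float, stat_sd: float) -> np.ndarray:
    """Stationary AR(1) path with the given autocorrelation and sd."""
    from scipy.signal import lfilter

    innov = rng.normal(0.0, stat_sd * np.sqrt(1.0 - phi**2), size=n)
    x0 = rng.normal(0.0, stat_sd)
    out, _ = lfilter([1.0], [1.0, -phi], innov, zi=np.array([phi * x0]))
    return out


def _latent_stress(rng: np.random.Generator, n: int, det: DeteriorationSpec | None) -> np.ndarray:
    s = _ar1(rng, n, STRESS_PHI, 1.0)
    if det is not None:
        t = np.arange(n)
        ramp = np.clip(
            (t - det.onset_minute) / (det.event_minute - det.onset_minute), 0.0, None
        )
        s = s + det.stress_at_event * ramp
    return s


def generate_session(scenario: SyntheticScenario, session_id: str = "synthetic") -> GeneratedSession:
    """Simulate one session; deterministic given ``scenario.seed``.

    Stable dynamics are per-channel AR(1) fluctuations around an
    age-dependent baseline with a sinusoidal circadian term, coupled
    across channels by a shared latent stress factor.  Deterioration
    ramps the stress mean linearly from onset to event.  Dropout then
    removes whole sensor-minutes and artifact replaces a fraction of the
    surviving sensor-minutes with out-of-range values.
    """
    p = scenario.resolved()
    n = scenario.duration_minutes
    rng = np.random.default_rng(scenario.seed)
    det = scenario.deterioration

    stress = _latent_stress(rng, n, det)
    t = np.arange(n)
    phase = rng.uniform(0, CIRCADIAN_PERIOD_MIN)
    values = {}
    for ch in CHANNELS:
        # AR(1) channel noise with stationary sd = configured sd
        noise = _ar1(rng, n, CHANNEL_PHI, p["sd"][ch])
        x = (
            p["baseline"][ch]
            + p["circadian"][ch] * np.sin(2 * np.pi * (t + phase) / CIRCADIAN_PERIOD_MIN)
            + STRESS_LOADING[ch] * stress
            + noise
        )
        if det is not None and ch in det.drift_per_min:
            x = x + det.drift_per_min[ch] * np.clip(t - det.onset_minute, 0, None)
        lo, hi = PHYSIOLOGIC_RANGE[ch]
        values[ch] = np.clip(x, lo, hi)

    frame = pd.DataFrame(values, index=pd.RangeIndex(n))

    artifact_minutes: dict[str, int] = {}
    for sensor, chans in SENSOR_CHANNELS.items():
        dropped = _burst_mask(rng, n, p["dropout"][sensor], DROPOUT_BURST_MIN)
        frame.loc[dropped, list(chans)] = np.nan
        captured = ~dropped
        corrupt = captured & _burst_mask(rng, n, p["artifact"][sensor], ARTIFACT_BURST_MIN)
        for ch in chans:
            lo_v, hi_v = ARTIFACT_VALUES[ch]
            pick_hi = rng.random(n) < 0.5
            frame.loc[corrupt & pick_hi, ch] = hi_v
            frame.loc[corrupt & ~pick_hi, ch] = lo_v
        artifact_minutes[sensor] = int(corrupt.sum())

    event = None
    if det is not None:
        event = DeteriorationEvent(
            session_id=session_id,
            onset_minute=det.onset_minute,
            event_minute=det.event_minute,
            event_type=det.event_type,
        )
    session = MonitoringSession(
        session_id=session_id,
        patient_age_months=scenario.patient_age_months,
        intended_start=0,
        intended_end=n,
        frame=frame,
        annotations=[event] if event else [],
    )
    return GeneratedSession(
        session=session, event=event, artifact_minutes=artifact_minutes, stress=stress
    )


def nurse_observations(gen: GeneratedSession, every_minutes: int = 60, seed: int = 0):
    """Derive intermittent 7-parameter nurse observations from a session.

    Observations are taken on a fixed cadence (hourly by default — the
    lower end of the one-to-four-hour bedside schedule).  HR, RR and
    SpO2 come from the session's own channels (falling back to the
    age baseline when the minute is missing); systolic blood pressure,
    capillary refill, respiratory distress and inspired oxygen are not
    wirelessly monitored, so they are synthesised from the same latent
    stress trace that drives the vital signs.
    """
    from .pews import PewsObservation

    session = gen.session
    rng = np.random.default_rng(seed)
    base = age_baseline(session.patient_age_months)
    sbp_base = 90.0 + min(session.patient_age_months, 144) / 144 * 25.0
    stress = gen.stress if gen.stress is not None else np.zeros(session.intended_minutes)
    obs = []
    for t in range(0, session.intended_minutes, every_minutes):
        s = float(stress[t])
        row = session.frame.loc[t] if t in session.frame.index else None

        def channel(ch):
            # a nurse reads the patient, not the telemetry: skip dropped
            # minutes and injected wireless artifact
            lo, hi = PHYSIOLOGIC_RANGE[ch]
            if row is not None and not np.isnan(row[ch]) and lo <= row[ch] <= hi:
                return float(row[ch])
            return base[ch] + STRESS_LOADING[ch] * s

        obs.append(
            PewsObservation(
                timestamp=t,
                respiratory_rate=channel("rr"),
                heart_rate=channel("hr"),
                spo2=min(channel("spo2"), 100.0),
                systolic_bp=sbp_base - 4.0 * s + rng.normal(0, 3),
                capillary_refill_seconds=max(1.0, 1.5 + 0.45 * s + rng.normal(0, 0.2)),
                respiratory_distress=int(np.clip(round(s / 2.0 + rng.normal(0, 0.3)), 0, 3)),
                inspired_oxygen=float(np.clip(0.21 + 0.07 * max(s, 0.0), 0.21, 1.0)),
            )
        )
    return obs


def generate_cohort(
    n_stable: int,
    n_deteriorating: int,
    seed: int,
    *,
    duration_minutes: int | None = None,
    onset_gap_median_minutes: int | None = None,
    dropout_rate: dict[str, float] | None = None,
    artifact_rate: dict[str, float] | None = None,
    full: bool = False,
) -> tuple[list[MonitoringSession], pd.DataFrame]:
    """Generate a case-control cohort of monitoring sessions.

    Deteriorating (case) sessions carry a :class:`DeteriorationEvent`
    whose event sits near the session end and whose onset precedes it by
    a lognormal gap (median ~47 h at study scale, scaled down for short
    sessions).  Stable (control) sessions carry no event.  Ages are drawn
    lognormally around a median of 27 months.  Returns the session list
    (cases first) and an event table ``session_id, onset_minute,
    event_minute, event_type``.
    """
    if n_stable < 0 or n_deteriorating < 0 or n_stable + n_deteriorating < 1:
        raise ValueError("cohort must contain at least one session")
    rng = np.random.default_rng(seed)
    generated: list[GeneratedSession] = []
    rows = []
    event_types = list(DeteriorationEvent._TYPES)

    def _age() -> float:
        return float(np.exp(rng.normal(np.log(27.0), 1.1)))

    for i in range(n_deteriorating):
        dur = duration_minutes if duration_minutes is not None else int(rng.uniform(2400, 5400))
        gap_med = (
            onset_gap_median_minutes
            if onset_gap_median_minutes is not None
            else 47 * 60
        )
        gap = int(np.exp(rng.normal(np.log(gap_med), 0.4)))
        event_minute = dur - max(10, dur // 50)
        # guarantee a pre-onset baseline period: the pre/post contrast is
        # undefined for a session monitored only after deterioration began
        onset = max(dur // 6, event_minute - gap)
        det = DeteriorationSpec(
            onset_minute=onset,
            event_minute=event_minute,
            event_type=event_types[rng.integers(len(event_types))],
        )
        scen = SyntheticScenario(
            patient_age_months=_age(),
            duration_minutes=dur,
            deterioration=det,
            dropout_rate=dropout_rate,
            artifact_rate=artifact_rate,
            seed=int(rng.integers(2**31)),
        )
        gen = generate_session(scen, session_id=f"case-{i:03d}")
        generated.append(gen)
        rows.append(
            {
                "session_id": gen.event.session_id,
                "onset_minute": gen.event.onset_minute,
                "event_minute": gen.event.event_minute,
                "event_type": gen.event.event_type,
            }
        )

    for i in range(n_stable):
        dur = duration_minutes if duration_minutes is not None else int(rng.uniform(1800, 4200))
        scen = SyntheticScenario(
            patient_age_months=_age(),
            duration_minutes=dur,
            dropout_rate=dropout_rate,
            artifact_rate=artifact_rate,
            seed=int(rng.integers(2**31)),
        )
        generated.append(generate_session(scen, session_id=f"control-{i:03d}"))

    events = pd.DataFrame(rows, columns=["session_id", "onset_minute", "event_minute", "event_type"])
    if full:
        return generated, events
    return [g.session for g in generated], events
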