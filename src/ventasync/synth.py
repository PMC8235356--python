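"""Synthetic pressure-control ventilation waveforms with labeled asynchronies.

Breath cycles are generated from a single-compartment model of respiratory
mechanics,

    P_aw(t) + P_mus(t) = R * Q(t) + V(t) / C + PEEP,

integrated by explicit Euler at 50 Hz.  ``P_aw`` is the airway pressure
applied by the ventilator (pressure-control: an exponential rise to
PEEP + driving pressure held for the inspiratory time, then release),
``P_mus`` the patient's inspiratory muscle pressure, ``Q`` flow and ``V``
lung volume above functional residual capacity.

Three cycle morphologies are produced:

* ``normal`` — passive breath, no patient effort.
* ``IEE`` (ineffective inspiratory effort during expiration) — a
  sub-threshold effort during expiration producing a transient flow
  deflection toward positive and a concave dip in airway pressure,
  without triggering a new breath.
* ``DT`` (double triggering) — patient effort outlasting the set
  inspiratory time retriggers the ventilator within a short window after
  cycle-off, so the second breath starts before exhalation completes
  (breath stacking: nonzero starting volume).  A DT event is two
  consecutive cycles, both labeled DT.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

SAMPLE_RATE = 50.0
DT_STEP = 1.0 / SAMPLE_RATE

LABEL_DT = "DT"
LABEL_IEE = "IEE"
LABEL_OTHER = "OTHER"
LABELS = (LABEL_DT, LABEL_IEE, LABEL_OTHER)


@dataclass(frozen=True)
class VentilatorSettings:
    """Pressure-control ventilator settings.

    Units: pressures in cmH2O, times in seconds, flow in L/s.
    """

    peep: float = 5.0
    driving_pressure: float = 15.0
    resp_rate: float = 15.0          # breaths/min
    insp_time: float = 1.0
    rise_time_constant: float = 0.1
    trigger_threshold: float = 0.05  # inspiratory-direction flow (L/s)
    sample_rate: float = SAMPLE_RATE
    # respiratory mechanics of the simulated patient
    resistance: float = 10.0         # cmH2O*s/L
    compliance: float = 0.05         # L/cmH2O

    def __post_init__(self) -> None:
        for name in ("peep", "driving_pressure", "resp_rate", "insp_time",
                     "rise_time_constant", "trigger_threshold",
                     "resistance", "compliance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.insp_time >= 60.0 / self.resp_rate:
            raise ValueError("insp_time must be shorter than the cycle period")
        if self.sample_rate != SAMPLE_RATE:
            raise ValueError("sample_rate is fixed at 50 Hz")

    @property
    def cycle_time(self) -> float:
        return 60.0 / self.resp_rate

    @property
    def exp_time(self) -> float:
        return self.cycle_time - self.insp_time


@dataclass(frozen=True)
class PatientEffort:
    """A single inspiratory muscle effort (half-sine Pmus profile)."""

    onset_time: float   # s from cycle start
    duration: float     # s
    magnitude: float    # peak muscle pressure, cmH2O

    def __post_init__(self) -> None:
        if self.onset_time < 0:
            raise ValueError("onset_time must be >= 0")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    def pmus(self, t: np.ndarray) -> np.ndarray:
        """Muscle pressure at times ``t`` (vectorized)."""
        phase = (t - self.onset_time) / self.duration
        out = np.zeros_like(t)
        active = (phase >= 0) & (phase <= 1)
        out[active] = self.magnitude * np.sin(np.pi * phase[active])
        return out


@dataclass
class BreathCycle:
    """One breath: time-aligned pressure/flow/volume arrays at 50 Hz."""

    t: np.ndarray
    pressure: np.ndarray
    flow: np.ndarray
    volume: np.ndarray
    label: str
    cycle_id: int = 0

    def __post_init__(self) -> None:
        n = len(self.t)
        if n < 2:
            raise ValueError("cycle needs at least 2 samples")
        if not (len(self.pressure) == len(self.flow) == len(self.volume) == n):
            raise ValueError("pressure/flow/volume/t lengths differ")
        steps = np.diff(self.t)
        if np.any(steps <= 0) or np.max(np.abs(steps - DT_STEP)) > 1e-9:
            raise ValueError("t must increase uniformly at 1/50 s")
        if self.volume[0] < -1e-12:
            raise ValueError("volume[0] must be >= 0")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class WaveformRecord:
    """An ordered sequence of breath cycles plus DT-event bookkeeping."""

    cycles: list
    dt_events: list = field(default_factory=list)
    seed: int = 0
    settings: VentilatorSettings = field(default_factory=VentilatorSettings)

    def __post_init__(self) -> None:
        ids = [c.cycle_id for c in self.cycles]
        if ids != list(range(len(ids))):
            raise ValueError("cycle_ids must be unique and contiguous from 0")
        by_id = {c.cycle_id: c for c in self.cycles}
        for a, b in self.dt_events:
            if b != a + 1:
                raise ValueError("DT event must pair consecutive cycles")
            if by_id[a].label != LABEL_DT or by_id[b].label != LABEL_DT:
                raise ValueError("DT event cycles must both be labeled DT")

    def labels(self) -> list:
        return [c.label for c in self.cycles]

    def __len__(self) -> int:
        return len(self.cycles)


def flow_to_volume(flow: np.ndarray, dt: float, v0: float = 0.0) -> np.ndarray:
    """Volume by cumulative trapezoidal integration of flow.

    Starts at ``v0`` (0 by default); a nonzero ``v0`` represents incomplete
    exhalation carried into the breath, as in breath stacking.
    """
    flow = np.asarray(flow, dtype=float)
    if flow.ndim != 1 or flow.size < 2:
        raise ValueError("flow must be a 1-D array of length >= 2")
    if dt <= 0:
        raise ValueError("dt must be positive")
    incr = 0.5 * (flow[1:] + flow[:-1]) * dt
    return v0 + np.concatenate([[0.0], np.cumsum(incr)])


def _pressure_waveform(t: np.ndarray, settings: VentilatorSettings,
                       insp_end: float) -> np.ndarray:
    """Ventilator-applied airway pressure: exponential rise, fast release."""
    tau = settings.rise_time_constant
    p = np.full_like(t, settings.peep)
    insp = t < insp_end
    p[insp] += settings.driving_pressure * (1.0 - np.exp(-t[insp] / tau))
    exp_mask = ~insp
    # release of the held pressure with a short decay constant
    p_at_end = settings.driving_pressure * (1.0 - np.exp(-insp_end / tau))
    p[exp_mask] += p_at_end * np.exp(-(t[exp_mask] - insp_end) / 0.04)
    return p


def _integrate(t: np.ndarray, p_aw: np.ndarray, pmus: np.ndarray,
               settings: VentilatorSettings, v0: float) -> tuple:
    """Euler integration of the single-compartment equation of motion."""
    r, c, peep = settings.resistance, settings.compliance, settings.peep
    n = len(t)
    flow = np.empty(n)
    v = v0
    for i in range(n):
        q = (p_aw[i] + pmus[i] - peep - v / c) / r
        flow[i] = q
        v = v + q * DT_STEP
    # report volume as the trapezoidal integral of the reported flow, so the
    # volume/flow identity holds exactly on the emitted arrays
    vol = flow_to_volume(flow, DT_STEP, v0=v0)
    return flow, vol


def _time_grid(duration: float, t0: float = 0.0) -> np.ndarray:
    n = max(2, int(round(duration * SAMPLE_RATE)))
    return t0 + np.arange(n) * DT_STEP


def simulate_cycle(kind: str, settings: VentilatorSettings | None = None,
                   effort: PatientEffort | None = None,
                   seed: int = 0) -> list:
    """Simulate one breath (normal/IEE) or a stacked DT pair.

    Returns a list of :class:`BreathCycle`: one cycle for ``normal`` and
    ``IEE``, exactly two consecutive cycles (both labeled DT) for ``DT``.
    For ``IEE`` the effort must start during expiration — an effort during
    inspiration would be a different asynchrony type and raises.
    """
    settings = settings or VentilatorSettings()
    rng = np.random.default_rng(seed)

    if kind == "normal":
        t = _time_grid(settings.cycle_time)
        p_aw = _pressure_waveform(t, settings, settings.insp_time)
        flow, vol = _integrate(t, p_aw, np.zeros_like(t), settings, 0.0)
        return [BreathCycle(t, p_aw, flow, vol, LABEL_OTHER)]

    if kind == "IEE":
        if effort is None:
            effort = PatientEffort(
                onset_time=settings.insp_time + 0.5 * settings.exp_time,
                duration=0.5, magnitude=3.0)
        if effort.onset_time <= settings.insp_time:
            raise ValueError(
                "IEE effort must begin during expiration; an inspiratory "
                "effort is a different asynchrony type")
        t = _time_grid(settings.cycle_time)
        p_aw = _pressure_waveform(t, settings, settings.insp_time)
        pmus = effort.pmus(t)
        # measured airway pressure dips concavely under a sub-threshold effort
        p_meas = p_aw - 0.4 * pmus
        flow, vol = _integrate(t, p_meas, pmus, settings, 0.0)
        return [BreathCycle(t, p_meas, flow, vol, LABEL_IEE)]

    if kind == "DT":
        # sustained effort past cycle-off; retrigger within 0.3 s
        retrig_delay = float(rng.uniform(0.1, 0.3))
        if effort is None:
            effort = PatientEffort(onset_time=0.2,
                                   duration=settings.insp_time + retrig_delay + 0.6,
                                   magnitude=6.0)
        t1 = _time_grid(settings.insp_time + retrig_delay)
        p1 = _pressure_waveform(t1, settings, settings.insp_time)
        pmus1 = effort.pmus(t1)
        flow1, vol1 = _integrate(t1, p1, pmus1, settings, 0.0)
        cyc1 = BreathCycle(t1, p1, flow1, vol1, LABEL_DT)

        # second stacked breath starts at the current (nonzero) volume
        t0 = t1[-1] + DT_STEP
        v0 = vol1[-1] + flow1[-1] * DT_STEP
        t2 = _time_grid(settings.cycle_time, t0=t0)
        p2 = _pressure_waveform(t2 - t0, settings, settings.insp_time)
        # the effort clock runs from the start of the pair, so evaluate at t2
        pmus2 = effort.pmus(t2)
        flow2, vol2 = _integrate(t2, p2, pmus2, settings, v0)
        cyc2 = BreathCycle(t2, p2, flow2, vol2, LABEL_DT)
        return [cyc1, cyc2]

    raise ValueError(f"unknown cycle kind {kind!r}")


def _jitter_settings(settings: VentilatorSettings, rng: np.random.Generator,
                     frac: float = 0.1) -> VentilatorSettings:
    def j(x):
        return float(x * rng.uniform(1 - frac, 1 + frac))
    return replace(settings,
                   driving_pressure=j(settings.driving_pressure),
                   insp_time=j(settings.insp_time),
                   resp_rate=j(settings.resp_rate),
                   resistance=j(settings.resistance),
                   compliance=j(settings.compliance))


def generate_dataset(n_per_class: dict, settings: VentilatorSettings | None = None,
                     noise_sd: float = 0.02, seed: int = 0,
                     artifact_fraction: float = 0.0) -> WaveformRecord:
    """Generate a labeled record with the requested class composition.

    ``n_per_class`` maps label -> count; the DT count is the number of DT
    *events* (each contributing two consecutive cycles).  ``noise_sd`` is
    additive Gaussian noise, scaled by each channel's per-cycle amplitude;
    volume is re-integrated from the noisy flow so the volume/flow identity
    holds exactly.  ``artifact_fraction`` of OTHER cycles receive a
    low-frequency oscillation artifact (a condensation-like disturbance);
    their label stays OTHER.  Deterministic in all arguments.
    """
    settings = settings or VentilatorSettings()
    counts = {LABEL_DT: 0, LABEL_IEE: 0, LABEL_OTHER: 0}
    counts.update({k: int(v) for k, v in n_per_class.items()})
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be >= 0")
    if sum(counts.values()) == 0:
        raise ValueError("at least one class count must be positive")
    if not (0 <= noise_sd < 0.5):
        raise ValueError("noise_sd must lie in [0, 0.5)")

    rng = np.random.default_rng(seed)
    events = ([LABEL_DT] * counts[LABEL_DT] + [LABEL_IEE] * counts[LABEL_IEE]
              + [LABEL_OTHER] * counts[LABEL_OTHER])
    order = rng.permutation(len(events))

    cycles: list = []
    dt_events: list = []
    t_offset = 0.0
    for idx in order:
        label = events[idx]
        s = _jitter_settings(settings, rng)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if label == LABEL_DT:
            new = simulate_cycle("DT", s, seed=sub_seed)
        elif label == LABEL_IEE:
            onset = s.insp_time + s.exp_time * float(rng.uniform(0.3, 0.6))
            eff = PatientEffort(onset_time=onset,
                                duration=float(rng.uniform(0.4, 0.6)),
                                magnitude=float(rng.uniform(2.0, 4.0)))
            new = simulate_cycle("IEE", s, effort=eff, seed=sub_seed)
        else:
            new = simulate_cycle("normal", s, seed=sub_seed)
            if artifact_fraction > 0 and rng.uniform() < artifact_fraction:
                _add_artifact(new[0], rng)

        for cyc in new:
            _apply_noise(cyc, noise_sd, rng)
            cyc.t = cyc.t - cyc.t[0] + t_offset
            t_offset = cyc.t[-1] + DT_STEP
            cyc.cycle_id = len(cycles)
            cycles.append(cyc)
        if label == LABEL_DT:
            dt_events.append((cycles[-2].cycle_id, cycles[-1].cycle_id))

    return WaveformRecord(cycles=cycles, dt_events=dt_events, seed=seed,
                          settings=settings)


def _apply_noise(cyc: BreathCycle, noise_sd: float,
                 rng: np.random.Generator) -> None:
    if noise_sd <= 0:
        return
    for name in ("pressure", "flow"):
        x = getattr(cyc, name)
        amp = float(np.ptp(x))
        x += rng.normal(0.0, noise_sd * amp, size=x.shape)
    cyc.volume = flow_to_volume(cyc.flow, DT_STEP, v0=cyc.volume[0])


def _add_artifact(cyc: BreathCycle, rng: np.random.Generator) -> None:
    """Low-frequency oscillation superimposed on pressure and flow."""
    f = float(rng.uniform(5.0, 10.0))
    phase = float(rng.uniform(0, 2 * np.pi))
    osc = np.sin(2 * np.pi * f * cyc.t + phase)
    cyc.pressure += 0.8 * osc
    cyc.flow += 0.05 * osc
    cyc.volume = flow_to_volume(cyc.flow, DT_STEP, v0=cyc.volume[0])


# ---------------------------------------------------------------------------
# rule-based reference classifier (noise-free separability guarantee)

def expiratory_excursions(cyc: BreathCycle, settings: VentilatorSettings | None = None,
                          thresh: float = 0.05) -> int:
    """Count expiratory flow excursions above the passive-decay envelope.

    Fits an exponential envelope to the early (unperturbed) expiratory flow
    and counts contiguous regions where the measured flow exceeds it by
    ``thresh`` L/s.  One excursion is the IEE signature.
    """
    flow = cyc.flow
    # expiration proper starts at the expiratory flow spike (global minimum)
    e0 = int(np.argmin(flow))
    seg = flow[e0:]
    if len(seg) < 30:
        return 0
    # fit log(-flow) on 0.2-0.5 s past the spike: clear of the release
    # transient, before any plausible effort onset
    idx = np.arange(10, 25)
    head = np.clip(-seg[idx], 1e-6, None)
    coef = np.polyfit(idx, np.log(head), 1)
    env = -np.exp(np.polyval(coef, np.arange(len(seg))))
    resid = seg - env
    # skip the release transient right at the spike, which decays faster
    # than the passive RC envelope
    above = resid[5:] > thresh
    return int(np.sum(above[1:] & ~above[:-1]) + (1 if above[0] else 0))


def rule_classify(record: WaveformRecord, vol_tol: float = 0.02) -> list:
    """Hand-written per-cycle rule: DT by stacked start volume, IEE by
    a single expiratory excursion, OTHER otherwise."""
    n = len(record.cycles)
    labels = [LABEL_OTHER] * n
    for i, cyc in enumerate(record.cycles):
        if cyc.volume[0] > vol_tol:
            labels[i] = LABEL_DT
            if i > 0:
                labels[i - 1] = LABEL_DT
    for i, cyc in enumerate(record.cycles):
        if labels[i] == LABEL_OTHER and expiratory_excursions(cyc) >= 1:
            labels[i] = LABEL_IEE
    return labels
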