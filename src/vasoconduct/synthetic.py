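"""Seeded synthetic cohorts of afferent-arteriolar diameter recordings.

The generator emulates the statistical structure of per-vessel diameter
time series used in conducted-vasoconstriction experiments: a resting
(baseline) phase, an electrical-stimulation phase during which the vessel
constricts locally and the constriction spreads upstream with exponential
spatial decay, and a recovery phase.  Diameter at position ``x`` (um from
the stimulation site) and time ``t`` is

    d(x, t) = D0 * (1 - c(x) * g(t)) + vasomotion(t) + noise

with ``c(x) = a * exp(-x / lam)`` (``a`` the local relative constriction,
``lam`` the length constant in um) and ``g(t)`` mono-exponential onset and
recovery kinetics.  Vasomotion is a slowly varying AR(1) process; the
measurement noise is white.  All randomness flows from a single integer
seed, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "StimulationProtocol",
    "GroupParams",
    "VesselRecording",
    "default_protocol",
    "default_group_params",
    "generate_vessel",
    "generate_cohort",
    "DEFAULT_GROUP_LABELS",
]

PHASE_BASELINE = "baseline"
PHASE_STIMULATION = "stimulation"
PHASE_RECOVERY = "recovery"

# Vasomotion is modelled as a stationary AR(1) over the sampling grid;
# one correlation value per 10-s step keeps the process slowly varying
# relative to white measurement noise.
VASOMOTION_AR1_RHO = 0.5


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class StimulationProtocol:
    """Timing and spatial layout of one recording.

    Durations are seconds; ``position_spacing`` is the um interval between
    successive upstream measurement sites (the site at 0 um is the
    stimulation point).
    """

    baseline_duration: float = 30.0
    stimulation_duration: float = 30.0
    recovery_duration: float = 30.0
    sampling_interval: float = 10.0
    position_spacing: float = 50.0

    def __post_init__(self) -> None:
        for name in ("baseline_duration", "stimulation_duration",
                     "recovery_duration", "sampling_interval",
                     "position_spacing"):
            v = getattr(self, name)
            _require(np.isfinite(v) and v > 0, f"{name} must be finite and > 0")
        dt = self.sampling_interval
        for name in ("baseline_duration", "stimulation_duration",
                     "recovery_duration"):
            v = getattr(self, name)
            _require(abs(v / dt - round(v / dt)) < 1e-9,
                     f"{name} must be an integer multiple of sampling_interval")

    @property
    def total_duration(self) -> float:
        return (self.baseline_duration + self.stimulation_duration
                + self.recovery_duration)

    @property
    def stimulation_onset(self) -> float:
        return self.baseline_duration

    @property
    def stimulation_end(self) -> float:
        return self.baseline_duration + self.stimulation_duration

    def sample_times(self) -> np.ndarray:
        """Sampling instants in seconds.

        A sample at time ``t`` summarises the interval ending at ``t``,
        so the first sample falls one interval after recording start and
        the last at the end of recovery.
        """
        n = int(round(self.total_duration / self.sampling_interval))
        return self.sampling_interval * np.arange(1, n + 1)

    def phase_of(self, t: float) -> str:
        if t <= self.stimulation_onset:
            return PHASE_BASELINE
        if t <= self.stimulation_end:
            return PHASE_STIMULATION
        return PHASE_RECOVERY

    def phases(self) -> list[str]:
        return [self.phase_of(t) for t in self.sample_times()]


@dataclass(frozen=True)
class GroupParams:
    """Generative parameters for one genotype group.

    ``true_local_constriction`` and ``true_length_constant`` are the
    generative counterparts of the fitted intercept ``a`` and length
    constant ``lam = -1/b``.  Diameter statistics are between-vessel;
    vasomotion/measurement noise are within-recording (um).
    """

    group_label: str
    n_vessels: int
    true_local_constriction: float
    true_length_constant: float
    baseline_diameter_mean: float
    baseline_diameter_sd: float
    traceable_length_min: float
    traceable_length_max: float
    constriction_onset_tau: float = 10.0
    recovery_tau: float = 5.0
    vasomotion_sd: float = 0.75
    measurement_noise_sd: float = 0.4

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "group_label":
                _require(isinstance(v, str) and v != "", "group_label must be non-empty")
                continue
            _require(np.isfinite(v), f"{f.name} must be finite")
        _require(self.n_vessels >= 1, "n_vessels must be >= 1")
        _require(0 <= self.true_local_constriction < 1,
                 "true_local_constriction must lie in [0, 1)")
        _require(self.true_length_constant > 0,
                 "true_length_constant must be > 0")
        _require(self.baseline_diameter_mean > 0,
                 "baseline_diameter_mean must be > 0")
        for name in ("baseline_diameter_sd", "vasomotion_sd",
                     "measurement_noise_sd"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        _require(self.constriction_onset_tau >= 0, "constriction_onset_tau must be >= 0")
        _require(self.recovery_tau >= 0, "recovery_tau must be >= 0")
        _require(self.traceable_length_min <= self.traceable_length_max,
                 "traceable_length_min must be <= traceable_length_max")
        _require(self.traceable_length_min > 0, "traceable lengths must be > 0")

    def validate_against(self, protocol: StimulationProtocol) -> None:
        dx = protocol.position_spacing
        for name in ("traceable_length_min", "traceable_length_max"):
            v = getattr(self, name)
            _require(abs(v / dx - round(v / dx)) < 1e-9,
                     f"{name} must be a multiple of position_spacing")


@dataclass(frozen=True)
class VesselRecording:
    """One vessel's diameter grid over positions x times, with phase labels.

    ``diameters`` has shape ``(len(positions), len(times))`` in um; every
    retained position carries a complete time series (positions beyond the
    vessel's traceable length are simply absent).
    """

    vessel_id: str
    group_label: str
    positions: np.ndarray
    times: np.ndarray
    phases: tuple[str, ...]
    diameters: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, float))
        object.__setattr__(self, "times", np.asarray(self.times, float))
        object.__setattr__(self, "diameters", np.asarray(self.diameters, float))
        _require(self.positions.ndim == 1 and self.positions.size >= 1,
                 "positions must be a non-empty 1-D array")
        _require(self.positions[0] == 0.0, "positions must start at 0")
        _require(np.all(np.diff(self.positions) > 0),
                 "positions must be strictly increasing")
        _require(self.diameters.shape == (self.positions.size, self.times.size),
                 "diameters must be positions x times")
        _require(len(self.phases) == self.times.size,
                 "phases must align with times")
        _require(np.all(self.diameters[np.isfinite(self.diameters)] > 0),
                 "diameters must be positive wherever present")

    @property
    def traceable_length(self) -> float:
        return float(self.positions[-1])

    def time_mask(self, phase: str) -> np.ndarray:
        return np.array([p == phase for p in self.phases])

    def position_index(self, position: float) -> int:
        idx = np.nonzero(np.isclose(self.positions, position))[0]
        if idx.size == 0:
            raise KeyError(
                f"position {position} um not present in vessel {self.vessel_id}")
        return int(idx[0])


def default_protocol() -> StimulationProtocol:
    """Standard protocol: 30 s baseline / 30 s stimulation / 30 s recovery,
    sampled every 10 s, measurement sites every 50 um."""
    return StimulationProtocol()


# Per-group defaults: vessel counts and resting diameters follow the study
# cohort tables; (a, lam) follow the published pooled fits; traceable-length
# ranges are 50-um-multiple windows whose uniform mean matches each group's
# reported mean length within the overall 100-500 um span.
_DEFAULTS: dict[str, dict] = {
    "Cx40 WT": dict(n_vessels=8, true_local_constriction=0.26,
                    true_length_constant=263.0,
                    baseline_diameter_mean=28.7, baseline_diameter_sd=5.3,
                    traceable_length_min=100.0, traceable_length_max=400.0),
    "Cx40 KO": dict(n_vessels=7, true_local_constriction=0.15,
                    true_length_constant=179.0,
                    baseline_diameter_mean=15.5, baseline_diameter_sd=3.4,
                    traceable_length_min=100.0, traceable_length_max=250.0),
    "Cx45 WT": dict(n_vessels=9, true_local_constriction=0.23,
                    true_length_constant=455.0,
                    baseline_diameter_mean=30.6, baseline_diameter_sd=2.7,
                    traceable_length_min=250.0, traceable_length_max=500.0),
    "Cx45 KO": dict(n_vessels=11, true_local_constriction=0.17,
                    true_length_constant=222.0,
                    baseline_diameter_mean=23.6, baseline_diameter_sd=3.1,
                    traceable_length_min=150.0, traceable_length_max=450.0),
}

DEFAULT_GROUP_LABELS = tuple(_DEFAULTS)


def default_group_params(group_label: str) -> GroupParams:
    """Default generative parameters for one of the four genotype groups."""
    try:
        kw = _DEFAULTS[group_label]
    except KeyError:
        valid = ", ".join(repr(k) for k in _DEFAULTS)
        raise ValueError(
            f"unknown group label {group_label!r}; valid labels: {valid}"
        ) from None
    return GroupParams(group_label=group_label, **kw)


def _kinetics(times: np.ndarray, protocol: StimulationProtocol,
              tau_on: float, tau_off: float) -> np.ndarray:
    """Constriction activation g(t) in [0, 1] along the sampling grid."""
    t_on, t_off = protocol.stimulation_onset, protocol.stimulation_end
    g = np.zeros_like(times, dtype=float)
    stim = times > t_on
    if tau_on == 0.0:
        g[stim & (times <= t_off)] = 1.0
        g_end = 1.0
    else:
        m = stim & (times <= t_off)
        g[m] = 1.0 - np.exp(-(times[m] - t_on) / tau_on)
        g_end = 1.0 - math.exp(-(t_off - t_on) / tau_on)
    rec = times > t_off
    if tau_off == 0.0:
        g[rec] = 0.0
    else:
        g[rec] = g_end * np.exp(-(times[rec] - t_off) / tau_off)
    return g


def _draw_traceable_length(params: GroupParams, protocol: StimulationProtocol,
                           rng: np.random.Generator) -> float:
    dx = protocol.position_spacing
    lo = int(round(params.traceable_length_min / dx))
    hi = int(round(params.traceable_length_max / dx))
    return dx * int(rng.integers(lo, hi + 1))


def _ar1(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) with marginal sd ``sd`` and lag-1 correlation ``rho``."""
    if sd == 0.0:
        return np.zeros(n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    innov_sd = sd * math.sqrt(1.0 - rho * rho)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + rng.normal(0.0, innov_sd)
    return x


def generate_vessel(params: GroupParams, protocol: StimulationProtocol,
                    seed: int, vessel_id: str | None = None) -> VesselRecording:
    """Simulate one vessel recording.

    The same ``(params, protocol, seed)`` always yields a bit-identical
    recording.  Randomness enters through: the vessel's resting diameter,
    its traceable length (uniform over allowed 50-um multiples), one AR(1)
    vasomotion trace per position, and white measurement noise.
    """
    params.validate_against(protocol)
    rng = np.random.default_rng(seed)

    d0 = -1.0
    # resting diameter must stay physical; redraw rare negative tails
    for _ in range(1000):
        d0 = rng.normal(params.baseline_diameter_mean, params.baseline_diameter_sd)
        if d0 > 1.0:
            break
    _require(d0 > 1.0, "could not draw a positive resting diameter")

    length = _draw_traceable_length(params, protocol, rng)
    positions = np.arange(0.0, length + 0.5 * protocol.position_spacing,
                          protocol.position_spacing)
    times = protocol.sample_times()
    g = _kinetics(times, protocol,
                  params.constriction_onset_tau, params.recovery_tau)
    cx = params.true_local_constriction * np.exp(
        -positions / params.true_length_constant)

    diam = d0 * (1.0 - np.outer(cx, g))
    for i in range(positions.size):
        diam[i] += _ar1(rng, times.size, params.vasomotion_sd, VASOMOTION_AR1_RHO)
    if params.measurement_noise_sd > 0:
        diam += rng.normal(0.0, params.measurement_noise_sd, size=diam.shape)
    # edge tracking cannot report non-positive widths
    np.clip(diam, 0.1, None, out=diam)

    if vessel_id is None:
        vessel_id = f"{params.group_label}-{seed}"
    return VesselRecording(vessel_id=vessel_id, group_label=params.group_label,
                           positions=positions, times=times,
                           phases=tuple(protocol.phases()), diameters=diam)


def _vessel_seed(master_seed: int, group_index: int, vessel_index: int) -> int:
    """Counter-based per-vessel seed: appending groups or vessels never
    perturbs earlier draws."""
    ss = np.random.SeedSequence(entropy=master_seed,
                                spawn_key=(group_index, vessel_index))
    return int(ss.generate_state(1)[0])


def generate_cohort(groups: list[GroupParams], protocol: StimulationProtocol,
                    seed: int) -> list[VesselRecording]:
    """Simulate all vessels of a multi-group cohort from one master seed."""
    labels = [g.group_label for g in groups]
    if len(set(labels)) != len(labels):
        raise ValueError("group labels must be distinct")
    recordings: list[VesselRecording] = []
    for gi, params in enumerate(groups):
        for vi in range(params.n_vessels):
            vid = f"{params.group_label.replace(' ', '_')}-v{vi + 1:02d}"
            rec = generate_vessel(params, protocol,
                                  _vessel_seed(seed, gi, vi), vessel_id=vid)
            recordings.append(rec)
    return recordings


def noiseless(params: GroupParams) -> GroupParams:
    """Copy of ``params`` with all stochastic and kinetic lags removed.

    Useful for exact round-trip checks: with zero noise and instantaneous
    onset the extracted profile equals a*exp(-x/lam) at every position.
    """
    return replace(params, baseline_diameter_sd=0.0, vasomotion_sd=0.0,
                   measurement_noise_sd=0.0, constriction_onset_tau=0.0)
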