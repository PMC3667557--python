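"""Smooth-pursuit eye movements under occlusion and reversal.

The generative process is a one-dimensional oculomotor plant: gaze angle
``x_o`` is driven by action through a viscous velocity state (decay time
constant 8 bins = 128 ms at 16-ms bins) and the target ``x_t`` is drawn
to a sinusoidally moving attracting point with a 1-bin time constant.
Sensations are the proprioceptive gaze angle plus 17 visual channels
with Gaussian receptive fields at 1-angular-unit spacing (about 2 deg of
visual angle each), gated by a smooth occluder ``O(x_t)`` in [0, 1].

The agent's model believes gaze and target are attracted to a common
fictive point ``v(1)`` whose motion is predicted by a second-level
harmonic oscillator with frequency cause ``v(2)`` (prior expectation
eta).  There is no action in the model: proprioceptive predictions are
fulfilled by reflex arcs.  The "trait" manipulation lowers the log
precision of second-level hidden-state prediction errors from -1 to
-1.25.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .engine import (
    GenerativeProcess,
    HierarchicalModel,
    LevelSpec,
    PriorSchedule,
    SimulationRecord,
    run_closed_loop,
    step,
)

DEG_PER_UNIT = 2.0  # 1 angular unit ~ 2 deg of visual angle
SACCADE_DEG_S = 30.0  # velocity criterion for a (catch-up) saccade


@dataclass
class Occluder:
    """Smooth occluding region over target location, gain in [0, 1]."""

    lo: float = 0.25
    hi: float = 2.0
    edge: float = 0.125


@dataclass
class PursuitWorldConfig:
    bin_ms: float = 16.0
    n_channels: int = 17
    rf_spacing: float = 1.0
    rf_width: float = 1.0
    occluder: Optional[Occluder] = field(default_factory=Occluder)
    target_amplitude: float = 1.0  # angular units (2 deg center-to-peak)
    target_period_bins: float = 48.0  # 768 ms
    target_phase_bins: float = 6.0  # phase lead: re-emergences at ~256+768k ms
    reversal_bin: Optional[float] = None
    oculomotor_time_constant: float = 8.0  # bins (128 ms)
    target_time_constant: float = 1.0  # bins (16 ms)
    noise_log_precision: float = 16.0

    def __post_init__(self) -> None:
        if self.n_channels % 2 == 0:
            raise ValueError("n_channels must be odd (centered array)")
        if self.oculomotor_time_constant <= 0 or self.target_time_constant <= 0:
            raise ValueError("time constants must be positive")


@dataclass
class PursuitModelConfig:
    sensory_log_precision: float = 3.0
    level2_log_precision: float = -1.0  # pathological: -1.25
    level2_cause_log_precision: float = -1.0
    eta_log_precision: float = 2.0
    attraction_gain: float = 0.125  # pull of the fictive point on gaze
    damping_gain: float = 0.5  # viscous damping of model gaze velocity
    oscillator_leak: float = 0.22  # amplitude restoring rate of the level-2 cycle
    oscillator_amplitude: float = 1.0  # preferred excursion of the level-2 cycle


def occluder_gain(x_t, occ: Optional[Occluder]):
    """O(x_t) in [0, 1]: ~0 deep inside the occluded region, ~1 outside."""
    if occ is None:
        return np.ones_like(np.asarray(x_t, float)) if np.ndim(x_t) else 1.0
    s = lambda z: 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
    inside = s((x_t - occ.lo) / occ.edge) * s((occ.hi - x_t) / occ.edge)
    return 1.0 - inside


def rf_responses(x_t: float, x_o: float, config: PursuitWorldConfig) -> np.ndarray:
    """Responses of the visual channel array to a (possibly occluded) target."""
    half = config.n_channels // 2
    centers = np.arange(-half, half + 1) * config.rf_spacing
    gain = occluder_gain(x_t, config.occluder)
    return gain * np.exp(-((x_t - x_o - centers) ** 2) / (2 * config.rf_width**2))


def target_attractor(t: float, config: PursuitWorldConfig) -> float:
    """Location the target is drawn to: a sinusoid, optionally reversed."""
    w = 2 * np.pi / config.target_period_bins
    if config.reversal_bin is not None and t >= config.reversal_bin:
        t = 2 * config.reversal_bin - t
    return config.target_amplitude * np.sin(w * (t + config.target_phase_bins))


def build_pursuit_process(config: PursuitWorldConfig) -> GenerativeProcess:
    """True world: states (x_o, x_o', x_t); sensations (s_o, 17 channels)."""
    tau_o = config.oculomotor_time_constant
    tau_t = config.target_time_constant

    def flow(x, v, a):
        a = np.atleast_1d(a)
        return np.array(
            [x[1], float(a[0]) - x[1] / tau_o, (float(np.atleast_1d(v)[0]) - x[2]) / tau_t]
        )

    def output(x, v, a):
        return np.concatenate([[x[0]], rf_responses(x[2], x[0], config)])

    def fx(x, v, a):
        return np.array(
            [[0.0, 1.0, 0.0], [0.0, -1.0 / tau_o, 0.0], [0.0, 0.0, -1.0 / tau_t]]
        )

    def fa(x, v, a):
        return np.array([[0.0], [1.0], [0.0]])

    def ga(x, v, a):
        return np.zeros((config.n_channels + 1, 1))

    return GenerativeProcess(
        n_x=3, n_s=config.n_channels + 1, n_a=1, n_v=1,
        flow=flow, output=output,
        cause=lambda t: np.array([target_attractor(t, config)]),
        noise_log_precision_x=config.noise_log_precision,
        noise_log_precision_s=config.noise_log_precision,
        jac={"fx": fx, "fa": fa, "ga": ga},
    )


def build_pursuit_model(
    world: PursuitWorldConfig, model_cfg: PursuitModelConfig
) -> HierarchicalModel:
    """Agent's model: common attracting point plus an oscillator prior."""
    tau_t = world.target_time_constant
    ka, kd = model_cfg.attraction_gain, model_cfg.damping_gain

    def flow1(x, v):
        return np.array(
            [x[1], ka * (v[0] - x[0]) - kd * x[1], (v[0] - x[2]) / tau_t]
        )

    def output1(x, v):
        return np.concatenate([[x[0]], rf_responses(x[2], x[0], world)])

    lv1 = LevelSpec(
        n_x=3, n_v=1, out_dim=world.n_channels + 1,
        flow=flow1, output=output1,
        log_precision_x=model_cfg.sensory_log_precision,
        log_precision_v=model_cfg.sensory_log_precision,
        jac={
            "fx": lambda x, v: np.array(
                [[0, 1, 0], [-ka, -kd, 0], [0, 0, -1 / tau_t]], float
            ),
            "fv": lambda x, v: np.array([[0.0], [ka], [1.0 / tau_t]]),
        },
    )

    # Second level: a limit-cycle (Hopf) oscillator whose rotation rate is
    # the cause v(2) and whose radial term weakly restores the preferred
    # excursion rho -- periodic prior beliefs of a characteristic amplitude.
    lam, rho = model_cfg.oscillator_leak, model_cfg.oscillator_amplitude

    def flow2(x, v):
        g = lam * (rho**2 - x[0] ** 2 - x[1] ** 2)
        return np.array([v[0] * x[1] + g * x[0], -v[0] * x[0] + g * x[1]])

    def fx2(x, v):
        g = lam * (rho**2 - x[0] ** 2 - x[1] ** 2)
        return np.array(
            [
                [g - 2 * lam * x[0] ** 2, v[0] - 2 * lam * x[0] * x[1]],
                [-v[0] - 2 * lam * x[0] * x[1], g - 2 * lam * x[1] ** 2],
            ]
        )

    lv2 = LevelSpec(
        n_x=2, n_v=1, out_dim=1,
        flow=flow2, output=lambda x, v: np.array([x[0]]),
        log_precision_x=model_cfg.level2_log_precision,
        log_precision_v=model_cfg.level2_cause_log_precision,
        jac={
            "fx": fx2,
            "fv": lambda x, v: np.array([[x[1]], [-x[0]]]),
            "gx": lambda x, v: np.array([[1.0, 0.0]]),
            "gv": lambda x, v: np.array([[0.0]]),
        },
    )
    omega = 2 * np.pi / world.target_period_bins
    prior = PriorSchedule(
        value=lambda t: np.array([omega]),
        log_precision=model_cfg.eta_log_precision,
    )
    # d = 3 so that sensations carry acceleration: action enters the plant
    # at the level of gaze acceleration, so the reflex arc needs the
    # second temporal derivative of the proprioceptive signal.
    return HierarchicalModel([lv1, lv2], n_orders=4, d_orders=3, prior=prior)


def initial_posterior(
    model: HierarchicalModel, world: PursuitWorldConfig
) -> np.ndarray:
    """Veridical initial beliefs: oscillator at phase/amplitude of the target."""
    from .engine import PosteriorState

    post = PosteriorState.zeros(model)
    omega = 2 * np.pi / world.target_period_bins
    A = world.target_amplitude
    ph = omega * world.target_phase_bins
    x_t0 = A * np.sin(ph)
    v_t0 = A * omega * np.cos(ph)
    x2 = np.zeros((2, model.n_orders))
    x2[:, 0] = [x_t0, A * np.cos(ph)]  # oscillator at target phase
    x2[0, 1] = v_t0
    x2[1, 1] = -A * omega * np.sin(ph)
    post.set_mu_x(1, x2)
    v2 = np.zeros((1, model.d_orders))
    v2[0, 0] = omega
    post.set_mu_v(1, v2)
    # gaze and target beliefs start on target (pursuit already engaged)
    x1 = np.zeros((3, model.n_orders))
    x1[:, 0] = [x_t0, v_t0, x_t0]
    x1[0, 1] = v_t0
    x1[2, 1] = v_t0
    post.set_mu_x(0, x1)
    v1 = np.zeros((1, model.d_orders))
    v1[0, 0] = x_t0
    v1[0, 1] = v_t0
    post.set_mu_v(0, v1)
    return post.flat


def initial_process_state(
    world: PursuitWorldConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """True plant state and action for a run that starts mid-pursuit."""
    omega = 2 * np.pi / world.target_period_bins
    ph = omega * world.target_phase_bins
    x_t0 = world.target_amplitude * np.sin(ph)
    v_t0 = world.target_amplitude * omega * np.cos(ph)
    x0 = np.array([x_t0, v_t0, x_t0])
    a0 = np.array([v_t0 / world.oculomotor_time_constant])
    return x0, a0


def run_pursuit(
    condition: str = "occlusion",
    level2_log_precision: float = -1.0,
    duration: int | None = None,
    seed: int = 0,
    world: PursuitWorldConfig | None = None,
    model_cfg: PursuitModelConfig | None = None,
) -> SimulationRecord:
    """Closed-loop pursuit in the occlusion or reversal condition."""
    if condition not in ("occlusion", "reversal"):
        raise ValueError(f"unknown condition {condition!r}")
    if world is None:
        world = PursuitWorldConfig()
        if condition == "reversal":
            world = replace(
                world, occluder=None, target_period_bins=32.0,
                target_phase_bins=0.0, reversal_bin=48.0,
            )
    if model_cfg is None:
        model_cfg = PursuitModelConfig()
    model_cfg = replace(model_cfg, level2_log_precision=level2_log_precision)
    if duration is None:
        duration = 184 if condition == "occlusion" else 96

    process = build_pursuit_process(world)
    model = build_pursuit_model(world, model_cfg)
    x0, a0 = initial_process_state(world)
    rec = run_closed_loop(
        process, model, duration=duration, rng_seed=seed,
        mu0=initial_posterior(model, world), x0=x0, a0=a0,
        metadata={
            "experiment": "pursuit", "condition": condition,
            "bin_ms": world.bin_ms,
            "level2_log_precision": level2_log_precision,
            "world": world, "model_cfg": model_cfg,
        },
    )
    return rec


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------


def velocity_deg_per_s(position: np.ndarray, bin_ms: float) -> np.ndarray:
    """Central-difference angular velocity in deg/s."""
    vel_units_per_bin = np.gradient(position)
    return vel_units_per_bin * DEG_PER_UNIT / (bin_ms / 1000.0)


def occlusion_episodes(record: SimulationRecord) -> list[tuple[int, int]]:
    """(start, end) bin index pairs of occlusion episodes (end exclusive)."""
    world: PursuitWorldConfig = record.metadata["world"]
    if world.occluder is None:
        return []
    x_t = record.true_states[:, 2]
    hidden = occluder_gain(x_t, world.occluder) < 0.5
    episodes, start = [], None
    for i, h in enumerate(hidden):
        if h and start is None:
            start = i
        elif not h and start is not None:
            episodes.append((start, i))
            start = None
    if start is not None:
        episodes.append((start, len(hidden)))
    return episodes


@dataclass
class PursuitMetrics:
    lag: np.ndarray  # target - gaze, angular units
    eye_velocity_deg_s: np.ndarray
    saccade_bins: np.ndarray  # bins where |velocity| > 30 deg/s
    end_of_occlusion_lag: list[float]  # mean |lag| over each episode's last third
    windowed_rms: dict  # window name -> RMS tracking error (units)
    episodes: list[tuple[int, int]]  # full occlusion episodes (cycles)


def pursuit_metrics(
    record: SimulationRecord, windows_ms: dict | None = None
) -> PursuitMetrics:
    world: PursuitWorldConfig = record.metadata["world"]
    bin_ms = world.bin_ms
    x_o = record.true_states[:, 0]
    x_t = record.true_states[:, 2]
    lag = x_t - x_o
    vel = velocity_deg_per_s(x_o, bin_ms)
    saccades = np.where(np.abs(vel) > SACCADE_DEG_S)[0]
    # occlusion cycles: complete episodes only (the run may begin inside an
    # occlusion -- that startup stretch is not a cycle)
    episodes = [
        (s, e)
        for s, e in occlusion_episodes(record)
        if s > 0 and e < record.n_bins
    ]
    eol = [
        float(np.mean(np.abs(lag[s + 2 * (e - s) // 3 : e + 1])))
        for s, e in episodes
    ]
    if windows_ms is None:
        windows_ms = {"visible_1200_1400": (1200, 1400),
                      "visible_2000_2200": (2000, 2200)}
    rms = {}
    for name, (lo, hi) in windows_ms.items():
        i0, i1 = int(lo / bin_ms), int(hi / bin_ms)
        if i1 <= len(lag):
            rms[name] = float(np.sqrt(np.mean(lag[i0:i1] ** 2)))
    return PursuitMetrics(lag, vel, saccades, eol, rms, episodes)


def peak_velocity_after_final_reemergence(record: SimulationRecord) -> float:
    """Peak |eye velocity| (deg/s) after the last complete re-emergence."""
    m = pursuit_metrics(record)
    ends = [e for _, e in m.episodes]
    if not ends:
        raise ValueError("no completed occlusion episode in this record")
    return float(np.max(np.abs(m.eye_velocity_deg_s[ends[-1]:])))


def reversal_metrics(record: SimulationRecord, window_bins: int = 10) -> dict:
    """Peak gaze-target displacement and peak eye speed in the immediate
    compensatory epoch after the trajectory reversal.

    The window (default 10 bins = 160 ms) covers the response to the
    unexpected reversal itself; later swings reflect re-locking of the
    periodic beliefs rather than the reversal response.
    """
    world: PursuitWorldConfig = record.metadata["world"]
    if world.reversal_bin is None:
        raise ValueError("record is not from a reversal condition")
    i0 = int(world.reversal_bin)
    i1 = i0 + window_bins
    x_o = record.true_states[:, 0]
    x_t = record.true_states[:, 2]
    vel = velocity_deg_per_s(x_o, world.bin_ms)
    return {
        "peak_displacement": float(np.max(np.abs(x_t - x_o)[i0:i1])),
        "peak_eye_speed_deg_s": float(np.max(np.abs(vel[i0:i1]))),
    }


def plant_impulse_time_constant(
    world: PursuitWorldConfig | None = None,
    impulse_bins: tuple[int, int] = (2, 6),
    impulse_amplitude: float = 0.5,
    duration: int = 48,
) -> float:
    """Fitted decay time constant (ms) of oculomotor velocity after an
    action impulse, with a stationary target and noise off.

    A single exponential is fit by linear regression on log speed over the
    decay; for the configured plant this recovers the 8-bin (128 ms)
    viscous time constant.
    """
    if world is None:
        world = PursuitWorldConfig(target_amplitude=0.0)
    world = replace(world, noise_log_precision=32.0)
    process = build_pursuit_process(world)

    x = np.zeros(3)
    vels = []
    for t in range(duration):
        a = np.array([impulse_amplitude if impulse_bins[0] <= t < impulse_bins[1]
                      else 0.0])
        vels.append(x[1])
        x = step(lambda u: process.flow(u, np.zeros(1), a), x, 1.0)
    vels = np.asarray(vels)
    t0 = impulse_bins[1] + 1
    seg = vels[t0 : t0 + 24]
    keep = seg > 1e-8
    tt = np.arange(seg.size)[keep]
    slope = np.polyfit(tt, np.log(seg[keep]), 1)[0]
    tau_bins = -1.0 / slope
    return float(tau_bins * world.bin_ms)
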