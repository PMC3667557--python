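"""Sensory attenuation, the force-matching illusion, and its pathologies.

One hidden state ``x_i`` (self-generated force, Newtons) is driven by a
squashed action and decays over four 100-ms time bins.  Proprioception
reports only the self-generated force, ``s_p = x_i``; somatosensation
reports the ambiguous mixture ``s_s = x_i + v_e`` of self-generated and
external forces.

The agent models internal and external forces symmetrically: hidden
states (x_i, x_e) excited by hidden causes (v_i, v_e).  Crucially, the
log precision of the sensory prediction errors falls with the expected
internal force: a squashing function of (mu_xi + mu_vi) scaled by the
attenuation parameter gamma.  Self-generated movement therefore
transiently loosens sensory evidence so reflex arcs can fulfil
proprioceptive predictions -- and widens the posterior confidence
interval around the self-generated force, which is how the
force-matching illusion arises when percepts are read out at the lower
90% confidence bound.

Manipulations: gamma = 6 (normal attenuation), gamma = 2 (failed
attenuation, akinesia/catatonia), gamma = 2 with all supra-sensory log
precisions boosted by 4 (compensation: movement restored, illusion
abolished, antagonistic delusion about v_e).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .engine import (
    GenerativeProcess,
    HierarchicalModel,
    LevelSpec,
    PriorSchedule,
    SimulationRecord,
    posterior_interval,
    run_closed_loop,
)

Z90 = 1.6449  # one-sided z for the 90% confidence bound
ACTUATOR_CAP = 4.0  # Newton/bin ceiling of the squashed actuator


@dataclass
class AttenuationConfig:
    gamma: float = 6.0  # attenuation strength (pathological: 2)
    level_boost: float = 0.0  # added to supra-sensory log precisions (comp.: 4)
    bin_ms: float = 100.0
    decay_time_constant: float = 4.0  # bins
    base_sensory_log_precision: float = 10.0
    state_log_precision: float = 4.0  # hidden-state errors (before boost)
    cause_vi_log_precision: float = 6.0  # prior on the internal cause
    cause_ve_log_precision: float = 1.0  # prior on the external cause
    reflex_log_precision: float = 0.5  # fixed spinal reflex gain (log units)
    squash_gain: float = 2.0
    squash_threshold: float = 0.3
    # prior schedule for v_i: Gaussian bump of this height/width (bins)
    self_amplitude: float = 1.0
    self_onset: float = 14.0
    self_width: float = 3.0
    # external force schedule: bump height in Newtons (None = no force)
    external_force: Optional[float] = None
    external_onset: float = 40.0
    external_width: float = 4.0
    duration: int = 60
    process_noise_log_precision: float = 12.0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")


def squash(u, gain: float = 2.0, threshold: float = 0.75):
    """Logistic squashing function in [0, 1]."""
    return 1.0 / (1.0 + np.exp(-np.clip(gain * (u - threshold), -500, 500)))


def attenuated_log_precision(
    mu_internal: float, gamma: float, base: float,
    gain: float = 2.0, threshold: float = 0.75,
) -> float:
    """Sensory log precision under attenuation: base - gamma * squash(mu).

    Smooth and monotone decreasing in the expected internal force; gamma=0
    recovers the unattenuated baseline.
    """
    return base - gamma * squash(mu_internal, gain, threshold)


def bump(t, onset: float, width: float, height: float):
    """Smooth transient: Gaussian in time."""
    return height * np.exp(-((t - onset) ** 2) / (2 * width**2))


def build_attenuation_process(config: AttenuationConfig) -> GenerativeProcess:
    """True world: self force x_i driven by squashed action, external force
    x_e excited by the exogenous cause v_e; both decay over four bins."""
    tau = config.decay_time_constant

    def flow(x, v, a):
        aa = float(np.atleast_1d(a)[0])
        ve = float(np.atleast_1d(v)[0])
        return np.array(
            [ACTUATOR_CAP * np.tanh(aa / ACTUATOR_CAP) - x[0] / tau,
             ve - x[1] / tau]
        )

    def output(x, v, a):
        return np.array([x[0], x[0] + x[1]])

    def v_e(t):
        if config.external_force is None:
            return np.array([0.0])
        return np.array(
            [bump(t, config.external_onset, config.external_width,
                  config.external_force)]
        )

    return GenerativeProcess(
        n_x=2, n_s=2, n_a=1, n_v=1,
        flow=flow, output=output, cause=v_e,
        noise_log_precision_x=config.process_noise_log_precision,
        noise_log_precision_s=config.process_noise_log_precision,
        jac={
            "fx": lambda x, v, a: np.array([[-1.0 / tau, 0.0], [0.0, -1.0 / tau]]),
            "fa": lambda x, v, a: np.array(
                [[1.0 - np.tanh(float(np.atleast_1d(a)[0]) / ACTUATOR_CAP) ** 2],
                 [0.0]]
            ),
            "gx": lambda x, v, a: np.array([[1.0, 0.0], [1.0, 1.0]]),
            "ga": lambda x, v, a: np.zeros((2, 1)),
            "gv": lambda x, v, a: np.zeros((2, 1)),
        },
    )


def build_attenuation_model(config: AttenuationConfig) -> HierarchicalModel:
    """Agent's model: symmetric (x_i, x_e) pairs, state-dependent sensory
    precision, supra-sensory precisions raised by ``level_boost``."""
    tau = config.decay_time_constant
    gamma, base = config.gamma, config.base_sensory_log_precision
    g, th = config.squash_gain, config.squash_threshold

    def flow(x, v):
        return np.array([v[0] - x[0] / tau, v[1] - x[1] / tau])

    def output(x, v):
        return np.array([x[0], x[0] + x[1]])

    def pi_sensory(x, v):
        mu_int = x[0] + v[0]  # expected internal force: state plus cause
        return np.full(2, attenuated_log_precision(mu_int, gamma, base, g, th))

    def dpi_sensory(x, v):
        mu_int = x[0] + v[0]
        s = squash(mu_int, g, th)
        d = -gamma * g * s * (1 - s)
        # columns: (x_i, x_e, v_i, v_e)
        return np.array([[d, 0.0, d, 0.0], [d, 0.0, d, 0.0]])

    lv = LevelSpec(
        n_x=2, n_v=2, out_dim=2,
        flow=flow, output=output,
        log_precision_x=config.state_log_precision + config.level_boost,
        log_precision_v=pi_sensory,
        dpi_v=dpi_sensory,
        jac={
            "fx": lambda x, v: np.array([[-1 / tau, 0.0], [0.0, -1 / tau]]),
            "fv": lambda x, v: np.eye(2),
            "gx": lambda x, v: np.array([[1.0, 0.0], [1.0, 1.0]]),
            "gv": lambda x, v: np.zeros((2, 2)),
        },
    )

    def eta(t):
        return np.array(
            [bump(t, config.self_onset, config.self_width,
                  config.self_amplitude), 0.0]
        )

    prior = PriorSchedule(
        value=eta,
        log_precision=np.array(
            [config.cause_vi_log_precision + config.level_boost,
             config.cause_ve_log_precision + config.level_boost]
        ),
    )
    return HierarchicalModel([lv], n_orders=3, d_orders=2, prior=prior)


@dataclass
class ForceTrialRecord:
    """Simulation record plus 90% bands for the force variables."""

    record: SimulationRecord
    config: AttenuationConfig

    def band(self, kind: str, component: int, coverage: float = 0.9):
        return posterior_interval(self.record, 0, kind, component, coverage)

    @property
    def true_self_force(self) -> np.ndarray:
        return self.record.true_states[:, 0]

    @property
    def true_external_force(self) -> np.ndarray:
        return self.record.true_states[:, 1]

    @property
    def true_external_cause(self) -> np.ndarray:
        return self.record.true_cause[:, 0]


def run_force_trial(
    config: AttenuationConfig, seed: int = 0
) -> ForceTrialRecord:
    """One closed-loop trial (self-generated and/or external force)."""
    process = build_attenuation_process(config)
    model = build_attenuation_model(config)
    rec = run_closed_loop(
        process, model, duration=config.duration, rng_seed=seed,
        store_covariance=True,
        reflex_log_precision=config.reflex_log_precision,
        metadata={"experiment": "force_trial", "bin_ms": config.bin_ms,
                  "config": config},
    )
    return ForceTrialRecord(rec, config)


def perceived_force(trial: ForceTrialRecord, floor: float = 0.05) -> float:
    """Perceived intensity: the lower 90% bound of the posterior internal
    force at the bin where its expectation peaks."""
    mu = trial.record.mu_x0(0, 0)
    peak = int(np.argmax(mu))
    if mu[peak] < floor:
        raise ValueError("no percept: posterior internal force never rises")
    lo, _ = trial.band("x", 0, 0.9)
    return float(lo[peak])


def force_matching(
    force_levels,
    gamma: float = 6.0,
    boost: float = 0.0,
    seed: int = 0,
    base_config: AttenuationConfig | None = None,
) -> list[tuple[float, float]]:
    """Reproduce the force-matching experiment.

    For each prior amplitude level: run a self-generation trial, read the
    force perceived at 90% confidence, then deliver exactly that force
    externally (the matched force) and verify it is perceived.  Returns
    (true self-generated force, matched external force) pairs in Newtons.
    """
    force_levels = list(force_levels)
    if len(force_levels) < 2:
        raise ValueError("need at least two force levels")
    if base_config is None:
        base_config = AttenuationConfig()
    pairs = []
    for lev in force_levels:
        cfg = replace(base_config, gamma=gamma, level_boost=boost,
                      self_amplitude=lev, external_force=None)
        trial = run_force_trial(cfg, seed=seed)
        matched = perceived_force(trial)
        true_self = float(np.max(trial.true_self_force))
        pairs.append((true_self, matched))
    return pairs


@dataclass
class OutcomeMetrics:
    movement_amplitude: float  # peak true self-generated force (N)
    illusion: float  # true self force minus matched external force (N)
    delusion_index: float  # extreme signed 90% bound of posterior v_e
    delusion_present: bool


def outcome_metrics(
    trial: ForceTrialRecord, matched_force: float | None = None
) -> OutcomeMetrics:
    """Movement amplitude, illusion magnitude and delusion index.

    The delusion index is the most extreme signed value of the 90% band of
    the posterior external cause during self-generated movement; a delusion
    is scored when the whole band lies on the side opposite the movement.
    """
    cfg = trial.config
    move = float(np.max(trial.true_self_force))
    if matched_force is None:
        try:
            matched_force = perceived_force(trial)
        except ValueError:
            matched_force = 0.0
    illusion = move - matched_force
    lo, hi = trial.band("v", 1, 0.9)
    # window of self-generated movement: around the v_i prior bump
    t = trial.record.time
    win = (t >= cfg.self_onset - 2 * cfg.self_width) & (
        t <= cfg.self_onset + 6 * cfg.self_width
    )
    idx = np.argmax(np.abs(np.where(win, np.minimum(np.abs(lo), np.abs(hi)), 0)))
    # most extreme band edge with the band excluding zero
    excl = win & ((lo > 0) | (hi < 0))
    if np.any(excl):
        cand = np.where(excl & (hi < 0), hi, np.where(excl & (lo > 0), lo, 0.0))
        delusion_index = float(cand[np.argmax(np.abs(cand))])
        present = delusion_index < 0  # antagonistic: opposes positive movement
    else:
        mid = 0.5 * (lo + hi)
        delusion_index = float(mid[idx]) if np.any(win) else 0.0
        present = False
    return OutcomeMetrics(move, illusion, delusion_index, present)
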