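"""Experiment runners, configuration, exports and validation checks.

Every experiment is driven by a plain configuration (YAML on disk or a
keyword dictionary), expands one global seed into named per-stream seeds,
and exports long-format CSV tables plus a structured-text summary whose
metrics include the qualitative checks each simulation is expected to
satisfy.  Reruns with the same configuration and seed are byte-identical;
the resolved configuration and its hash are written next to the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import attenuation as att
from . import birdsong as bs
from . import pursuit as pur
from .engine import (
    GenerativeProcess,
    HierarchicalModel,
    LevelSpec,
    PosteriorState,
    compute_errors,
    constant_prior,
    free_energy,
    free_energy_gradient,
)

log = logging.getLogger("actinf")

EXPERIMENTS = ("birdsong", "pursuit", "force-trial", "force-matching")


@dataclass
class RunConfig:
    """One experiment run: name, parameter block, seed, output directory."""

    experiment: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; "
                f"expected one of {EXPERIMENTS}"
            )


@dataclass
class MetricsSummary:
    """Named scalar metrics (with units in the name where relevant) plus the
    qualitative checks evaluated on this run."""

    experiment: str
    seed: int
    config_hash: str
    metrics: dict = field(default_factory=dict)
    checks: dict = field(default_factory=dict)  # name -> bool

    @property
    def all_passed(self) -> bool:
        return all(bool(v) for v in self.checks.values())

    def to_text(self) -> str:
        payload = {
            "experiment": self.experiment,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "metrics": {k: _scalar(v) for k, v in self.metrics.items()},
            "checks": {k: bool(v) for k, v in self.checks.items()},
        }
        return yaml.safe_dump(payload, sort_keys=False)


def _scalar(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, (list, tuple)):
        return [_scalar(x) for x in v]
    return v


def load_config(path: str | Path) -> RunConfig:
    """Read a run configuration from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(
        experiment=raw.get("experiment"),
        params=raw.get("params", {}) or {},
        seed=int(raw.get("seed", 0)),
        out_dir=raw.get("out_dir"),
    )


def resolved_config(config: RunConfig) -> dict:
    return {
        "experiment": config.experiment,
        "params": config.params,
        "seed": config.seed,
    }


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(resolved_config(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _apply(cls_default, overrides: dict):
    """Build a config dataclass from defaults plus overrides."""
    known = {f.name for f in dataclasses.fields(cls_default)}
    bad = set(overrides) - known
    if bad:
        raise ValueError(f"unknown config fields {sorted(bad)} for "
                         f"{type(cls_default).__name__}")
    return replace(cls_default, **overrides)


# --------------------------------------------------------------------------
# experiment drivers
# --------------------------------------------------------------------------


def run_birdsong_experiment(config: RunConfig) -> tuple[MetricsSummary, dict]:
    """Three precision regimes on one omission-edited song (the module's
    acceptance surface) and the intact-song recognition run."""
    p = dict(config.params)
    omitted_n = int(p.pop("omit", 3))
    regimes = p.pop(
        "regimes",
        {"normal": (2.0, 8.0, 16.0),
         "low_level2": (2.0, 8.0, 2.0),
         "low_sensory": (-2.0, 8.0, 2.0)},
    )
    cfg = _apply(bs.BirdsongConfig(), p)
    song = bs.generate_song(rng_seed=config.seed, config=cfg)
    if len(song.chirps) < omitted_n + 1:
        raise RuntimeError(
            f"misconfigured attractor: only {len(song.chirps)} chirps"
        )
    edited = bs.omit_chirps(song, omitted_n)
    records, metrics = {}, {}
    for name, lp in regimes.items():
        rec = bs.run_birdsong(edited, tuple(lp), seed=config.seed, config=cfg)
        records[name] = rec
        om = bs.omission_metrics(rec, song, omitted_n)
        hal = bs.hallucinosis_metrics(rec, edited)
        metrics[f"{name}_omission_peak_xi"] = om.omitted_peaks[0]
        metrics[f"{name}_chirp_peaks_xi"] = om.chirp_peaks
        metrics[f"{name}_mean_xi"] = om.mean_xi
        metrics[f"{name}_post_song_amplitude"] = hal["post_song_mean_amplitude"]
        metrics[f"{name}_within_song_amplitude"] = hal["within_song_mean_amplitude"]
    m_n = bs.omission_metrics(records["normal"], song, omitted_n)
    m_l = bs.omission_metrics(records["low_level2"], song, omitted_n)
    m_s = bs.omission_metrics(records["low_sensory"], song, omitted_n)
    hal_s = bs.hallucinosis_metrics(records["low_sensory"], edited)
    checks = {
        "omission_peak_is_global_max": m_n.omitted_peaks[0] > max(m_n.chirp_peaks),
        "low_level2_attenuates_omission": m_l.omitted_peaks[0] < m_n.omitted_peaks[0],
        "low_level2_third_chirp_near_omission": (
            m_l.chirp_peaks[2] >= 0.75 * m_l.omitted_peaks[0]
        ),
        "hallucinosis_persists": (
            hal_s["post_song_mean_amplitude"]
            > 0.5 * hal_s["within_song_mean_amplitude"]
        ),
        "hallucinosis_lowest_weighted_error": (
            m_s.mean_xi < m_n.mean_xi and m_s.mean_xi < m_l.mean_xi
        ),
    }
    summary = MetricsSummary(config.experiment, config.seed,
                             config_hash(config), metrics, checks)
    return summary, records


def run_pursuit_experiment(config: RunConfig) -> tuple[MetricsSummary, dict]:
    """Occlusion or reversal condition, normal (-1) vs reduced (-1.25)."""
    p = dict(config.params)
    condition = p.pop("condition", "occlusion")
    levels = p.pop("level2_log_precisions", (-1.0, -1.25))
    duration = p.pop("duration", None)
    records, metrics = {}, {}
    for l2 in levels:
        rec = pur.run_pursuit(condition, l2, duration=duration,
                              seed=config.seed)
        records[l2] = rec
    checks = {}
    if condition == "occlusion":
        per = {}
        for l2, rec in records.items():
            m = pur.pursuit_metrics(rec)
            vfin = pur.peak_velocity_after_final_reemergence(rec)
            per[l2] = (m, vfin)
            metrics[f"eol_lag_units[{l2}]"] = m.end_of_occlusion_lag
            metrics[f"peak_final_velocity_deg_s[{l2}]"] = vfin
            metrics[f"visible_rms_units[{l2}]"] = m.windowed_rms
        (m_n, v_n), (m_p, v_p) = per[levels[0]], per[levels[1]]
        n = min(len(m_n.end_of_occlusion_lag), len(m_p.end_of_occlusion_lag))
        checks["lag_larger_after_first_cycle"] = all(
            m_p.end_of_occlusion_lag[i] > m_n.end_of_occlusion_lag[i]
            for i in range(1, n)
        )
        checks["third_cycle_worse_than_first"] = (
            m_p.end_of_occlusion_lag[2] > m_p.end_of_occlusion_lag[0]
        )
        checks["visible_windows_normal"] = all(
            abs(m_p.windowed_rms[k] - m_n.windowed_rms[k])
            < 0.25 * m_n.windowed_rms[k]
            for k in m_n.windowed_rms
        )
        checks["catch_up_saccade_only_when_reduced"] = (
            v_p > pur.SACCADE_DEG_S >= v_n
        )
    else:
        per = {l2: pur.reversal_metrics(rec) for l2, rec in records.items()}
        for l2, m in per.items():
            metrics[f"peak_displacement_units[{l2}]"] = m["peak_displacement"]
            metrics[f"peak_eye_speed_deg_s[{l2}]"] = m["peak_eye_speed_deg_s"]
        a, b = per[levels[0]], per[levels[1]]
        checks["reversal_paradox_displacement"] = (
            b["peak_displacement"] < a["peak_displacement"]
        )
        checks["reversal_paradox_velocity"] = (
            b["peak_eye_speed_deg_s"] < a["peak_eye_speed_deg_s"]
        )
    summary = MetricsSummary(config.experiment, config.seed,
                             config_hash(config), metrics, checks)
    return summary, records


def run_force_trial_experiment(config: RunConfig) -> tuple[MetricsSummary, dict]:
    cfg = _apply(att.AttenuationConfig(), config.params)
    trial = att.run_force_trial(cfg, seed=config.seed)
    out = att.outcome_metrics(trial)
    metrics = {
        "movement_amplitude_N": out.movement_amplitude,
        "illusion_N": out.illusion,
        "delusion_index_N": out.delusion_index,
        "delusion_present": out.delusion_present,
    }
    checks = {"finite_run": bool(np.all(np.isfinite(trial.record.free_energy)))}
    summary = MetricsSummary(config.experiment, config.seed,
                             config_hash(config), metrics, checks)
    return summary, {"trial": trial.record}


def run_force_matching_experiment(
    config: RunConfig,
) -> tuple[MetricsSummary, dict]:
    """Force matching under normal attenuation, failed attenuation, and
    failed attenuation with compensatory high-level precision."""
    p = dict(config.params)
    levels = p.pop("force_levels", (0.5, 1.0, 1.5, 2.0))
    base = _apply(att.AttenuationConfig(), p)
    pairs_n = att.force_matching(levels, gamma=6.0, boost=0.0,
                                 seed=config.seed, base_config=base)
    pairs_c = att.force_matching(levels, gamma=2.0, boost=4.0,
                                 seed=config.seed, base_config=base)
    t_norm = att.run_force_trial(replace(base, gamma=6.0), seed=config.seed)
    t_akin = att.run_force_trial(replace(base, gamma=2.0), seed=config.seed)
    t_comp = att.run_force_trial(
        replace(base, gamma=2.0, level_boost=4.0), seed=config.seed
    )
    m_norm = att.outcome_metrics(t_norm)
    m_comp = att.outcome_metrics(t_comp)
    move_n = m_norm.movement_amplitude
    move_a = float(np.max(t_akin.true_self_force))
    move_c = m_comp.movement_amplitude
    metrics = {
        "pairs_normal": [list(map(float, p_)) for p_ in pairs_n],
        "pairs_compensated": [list(map(float, p_)) for p_ in pairs_c],
        "movement_normal_N": move_n,
        "movement_failed_attenuation_N": move_a,
        "movement_compensated_N": move_c,
        "illusion_normal_N": m_norm.illusion,
        "illusion_compensated_N": m_comp.illusion,
        "delusion_index_N": m_comp.delusion_index,
    }
    checks = {
        "illusion_positive_at_all_levels": all(a > b for a, b in pairs_n),
        "akinesia": move_a < 0.25 * move_n,
        "compensation_restores_movement": abs(move_c - move_n) < 0.25 * move_n,
        "compensation_abolishes_illusion": (
            abs(m_comp.illusion) < 0.2 * abs(m_norm.illusion)
        ),
        "compensation_induces_delusion": (
            m_comp.delusion_present and m_comp.delusion_index < 0
        ),
        "no_delusion_under_normal_attenuation": not m_norm.delusion_present,
    }
    summary = MetricsSummary(config.experiment, config.seed,
                             config_hash(config), metrics, checks)
    return summary, {"normal": t_norm.record, "failed": t_akin.record,
                     "compensated": t_comp.record}


_DRIVERS = {
    "birdsong": run_birdsong_experiment,
    "pursuit": run_pursuit_experiment,
    "force-trial": run_force_trial_experiment,
    "force-matching": run_force_matching_experiment,
}


def run_experiment(config: RunConfig) -> MetricsSummary:
    """Run one experiment; export tables and summary if out_dir is set."""
    summary, records = _DRIVERS[config.experiment](config)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, rec in records.items():
            df = rec.to_frame()
            df.to_csv(out / f"{config.experiment}_{name}.csv", index=False)
        (out / "summary.yaml").write_text(summary.to_text())
        (out / "config.yaml").write_text(
            yaml.safe_dump(
                {**resolved_config(config), "config_hash": summary.config_hash},
                sort_keys=False, default_flow_style=False,
            )
        )
        log.info("wrote outputs to %s", out)
    return summary


# --------------------------------------------------------------------------
# gradient validation
# --------------------------------------------------------------------------


def random_model(
    rng: np.random.Generator,
    n_levels: int | None = None,
    state_dependent: bool = True,
) -> HierarchicalModel:
    """A random small hierarchical model (dims <= 3, tanh nonlinearities)."""
    if n_levels is None:
        n_levels = int(rng.integers(1, 3))
    levels = []
    out_dim_below = int(rng.integers(1, 4))  # sensory dimension
    for i in range(n_levels):
        n_x = int(rng.integers(1, 4))
        n_v = int(rng.integers(1, 3))

        def make(n_in_x, n_in_v, n_out):
            W1 = rng.normal(size=(n_out, n_in_x)) * 0.6
            W2 = rng.normal(size=(n_out, n_in_v)) * 0.6
            b = rng.normal(size=n_out) * 0.3
            return lambda x, v: np.tanh(W1 @ x + W2 @ v + b)

        lv = LevelSpec(
            n_x=n_x, n_v=n_v, out_dim=out_dim_below,
            flow=make(n_x, n_v, n_x), output=make(n_x, n_v, out_dim_below),
            log_precision_x=float(rng.uniform(-1, 1)),
            log_precision_v=float(rng.uniform(-1, 1)),
        )
        if state_dependent and rng.random() < 0.7:
            w = rng.normal(size=n_x) * 0.5
            base = float(rng.uniform(-0.5, 0.5))
            dim = lv.out_dim
            lv.log_precision_v = (
                lambda x, v, w=w, base=base, dim=dim: base
                + 0.8 * np.tanh(w @ x) * np.ones(dim)
            )
        levels.append(lv)
        out_dim_below = n_v
    prior = constant_prior(rng.normal(size=levels[-1].n_v) * 0.5,
                           float(rng.uniform(-1, 1)))
    return HierarchicalModel(
        levels, n_orders=int(rng.integers(2, 4)), d_orders=2, prior=prior
    )


def random_process(rng: np.random.Generator, n_s: int) -> GenerativeProcess:
    """A random toy process with one action channel, for action checks."""
    n_x = int(rng.integers(1, 3))
    Wx = rng.normal(size=(n_x, n_x)) * 0.4
    Wa = rng.normal(size=(n_x, 1)) * 0.8
    G = rng.normal(size=(n_s, n_x)) * 0.6
    Ga = rng.normal(size=(n_s, 1)) * 0.5
    return GenerativeProcess(
        n_x=n_x, n_s=n_s, n_a=1,
        flow=lambda x, v, a: -x + np.tanh(Wx @ x) + Wa @ np.atleast_1d(a),
        output=lambda x, v, a: G @ x + Ga @ np.atleast_1d(a),
    )


def gradient_check(seed: int = 0, n_models: int = 20) -> dict:
    """Compare the assembled recognition/action flows against central
    finite differences of the free energy over random small models.

    Returns the worst relative discrepancies and the per-model worst term
    (state, cause or action block).
    """
    rng = np.random.default_rng(seed)
    worst_rec, worst_act = 0.0, 0.0
    reports = []
    for k in range(n_models):
        model = random_model(rng)
        mu = PosteriorState(model, rng.normal(size=model.n_flat) * 0.5)
        s = rng.normal(size=(model.levels[0].out_dim, model.d_orders))
        grad = free_energy_gradient(model, mu, s, 0.0)
        fd = np.zeros_like(grad)
        for j in range(grad.size):
            h = 1e-5 * max(1.0, abs(mu.flat[j]))
            up = mu.flat.copy(); up[j] += h
            dn = mu.flat.copy(); dn[j] -= h
            fd[j] = (
                free_energy(model, PosteriorState(model, up), s)
                - free_energy(model, PosteriorState(model, dn), s)
            ) / (2 * h)
        scale = max(1e-9, float(np.max(np.abs(fd))))
        err = np.abs(grad - fd) / scale
        rec_err = float(np.max(err))
        worst_rec = max(worst_rec, rec_err)
        labels = model.order0_labels()
        worst_idx = int(np.argmax(err))
        worst_term = "x" if any(
            sl.start <= worst_idx < sl.start + lv.n_x * model.n_orders
            for (sl, _), lv in zip(model.block_slices(), model.levels)
        ) else "v"

        # action: toy process whose sensations depend on action
        proc = random_process(rng, model.levels[0].out_dim)
        x_p = rng.normal(size=proc.n_x) * 0.5
        a = rng.normal(size=1) * 0.3
        d = model.d_orders

        def F_of_a(aa):
            s_t = proc.sensations_tilde(x_p, np.zeros(0), np.atleast_1d(aa), d)
            return free_energy(model, mu, s_t)

        h = 1e-5
        fd_a = (F_of_a(a[0] + h) - F_of_a(a[0] - h)) / (2 * h)
        s_t = proc.sensations_tilde(x_p, np.zeros(0), a, d)
        errors = compute_errors(model, mu, s_t)
        from .engine import action_flow

        adot = action_flow(proc, errors, x_p, np.zeros(0), a, d)
        act_err = abs(adot[0] + fd_a) / max(1e-9, abs(fd_a))
        worst_act = max(worst_act, float(act_err))
        reports.append(
            {"model": k, "recognition_rel_err": rec_err,
             "action_rel_err": float(act_err), "worst_term": worst_term}
        )
    return {
        "n_models": n_models,
        "max_recognition_rel_err": worst_rec,
        "max_action_rel_err": worst_act,
        "models": reports,
    }
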