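"""Birdsong perception with coupled Lorenz attractors: omission responses,
oddball attenuation and hallucinosis under different precision regimes.

A slow Lorenz attractor (one cycle per song) delivers two control
parameters -- the Rayleigh and Prandtl numbers -- to a fast Lorenz
attractor whose states drive a synthetic syrinx, producing chirps with
frequencies between 2 and 5 kHz roughly every second.  The agent inverts
the same two-level model from a two-channel summary of the sonogram
(amplitude, and amplitude-weighted frequency), recovering the hidden
states and the slowly varying control parameters.

Precision regimes (sensory, level-1 states, level-2):
  (2, 8, 16)  -- normal: omitting the last chirps elicits a vigorous
                 omission response (the analogue of violation potentials);
  (2, 8, 2)   -- weak top-down precision: the omission response is
                 attenuated and ordinary chirps become surprising
                 (trait-like loss of mismatch responses);
  (-2, 8, 2)  -- compensatory loss of sensory precision: predictions
                 detach from the input and persist after the song ends
                 (hallucinosis), with low-amplitude weighted errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .engine import (
    GenerativeProcess,
    HierarchicalModel,
    LevelSpec,
    PosteriorState,
    SimulationRecord,
    run_closed_loop,
)
from .gencoords import RoughnessModel, smooth_noise

FREQ_CENTER_KHZ = 3.5  # center of the 2-5 kHz syrinx range


@dataclass
class LorenzParams:
    prandtl: float = 10.0
    rayleigh: float = 28.0
    beta: float = 8.0 / 3.0
    rate: float = 1.0  # time scaling of the flow (per bin)

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")


def lorenz_flow(x: np.ndarray, params: LorenzParams) -> np.ndarray:
    """Classical Lorenz equations, scaled by ``params.rate``."""
    s, r, b = params.prandtl, params.rayleigh, params.beta
    return params.rate * np.array(
        [s * (x[1] - x[0]), x[0] * (r - x[2]) - x[1], x[0] * x[1] - b * x[2]]
    )


def lorenz_jacobian(x: np.ndarray, params: LorenzParams) -> np.ndarray:
    s, r, b = params.prandtl, params.rayleigh, params.beta
    return params.rate * np.array(
        [[-s, s, 0.0], [r - x[2], -1.0, -x[0]], [x[1], x[0], -b]]
    )


@dataclass
class BirdsongConfig:
    bin_ms: float = 16.0
    fast_rate: float = 0.0135  # Lorenz time units per bin (~1 chirp/s)
    slow_rate_ratio: float = 5.5  # fast rate / slow rate (one song per cycle)
    duration: int = 320  # bins (~5.1 s, roughly one slow cycle)
    # syrinx maps
    amp_threshold: float = 10.0  # |x1| above which the syrinx sounds
    amp_gain: float = 0.35
    amp_softness: float = 0.4  # softplus sharpness of the rectifier
    freq_center_state: float = 27.0  # x3 value mapped to mid frequency
    freq_width_state: float = 8.0
    # control parametrization: the hidden causes v(1) are dimensionless;
    # the level-1 flow squashes gain*v into the admissible (Rayleigh,
    # Prandtl) box, so the box is respected for any drift of the causes
    rayleigh_center: float = 28.5
    rayleigh_span: float = 3.5
    prandtl_span: float = 1.5
    control_gain: float = 32.0
    # precisions (sensory, level-1 states, level-2 states and causes)
    log_precisions: tuple = (2.0, 8.0, 16.0)
    noise_log_precision_states: float = 12.0
    chirp_threshold: float = 0.2  # fraction of max amplitude
    chirp_min_bins: int = 3


def control_map(y: np.ndarray, config: BirdsongConfig) -> np.ndarray:
    """Slow-attractor states -> dimensionless control causes (monotone affine).

    Composed with :func:`params_from_causes` this sends the slow attractor
    mean to the canonical chaotic pair and stays in the admissible box for
    any excursion.
    """
    g = config.control_gain
    return np.array([y[0] / (15.0 * g), y[1] / (20.0 * g)])


def control_map_jacobian(y: np.ndarray, config: BirdsongConfig) -> np.ndarray:
    g = config.control_gain
    J = np.zeros((2, 3))
    J[0, 0] = 1.0 / (15.0 * g)
    J[1, 1] = 1.0 / (20.0 * g)
    return J


def params_from_causes(v: np.ndarray, config: BirdsongConfig) -> np.ndarray:
    """Dimensionless causes -> (rayleigh, prandtl), squashed into the box."""
    g = config.control_gain
    return np.array(
        [
            config.rayleigh_center + config.rayleigh_span * np.tanh(g * v[0]),
            10.0 + config.prandtl_span * np.tanh(g * v[1]),
        ]
    )


def params_jacobian(v: np.ndarray, config: BirdsongConfig) -> np.ndarray:
    """d(rayleigh, prandtl)/dv, diagonal."""
    g = config.control_gain
    return np.diag(
        [
            config.rayleigh_span * g * (1 - np.tanh(g * v[0]) ** 2),
            config.prandtl_span * g * (1 - np.tanh(g * v[1]) ** 2),
        ]
    )


def _softplus(z):
    return np.logaddexp(0.0, z)


def syrinx(x: np.ndarray, config: BirdsongConfig) -> tuple[float, float]:
    """Fast-attractor states -> (frequency kHz, amplitude).

    Amplitude is a rectified function of the first state's excursion (so
    the syrinx sounds once per attractor orbit); frequency is an affine
    map of the third state squashed into the 2-5 kHz range.
    """
    r = np.sqrt(x[0] ** 2 + 1.0)
    k = config.amp_softness
    amp = config.amp_gain * _softplus(k * (r - config.amp_threshold)) / k
    freq = 3.5 + 1.5 * np.tanh(
        (x[2] - config.freq_center_state) / config.freq_width_state
    )
    return float(freq), float(amp)


def sensory_map(freq, amp) -> np.ndarray:
    """Two sonogram summary channels: energy and energy-weighted frequency.

    Both vanish in silence, so omitting a chirp simply zeroes the input.
    """
    freq = np.asarray(freq, float)
    amp = np.asarray(amp, float)
    return np.stack([amp, amp * (freq - FREQ_CENTER_KHZ)])


@dataclass
class SongStimulus:
    """A synthesized song: per-bin frequency/amplitude plus annotations."""

    frequency: np.ndarray  # kHz
    amplitude: np.ndarray  # arbitrary units >= 0
    chirps: list  # (onset, offset) bin intervals, ordered
    bin_ms: float = 16.0
    true_fast: Optional[np.ndarray] = None  # (T, 3) generator states
    true_slow: Optional[np.ndarray] = None  # (T, 3)
    true_controls: Optional[np.ndarray] = None  # (T, 2) rayleigh/prandtl
    seed: Optional[int] = None

    @property
    def n_bins(self) -> int:
        return self.amplitude.size

    def channels(self) -> np.ndarray:
        """(2, T) sensory summary channels."""
        return sensory_map(self.frequency, self.amplitude)


def annotate_chirps(
    amplitude: np.ndarray, threshold_frac: float = 0.2, min_bins: int = 3
) -> list[tuple[int, int]]:
    """Chirp intervals by amplitude thresholding (fraction of the maximum)."""
    if np.max(amplitude) <= 0:
        return []
    above = amplitude > threshold_frac * np.max(amplitude)
    chirps, start = [], None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_bins:
                chirps.append((start, i))
            start = None
    if start is not None and len(above) - start >= min_bins:
        chirps.append((start, len(above)))
    return chirps


def generate_song(
    duration: int | None = None,
    rng_seed: int = 0,
    config: BirdsongConfig | None = None,
    burn_in: int = 200,
) -> SongStimulus:
    """Synthesize one song: a cycle of the slow attractor driving the fast
    attractor through the syrinx.  Deterministic for a fixed seed."""
    if config is None:
        config = BirdsongConfig()
    if duration is None:
        duration = config.duration
    slow_rate = config.fast_rate / config.slow_rate_ratio
    slow = LorenzParams(rate=slow_rate)
    T = duration + burn_in
    ss = np.random.SeedSequence(rng_seed)
    sx, sy = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2)]
    w_fast = smooth_noise(sx, T, config.noise_log_precision_states,
                          RoughnessModel(), dim=3)
    w_slow = smooth_noise(sy, T, config.noise_log_precision_states,
                          RoughnessModel(), dim=3)

    # settle both attractors onto their wings before the song starts: the
    # slow system is integrated in its own time (deterministically, with a
    # small seeded perturbation so different seeds give different songs)
    rng = np.random.default_rng(int(ss.generate_state(1)[0] % 2**31))
    x = np.array([1.0, 1.0, 25.0])
    y = np.array([8.0, 10.0, 27.0]) + 0.5 * rng.standard_normal(3)
    unit = LorenzParams()
    for _ in range(3000):
        y = y + 0.005 * lorenz_flow(y, unit)
    n_sub = 4
    freq = np.zeros(duration)
    amp = np.zeros(duration)
    fast = np.zeros((duration, 3))
    slow_rec = np.zeros((duration, 3))
    controls = np.zeros((duration, 2))
    for t in range(T):
        if t >= burn_in:
            i = t - burn_in
            f, a = syrinx(x, config)
            freq[i], amp[i] = f, a
            fast[i] = x
            slow_rec[i] = y
            controls[i] = params_from_causes(control_map(y, config), config)
        ctrl = params_from_causes(control_map(y, config), config)
        fast_params = LorenzParams(
            prandtl=ctrl[1], rayleigh=ctrl[0], rate=config.fast_rate
        )
        for _ in range(n_sub):
            x = x + (lorenz_flow(x, fast_params) + w_fast[:, t]) / n_sub
            y = y + (lorenz_flow(y, slow) + w_slow[:, t]) / n_sub
    chirps = annotate_chirps(amp, config.chirp_threshold, config.chirp_min_bins)
    return SongStimulus(
        frequency=freq, amplitude=amp, chirps=chirps, bin_ms=config.bin_ms,
        true_fast=fast, true_slow=slow_rec, true_controls=controls,
        seed=rng_seed,
    )


def omit_chirps(stimulus: SongStimulus, k: int) -> SongStimulus:
    """Silence the stimulus from the onset of the k-th-from-last chirp.

    Earlier bins are bit-identical; annotations are recomputed.
    """
    if k < 0 or k > len(stimulus.chirps):
        raise ValueError(f"cannot omit {k} of {len(stimulus.chirps)} chirps")
    if k == 0:
        return stimulus
    cut = stimulus.chirps[-k][0]
    amp = stimulus.amplitude.copy()
    amp[cut:] = 0.0
    return SongStimulus(
        frequency=stimulus.frequency.copy(), amplitude=amp,
        chirps=[c for c in stimulus.chirps if c[1] <= cut],
        bin_ms=stimulus.bin_ms, true_fast=stimulus.true_fast,
        true_slow=stimulus.true_slow, true_controls=stimulus.true_controls,
        seed=stimulus.seed,
    )


def sonogram(
    frequency: np.ndarray,
    amplitude: np.ndarray,
    freq_grid: np.ndarray | None = None,
    bandwidth_khz: float = 0.15,
) -> np.ndarray:
    """Time-frequency intensity image: a Gaussian ridge at each bin's
    frequency, scaled by its amplitude.  Rows are the frequency grid."""
    if freq_grid is None:
        freq_grid = np.linspace(2.0, 5.0, 64)
    ridge = np.exp(
        -((freq_grid[:, None] - frequency[None, :]) ** 2) / (2 * bandwidth_khz**2)
    )
    return ridge * np.asarray(amplitude)[None, :]


# --------------------------------------------------------------------------
# recognition
# --------------------------------------------------------------------------


def build_playback_process(
    stimulus: SongStimulus, sensory_noise_log_precision: float
) -> GenerativeProcess:
    """Stimulus playback: sensations are the recorded channels plus noise."""
    ch = stimulus.channels()
    T = stimulus.n_bins

    def cause(t):
        i = min(max(int(round(t)), 0), T - 1)
        return ch[:, i]

    return GenerativeProcess(
        n_x=0, n_s=2, n_a=0, n_v=2,
        output=lambda x, v, a: np.asarray(v, float),
        cause=cause,
        noise_log_precision_s=sensory_noise_log_precision,
        jac={"gv": lambda x, v, a: np.eye(2)},
    )


def build_birdsong_model(
    config: BirdsongConfig, log_precisions: Sequence[float] | None = None
) -> HierarchicalModel:
    """Two-level model: fast attractor under slowly varying controls."""
    if log_precisions is None:
        log_precisions = config.log_precisions
    pi_s, pi_x1, pi_2 = log_precisions

    def flow1(x, v):
        ray, pr = params_from_causes(v, config)
        p = LorenzParams(prandtl=pr, rayleigh=ray, rate=config.fast_rate)
        return lorenz_flow(x, p)

    def fx1(x, v):
        ray, pr = params_from_causes(v, config)
        p = LorenzParams(prandtl=pr, rayleigh=ray, rate=config.fast_rate)
        return lorenz_jacobian(x, p)

    def fv1(x, v):
        dparams = config.fast_rate * np.array(
            [[0.0, x[1] - x[0]], [x[0], 0.0], [0.0, 0.0]]
        )[:, ::-1]  # columns (rayleigh, prandtl)
        return dparams @ params_jacobian(v, config)

    def output1(x, v):
        f, a = syrinx(x, config)
        return np.array([a, a * (f - FREQ_CENTER_KHZ)])

    lv1 = LevelSpec(
        n_x=3, n_v=2, out_dim=2,
        flow=flow1, output=output1,
        log_precision_x=pi_x1, log_precision_v=pi_s,
        jac={"fx": fx1, "fv": fv1},
    )

    slow = LorenzParams(rate=config.fast_rate / config.slow_rate_ratio)
    lv2 = LevelSpec(
        n_x=3, n_v=0, out_dim=2,
        flow=lambda x, v: lorenz_flow(x, slow),
        output=lambda x, v: control_map(x, config),
        log_precision_x=pi_2, log_precision_v=pi_2,
        jac={
            "fx": lambda x, v: lorenz_jacobian(x, slow),
            "gx": lambda x, v: control_map_jacobian(x, config),
        },
    )
    return HierarchicalModel([lv1, lv2], n_orders=4, d_orders=2)


def initial_posterior(
    model: HierarchicalModel, stimulus: SongStimulus, config: BirdsongConfig
) -> np.ndarray:
    """Start the filter on the generator's trajectory (states and controls)."""
    post = PosteriorState.zeros(model)
    if stimulus.true_fast is not None:
        x1 = np.zeros((3, model.n_orders))
        x1[:, 0] = stimulus.true_fast[0]
        x1[:, 1] = lorenz_flow(
            stimulus.true_fast[0],
            LorenzParams(
                prandtl=stimulus.true_controls[0][1],
                rayleigh=stimulus.true_controls[0][0],
                rate=config.fast_rate,
            ),
        )
        post.set_mu_x(0, x1)
        v1 = np.zeros((2, model.d_orders))
        if stimulus.true_slow is not None:
            v1[:, 0] = control_map(stimulus.true_slow[0], config)
        post.set_mu_v(0, v1)
    if stimulus.true_slow is not None:
        slow = LorenzParams(rate=config.fast_rate / config.slow_rate_ratio)
        x2 = np.zeros((3, model.n_orders))
        x2[:, 0] = stimulus.true_slow[0]
        x2[:, 1] = lorenz_flow(stimulus.true_slow[0], slow)
        post.set_mu_x(1, x2)
    return post.flat


def run_birdsong(
    stimulus: SongStimulus,
    log_precisions: Sequence[float] = (2.0, 8.0, 16.0),
    seed: int = 0,
    config: BirdsongConfig | None = None,
) -> SimulationRecord:
    """Perception-only closed loop on a (possibly omission-edited) song."""
    if config is None:
        config = BirdsongConfig()
    process = build_playback_process(stimulus, log_precisions[0])
    model = build_birdsong_model(config, log_precisions)
    rec = run_closed_loop(
        process, model, duration=stimulus.n_bins, rng_seed=seed,
        mu0=initial_posterior(model, stimulus, config),
        metadata={
            "experiment": "birdsong", "bin_ms": config.bin_ms,
            "log_precisions": tuple(log_precisions),
            "stimulus": stimulus, "config": config,
        },
    )
    return rec


def predicted_channels(record: SimulationRecord) -> np.ndarray:
    """(2, T) sensory predictions g(mu) along the recognition trajectory."""
    config: BirdsongConfig = record.metadata["config"]
    out = np.zeros((2, record.n_bins))
    for t in range(record.n_bins):
        x = np.array([record.mu_x0(0, c)[t] for c in range(3)])
        f, a = syrinx(x, config)
        out[:, t] = [a, a * (f - FREQ_CENTER_KHZ)]
    return out


def predicted_sonogram(record: SimulationRecord, **kw) -> np.ndarray:
    """Sonogram image of the agent's percept (predictions of the syrinx)."""
    config: BirdsongConfig = record.metadata["config"]
    T = record.n_bins
    freq = np.zeros(T)
    amp = np.zeros(T)
    for t in range(T):
        x = np.array([record.mu_x0(0, c)[t] for c in range(3)])
        freq[t], amp[t] = syrinx(x, config)
    return sonogram(freq, amp, **kw)


def sensory_xi_magnitude(record: SimulationRecord) -> np.ndarray:
    """|xi| at the sensory level per bin (norm over channels, order 0)."""
    xi = record.xi[(0, "v")]  # (T, 2 * d), order-major
    return np.linalg.norm(xi[:, :2], axis=1)


@dataclass
class OmissionMetrics:
    chirp_peaks: list  # peak |xi_s| in each presented-chirp window
    omitted_peaks: list  # peak |xi_s| in each omitted-chirp window
    post_song_peak: float
    mean_xi: float
    oddball_contrast: float  # omission peak minus third-chirp peak
    windows: dict


def omission_metrics(
    record: SimulationRecord,
    original: SongStimulus,
    omitted: int,
    margin: int = 6,
) -> OmissionMetrics:
    """Peak weighted sensory prediction error per chirp window.

    Windows are taken from the *original* annotations: presented chirps,
    omitted chirps (where the response to the violation appears), and the
    stretch after the original song ends.
    """
    mag = sensory_xi_magnitude(record)
    T = mag.size
    chirps = original.chirps
    presented = chirps[: len(chirps) - omitted]
    omitted_w = chirps[len(chirps) - omitted :]

    def peak(win):
        a, b = max(0, win[0] - 2), min(T, win[1] + margin)
        return float(np.max(mag[a:b])) if b > a else 0.0

    chirp_peaks = [peak(w) for w in presented]
    omitted_peaks = [peak(w) for w in omitted_w]
    post_start = (chirps[-1][1] + margin) if chirps else 0
    post_peak = float(np.max(mag[post_start:])) if post_start < T else 0.0
    third = chirp_peaks[2] if len(chirp_peaks) >= 3 else float("nan")
    contrast = (omitted_peaks[0] - third) if omitted_peaks else float("nan")
    return OmissionMetrics(
        chirp_peaks=chirp_peaks, omitted_peaks=omitted_peaks,
        post_song_peak=post_peak, mean_xi=float(np.mean(mag)),
        oddball_contrast=float(contrast),
        windows={"presented": presented, "omitted": omitted_w,
                 "post_song_start": post_start},
    )


def hallucinosis_metrics(
    record: SimulationRecord, presented: SongStimulus, margin: int = 10
) -> dict:
    """Predicted amplitude persistence after the presented stimulus ends.

    ``presented`` is the stimulus the agent actually heard (for an
    omission run, the truncated song); persistence of the percept into the
    ensuing silence is the signature of hallucinosis.
    """
    pred = predicted_channels(record)[0]
    last_off = presented.chirps[-1][1] if presented.chirps else 0
    start = presented.chirps[0][0] if presented.chirps else 0
    within = float(np.mean(pred[start:last_off]))
    post = pred[min(last_off + margin, pred.size - 1) :]
    return {
        "within_song_mean_amplitude": within,
        "post_song_mean_amplitude": float(np.mean(post)) if post.size else 0.0,
        "mean_xi": float(np.mean(sensory_xi_magnitude(record))),
    }
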