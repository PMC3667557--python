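"""Shared fixtures and independent numerical oracles.

The oracles here (central finite differences, a textbook Kalman filter,
brute-force scans over exported tables) are deliberately written straight
from their definitions, independent of the package's implementation path.
"""

from __future__ import annotations

import numpy as np
import pytest


def central_diff(f, x0: float, h: float = 1e-5) -> float:
    """Plain central finite difference of a scalar function."""
    return (f(x0 + h) - f(x0 - h)) / (2 * h)


def fd_gradient(f, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central finite-difference gradient of a scalar field."""
    g = np.zeros_like(x, dtype=float)
    for j in range(x.size):
        hj = h * max(1.0, abs(x[j]))
        up, dn = x.copy(), x.copy()
        up[j] += hj
        dn[j] -= hj
        g[j] = (f(up) - f(dn)) / (2 * hj)
    return g


def kalman_filter_1d(y: np.ndarray, A: float, Q: float, R: float,
                     x0: float = 0.0, P0: float = 1.0) -> np.ndarray:
    """Textbook scalar Kalman filter; returns filtered means."""
    xh, P = x0, P0
    means = np.empty_like(y, dtype=float)
    for k, obs in enumerate(y):
        K = P / (P + R)
        xh = xh + K * (obs - xh)
        P = (1 - K) * P
        means[k] = xh
        xh = A * xh
        P = A * A * P + Q
    return means


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


# ---- expensive shared simulation records (built once per session) --------


@pytest.fixture(scope="session")
def pursuit_occlusion_records():
    """Occluded pursuit at normal (-1) and reduced (-1.25) precision."""
    from actinf.pursuit import run_pursuit

    return {
        -1.0: run_pursuit("occlusion", -1.0, seed=0),
        -1.25: run_pursuit("occlusion", -1.25, seed=0),
    }


@pytest.fixture(scope="session")
def pursuit_reversal_records():
    from actinf.pursuit import run_pursuit

    return {
        -1.0: run_pursuit("reversal", -1.0, seed=0),
        -1.25: run_pursuit("reversal", -1.25, seed=0),
    }


@pytest.fixture(scope="session")
def birdsong_regimes():
    """Default song, three precision regimes on the omission-edited song."""
    from actinf.birdsong import generate_song, omit_chirps, run_birdsong

    song = generate_song(rng_seed=0)
    edited = omit_chirps(song, 3)
    records = {
        name: run_birdsong(edited, lp, seed=0)
        for name, lp in [
            ("normal", (2.0, 8.0, 16.0)),
            ("low_level2", (2.0, 8.0, 2.0)),
            ("low_sensory", (-2.0, 8.0, 2.0)),
        ]
    }
    return song, edited, records


@pytest.fixture(scope="session")
def force_suite():
    """Force trials for the three attenuation conditions plus an external
    force trial, all with bands."""
    from dataclasses import replace

    import numpy as np

    from actinf.attenuation import AttenuationConfig, run_force_trial

    base = AttenuationConfig()
    normal = run_force_trial(base, seed=0)
    failed = run_force_trial(replace(base, gamma=2.0), seed=0)
    comp = run_force_trial(replace(base, gamma=2.0, level_boost=4.0), seed=0)
    m6 = float(np.max(normal.true_self_force))
    external = run_force_trial(replace(base, external_force=m6), seed=0)
    return {"normal": normal, "failed": failed, "compensated": comp,
            "external": external}
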