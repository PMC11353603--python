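"""Deterministic unit-sphere direction sets and Watson-distribution quadrature.

All orientation averaging in the package (phantom signal generation, NODDI
fitting, kurtosis scalarization) runs over deterministic spherical Fibonacci
lattices so that results are exactly reproducible without seeded Monte Carlo.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "fibonacci_sphere",
    "watson_weights",
    "rotation_to",
    "odi_from_kappa",
    "kappa_from_odi",
]

_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0


def fibonacci_sphere(n: int) -> np.ndarray:
    """Return ``n`` near-uniform unit vectors on S² (spherical Fibonacci lattice).

    Deterministic given ``n``. Points are returned as an ``(n, 3)`` array of
    unit vectors.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n, dtype=float)
    # offset 0.5 avoids poles; longitude advances by the golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = 2.0 * np.pi * i / _GOLDEN
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def watson_weights(dirs: np.ndarray, mu: np.ndarray, kappa: float) -> np.ndarray:
    """Discrete Watson-distribution weights on a direction set.

    The Watson density on the sphere is proportional to ``exp(kappa (mu·x)²)``
    (antipodally symmetric; ``kappa >= 0`` concentrates around ±mu).  Weights
    are evaluated at ``dirs`` and renormalized to sum to 1, so they act as a
    quadrature rule for orientation averages.  ``kappa = inf`` returns a delta
    at the direction closest to ``mu``.
    """
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    c2 = (dirs @ mu) ** 2
    if np.isinf(kappa):
        w = np.zeros(len(dirs))
        w[np.argmax(c2)] = 1.0
        return w
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    logw = kappa * c2
    logw -= logw.max()  # overflow guard
    w = np.exp(logw)
    return w / w.sum()


def rotation_to(target: np.ndarray) -> np.ndarray:
    """Rotation matrix taking the +z axis onto unit vector ``target``."""
    t = np.asarray(target, dtype=float)
    t = t / np.linalg.norm(t)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, t)
    c = float(z @ t)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def odi_from_kappa(kappa: float) -> float:
    """Orientation dispersion index ODI = (2/π)·arctan(1/κ); ODI(∞)=0, ODI(0)=1."""
    if np.isinf(kappa):
        return 0.0
    if kappa <= 0:
        return 1.0
    return float(2.0 / np.pi * np.arctan(1.0 / kappa))


def kappa_from_odi(odi: float) -> float:
    """Inverse of :func:`odi_from_kappa` on (0, 1]."""
    if not 0.0 < odi <= 1.0:
        raise ValueError("ODI must be in (0, 1]")
    if odi == 1.0:
        return 0.0
    return float(1.0 / np.tan(np.pi * odi / 2.0))
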