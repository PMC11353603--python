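"""Diffusion tensor and diffusion kurtosis estimation.

Both fits are two-pass weighted least squares on the log-signal: an ordinary
LS pass provides predicted signals, whose squares become the weights of the
second pass (the standard variance-stabilizing WLS for log-linearized
diffusion models).

The tensor is fitted from the b ≤ 1000 s/mm² volumes only, since the
mono-exponential tensor representation breaks down at high b; the kurtosis
fit uses every shell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import DWIDataset, GradientScheme, ScalarMap
from .orientations import fibonacci_sphere

__all__ = [
    "TensorFit",
    "KurtosisFit",
    "fit_dti",
    "dti_scalars",
    "fit_dki",
    "dki_scalars",
    "tensor_eigs",
]

#: Tensor element order used everywhere: xx, yy, zz, xy, xz, yz.
TENSOR_ORDER = ("xx", "yy", "zz", "xy", "xz", "yz")

#: Apparent-kurtosis clamp applied before scalarization.
K_CLAMP = (0.0, 10.0)

#: Direction set for MK averaging.
N_MK_DIRS = 256
#: In-plane directions for RK averaging.
N_RK_DIRS = 64

#: 15 unique quartic index combinations (i<=j<=k<=l) with multiplicities.
_W_IDX = [
    (0, 0, 0, 0), (1, 1, 1, 1), (2, 2, 2, 2),
    (0, 0, 0, 1), (0, 0, 0, 2), (0, 1, 1, 1), (1, 1, 1, 2), (0, 2, 2, 2), (1, 2, 2, 2),
    (0, 0, 1, 1), (0, 0, 2, 2), (1, 1, 2, 2),
    (0, 0, 1, 2), (0, 1, 1, 2), (0, 1, 2, 2),
]


def _quartic_multiplicity(idx: tuple[int, int, int, int]) -> int:
    from math import factorial
    counts = [idx.count(i) for i in set(idx)]
    m = factorial(4)
    for c in counts:
        m //= factorial(c)
    return m


_W_MULT = np.array([_quartic_multiplicity(i) for i in _W_IDX], dtype=float)


@dataclass
class TensorFit:
    """Per-voxel symmetric diffusion tensor (order xx, yy, zz, xy, xz, yz)."""

    D: np.ndarray            # (..., 6) mm²/s
    log_s0: np.ndarray       # (...,)
    residual_norm: np.ndarray
    valid: np.ndarray        # (...,) bool
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


@dataclass
class KurtosisFit:
    """Per-voxel tensor + dimensionless kurtosis tensor (15 unique W elements)."""

    D: np.ndarray            # (..., 6) mm²/s
    W: np.ndarray            # (..., 15) dimensionless
    log_s0: np.ndarray
    valid: np.ndarray
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def md(self) -> np.ndarray:
        return self.D[..., :3].mean(axis=-1)


def _tensor_design(b: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Columns: 1, −b gᵢgⱼ terms in TENSOR_ORDER (cross terms doubled)."""
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    cols = [
        np.ones_like(b),
        -b * gx * gx, -b * gy * gy, -b * gz * gz,
        -2 * b * gx * gy, -2 * b * gx * gz, -2 * b * gy * gz,
    ]
    return np.stack(cols, axis=1)


def _kurtosis_design(b: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Tensor design extended with (b²/6)·multiplicity·g-quartic columns.

    The 15 kurtosis columns carry the linear parameters MD²·W; W itself is
    recovered after the fit by dividing by the fitted MD².
    """
    X = _tensor_design(b, g)
    quartic = np.stack(
        [
            m * g[:, i] * g[:, j] * g[:, k] * g[:, l]
            for (i, j, k, l), m in zip(_W_IDX, _W_MULT)
        ],
        axis=1,
    )
    return np.concatenate([X, (b[:, None] ** 2 / 6.0) * quartic], axis=1)


def _wls_two_pass(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-pass WLS: OLS, then weights = squared predicted signal.

    ``y`` is log-signal with shape (n_voxel, n_vol). Returns (beta, resnorm).
    """
    pinv = np.linalg.pinv(X)
    beta = y @ pinv.T
    pred_log = beta @ X.T
    w = np.exp(2.0 * np.clip(pred_log, -50, 50))  # squared predicted signal
    n_vox, n_par = y.shape[0], X.shape[1]
    out = np.empty((n_vox, n_par))
    resnorm = np.empty(n_vox)
    for v in range(n_vox):
        Xw = X * w[v, :, None]
        A = X.T @ Xw
        bvec = Xw.T @ y[v]
        try:
            out[v] = np.linalg.solve(A, bvec)
        except np.linalg.LinAlgError:
            out[v] = beta[v]
        resnorm[v] = np.linalg.norm(X @ out[v] - y[v])
    return out, resnorm


def _masked_log_signal(
    dwi: DWIDataset, vol_idx: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Log signal for masked voxels; flags voxels with nonpositive signal."""
    sig = dwi.signal[..., vol_idx][mask]
    ok = np.all(sig > 0, axis=1)
    logs = np.full_like(sig, -np.inf)
    logs[ok] = np.log(sig[ok])
    return logs, ok


def fit_dti(
    dwi: DWIDataset,
    scheme: GradientScheme,
    mask: np.ndarray | None = None,
    b_max: float = 1000.0,
) -> TensorFit:
    """Two-pass WLS diffusion tensor fit on the b ≤ ``b_max`` volumes."""
    mask = dwi.mask if mask is None else np.asarray(mask, dtype=bool)
    use = scheme.bvals <= b_max + scheme.shell_tol
    b = scheme.bvals[use]
    g = scheme.bvecs[use]
    n_dirs = len(np.unique(np.round(g[b > scheme.shell_tol], 6), axis=0))
    if n_dirs < 6:
        raise ValueError("need >= 6 unique nonzero-b directions for a tensor fit")
    X = _tensor_design(b, g)
    y, ok = _masked_log_signal(dwi, np.where(use)[0], mask)
    y[~ok] = 0.0
    beta, resnorm = _wls_two_pass(X, y)

    shape = mask.shape
    D = np.zeros(shape + (6,))
    log_s0 = np.zeros(shape)
    rn = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)
    D[mask] = beta[:, 1:7]
    log_s0[mask] = beta[:, 0]
    rn[mask] = resnorm
    valid[mask] = ok
    return TensorFit(D, log_s0, rn, valid, mask, dwi.affine)


def tensor_eigs(D6: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and eigenvectors of 6-element tensors."""
    D6 = np.asarray(D6, dtype=float)
    lead = D6.shape[:-1]
    M = np.zeros(lead + (3, 3))
    M[..., 0, 0] = D6[..., 0]
    M[..., 1, 1] = D6[..., 1]
    M[..., 2, 2] = D6[..., 2]
    M[..., 0, 1] = M[..., 1, 0] = D6[..., 3]
    M[..., 0, 2] = M[..., 2, 0] = D6[..., 4]
    M[..., 1, 2] = M[..., 2, 1] = D6[..., 5]
    vals, vecs = np.linalg.eigh(M)
    # eigh sorts ascending; flip to descending λ1 >= λ2 >= λ3
    return vals[..., ::-1], vecs[..., :, ::-1]


def dti_scalars(fit: TensorFit) -> dict[str, ScalarMap]:
    """FA, MD, AD, RD from the tensor eigenvalues (clipped to ≥ 0)."""
    evals, _ = tensor_eigs(fit.D)
    evals = np.clip(evals, 0.0, None)
    md = evals.mean(axis=-1)
    ad = evals[..., 0]
    rd = evals[..., 1:].mean(axis=-1)
    num = np.linalg.norm(evals - md[..., None], axis=-1)
    den = np.linalg.norm(evals, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    fa = np.clip(fa, 0.0, 1.0)
    bad = ~(fit.mask & fit.valid)
    out = {}
    for name, vals, units in [
        ("FA", fa, ""), ("MD", md, "mm^2/s"), ("AD", ad, "mm^2/s"), ("RD", rd, "mm^2/s"),
    ]:
        v = vals.copy()
        v[bad] = np.nan
        out[name] = ScalarMap(v, name, units=units, affine=fit.affine)
    return out


def fit_dki(
    dwi: DWIDataset,
    scheme: GradientScheme,
    mask: np.ndarray | None = None,
) -> KurtosisFit:
    """Joint WLS kurtosis fit over all shells.

    Model: ``ln S = ln S0 − b·D(n) + (b²/6)·MD²·K(n)``; the 15 quartic
    coefficients are fitted linearly as MD²·W and rescaled by the fitted MD²
    afterwards (standard kurtosis-tensor parameterization).
    """
    mask = dwi.mask if mask is None else np.asarray(mask, dtype=bool)
    shells = scheme.shells()
    if len(shells) < 2:
        raise ValueError("kurtosis fit needs >= 2 nonzero shells")
    n_comb = sum(len(v) for v in shells.values())
    if n_comb < 21:
        raise ValueError("kurtosis fit needs >= 21 direction-shell combinations")
    X = _kurtosis_design(scheme.bvals, scheme.bvecs)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient kurtosis design (too few directions)")
    y, ok = _masked_log_signal(dwi, np.arange(len(scheme)), mask)
    y[~ok] = 0.0
    beta, _ = _wls_two_pass(X, y)

    D_flat = beta[:, 1:7]
    md = D_flat[:, :3].mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        W_flat = beta[:, 7:] / (md**2)[:, None]
    ok &= md > 0
    W_flat[~np.isfinite(W_flat).all(axis=1)] = 0.0

    shape = mask.shape
    D = np.zeros(shape + (6,))
    W = np.zeros(shape + (15,))
    log_s0 = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)
    D[mask] = D_flat
    W[mask] = W_flat
    log_s0[mask] = beta[:, 0]
    valid[mask] = ok
    return KurtosisFit(D, W, log_s0, valid, mask, dwi.affine)


def apparent_values(fit: KurtosisFit, dirs: np.ndarray, flat: bool = True):
    """Apparent diffusivity D(n) and clamped kurtosis K(n) on ``dirs``.

    Operates on the masked voxels (rows) against each direction (columns).
    ``K(n) = MD²/D(n)² · W(n)`` with W(n) the quartic form of the kurtosis
    tensor; clamped to ``K_CLAMP`` for noise robustness.
    """
    D = fit.D[fit.mask] if flat else fit.D
    W = fit.W[fit.mask] if flat else fit.W
    gx, gy, gz = dirs[:, 0], dirs[:, 1], dirs[:, 2]
    quad = np.stack([gx * gx, gy * gy, gz * gz, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz], axis=1)
    Dn = D @ quad.T  # (n_vox, n_dirs)
    quart = np.stack(
        [m * np.prod([dirs[:, ax] for ax in idx], axis=0)
         for idx, m in zip(_W_IDX, _W_MULT)],
        axis=1,
    )
    Wn = W @ quart.T
    md = D[:, :3].mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        Kn = (md**2)[:, None] * Wn / Dn**2
    Kn = np.clip(np.nan_to_num(Kn), *K_CLAMP)
    return Dn, Kn


def dki_scalars(fit: KurtosisFit) -> dict[str, ScalarMap]:
    """MK, AK, RK by deterministic direction averaging of K(n).

    MK averages K over a 256-point sphere set; AK evaluates K along the
    principal tensor eigenvector; RK averages over 64 directions equally
    spaced in the perpendicular plane. Near-degenerate tensors (λ1 ≈ λ2) get a
    fixed tie-break (eigenvector with largest |z|).
    """
    sphere = fibonacci_sphere(N_MK_DIRS)
    _, K_sphere = apparent_values(fit, sphere)
    mk_flat = K_sphere.mean(axis=1)

    evals, evecs = tensor_eigs(fit.D[fit.mask])
    e1 = evecs[..., :, 0]
    degenerate = (evals[..., 0] - evals[..., 1]) < 1e-6 * np.maximum(evals[..., 0], 1e-30)
    if np.any(degenerate):
        # tie-break: among the two leading eigenvectors pick the larger |z|
        e2 = evecs[degenerate][..., :, 1]
        pick = np.abs(e2[:, 2]) > np.abs(e1[degenerate][:, 2])
        e1_deg = e1[degenerate].copy()
        e1_deg[pick] = e2[pick]
        e1[degenerate] = e1_deg

    D = fit.D[fit.mask]
    W = fit.W[fit.mask]
    md = D[:, :3].mean(axis=1)
    n_vox = len(D)
    ak_flat = np.empty(n_vox)
    rk_flat = np.empty(n_vox)
    angles = np.linspace(0.0, np.pi, N_RK_DIRS, endpoint=False)
    for v in range(n_vox):
        axis = e1[v]
        # orthonormal frame around the principal axis
        helper = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(axis, helper)
        u /= np.linalg.norm(u)
        w_ = np.cross(axis, u)
        perp = np.cos(angles)[:, None] * u + np.sin(angles)[:, None] * w_
        dirs = np.vstack([axis[None, :], perp])
        sub = KurtosisFit(
            D=D[v : v + 1], W=W[v : v + 1], log_s0=md[v : v + 1],
            valid=np.ones(1, bool), mask=np.ones(1, bool), affine=fit.affine,
        )
        _, Kv = apparent_values(sub, dirs, flat=False)
        ak_flat[v] = Kv[0, 0]
        rk_flat[v] = Kv[0, 1:].mean()

    bad_flat = ~fit.valid[fit.mask]
    out = {}
    for name, flat_vals in [("MK", mk_flat), ("AK", ak_flat), ("RK", rk_flat)]:
        vol = np.full(fit.mask.shape, np.nan)
        vals = flat_vals.copy()
        vals[bad_flat] = np.nan
        vol[fit.mask] = vals
        out[name] = ScalarMap(vol, name, affine=fit.affine)
    return out
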