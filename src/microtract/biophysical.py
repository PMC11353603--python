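"""Biophysical microstructure models: WMTI, MC-SMT and NODDI.

* WMTI derives the axonal water fraction and extra-axonal diffusivities
  directly from the kurtosis fit (AWF = Kmax/(Kmax+3); the extra-axonal
  branch, De > Da, is reconstructed as a tensor).
* MC-SMT fits a two-compartment stick + tortuosity-zeppelin kernel to the
  per-shell spherical-mean signal, which is invariant to the fiber
  orientation distribution.
* NODDI fits a Watson-dispersed stick, a tortuosity-coupled extra-cellular
  zeppelin and an isotropic free-water ball to the full multi-shell signal,
  with the canonical fixed diffusivities (λ∥ = 1.7e-3, d_iso = 3.0e-3 mm²/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erf

from .io import DWIDataset, GradientScheme, ScalarMap
from .orientations import (
    fibonacci_sphere,
    kappa_from_odi,
    odi_from_kappa,
    rotation_to,
    watson_weights,
)
from .signal_models import KurtosisFit, TensorFit, apparent_values, tensor_eigs

__all__ = [
    "WMTIMetrics",
    "SMTFit",
    "NODDIFit",
    "wmti_from_dki",
    "spherical_mean",
    "fit_mcsmt",
    "fit_noddi",
    "stick_spherical_mean",
    "zeppelin_spherical_mean",
]

N_WMTI_DIRS = 256
N_NODDI_QUAD = 300

#: MC-SMT intrinsic-diffusivity bounds, mm²/s.
SMT_LAMBDA_BOUNDS = (1e-4, 3.05e-3)

#: NODDI fixed diffusivities, mm²/s.
NODDI_LAMBDA_PAR = 1.7e-3
NODDI_D_ISO = 3.0e-3


@dataclass
class WMTIMetrics:
    AWF: np.ndarray
    axEAD: np.ndarray
    radEAD: np.ndarray
    valid: np.ndarray
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def maps(self) -> dict[str, ScalarMap]:
        return _as_maps(
            {"AWF": (self.AWF, ""), "axEAD": (self.axEAD, "mm^2/s"),
             "radEAD": (self.radEAD, "mm^2/s")},
            self.mask, self.valid, self.affine,
        )


@dataclass
class SMTFit:
    INTRA: np.ndarray
    lam: np.ndarray  # intrinsic diffusivity, mm²/s
    valid: np.ndarray
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def EMD(self) -> np.ndarray:
        """Extra-axonal microscopic mean diffusivity λ(3 − 2v)/3, mm²/s."""
        return self.lam * (3.0 - 2.0 * self.INTRA) / 3.0

    @property
    def ETR(self) -> np.ndarray:
        """Extra-axonal microscopic transverse diffusivity λ(1 − v), mm²/s."""
        return self.lam * (1.0 - self.INTRA)

    def maps(self) -> dict[str, ScalarMap]:
        return _as_maps(
            {"INTRA": (self.INTRA, ""), "EMD": (self.EMD, "mm^2/s"),
             "ETR": (self.ETR, "mm^2/s")},
            self.mask, self.valid, self.affine,
        )


@dataclass
class NODDIFit:
    NDI: np.ndarray
    ODI: np.ndarray
    ISO: np.ndarray
    kappa: np.ndarray
    valid: np.ndarray
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def maps(self) -> dict[str, ScalarMap]:
        return _as_maps(
            {"NDI": (self.NDI, ""), "ODI": (self.ODI, ""), "ISO": (self.ISO, "")},
            self.mask, self.valid, self.affine,
        )


def _as_maps(named, mask, valid, affine) -> dict[str, ScalarMap]:
    out = {}
    for name, (vol, units) in named.items():
        v = np.array(vol, dtype=float, copy=True)
        v[~(mask & valid)] = np.nan
        out[name] = ScalarMap(v, name, units=units, affine=affine)
    return out


# ---------------------------------------------------------------------------
# WMTI

def wmti_from_dki(fit: KurtosisFit) -> WMTIMetrics:
    """White-matter tract integrity metrics from the kurtosis fit.

    Per voxel: AWF = max_n K(n)/(K(n)+3) over a 256-direction set; the
    directional extra-axonal diffusivity
    ``De(n) = D(n)·[1 + sqrt(K(n)·AWF / (3(1−AWF)))]`` is least-squares fitted
    with a symmetric tensor whose largest eigenvalue is axEAD and whose two
    remaining eigenvalues average to radEAD. Voxels with max K(n) ≤ 0 or
    AWF ≥ 0.999 are flagged invalid.
    """
    dirs = fibonacci_sphere(N_WMTI_DIRS)
    Dn, Kn = apparent_values(fit, dirs)
    kmax = Kn.max(axis=1)
    ok = fit.valid[fit.mask] & (kmax > 0)
    awf = kmax / (kmax + 3.0)
    ok &= awf < 0.999
    awf_safe = np.clip(awf, 0.0, 0.9989)

    with np.errstate(invalid="ignore", divide="ignore"):
        De = Dn * (1.0 + np.sqrt(Kn * awf_safe[:, None] / (3.0 * (1.0 - awf_safe[:, None]))))
    gx, gy, gz = dirs[:, 0], dirs[:, 1], dirs[:, 2]
    A = np.stack([gx * gx, gy * gy, gz * gz, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz], axis=1)
    pinv = np.linalg.pinv(A)
    De6 = De @ pinv.T
    evals, _ = tensor_eigs(De6)
    evals = np.clip(evals, 0.0, None)
    ax = evals[:, 0]
    rad = evals[:, 1:].mean(axis=1)

    shape = fit.mask.shape
    AWF = np.zeros(shape)
    axEAD = np.zeros(shape)
    radEAD = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)
    AWF[fit.mask] = awf_safe
    axEAD[fit.mask] = ax
    radEAD[fit.mask] = rad
    valid[fit.mask] = ok
    return WMTIMetrics(AWF, axEAD, radEAD, valid, fit.mask, fit.affine)


# ---------------------------------------------------------------------------
# MC-SMT

def spherical_mean(
    dwi: DWIDataset,
    scheme: GradientScheme,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-shell spherical-mean attenuation.

    Returns ``(shell_bvals, means, valid)`` where ``means`` has shape
    (n_masked_voxels, n_shells): the mean of S/S0 over each shell's
    directions, with S0 the mean of the b=0 volumes. Voxels with S0 ≤ 0 are
    flagged invalid.
    """
    mask = dwi.mask if mask is None else np.asarray(mask, dtype=bool)
    shells = scheme.shells()
    if len(shells) < 2:
        raise ValueError("spherical-mean fit needs >= 2 nonzero shells")
    sig = dwi.signal[mask]
    s0 = sig[:, scheme.b0_mask].mean(axis=1)
    ok = s0 > 0
    s0_safe = np.where(ok, s0, 1.0)
    shell_b = np.array(sorted(shells))
    means = np.stack(
        [sig[:, shells[b]].mean(axis=1) / s0_safe for b in shell_b], axis=1
    )
    return shell_b, means, ok


def stick_spherical_mean(b: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Closed-form orientation average of a stick: √π·erf(√(bλ))/(2√(bλ))."""
    x = np.sqrt(np.maximum(np.asarray(b) * np.asarray(lam), 1e-300))
    out = np.sqrt(np.pi) * erf(x) / (2.0 * x)
    return np.where(np.asarray(b) * np.asarray(lam) < 1e-12, 1.0, out)


def zeppelin_spherical_mean(b, lam_par, lam_perp) -> np.ndarray:
    """Orientation average of an axially symmetric tensor compartment."""
    return np.exp(-np.asarray(b) * lam_perp) * stick_spherical_mean(b, lam_par - lam_perp)


def _smt_kernel(b: np.ndarray, v: float, lam: float) -> np.ndarray:
    """Two-compartment spherical-mean signal: stick + tortuosity zeppelin."""
    intra = stick_spherical_mean(b, lam)
    extra = zeppelin_spherical_mean(b, lam, (1.0 - v) * lam)
    return v * intra + (1.0 - v) * extra


def fit_mcsmt(
    shell_means: np.ndarray,
    shell_bvals: np.ndarray,
    n_grid: int = 11,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit (INTRA, λ) per voxel by multi-start bounded nonlinear least squares.

    An ``n_grid × n_grid`` grid over INTRA ∈ [0,1] × λ ∈ bounds seeds a
    trust-region refinement of the best cell. Returns (INTRA, λ, converged);
    non-converged voxels keep the grid optimum and are flagged.
    """
    shell_means = np.atleast_2d(shell_means)
    b = np.asarray(shell_bvals, dtype=float)
    lo, hi = SMT_LAMBDA_BOUNDS
    v_grid = np.linspace(0.0, 1.0, n_grid)
    l_grid = np.linspace(lo, hi, n_grid)
    kernels = np.stack(
        [[_smt_kernel(b, v, lam) for lam in l_grid] for v in v_grid]
    )  # (nv, nl, n_shell)

    n_vox = len(shell_means)
    intra = np.empty(n_vox)
    lam = np.empty(n_vox)
    converged = np.ones(n_vox, dtype=bool)
    sse = ((kernels[None] - shell_means[:, None, None, :]) ** 2).sum(axis=-1)
    best = sse.reshape(n_vox, -1).argmin(axis=1)
    iv, il = np.unravel_index(best, (n_grid, n_grid))
    for k in range(n_vox):
        y = shell_means[k]
        x0 = np.array([v_grid[iv[k]], l_grid[il[k]]])
        try:
            res = least_squares(
                lambda p: _smt_kernel(b, p[0], p[1]) - y,
                np.clip(x0, [0.0, lo], [1.0, hi]),
                bounds=([0.0, lo], [1.0, hi]),
                xtol=1e-12, ftol=1e-10, gtol=1e-12, max_nfev=500,
            )
            if res.success:
                intra[k], lam[k] = res.x
            else:
                intra[k], lam[k] = x0
                converged[k] = False
        except Exception:
            intra[k], lam[k] = x0
            converged[k] = False
    return intra, lam, converged


def fit_mcsmt_volume(
    dwi: DWIDataset,
    scheme: GradientScheme,
    mask: np.ndarray | None = None,
) -> SMTFit:
    """Spherical means + MC-SMT fit packaged as volume maps."""
    mask = dwi.mask if mask is None else np.asarray(mask, dtype=bool)
    shell_b, means, ok = spherical_mean(dwi, scheme, mask)
    intra, lam, conv = fit_mcsmt(means, shell_b)
    shape = mask.shape
    INTRA = np.zeros(shape)
    LAM = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)
    INTRA[mask] = intra
    LAM[mask] = lam
    valid[mask] = ok & conv
    return SMTFit(INTRA, LAM, valid, mask, dwi.affine)


# ---------------------------------------------------------------------------
# NODDI

def _noddi_signal(
    b: np.ndarray,
    g: np.ndarray,
    mu: np.ndarray,
    ndi: float,
    kappa: float,
    iso: float,
    n_quad: int = N_NODDI_QUAD,
) -> np.ndarray:
    """Three-compartment NODDI signal for one voxel (normalized, S(b=0)=1)."""
    quad = rotation_to(mu) @ fibonacci_sphere(n_quad).T  # (3, Q), centered on mu
    quad = quad.T
    w = watson_weights(quad, mu, kappa)
    c2 = (g @ quad.T) ** 2
    stick = np.exp(-b[:, None] * NODDI_LAMBDA_PAR * c2) @ w
    lam_perp = NODDI_LAMBDA_PAR * (1.0 - ndi)
    zep = np.exp(-b * lam_perp) * (
        np.exp(-b[:, None] * (NODDI_LAMBDA_PAR - lam_perp) * c2) @ w
    )
    tissue = ndi * stick + (1.0 - ndi) * zep
    return (1.0 - iso) * tissue + iso * np.exp(-b * NODDI_D_ISO)


def fit_noddi(
    dwi: DWIDataset,
    scheme: GradientScheme,
    mask: np.ndarray | None = None,
    dti_fit: TensorFit | None = None,
    grid: tuple[int, int, int] = (21, 21, 11),
    n_quad: int = N_NODDI_QUAD,
) -> NODDIFit:
    """Grid search + bounded local refinement of (NDI, ODI, ISO) per voxel.

    The mean orientation is fixed to the principal DTI eigenvector (computed
    here if no tensor fit is supplied). The grid evaluates every
    NDI × ODI × ISO cell; the best cell seeds a bounded trust-region
    refinement. Failed refinements fall back to the grid optimum and are
    flagged.
    """
    from .signal_models import fit_dti

    mask = dwi.mask if mask is None else np.asarray(mask, dtype=bool)
    if dti_fit is None:
        dti_fit = fit_dti(dwi, scheme, mask)
    _, evecs = tensor_eigs(dti_fit.D[mask])
    mus = evecs[..., :, 0]

    b = scheme.bvals
    g = scheme.bvecs
    sig = dwi.signal[mask]
    s0 = sig[:, scheme.b0_mask].mean(axis=1)
    ok = s0 > 0
    atten = sig / np.where(ok, s0, 1.0)[:, None]

    n_ndi, n_odi, n_iso = grid
    ndi_grid = np.linspace(0.01, 0.99, n_ndi)
    odi_grid = np.linspace(0.02, 0.99, n_odi)
    iso_grid = np.linspace(0.0, 1.0, n_iso)
    kappa_grid = np.array([kappa_from_odi(o) for o in odi_grid])
    ball = np.exp(-b * NODDI_D_ISO)

    quad0 = fibonacci_sphere(n_quad)
    weights = np.stack([watson_weights(quad0, [0, 0, 1], k) for k in kappa_grid])

    n_vox = len(sig)
    NDI = np.empty(n_vox)
    ODI = np.empty(n_vox)
    ISOv = np.empty(n_vox)
    KAP = np.empty(n_vox)
    conv = np.ones(n_vox, dtype=bool)

    for v in range(n_vox):
        mu = mus[v]
        quad = (rotation_to(mu) @ quad0.T).T
        c2 = (g @ quad.T) ** 2  # (V, Q)
        M1 = np.exp(-b[:, None] * NODDI_LAMBDA_PAR * c2)
        # stick Watson means for every kappa on the grid: (n_odi, V)
        stick_k = weights @ M1.T
        # tissue signal per (ndi, odi): zeppelin exponent scales with ndi
        sse_best = np.inf
        best = (0, 0, 0)
        tissue_cache = np.empty((n_ndi, n_odi, len(b)))
        for a, ndi in enumerate(ndi_grid):
            lam_perp = NODDI_LAMBDA_PAR * (1.0 - ndi)
            Mf = M1**ndi  # exp(-b (λ∥−λ⊥) c²) with λ∥−λ⊥ = λ∥·ndi
            zep_k = np.exp(-b * lam_perp)[None, :] * (weights @ Mf.T)
            tissue_cache[a] = ndi * stick_k + (1.0 - ndi) * zep_k
        y = atten[v]
        for c, iso in enumerate(iso_grid):
            model = (1.0 - iso) * tissue_cache + iso * ball  # (n_ndi, n_odi, V)
            sse = ((model - y) ** 2).sum(axis=-1)
            am = np.unravel_index(sse.argmin(), sse.shape)
            if sse[am] < sse_best:
                sse_best = sse[am]
                best = (am[0], am[1], c)
        x0 = np.array([ndi_grid[best[0]], odi_grid[best[1]], iso_grid[best[2]]])
        # fast residual: the quadrature geometry (c2, c2_mu) is fixed per
        # voxel, only the Watson weights and the ndi-power of M1 vary
        c2_mu = (quad @ mu) ** 2

        def _resid(p, _M1=M1, _c2mu=c2_mu, _y=y):
            ndi_, odi_, iso_ = p
            kap = kappa_from_odi(min(max(odi_, 1e-4), 1.0))
            if np.isinf(kap):
                w_ = np.zeros(len(_c2mu))
                w_[np.argmax(_c2mu)] = 1.0
            else:
                logw = kap * _c2mu
                w_ = np.exp(logw - logw.max())
                w_ /= w_.sum()
            stick = _M1 @ w_
            lam_perp = NODDI_LAMBDA_PAR * (1.0 - ndi_)
            zep = np.exp(-b * lam_perp) * ((_M1**ndi_) @ w_)
            tissue = ndi_ * stick + (1.0 - ndi_) * zep
            return (1.0 - iso_) * tissue + iso_ * ball - _y

        try:
            res = least_squares(
                _resid,
                x0,
                bounds=([0.0, 0.01, 0.0], [1.0, 1.0, 1.0]),
                xtol=1e-8, ftol=1e-10, gtol=1e-10, max_nfev=500,
            )
            if res.success and (res.fun**2).sum() <= sse_best + 1e-12:
                x = res.x
            else:
                x = x0
                conv[v] = res.success
        except Exception:
            x = x0
            conv[v] = False
        NDI[v], ODI[v], ISOv[v] = x
        KAP[v] = kappa_from_odi(max(ODI[v], 1e-6))

    shape = mask.shape
    out_ndi = np.zeros(shape)
    out_odi = np.zeros(shape)
    out_iso = np.zeros(shape)
    out_kap = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)
    out_ndi[mask] = NDI
    out_odi[mask] = ODI
    out_iso[mask] = ISOv
    out_kap[mask] = KAP
    valid[mask] = ok & conv
    return NODDIFit(out_ndi, out_odi, out_iso, out_kap, valid, mask, dwi.affine)
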