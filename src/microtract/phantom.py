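"""Synthetic multi-shell DWI phantoms, streamline bundles, and cohorts.

White-matter voxels are simulated as an intra-axonal stick plus an
extra-axonal zeppelin (with a tortuosity-coupled radial diffusivity), plus an
optional isotropic free-water ball; fiber orientations are Watson-dispersed
around a mean direction.  Magnitude noise is Rician.  The generator also
produces arc-shaped callosal-like streamline bundles and four-group cohort
tables whose metric distributions shift monotonically with disease grade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DWIDataset, GradientScheme, ScalarMap, StreamlineBundle
from .orientations import fibonacci_sphere, odi_from_kappa, rotation_to, watson_weights

__all__ = [
    "CompartmentSubstrate",
    "PhantomSpec",
    "CohortSpec",
    "make_scheme",
    "substrate_signal",
    "add_noise",
    "build_phantom",
    "simulate_cohort",
    "GROUPS",
]

#: Cohort group labels ordered by disease grade.
GROUPS = ("control", "subCI", "MCI", "dementia")

#: Number of Watson-quadrature orientations used in signal synthesis.
N_WATSON_QUAD = 300


@dataclass
class CompartmentSubstrate:
    """Generative stick + zeppelin (+ ball) voxel substrate.

    The extra-axonal zeppelin obeys the tortuosity rule
    ``lambda_perp = lambda_par * (1 - f_intra / (f_intra + f_extra))`` — the
    same coupling the MC-SMT and NODDI estimators assume, which makes
    parameter recovery well posed.
    """

    f_intra: float = 0.65
    f_iso: float = 0.0
    lambda_par: float = 2.0e-3  # mm²/s, intrinsic parallel diffusivity
    d_iso: float = 3.0e-3       # mm²/s, free-water diffusivity
    mu: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    kappa: float = np.inf       # Watson concentration; inf = coherent fibers

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_intra <= 1.0 and 0.0 <= self.f_iso <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if self.f_intra + self.f_iso > 1.0 + 1e-12:
            raise ValueError("f_intra + f_iso must be <= 1")
        if not 0.0 < self.lambda_par <= 4e-3:
            raise ValueError("lambda_par must be in (0, 4e-3] mm²/s")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        self.mu = np.asarray(self.mu, dtype=float)
        self.mu = self.mu / np.linalg.norm(self.mu)

    @property
    def f_extra(self) -> float:
        return 1.0 - self.f_intra - self.f_iso

    @property
    def lambda_perp_extra(self) -> float:
        """Tortuosity-rule extra-axonal radial diffusivity, mm²/s."""
        denom = self.f_intra + self.f_extra
        if denom <= 0:
            return 0.0
        return self.lambda_par * (1.0 - self.f_intra / denom)


@dataclass
class PhantomSpec:
    """Geometry + substrates for one synthetic bundle phantom."""

    dims: tuple[int, int, int] = (20, 20, 10)
    voxel_size: float = 2.0          # mm, isotropic
    bundle_radius: float = 4.0       # mm
    arc_height: float = 6.0          # mm sagittal bow of the arc centerline
    substrate: CompartmentSubstrate = field(default_factory=CompartmentSubstrate)
    background: CompartmentSubstrate = field(
        default_factory=lambda: CompartmentSubstrate(f_intra=0.0, f_iso=1.0)
    )
    S0: float = 1000.0
    snr: float | None = 30.0         # None disables noise
    n_streamlines: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d < m for d, m in zip(self.dims, (8, 8, 4))):
            raise ValueError("grid must be at least 8x8x4 voxels")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be > 0 (or None to disable noise)")


@dataclass
class CohortSpec:
    """Four-group cohort of per-subject central-segment metric values.

    ``effects[metric]`` gives the per-grade location shift in units of the
    within-group scale: group g gets location ``loc + grade(g) * effect * scale``.
    Metrics are correlated through a Gaussian copula with common correlation
    ``rho`` on normal marginals, clipped to physical ranges.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"control": 20, "subCI": 20, "MCI": 20, "dementia": 20}
    )
    locations: dict[str, float] = field(default_factory=dict)
    scales: dict[str, float] = field(default_factory=dict)
    effects: dict[str, float] = field(default_factory=dict)
    rho: float = 0.3
    tract: str = "forceps_minor"
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 2:
                raise ValueError("each group needs >= 2 subjects")
        if any(s <= 0 for s in self.scales.values()):
            raise ValueError("scales must be > 0")


# ---------------------------------------------------------------------------
# acquisition scheme

def make_scheme(
    n_per_shell: int = 64,
    bvals: tuple[float, ...] = (1000.0, 2500.0),
    n_b0: int = 1,
    seed: int = 0,
) -> GradientScheme:
    """Deterministic multi-shell scheme: the same spherical Fibonacci direction
    set reused on every nonzero shell, preceded by ``n_b0`` b=0 volumes."""
    if n_per_shell < 6:
        raise ValueError("need >= 6 directions per shell for a tensor fit")
    dirs = fibonacci_sphere(n_per_shell)
    all_b = [np.zeros(n_b0)]
    all_v = [np.zeros((n_b0, 3))]
    for b in bvals:
        all_b.append(np.full(n_per_shell, float(b)))
        all_v.append(dirs)
    return GradientScheme(np.concatenate(all_b), np.vstack(all_v))


# ---------------------------------------------------------------------------
# signal synthesis

def _stick_attenuation(b: np.ndarray, g: np.ndarray, fiber: np.ndarray, lam: float) -> np.ndarray:
    """exp(-b·λ·(g·u)²) for each (volume, fiber orientation) pair."""
    c2 = (g @ fiber.T) ** 2  # (V, Q)
    return np.exp(-b[:, None] * lam * c2)


def substrate_signal(
    sub: CompartmentSubstrate,
    scheme: GradientScheme,
    n_quad: int = N_WATSON_QUAD,
) -> np.ndarray:
    """Noise-free normalized signal S/S0 per scheme volume.

    ``S/S0 = f_intra·⟨E_stick⟩ + f_extra·⟨E_zeppelin⟩ + f_iso·exp(−b·d_iso)``
    where ⟨·⟩ averages over the Watson orientation distribution by quadrature
    on a deterministic ``n_quad``-point sphere set. S(b=0) = 1 exactly.
    """
    b = scheme.bvals
    g = scheme.bvecs
    quad = fibonacci_sphere(n_quad)
    w = watson_weights(quad, sub.mu, sub.kappa)
    if np.isinf(sub.kappa):
        quad = sub.mu[None, :]  # exact delta, not nearest lattice point
        w = np.ones(1)

    signal = np.zeros(len(b))
    if sub.f_intra > 0:
        e_stick = _stick_attenuation(b, g, quad, sub.lambda_par) @ w
        signal += sub.f_intra * e_stick
    if sub.f_extra > 0:
        lp = sub.lambda_perp_extra
        # zeppelin = isotropic λ_perp baseline × stick with (λ_par − λ_perp)
        e_zep = np.exp(-b * lp) * (
            _stick_attenuation(b, g, quad, sub.lambda_par - lp) @ w
        )
        signal += sub.f_extra * e_zep
    if sub.f_iso > 0:
        signal += sub.f_iso * np.exp(-b * sub.d_iso)
    signal[scheme.b0_mask] = 1.0
    return signal


def add_noise(
    signal: np.ndarray,
    S0: float,
    snr: float,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Rician-corrupt a signal array: ``sqrt((S + σε₁)² + (σε₂)²)``, σ = S0/snr."""
    if snr <= 0:
        raise ValueError("snr must be > 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    signal = np.asarray(signal, dtype=float)
    sigma = S0 / snr
    e1 = rng.standard_normal(signal.shape)
    e2 = rng.standard_normal(signal.shape)
    return np.sqrt((signal + sigma * e1) ** 2 + (sigma * e2) ** 2)


# ---------------------------------------------------------------------------
# bundle phantom

def _arc_centerline(spec: PhantomSpec, n: int = 200) -> np.ndarray:
    """Parametric arc spanning the grid along x, bowed in z — a callosal-like
    parasagittal arch. Returned in world mm (voxel-center affine, origin 0)."""
    dx, dy, dz = spec.dims
    vs = spec.voxel_size
    t = np.linspace(0.0, 1.0, n)
    x = (0.15 * dx + 0.7 * dx * t) * vs
    y = np.full(n, 0.5 * (dy - 1) * vs)
    z0 = 0.35 * (dz - 1) * vs
    z = z0 + spec.arc_height * np.sin(np.pi * t)
    return np.stack([x, y, z], axis=1)


def _point_line_distance(points: np.ndarray, polyline: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Min distance from each point to the polyline and the tangent there."""
    seg_a = polyline[:-1]
    seg_v = polyline[1:] - seg_a
    seg_len2 = np.einsum("ij,ij->i", seg_v, seg_v)
    dmin = np.full(len(points), np.inf)
    tangents = np.zeros((len(points), 3))
    for a, v, l2 in zip(seg_a, seg_v, seg_len2):
        t = np.clip((points - a) @ v / l2, 0.0, 1.0)
        proj = a + t[:, None] * v
        d = np.linalg.norm(points - proj, axis=1)
        closer = d < dmin
        dmin[closer] = d[closer]
        tangents[closer] = v / np.sqrt(l2)
    return dmin, tangents


def build_phantom(
    spec: PhantomSpec, scheme: GradientScheme
) -> tuple[DWIDataset, dict[str, ScalarMap], StreamlineBundle]:
    """Build a bundle phantom: DWI volume, ground-truth maps, streamlines.

    Voxels within ``bundle_radius`` of the arc centerline receive the bundle
    substrate oriented along the local tangent; the rest get the (isotropic)
    background substrate. Ground truth includes f_intra, f_iso, ODI derived
    from kappa, and the tortuosity-rule extra-axonal diffusivities.
    """
    dims = tuple(spec.dims)
    vs = spec.voxel_size
    affine = np.diag([vs, vs, vs, 1.0])
    center = _arc_centerline(spec)
    extent = np.array(dims) * vs
    if spec.bundle_radius > min(extent) / 2:
        raise ValueError("bundle radius exceeds grid extent")

    ii, jj, kk = np.meshgrid(*(np.arange(d) for d in dims), indexing="ij")
    vox_world = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * vs
    dist, tangents = _point_line_distance(vox_world, center)
    in_bundle = (dist <= spec.bundle_radius).reshape(dims)

    rng = np.random.default_rng(spec.seed)
    nvol = len(scheme)
    signal = np.empty(dims + (nvol,))
    bg_sig = substrate_signal(spec.background, scheme)
    signal[...] = bg_sig * spec.S0

    sub = spec.substrate
    flat_idx = np.where(in_bundle.ravel())[0]
    # cache signals per unique tangent to avoid recomputing the quadrature
    cache: dict[tuple, np.ndarray] = {}
    for fi in flat_idx:
        tan = tangents[fi]
        key = tuple(np.round(tan, 6))
        if key not in cache:
            voxel_sub = CompartmentSubstrate(
                f_intra=sub.f_intra, f_iso=sub.f_iso, lambda_par=sub.lambda_par,
                d_iso=sub.d_iso, mu=tan, kappa=sub.kappa,
            )
            cache[key] = substrate_signal(voxel_sub, scheme)
        signal.reshape(-1, nvol)[fi] = cache[key] * spec.S0

    if spec.snr is not None:
        signal = add_noise(signal, spec.S0, spec.snr, rng)

    mask = np.ones(dims, dtype=bool)
    dwi = DWIDataset(signal, affine, mask)

    def _gt(values: np.ndarray, name: str, units: str = "") -> ScalarMap:
        return ScalarMap(values, name, units=units, affine=affine)

    odi_val = odi_from_kappa(sub.kappa)
    truth = {
        "INTRA": _gt(np.where(in_bundle, sub.f_intra, spec.background.f_intra), "INTRA"),
        "ISO": _gt(np.where(in_bundle, sub.f_iso, spec.background.f_iso), "ISO"),
        "ODI": _gt(
            np.where(in_bundle, odi_val, odi_from_kappa(spec.background.kappa)), "ODI"
        ),
        "radEAD": _gt(
            np.where(in_bundle, sub.lambda_perp_extra, spec.background.lambda_perp_extra),
            "radEAD", units="mm^2/s",
        ),
        "axEAD": _gt(
            np.where(in_bundle, sub.lambda_par, spec.background.lambda_par),
            "axEAD", units="mm^2/s",
        ),
    }

    # streamlines: jittered parallel copies of the centerline, inside the bundle
    sls = []
    jitter_scale = 0.4 * spec.bundle_radius
    for _ in range(spec.n_streamlines):
        offset = rng.normal(scale=jitter_scale / 2.0, size=3)
        offset = np.clip(offset, -jitter_scale, jitter_scale)
        offset[0] = 0.0  # keep endpoints at the same arc-length positions
        sls.append(center + offset)
    bundle = StreamlineBundle(sls, name="forceps_minor")
    return dwi, truth, bundle


# ---------------------------------------------------------------------------
# cohort simulation

#: Default per-metric (location, scale, per-grade effect in scale units).
#: Locations/scales are realistic central-segment values for callosal white
#: matter on the reporting scale of each metric; the signs of the effects
#: encode the expected disease gradient (anisotropy/kurtosis/density fall,
#: diffusivity/free water rise with grade).
DEFAULT_COHORT_PARAMS: dict[str, tuple[float, float, float]] = {
    "FA": (0.70, 0.05, -0.8),
    "MD": (0.80, 0.06, +0.8),    # 1e-3 mm²/s
    "AD": (1.60, 0.10, +0.5),
    "RD": (0.45, 0.06, +0.8),
    "MK": (1.10, 0.10, -0.7),
    "AK": (0.80, 0.08, -0.4),
    "RK": (1.60, 0.18, -0.8),
    "AWF": (0.42, 0.04, -0.8),
    "axEAD": (2.10, 0.15, +0.4),
    "radEAD": (0.85, 0.10, +0.6),
    "INTRA": (0.65, 0.05, -0.8),
    "EMD": (1.35, 0.10, +0.7),   # 1e-3 mm²/s
    "ETR": (0.75, 0.09, +0.8),
    "NDI": (0.60, 0.05, -0.6),
    "ODI": (0.15, 0.03, +0.3),
    "ISO": (0.10, 0.04, +0.7),
}

_FRACTION_RANGE = {
    "FA": (0, 1), "AWF": (0, 1), "INTRA": (0, 1),
    "NDI": (0, 1), "ODI": (0, 1), "ISO": (0, 1),
}


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate per-subject central-segment metric values for four groups.

    Long-format table with columns (subject_id, group, tract, metric, value).
    Metrics are drawn jointly per subject from a Gaussian copula with
    exchangeable correlation ``spec.rho``; marginals are normal with the
    per-group location ``loc + grade·effect·scale``, then clipped to physical
    ranges. With all effects zero the four groups are exchangeable.
    """
    rng = np.random.default_rng(spec.seed)
    metrics = list(DEFAULT_COHORT_PARAMS)
    m = len(metrics)
    corr = np.full((m, m), spec.rho)
    np.fill_diagonal(corr, 1.0)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation structure not positive definite") from exc

    rows = []
    sid = 0
    for grade, group in enumerate(GROUPS):
        n = spec.group_sizes.get(group, 0)
        for _ in range(n):
            z = chol @ rng.standard_normal(m)
            for zi, metric in zip(z, metrics):
                loc0, scale0, eff0 = DEFAULT_COHORT_PARAMS[metric]
                loc = spec.locations.get(metric, loc0)
                scale = spec.scales.get(metric, scale0)
                eff = spec.effects.get(metric, eff0)
                val = loc + grade * eff * scale + zi * scale
                if metric in _FRACTION_RANGE:
                    val = float(np.clip(val, *_FRACTION_RANGE[metric]))
                else:
                    val = float(max(val, 0.0))
                rows.append((f"sub-{sid:03d}", group, spec.tract, metric, val))
            sid += 1
    return pd.DataFrame(rows, columns=["subject_id", "group", "tract", "metric", "value"])
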