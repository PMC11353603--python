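"""Core data model and I/O for multi-shell diffusion MRI pipelines.

Conventions used throughout the package:

* diffusivities are stored internally in mm²/s; the reporting layer rescales
  (MD/AD/RD and the WMTI diffusivities are printed as 10⁻³ mm²/s, the SMT
  extra-axonal diffusivities in plain mm²/s);
* world coordinates are mm, RAS; voxel indices are 0-based with the
  voxel-center convention for the affine;
* gradient directions (bvecs) are interpreted in the image frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel import streamlines as nib_streamlines
from scipy.ndimage import map_coordinates

__all__ = [
    "METRICS",
    "FRACTION_METRICS",
    "DIFFUSIVITY_METRICS",
    "GradientScheme",
    "DWIDataset",
    "ScalarMap",
    "StreamlineBundle",
    "read_dwi",
    "write_dwi",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "read_streamlines",
    "write_streamlines",
    "sample_scalar",
]

#: Controlled vocabulary of the 16 reported microstructure metrics.
METRICS = (
    "FA", "MD", "AD", "RD",          # diffusion tensor
    "MK", "AK", "RK",                # kurtosis tensor
    "AWF", "axEAD", "radEAD",        # white-matter tract integrity
    "INTRA", "EMD", "ETR",           # multicompartment spherical mean
    "NDI", "ODI", "ISO",             # NODDI
)

FRACTION_METRICS = frozenset({"FA", "NDI", "ODI", "ISO", "INTRA", "AWF"})
DIFFUSIVITY_METRICS = frozenset({"MD", "AD", "RD", "axEAD", "radEAD", "EMD", "ETR"})

#: Default b-value clustering tolerance, s/mm².
SHELL_TOL = 50.0


@dataclass
class GradientScheme:
    """Per-volume b-values (s/mm²) and unit gradient directions."""

    bvals: np.ndarray
    bvecs: np.ndarray  # (V, 3)
    shell_tol: float = SHELL_TOL

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        if len(self.bvals) != len(self.bvecs):
            raise ValueError(
                f"{len(self.bvals)} b-values but {len(self.bvecs)} directions"
            )
        if np.any(self.bvals < 0):
            raise ValueError("b-values must be >= 0")
        nz = self.bvals > self.shell_tol
        norms = np.linalg.norm(self.bvecs[nz], axis=1)
        if np.any(norms < 1e-12):
            raise ValueError("zero direction vector at nonzero b")
        self.bvecs = self.bvecs.copy()
        self.bvecs[nz] /= norms[:, None]
        if not np.any(~nz):
            raise ValueError("scheme must contain at least one b=0 volume")

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= self.shell_tol

    def shells(self) -> dict[float, np.ndarray]:
        """Cluster nonzero b-values into shells by nearest centroid.

        Greedy 1-D clustering at tolerance ``shell_tol`` (robust to
        scanner-rounded b-values). Returns ``{shell_b: volume index array}``
        for nonzero shells, keyed by the cluster mean.
        """
        out: dict[float, np.ndarray] = {}
        nz_idx = np.where(~self.b0_mask)[0]
        if len(nz_idx) == 0:
            return out
        bs = self.bvals[nz_idx]
        order = np.argsort(bs)
        groups: list[list[int]] = []
        for pos in order:
            b = bs[pos]
            if groups and abs(b - np.mean(bs[groups[-1]])) <= self.shell_tol:
                groups[-1].append(pos)
            else:
                groups.append([pos])
        for grp in groups:
            centroid = float(np.mean(bs[grp]))
            out[centroid] = nz_idx[np.array(grp)]
        return out


@dataclass
class DWIDataset:
    """4D diffusion-weighted signal with voxel geometry."""

    signal: np.ndarray  # (X, Y, Z, V)
    affine: np.ndarray  # (4, 4) voxel -> world mm
    mask: np.ndarray | None = None  # (X, Y, Z) bool

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (X, Y, Z, V)")
        self.affine = np.asarray(self.affine, dtype=float)
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if self.mask is None:
            self.mask = np.ones(self.signal.shape[:3], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.signal.shape[:3]:
            raise ValueError("mask shape does not match signal grid")

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class ScalarMap:
    """A 3D per-voxel metric map with its name from the controlled vocabulary."""

    values: np.ndarray
    metric_name: str
    units: str = ""
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("scalar map must be 3D")
        if self.metric_name not in METRICS:
            raise ValueError(
                f"unknown metric {self.metric_name!r}; expected one of {METRICS}"
            )
        self.affine = np.asarray(self.affine, dtype=float)


@dataclass
class StreamlineBundle:
    """An ordered list of polylines in world mm."""

    streamlines: list[np.ndarray]
    name: str = "other"

    def __post_init__(self) -> None:
        cleaned = []
        for sl in self.streamlines:
            sl = np.asarray(sl, dtype=float).reshape(-1, 3)
            if len(sl) < 2:
                raise ValueError("every streamline needs >= 2 points")
            if np.any(np.all(np.diff(sl, axis=0) == 0, axis=1)):
                raise ValueError("consecutive duplicate points in streamline")
            cleaned.append(sl)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)


# ---------------------------------------------------------------------------
# readers / writers

def read_bvals_bvecs(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    """Read FSL-dialect gradient tables (1×V b-values; 3×V directions)."""
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # ambiguous 3x3: FSL convention is rows = components
        bvecs = bvecs.T
    return bvals, bvecs.reshape(-1, 3)


def write_bvals_bvecs(scheme: GradientScheme, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.1f")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.8f")


def read_dwi(nifti_path, bval_path, bvec_path) -> tuple[DWIDataset, GradientScheme]:
    """Load a 4D NIfTI with its FSL b-value/b-vector tables.

    Raises on non-4D images or a volume-count/gradient-table mismatch; bvecs
    at nonzero b are renormalized to unit length.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D image, got {data.ndim}D")
    bvals, bvecs = read_bvals_bvecs(bval_path, bvec_path)
    if len(bvals) != data.shape[3]:
        raise ValueError(
            f"gradient table has {len(bvals)} entries but image has "
            f"{data.shape[3]} volumes"
        )
    scheme = GradientScheme(bvals, bvecs)
    return DWIDataset(data, img.affine), scheme


def write_dwi(dwi: DWIDataset, scheme: GradientScheme, nifti_path, bval_path, bvec_path) -> None:
    nib.save(nib.Nifti1Image(dwi.signal.astype(np.float64), dwi.affine), str(nifti_path))
    write_bvals_bvecs(scheme, bval_path, bvec_path)


def write_scalar_map(smap: ScalarMap, path) -> None:
    """Write a scalar map as NIfTI; the metric name goes into the filename."""
    nib.save(nib.Nifti1Image(smap.values.astype(np.float64), smap.affine), str(path))


def read_scalar_map(path, metric_name: str) -> ScalarMap:
    img = nib.load(str(path))
    return ScalarMap(np.asarray(img.dataobj, dtype=float), metric_name, affine=img.affine)


def read_streamlines(path) -> StreamlineBundle:
    """Read a TCK or TRK file into world-mm coordinates.

    TRK points are mapped to world mm ("rasmm" space) using the header's
    voxel-to-world transform, so both dialects yield identical coordinates for
    the same geometry.
    """
    path = Path(path)
    tfile = nib_streamlines.load(str(path))  # raises on unknown magic
    sls = [np.asarray(s, dtype=float) for s in tfile.tractogram.streamlines]
    name = path.stem.split(".")[0]
    if name not in ("forceps_minor", "body", "forceps_major"):
        name = "other"
    if not sls:
        bundle = StreamlineBundle.__new__(StreamlineBundle)
        bundle.streamlines = []
        bundle.name = name
        return bundle
    return StreamlineBundle(sls, name=name)


def write_streamlines(bundle: StreamlineBundle, path, affine: np.ndarray | None = None) -> None:
    """Write a bundle as TCK or TRK (by extension), coordinates in world mm."""
    path = Path(path)
    tractogram = nib_streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in bundle.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    if path.suffix == ".tck":
        nib_streamlines.save(tractogram, str(path))
    elif path.suffix == ".trk":
        header = nib_streamlines.trk.TrkFile.create_empty_header()
        aff = np.eye(4) if affine is None else np.asarray(affine, dtype=float)
        header["voxel_to_rasmm"] = aff.astype(np.float32)
        header["voxel_sizes"] = np.linalg.norm(aff[:3, :3], axis=0).astype(np.float32)
        trk = nib_streamlines.trk.TrkFile(tractogram, header=header)
        trk.save(str(path))
    else:
        raise ValueError(f"unknown streamline format {path.suffix!r}")


# ---------------------------------------------------------------------------
# scalar sampling

def sample_scalar(
    smap: ScalarMap | np.ndarray,
    affine: np.ndarray,
    points: np.ndarray,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Trilinear interpolation of a 3D map at world-mm ``points``.

    Points falling outside the volume's world bounding box, or inside voxels
    excluded by ``mask``, yield NaN (the missing-value marker); out-of-box
    points additionally raise a warning with their count.
    """
    values = smap.values if isinstance(smap, ScalarMap) else np.asarray(smap, dtype=float)
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    inv = np.linalg.inv(affine)
    vox = points @ inv[:3, :3].T + inv[:3, 3]

    shape = np.array(values.shape, dtype=float)
    outside = np.any((vox < -0.5) | (vox > shape - 0.5), axis=1)
    if np.any(outside):
        warnings.warn(
            f"{int(outside.sum())} sample point(s) outside the volume bounding box",
            stacklevel=2,
        )
    out = map_coordinates(values, vox.T, order=1, mode="nearest")
    out = np.asarray(out, dtype=float)
    out[outside] = np.nan
    if mask is not None:
        nearest = np.clip(np.round(vox).astype(int), 0, np.array(values.shape) - 1)
        inside = ~outside
        idx = nearest[inside]
        masked_out = ~np.asarray(mask, dtype=bool)[idx[:, 0], idx[:, 1], idx[:, 2]]
        tmp = out[inside]
        tmp[masked_out] = np.nan
        out[inside] = tmp
    return out
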