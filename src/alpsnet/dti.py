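"""Diffusion tensor estimation from diffusion-weighted MRI.

The diffusion tensor model describes the water displacement profile in each
voxel as a zero-mean Gaussian with covariance proportional to a symmetric
positive tensor ``D``.  Under the Stejskal--Tanner equation the measured
signal for a gradient direction ``g`` (unit vector) and b-value ``b`` is

    S = S0 * exp(-b * g^T D g)

so that ``ln(S/S0)`` is linear in the six unique tensor elements and the
tensor can be recovered by ordinary least squares on the log-signal
(log-linear fit, the baseline behaviour of FSL ``dtifit``).

Diffusivities are expressed in um^2/ms (= 1e-3 mm^2/s) throughout, so a
b-value given in s/mm^2 enters the exponent with a factor of 1e-3.

The axis diffusivities Dxx/Dyy/Dzz exposed here are the tensor diagonal in
image axes (the FSL tensor-component convention) -- this is what
"diffusivity map along the x-axis" denotes in the perivascular-space
(ALPS) literature, not a projection onto eigenvectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

log = logging.getLogger(__name__)

#: b-values within this many s/mm^2 of zero are treated as b=0 volumes.
B0_TOLERANCE = 50.0

#: signals are floored at this fraction of S0 before taking the log.
SIGNAL_FLOOR_FRACTION = 1e-6

#: unit-norm tolerance for gradient directions of diffusion-weighted volumes.
BVEC_NORM_TOL = 1e-3

# diffusivity unit conversion: um^2/ms per mm^2/s
_UNIT = 1e-3


class DWIFormatError(ValueError):
    """Raised when DWI inputs are inconsistent or malformed."""


@dataclass
class DWIVolume:
    """A 4D diffusion-weighted acquisition.

    Parameters
    ----------
    signal
        Non-negative array of shape (X, Y, Z, V).
    bvals
        Per-volume b-value in s/mm^2, shape (V,).
    bvecs
        Per-volume gradient direction, shape (V, 3); unit norm required for
        diffusion-weighted volumes (b > ``B0_TOLERANCE``).
    voxel_size_mm
        Voxel edge lengths (dx, dy, dz) in mm.
    affine
        Optional 4x4 voxel-to-world matrix (defaults to a scaled identity).
    """

    signal: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size_mm) + [1.0])
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.signal.ndim != 4:
            raise DWIFormatError(f"signal must be 4D, got shape {self.signal.shape}")
        nvol = self.signal.shape[3]
        if self.bvals.shape != (nvol,):
            raise DWIFormatError(
                f"bvals has {self.bvals.size} entries for {nvol} volumes"
            )
        if self.bvecs.shape != (nvol, 3):
            raise DWIFormatError(
                f"bvecs has shape {self.bvecs.shape}, expected ({nvol}, 3)"
            )
        if np.any(self.signal < 0):
            raise DWIFormatError("signal contains negative values")
        if self.n_b0 < 1:
            raise DWIFormatError(
                "at least one b=0 volume is required "
                f"(none within {B0_TOLERANCE} s/mm^2 of 0)"
            )
        dw = ~self.b0_mask
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        bad = np.flatnonzero(np.abs(norms - 1.0) > BVEC_NORM_TOL)
        if bad.size:
            rows = np.flatnonzero(dw)[bad]
            raise DWIFormatError(
                f"non-unit gradient directions for volumes {rows.tolist()} "
                f"(norms {norms[bad].round(4).tolist()})"
            )
        if dw.sum() < 6:
            raise DWIFormatError("at least 6 diffusion-weighted volumes required")
        # non-collinearity: the 6-column design must have full rank
        if np.linalg.matrix_rank(_design_matrix(self.bvals[dw], self.bvecs[dw])) < 6:
            raise DWIFormatError(
                "gradient directions do not span the tensor space "
                "(rank-deficient design)"
            )

    # -- derived ----------------------------------------------------------
    @property
    def b0_mask(self) -> np.ndarray:
        return np.abs(self.bvals) <= B0_TOLERANCE

    @property
    def n_b0(self) -> int:
        return int(self.b0_mask.sum())

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass
class TensorField:
    """Per-voxel diffusion tensors and derived scalar maps.

    ``evals`` are sorted descending (lambda1 >= lambda2 >= lambda3) and
    clamped at zero; the stored ``tensor`` is reconstructed from the clamped
    eigensystem so the trace identity Dxx+Dyy+Dzz = lambda1+lambda2+lambda3
    holds exactly on every fitted voxel.
    """

    tensor: np.ndarray  # (X, Y, Z, 3, 3)
    evals: np.ndarray  # (X, Y, Z, 3) descending
    evecs: np.ndarray  # (X, Y, Z, 3, 3) columns matching evals
    fa: np.ndarray  # (X, Y, Z)
    md: np.ndarray  # (X, Y, Z)
    mask: np.ndarray  # (X, Y, Z) bool, True where fitted
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    qc: dict = field(default_factory=dict)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.tensor.shape[:3]

    @property
    def dxx(self) -> np.ndarray:
        return self.tensor[..., 0, 0]

    @property
    def dyy(self) -> np.ndarray:
        return self.tensor[..., 1, 1]

    @property
    def dzz(self) -> np.ndarray:
        return self.tensor[..., 2, 2]

    @property
    def e1(self) -> np.ndarray:
        """Principal eigenvector, sign-normalized (see :func:`normalize_e1_sign`)."""
        return self.evecs[..., :, 0]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_fsl_vectors(path: str | Path, n_expected_cols: int | None = None) -> np.ndarray:
    arr = np.loadtxt(path, ndmin=2)
    return arr


def load_dwi(nifti_path, bval_path, bvec_path) -> DWIVolume:
    """Read a 4D NIfTI plus FSL-dialect ``bvals``/``bvecs`` text files.

    bvecs may be stored 3xN (FSL convention) or Nx3; both are accepted.
    Volume counts must agree across the three files.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise DWIFormatError(f"{nifti_path}: expected 4D image, got {data.ndim}D")
    nvol = data.shape[3]
    bvals = np.loadtxt(bval_path).ravel()
    if bvals.size != nvol:
        raise DWIFormatError(
            f"{bval_path}: {bvals.size} b-values for {nvol} volumes"
        )
    bvecs = _read_fsl_vectors(bvec_path)
    if bvecs.shape == (3, nvol):
        bvecs = bvecs.T
    if bvecs.shape != (nvol, 3):
        raise DWIFormatError(
            f"{bvec_path}: shape {bvecs.shape} incompatible with {nvol} volumes"
        )
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DWIVolume(data, bvals, bvecs, voxel_size_mm=voxel, affine=img.affine)


def save_dwi(dwi: DWIVolume, out_dir, stem: str = "dwi") -> dict[str, Path]:
    """Write NIfTI (.nii.gz) plus FSL 3-row ``bvals``/``bvecs`` files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "nifti": out / f"{stem}.nii.gz",
        "bvals": out / f"{stem}.bval",
        "bvecs": out / f"{stem}.bvec",
    }
    nib.Nifti1Image(dwi.signal.astype(np.float64), dwi.affine).to_filename(
        str(paths["nifti"])
    )
    np.savetxt(paths["bvals"], dwi.bvals[None, :], fmt="%.6g")
    np.savetxt(paths["bvecs"], dwi.bvecs.T, fmt="%.9f")
    return paths


def save_scalar_maps(tf: TensorField, out_dir) -> dict[str, Path]:
    """Write FA/MD/Dxx/Dyy/Dzz as NIfTI volumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(tf.voxel_size_mm) + [1.0])
    maps = {"FA": tf.fa, "MD": tf.md, "Dxx": tf.dxx, "Dyy": tf.dyy, "Dzz": tf.dzz}
    paths = {}
    for name, vol in maps.items():
        p = out / f"{name}.nii.gz"
        nib.Nifti1Image(np.asarray(vol, dtype=np.float64), affine).to_filename(str(p))
        paths[name] = p
    return paths


# ---------------------------------------------------------------------------
# Tensor fitting
# ---------------------------------------------------------------------------

def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows b*1e-3*[gx^2, gy^2, gz^2, 2gxgy, 2gxgz, 2gygz] for D in um^2/ms."""
    g = bvecs
    b = bvals * _UNIT
    return b[:, None] * np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )


def _six_to_tensor(d6: np.ndarray) -> np.ndarray:
    """(..., 6) [Dxx,Dyy,Dzz,Dxy,Dxz,Dyz] -> (..., 3, 3) symmetric."""
    out = np.empty(d6.shape[:-1] + (3, 3), dtype=float)
    out[..., 0, 0] = d6[..., 0]
    out[..., 1, 1] = d6[..., 1]
    out[..., 2, 2] = d6[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = d6[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = d6[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = d6[..., 5]
    return out


def fa_from_evals(evals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from eigenvalues (any trailing axis of 3)."""
    ev = np.asarray(evals, dtype=float)
    l1, l2, l3 = ev[..., 0], ev[..., 1], ev[..., 2]
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l1 - l3) ** 2
    den = l1**2 + l2**2 + l3**2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(0.5) * np.sqrt(num) / np.sqrt(den)
    return np.where(den > 0, fa, 0.0)


def normalize_e1_sign(evecs: np.ndarray) -> np.ndarray:
    """Flip principal eigenvectors to non-negative z (then y, then x).

    The tensor model is antipodally symmetric, so e1 and -e1 are equivalent;
    a fixed hemisphere convention makes outputs reproducible.
    """
    e1 = evecs[..., :, 0]
    sign = np.sign(e1[..., 2])
    zero = sign == 0
    sign = np.where(zero, np.sign(e1[..., 1]), sign)
    zero = sign == 0
    sign = np.where(zero, np.sign(e1[..., 0]), sign)
    sign = np.where(sign == 0, 1.0, sign)
    out = evecs.copy()
    out[..., :, 0] = e1 * sign[..., None]
    return out


def tensorfield_from_tensors(
    tensors: np.ndarray,
    voxel_size_mm=(2.0, 2.0, 2.0),
    mask: np.ndarray | None = None,
    qc: dict | None = None,
) -> TensorField:
    """Build a :class:`TensorField` (eigensystem, FA, MD) from raw tensors.

    Negative eigenvalues are clamped to zero and the tensor rebuilt from the
    clamped eigensystem, keeping FA in [0, 1] and the trace identity exact.
    """
    tensors = np.asarray(tensors, dtype=float)
    grid = tensors.shape[:3]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    evals = np.zeros(grid + (3,))
    evecs = np.zeros(grid + (3, 3))
    evecs[..., 0, 0] = evecs[..., 1, 1] = evecs[..., 2, 2] = 1.0
    flat = tensors[mask]
    if flat.size:
        w, v = np.linalg.eigh(flat)  # ascending
        w = w[:, ::-1]
        v = v[:, :, ::-1]
        w = np.clip(w, 0.0, None)
        evals[mask] = w
        evecs[mask] = v
    evecs = normalize_e1_sign(evecs)
    # reconstruct from clamped eigensystem
    rebuilt = np.zeros_like(tensors)
    if flat.size:
        rebuilt[mask] = np.einsum(
            "...ij,...j,...kj->...ik", evecs[mask], evals[mask], evecs[mask]
        )
    fa = np.where(mask, fa_from_evals(evals), 0.0)
    md = np.where(mask, evals.sum(axis=-1) / 3.0, 0.0)
    return TensorField(
        tensor=rebuilt,
        evals=evals,
        evecs=evecs,
        fa=fa,
        md=md,
        mask=mask,
        voxel_size_mm=tuple(voxel_size_mm),
        qc=qc or {},
    )


def fit_tensor(dwi: DWIVolume, mask: np.ndarray | None = None) -> TensorField:
    """Log-linear least-squares tensor fit.

    Per masked voxel solves ``ln(S_i/S0) = -b_i g_i^T D g_i`` for the six
    unique tensor elements; S0 is the mean of the b=0 volumes.  Zero or
    negative signals are floored at ``SIGNAL_FLOOR_FRACTION * S0`` before the
    log.  Voxels with fewer than 6 usable (strictly positive) diffusion
    measurements, or non-positive S0, are excluded from the output mask and
    counted in ``TensorField.qc``.
    """
    grid = dwi.grid_shape
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != grid:
            raise ValueError(f"mask shape {mask.shape} != grid {grid}")

    b0 = dwi.b0_mask
    s0 = dwi.signal[..., b0].mean(axis=-1)
    dw_signal = dwi.signal[..., ~b0]

    usable = (dw_signal > 0).sum(axis=-1)
    good = mask & (s0 > 0) & (usable >= 6)
    n_excluded = int(mask.sum() - good.sum())
    if n_excluded:
        log.warning("fit_tensor: excluded %d voxels with insufficient data", n_excluded)

    B = _design_matrix(dwi.bvals[~b0], dwi.bvecs[~b0])
    Binv = np.linalg.pinv(B)

    sig = dw_signal[good]  # (n_vox, n_dw)
    s0v = s0[good][:, None]
    floor = SIGNAL_FLOOR_FRACTION * s0v
    sig = np.maximum(sig, floor)
    y = -np.log(sig / s0v)  # (n_vox, n_dw)
    d6 = y @ Binv.T  # (n_vox, 6)

    tensors = np.zeros(grid + (3, 3))
    tensors[good] = _six_to_tensor(d6)
    qc = {"n_masked": int(mask.sum()), "n_fitted": int(good.sum()), "n_excluded": n_excluded}
    return tensorfield_from_tensors(tensors, dwi.voxel_size_mm, good, qc)


def tensor_scalars(tf: TensorField) -> dict[str, np.ndarray]:
    """Scalar/vector maps consumed by the ALPS and tractography stages."""
    return {
        "FA": tf.fa,
        "MD": tf.md,
        "Dxx": tf.dxx,
        "Dyy": tf.dyy,
        "Dzz": tf.dzz,
        "e1": tf.e1,
    }


# ---------------------------------------------------------------------------
# QC color FA
# ---------------------------------------------------------------------------

def color_fa(tf: TensorField) -> np.ndarray:
    """Direction-encoded color FA: RGB = FA * |e1| (red=x, green=y, blue=z)."""
    rgb = tf.fa[..., None] * np.abs(tf.e1)
    return np.clip(rgb, 0.0, 1.0)


def save_color_fa(tf: TensorField, out_dir, stem: str = "colorfa") -> list[Path]:
    """Write the color-FA volume as an 8-bit PNG stack (one axial slice each)."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rgb8 = (color_fa(tf) * 255).round().astype(np.uint8)
    paths = []
    for k in range(rgb8.shape[2]):
        p = out / f"{stem}_z{k:03d}.png"
        Image.fromarray(np.transpose(rgb8[:, :, k, :], (1, 0, 2))).save(p)
        paths.append(p)
    return paths
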