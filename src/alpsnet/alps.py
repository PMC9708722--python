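"""ALPS index: diffusivity along the perivascular space.

At the level of the lateral ventricle body the medullary veins run
right-left (x), perpendicular both to the projection fibers (z, inferior-
superior) and to the association fibers (y, anterior-posterior).  Water
diffusivity measured along x inside those two fiber populations therefore
isolates the perivascular compartment, and the ALPS index

    ALPS = mean(Dx_proj, Dx_assoc) / mean(Dy_proj, Dz_assoc)

compares it against the fiber-perpendicular background diffusivity.  An
index near 1 means no preferential perivascular diffusion; healthy values
sit near 2 and fall with glymphatic impairment.

Four spherical ROIs (default 5 mm diameter), one per fiber class and
hemisphere, are averaged first; the ratio is applied to the ROI-mean
diffusivities.  The bilateral mean of the left and right index is the
subject-level summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dti import TensorField, fit_tensor, load_dwi
from .synthcohort import PhantomTruth, alps_from_diffusivities

log = logging.getLogger(__name__)

ROI_KEYS = ("proj_L", "proj_R", "assoc_L", "assoc_R")
DEFAULT_ROI_DIAMETER_MM = 5.0
LOW_FA_FLAG_THRESHOLD = 0.15  # proxy for "ROI overlaps a lesion / CSF"


class ROIError(ValueError):
    """Raised for invalid ROI definitions."""


@dataclass
class ROI:
    center: tuple[float, float, float]  # 0-based voxel coordinates
    diameter_mm: float = DEFAULT_ROI_DIAMETER_MM
    hemisphere: str = ""
    fiber_class: str = ""  # 'projection' or 'association'


@dataclass
class ROISet:
    """The four ALPS ROIs, keyed proj_L / proj_R / assoc_L / assoc_R."""

    rois: dict[str, ROI]
    qc_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [k for k in ROI_KEYS if k not in self.rois]
        extra = [k for k in self.rois if k not in ROI_KEYS]
        if missing or extra:
            raise ROIError(
                f"ROI set must have exactly the keys {ROI_KEYS}; "
                f"missing {missing}, unexpected {extra}"
            )

    def __getitem__(self, key: str) -> ROI:
        return self.rois[key]

    def validate_against_grid(
        self, grid_shape, voxel_size_mm
    ) -> None:
        for key, roi in self.rois.items():
            if not all(0 <= c < g for c, g in zip(roi.center, grid_shape)):
                raise ROIError(f"{key}: center {roi.center} outside grid {grid_shape}")
        # projection and association ROIs must not overlap
        vox = {
            k: set(map(tuple, rasterize_roi(r.center, r.diameter_mm,
                                            voxel_size_mm, grid_shape)[0]))
            for k, r in self.rois.items()
        }
        for p in ("proj_L", "proj_R"):
            for a in ("assoc_L", "assoc_R"):
                if vox[p] & vox[a]:
                    raise ROIError(f"ROIs {p} and {a} overlap")


def rasterize_roi(
    center, diameter_mm, voxel_size_mm, grid_shape
) -> tuple[np.ndarray, bool]:
    """Voxels whose centers lie within ``diameter_mm/2`` of the ROI center.

    Distances are Euclidean in mm; the ROI center is given in 0-based voxel
    coordinates.  Returns ``(indices, clipped)`` where ``indices`` is an
    (N, 3) integer array and ``clipped`` flags truncation at a grid edge.

    Raises :class:`ROIError` on an empty set (diameter below the voxel
    pitch with an off-center placement).
    """
    center = np.asarray(center, dtype=float)
    voxel = np.asarray(voxel_size_mm, dtype=float)
    grid = np.asarray(grid_shape, dtype=int)
    if diameter_mm <= 0:
        raise ROIError("ROI diameter must be positive")
    if not np.all((center >= 0) & (center < grid)):
        raise ROIError(f"ROI center {center.tolist()} outside grid {grid.tolist()}")
    radius = diameter_mm / 2.0
    reach = np.ceil(radius / voxel).astype(int)
    lo = np.floor(center).astype(int) - reach
    hi = np.floor(center).astype(int) + reach + 1
    clipped = bool(np.any(lo < 0) or np.any(hi > grid))
    lo_c = np.maximum(lo, 0)
    hi_c = np.minimum(hi, grid)
    ii, jj, kk = np.meshgrid(
        *[np.arange(l, h) for l, h in zip(lo_c, hi_c)], indexing="ij"
    )
    idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    dist = np.linalg.norm((idx - center) * voxel, axis=1)
    inside = idx[dist <= radius]
    if inside.size == 0:
        raise ROIError(
            f"ROI at {center.tolist()} with diameter {diameter_mm} mm "
            "contains no voxel centers"
        )
    if clipped:
        # clipped only counts if the sphere actually loses voxels
        full = np.column_stack(
            [g.ravel() for g in np.meshgrid(
                *[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")]
        )
        full_dist = np.linalg.norm((full - center) * voxel, axis=1)
        clipped = int((full_dist <= radius).sum()) > len(inside)
        if clipped:
            log.warning("ROI at %s clipped at grid boundary", center.tolist())
    return inside, clipped


def place_default_rois(
    truth_or_config: PhantomTruth | dict,
    tf: TensorField | None = None,
    diameter_mm: float = DEFAULT_ROI_DIAMETER_MM,
) -> ROISet:
    """Build the four ALPS ROIs from phantom truth or an explicit config.

    Phantom mode passes through the ground-truth bundle centers; config mode
    expects a mapping ``{proj_L: [i, j, k], ...}`` with all four keys.  If a
    tensor field is supplied the mean FA of each ROI is checked against
    ``LOW_FA_FLAG_THRESHOLD`` and low-FA ROIs are flagged (a proxy for the
    manual check that ROIs avoid ischemic lesions); flagged ROIs are
    reported, not rejected.
    """
    if isinstance(truth_or_config, PhantomTruth):
        centers = truth_or_config.roi_centers
    else:
        centers = dict(truth_or_config)
    missing = [k for k in ROI_KEYS if k not in centers]
    if missing:
        raise ROIError(f"missing ROI centers for {missing}")
    rois = {
        key: ROI(
            center=tuple(float(c) for c in centers[key]),
            diameter_mm=diameter_mm,
            hemisphere=key[-1],
            fiber_class="projection" if key.startswith("proj") else "association",
        )
        for key in ROI_KEYS
    }
    roiset = ROISet(rois)
    if tf is not None:
        roiset.validate_against_grid(tf.grid_shape, tf.voxel_size_mm)
        for key, roi in rois.items():
            idx, clipped = rasterize_roi(
                roi.center, roi.diameter_mm, tf.voxel_size_mm, tf.grid_shape
            )
            mean_fa = float(tf.fa[idx[:, 0], idx[:, 1], idx[:, 2]].mean())
            if mean_fa < LOW_FA_FLAG_THRESHOLD:
                roiset.qc_flags.append(
                    f"{key}: mean ROI FA {mean_fa:.3f} < {LOW_FA_FLAG_THRESHOLD}"
                )
            if clipped:
                roiset.qc_flags.append(f"{key}: ROI clipped at grid boundary")
    return roiset


@dataclass
class ALPSResult:
    """Per-hemisphere ROI diffusivities and ALPS indices (um^2/ms)."""

    dx_proj: dict[str, float]
    dy_proj: dict[str, float]
    dx_assoc: dict[str, float]
    dz_assoc: dict[str, float]
    alps: dict[str, float]  # keys 'L', 'R'
    mean_alps: float
    roi_voxel_counts: dict[str, int]
    qc_flags: list[str] = field(default_factory=list)

    def as_row(self) -> dict:
        return {
            "alps_L": self.alps["L"],
            "alps_R": self.alps["R"],
            "mean_alps": self.mean_alps,
            **{f"dx_proj_{h}": self.dx_proj[h] for h in "LR"},
            **{f"dy_proj_{h}": self.dy_proj[h] for h in "LR"},
            **{f"dx_assoc_{h}": self.dx_assoc[h] for h in "LR"},
            **{f"dz_assoc_{h}": self.dz_assoc[h] for h in "LR"},
            "qc": "; ".join(self.qc_flags),
        }


def compute_alps(tf: TensorField, rois: ROISet) -> ALPSResult:
    """Bilateral ALPS index from ROI-mean axis diffusivities.

    Per hemisphere: Dx_proj and Dy_proj are the mean Dxx / Dyy over the
    projection ROI, Dx_assoc and Dz_assoc the mean Dxx / Dzz over the
    association ROI; the index is their ratio (ROI means first, then the
    ratio).  ``mean_alps`` is the exact average of left and right.
    """
    rois.validate_against_grid(tf.grid_shape, tf.voxel_size_mm)
    qc = list(rois.qc_flags)
    counts: dict[str, int] = {}
    means: dict[str, dict[str, float]] = {}
    for key in ROI_KEYS:
        roi = rois[key]
        idx, clipped = rasterize_roi(
            roi.center, roi.diameter_mm, tf.voxel_size_mm, tf.grid_shape
        )
        sel = (idx[:, 0], idx[:, 1], idx[:, 2])
        counts[key] = len(idx)
        means[key] = {
            "dxx": float(tf.dxx[sel].mean()),
            "dyy": float(tf.dyy[sel].mean()),
            "dzz": float(tf.dzz[sel].mean()),
            "fa": float(tf.fa[sel].mean()),
        }
        if clipped and f"{key}: ROI clipped at grid boundary" not in qc:
            qc.append(f"{key}: ROI clipped at grid boundary")
        if means[key]["fa"] < LOW_FA_FLAG_THRESHOLD:
            flag = f"{key}: mean ROI FA {means[key]['fa']:.3f} < {LOW_FA_FLAG_THRESHOLD}"
            if flag not in qc:
                qc.append(flag)

    dx_proj, dy_proj, dx_assoc, dz_assoc, alps = {}, {}, {}, {}, {}
    for h in ("L", "R"):
        dx_proj[h] = means[f"proj_{h}"]["dxx"]
        dy_proj[h] = means[f"proj_{h}"]["dyy"]
        dx_assoc[h] = means[f"assoc_{h}"]["dxx"]
        dz_assoc[h] = means[f"assoc_{h}"]["dzz"]
        alps[h] = alps_from_diffusivities(
            dx_proj[h], dx_assoc[h], dy_proj[h], dz_assoc[h]
        )
    return ALPSResult(
        dx_proj=dx_proj,
        dy_proj=dy_proj,
        dx_assoc=dx_assoc,
        dz_assoc=dz_assoc,
        alps=alps,
        mean_alps=(alps["L"] + alps["R"]) / 2.0,
        roi_voxel_counts=counts,
        qc_flags=qc,
    )


def alps_batch(subjects: list[dict]) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Compute ALPS for a list of subjects; failures are logged, not fatal.

    Each subject dict needs an ``id`` plus either in-memory objects
    (``tf`` TensorField, or ``dwi`` DWIVolume) or file paths (``nifti``,
    ``bvals``, ``bvecs``), and ROIs (``rois`` ROISet, ``truth``
    PhantomTruth, or ``roi_centers`` mapping).

    Returns (results table with one row per successful subject, list of
    (id, error message) for failures).
    """
    if not subjects:
        raise ValueError("empty subject list")
    ids = [s.get("id") for s in subjects]
    dupes = {i for i in ids if ids.count(i) > 1}
    if None in ids or dupes:
        raise ValueError(f"subject ids must be unique and present (duplicates: {sorted(dupes)})")

    rows, failures = [], []
    for subj in subjects:
        sid = subj["id"]
        try:
            if "tf" in subj:
                tf = subj["tf"]
            elif "dwi" in subj:
                tf = fit_tensor(subj["dwi"], subj.get("mask"))
            else:
                dwi = load_dwi(subj["nifti"], subj["bvals"], subj["bvecs"])
                tf = fit_tensor(dwi, subj.get("mask"))
            if "rois" in subj:
                rois = subj["rois"]
            elif "truth" in subj:
                rois = place_default_rois(subj["truth"], tf)
            else:
                rois = place_default_rois(subj["roi_centers"], tf)
            res = compute_alps(tf, rois)
            rows.append({"id": sid, **res.as_row()})
        except Exception as exc:  # noqa: BLE001 - batch isolation is the contract
            log.warning("ALPS failed for subject %s: %s", sid, exc)
            failures.append((sid, str(exc)))
    return pd.DataFrame(rows), failures


def save_alps_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
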