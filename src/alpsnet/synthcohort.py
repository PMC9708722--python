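"""Synthetic diffusion phantoms and cohort simulators with known ground truth.

Three generators stand in for patient data so that every downstream stage of
the pipeline (tensor fit, ALPS index, tractography, connectome metrics,
mediation statistics) can be validated against an analytic oracle:

``generate_dwi_phantom``
    A diffusion-weighted acquisition of a digital phantom built in
    atlas-aligned axes (x = right-left, y = anterior-posterior,
    z = inferior-superior): a CSF-filled ventricle proxy flanked by
    projection-fiber bundles (principal axis z) and association-fiber
    bundles (principal axis y), with a tunable additive x-axis diffusivity
    (the perivascular component the ALPS index measures).  The forward model
    is the Stejskal-Tanner signal equation with optional Rician noise.

``generate_tract_phantom``
    A tensor field with fiber bundles following arbitrary voxel polylines
    (FA ~ 0.8 inside, < 0.2 outside) plus a parcellation labeling the bundle
    endpoints, with the true region adjacency recorded -- the oracle for
    deterministic tractography and connectome construction.

``simulate_cohort``
    Per-subject covariate tables following a single-mediator structural
    model: ALPS ~ N(group mean, group SD); Eg = alpha + a*ALPS + e1;
    MoCA = mu + c'*ALPS + b*Eg + covariates + e2, clipped to [0, 30].
    Defaults use the normal-cognition / vascular-cognitive-impairment group
    means 1.95 +/- 0.11 and 1.80 +/- 0.16.

All diffusivities are in um^2/ms (= 1e-3 mm^2/s).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dti import DWIVolume, TensorField, tensorfield_from_tensors

log = logging.getLogger(__name__)

CSF_DIFFUSIVITY = 3.0  # um^2/ms, free water at body temperature


class GeometryError(ValueError):
    """Raised for invalid phantom geometry (overlaps, out-of-grid paths)."""


# ---------------------------------------------------------------------------
# Gradient scheme
# ---------------------------------------------------------------------------

def gradient_directions(n: int, seed: int = 20220, n_iter: int = 400) -> np.ndarray:
    """Electrostatically spread unit gradient directions, deterministic.

    Points (with their antipodes, since the tensor model is antipodally
    symmetric) start from a seeded random draw on the sphere and relax under
    pairwise Coulomb repulsion, then are renormalized each step.
    """
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    step = 1.0 / n
    for _ in range(n_iter):
        diff = v[:, None, :] - v[None, :, :]
        summ = v[:, None, :] + v[None, :, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            dn = np.linalg.norm(diff, axis=-1) ** 3
            sn = np.linalg.norm(summ, axis=-1) ** 3
            f = np.where(dn[..., None] > 0, diff / dn[..., None], 0.0)
            f = f + np.where(sn[..., None] > 0, summ / sn[..., None], 0.0)
        v = v + step * f.sum(axis=1)
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v


# ---------------------------------------------------------------------------
# DWI phantom
# ---------------------------------------------------------------------------

@dataclass
class BundleSpec:
    """A rectangular fiber bundle: half-open voxel extent per axis, principal
    axis ('z' projection, 'y' association), axial eigenvalues in um^2/ms."""

    extent: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    axis: str  # 'y' or 'z'
    lambda_par: float = 1.2
    lambda_perp: float = 0.3


def _default_bundles() -> dict[str, BundleSpec]:
    # 40x40x20 grid: ventricle in the middle, projection bundles beside it,
    # association bundles lateral to those.
    return {
        "projection_L": BundleSpec(((13, 17), (12, 28), (2, 18)), "z"),
        "projection_R": BundleSpec(((23, 27), (12, 28), (2, 18)), "z"),
        "association_L": BundleSpec(((8, 12), (8, 32), (2, 18)), "y"),
        "association_R": BundleSpec(((28, 32), (8, 32), (2, 18)), "y"),
    }


@dataclass
class PhantomConfig:
    """Geometry, diffusivity and acquisition settings for the DWI phantom."""

    grid_shape: tuple[int, int, int] = (40, 40, 20)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    bundles: dict[str, BundleSpec] = field(default_factory=_default_bundles)
    #: additive x-axis diffusivity inside the periventricular bundles,
    #: scalar or {'L': dL, 'R': dR}.  Default 0.24 on lambda_perp 0.3 gives
    #: an analytic ALPS of 0.54/0.30 = 1.8.
    perivascular_delta: float | dict[str, float] = 0.24
    background_diffusivity: float = 0.8
    ventricle_extent: tuple = ((17, 23), (12, 28), (4, 16))
    csf_diffusivity: float = CSF_DIFFUSIVITY
    b_values: tuple[float, ...] = (0.0, 1000.0)
    n_directions: int = 64
    directions: np.ndarray | None = None  # override for the b>0 scheme
    s0: float = 100.0
    snr: float = np.inf  # Rician S0/sigma; inf = noiseless
    seed: int = 0

    def delta(self, hemisphere: str) -> float:
        if isinstance(self.perivascular_delta, dict):
            return float(self.perivascular_delta[hemisphere])
        return float(self.perivascular_delta)

    def validate(self) -> None:
        if self.background_diffusivity <= 0 or self.csf_diffusivity <= 0:
            raise ValueError("diffusivities must be positive")
        for name, b in self.bundles.items():
            if b.lambda_par <= 0 or b.lambda_perp <= 0:
                raise ValueError(f"{name}: diffusivities must be positive")
            if b.lambda_par < b.lambda_perp:
                # equality is allowed: an isotropic "bundle" is the
                # degenerate phantom whose analytic ALPS is exactly 1
                raise ValueError(f"{name}: lambda_par must be >= lambda_perp")
            if b.axis not in ("y", "z"):
                raise ValueError(f"{name}: axis must be 'y' or 'z'")
            if self.delta(_hemisphere(name)) < 0:
                raise ValueError("perivascular_delta must be >= 0")
        extents = {**{k: b.extent for k, b in self.bundles.items()},
                   "ventricle": self.ventricle_extent}
        names = list(extents)
        for i, ni in enumerate(names):
            for lo, hi in extents[ni]:
                if not (0 <= lo < hi):
                    raise GeometryError(f"{ni}: bad extent {extents[ni]}")
            for g, e in zip(self.grid_shape, extents[ni]):
                if e[1] > g:
                    raise GeometryError(f"{ni}: extent exceeds grid {self.grid_shape}")
            for nj in names[i + 1:]:
                if _extents_overlap(extents[ni], extents[nj]):
                    raise GeometryError(f"bundle extents overlap: {ni} and {nj}")
        if not any(bv == 0 for bv in self.b_values):
            raise ValueError("at least one b=0 volume is required")
        if self.directions is not None:
            d = np.asarray(self.directions, dtype=float)
            norms = np.linalg.norm(d, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-3):
                raise ValueError("gradient directions must be unit vectors")
        elif self.n_directions < 6:
            raise ValueError("need at least 6 gradient directions")
        if self.snr <= 0:
            raise ValueError("snr must be positive (np.inf for noiseless)")


def _hemisphere(bundle_name: str) -> str:
    return "L" if bundle_name.endswith("_L") else "R"


def _extents_overlap(e1, e2) -> bool:
    return all(a[0] < b[1] and b[0] < a[1] for a, b in zip(e1, e2))


def _extent_slices(extent):
    return tuple(slice(lo, hi) for lo, hi in extent)


def _extent_center(extent) -> tuple[int, int, int]:
    return tuple(int((lo + hi) // 2) for lo, hi in extent)


@dataclass
class PhantomTruth:
    """Exact tensors, ROI centers, and per-bundle diffusivities of a phantom."""

    tensors: np.ndarray  # (X, Y, Z, 3, 3), noiseless ground truth
    roi_centers: dict[str, tuple[int, int, int]]  # keys proj_L/proj_R/assoc_L/assoc_R
    bundle_diffusivities: dict[str, tuple[float, float, float]]  # (Dxx, Dyy, Dzz)
    voxel_size_mm: tuple[float, float, float]

    def analytic_alps(self, hemisphere: str | None = None) -> float:
        """Closed-form ALPS value from the stored bundle diffusivities."""
        if hemisphere is None:
            return 0.5 * (self.analytic_alps("L") + self.analytic_alps("R"))
        dx_proj, dy_proj, _ = self.bundle_diffusivities[f"projection_{hemisphere}"]
        dx_assoc, _, dz_assoc = self.bundle_diffusivities[f"association_{hemisphere}"]
        return alps_from_diffusivities(dx_proj, dx_assoc, dy_proj, dz_assoc)


def alps_from_diffusivities(dx_proj, dx_assoc, dy_proj, dz_assoc) -> float:
    """ALPS index: mean(Dx_proj, Dx_assoc) / mean(Dy_proj, Dz_assoc)."""
    den = 0.5 * (dy_proj + dz_assoc)
    if den <= 0:
        raise ValueError("ALPS denominator mean(Dy_proj, Dz_assoc) must be > 0")
    return 0.5 * (dx_proj + dx_assoc) / den


def analytic_alps(truth: PhantomTruth) -> float:
    """Bilateral-mean ALPS oracle for a phantom (see :class:`PhantomTruth`)."""
    return truth.analytic_alps()


def _bundle_tensor(spec: BundleSpec, delta: float) -> np.ndarray:
    if spec.axis == "z":
        diag = (spec.lambda_perp + delta, spec.lambda_perp, spec.lambda_par)
    else:  # 'y', association
        diag = (spec.lambda_perp + delta, spec.lambda_par, spec.lambda_perp)
    return np.diag(diag)


def generate_dwi_phantom(config: PhantomConfig) -> tuple[DWIVolume, PhantomTruth]:
    """Simulate the DWI acquisition of the periventricular phantom.

    Signal follows S_i = S0 * exp(-b_i g_i^T D g_i) per voxel; Rician noise
    of scale S0/snr is applied when ``config.snr`` is finite.  The returned
    truth carries the exact tensors, the four ALPS ROI centers (one per
    bundle) and the augmented per-bundle diagonal diffusivities.
    """
    config.validate()
    grid = config.grid_shape

    tensors = np.zeros(grid + (3, 3))
    tensors[..., :, :] = np.diag([config.background_diffusivity] * 3)
    tensors[_extent_slices(config.ventricle_extent)] = np.diag(
        [config.csf_diffusivity] * 3
    )
    bundle_diffs: dict[str, tuple[float, float, float]] = {}
    roi_centers: dict[str, tuple[int, int, int]] = {}
    for name, spec in config.bundles.items():
        D = _bundle_tensor(spec, config.delta(_hemisphere(name)))
        tensors[_extent_slices(spec.extent)] = D
        bundle_diffs[name] = tuple(np.diag(D))
        short = ("proj_" if spec.axis == "z" else "assoc_") + _hemisphere(name)
        roi_centers[short] = _extent_center(spec.extent)

    if config.directions is not None:
        dirs = np.asarray(config.directions, dtype=float)
    else:
        dirs = gradient_directions(config.n_directions)

    bvals, bvecs = [], []
    for b in config.b_values:
        if b == 0:
            bvals.append(0.0)
            bvecs.append(np.array([0.0, 0.0, 0.0]))
        else:
            bvals.extend([float(b)] * len(dirs))
            bvecs.extend(dirs)
    bvals = np.array(bvals)
    bvecs = np.array(bvecs)

    # Stejskal-Tanner forward model; D in um^2/ms, b in s/mm^2 -> factor 1e-3
    quad = np.einsum("vi,xyzij,vj->xyzv", bvecs, tensors, bvecs)
    signal = config.s0 * np.exp(-bvals * 1e-3 * quad)

    if np.isfinite(config.snr):
        rng = np.random.default_rng(config.seed)
        sigma = config.s0 / config.snr
        n1 = rng.normal(0.0, sigma, signal.shape)
        n2 = rng.normal(0.0, sigma, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)

    dwi = DWIVolume(signal, bvals, bvecs, voxel_size_mm=config.voxel_size_mm)
    truth = PhantomTruth(tensors, roi_centers, bundle_diffs, config.voxel_size_mm)
    return dwi, truth


# ---------------------------------------------------------------------------
# Tract phantom
# ---------------------------------------------------------------------------

#: axially symmetric bundle eigenvalues giving FA ~ 0.80
TRACT_BUNDLE_EVALS = (1.2, 0.21, 0.21)


def generate_tract_phantom(
    grid_shape: tuple[int, int, int],
    bundle_paths: list[tuple[int, int, np.ndarray]],
    voxel_size_mm=(2.0, 2.0, 2.0),
    bundle_radius_vox: float = 1.5,
    region_radius_vox: int = 2,
    max_bend_deg: float = 90.0,
    background_diffusivity: float = 0.7,
    bundle_evals: tuple[float, float, float] = TRACT_BUNDLE_EVALS,
) -> tuple[TensorField, np.ndarray, set[tuple[int, int]]]:
    """Tensor field + parcellation for bundles along voxel polylines.

    Each entry of ``bundle_paths`` is ``(region_a, region_b, points)`` with
    ``points`` an (N, 3) polyline in voxel coordinates joining the two
    regions.  Voxels within ``bundle_radius_vox`` of the polyline get an
    axially symmetric tensor aligned with the local path tangent
    (FA ~ 0.8); the background is isotropic (FA = 0).  Cubic label boxes of
    radius ``region_radius_vox`` are stamped at the path endpoints.

    Returns the tensor field, the parcellation volume (0 = unlabeled), and
    the true region adjacency as a set of sorted label pairs.
    """
    grid = tuple(int(g) for g in grid_shape)
    lam_par, lam_perp = bundle_evals[0], bundle_evals[1]
    tensors = np.zeros(grid + (3, 3))
    tensors[..., :, :] = np.diag([background_diffusivity] * 3)
    parcellation = np.zeros(grid, dtype=int)
    adjacency: set[tuple[int, int]] = set()

    idx = np.indices(grid).reshape(3, -1).T.astype(float)  # voxel centers

    for region_a, region_b, points in bundle_paths:
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
            raise ValueError("each path needs >= 2 points of 3 coordinates")
        if np.any(pts < 0) or np.any(pts >= np.array(grid)):
            raise GeometryError("bundle path exits the grid")
        seg = np.diff(pts, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        if np.any(seg_len == 0):
            raise ValueError("zero-length path segment")
        tang = seg / seg_len[:, None]
        for t0, t1 in zip(tang[:-1], tang[1:]):
            ang = np.degrees(np.arccos(np.clip(t0 @ t1, -1.0, 1.0)))
            if ang > max_bend_deg + 1e-9:
                raise GeometryError(
                    f"path bend {ang:.1f} deg exceeds max {max_bend_deg} deg"
                )
        for k in range(len(seg)):
            a, b = pts[k], pts[k + 1]
            t = tang[k]
            # distance of every voxel center to segment [a, b]
            ap = idx - a
            proj = np.clip(ap @ t, 0.0, seg_len[k])
            closest = a + proj[:, None] * t
            d = np.linalg.norm(idx - closest, axis=1)
            inside = d <= bundle_radius_vox
            D = lam_perp * np.eye(3) + (lam_par - lam_perp) * np.outer(t, t)
            ii = idx[inside].astype(int)
            tensors[ii[:, 0], ii[:, 1], ii[:, 2]] = D
        for label, endpoint in ((region_a, pts[0]), (region_b, pts[-1])):
            c = np.round(endpoint).astype(int)
            lo = np.maximum(c - region_radius_vox, 0)
            hi = np.minimum(c + region_radius_vox + 1, grid)
            parcellation[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = label
        adjacency.add(tuple(sorted((int(region_a), int(region_b)))))

    tf = tensorfield_from_tensors(tensors, voxel_size_mm)
    return tf, parcellation, adjacency


def straight_bundle_phantom(grid=(11, 11, 36), **kwargs):
    """Single straight z-axis bundle joining regions 1 (bottom) and 2 (top)."""
    c = grid[0] // 2
    path = np.array([[c, c, 3.0], [c, c, grid[2] - 4.0]])
    return generate_tract_phantom(grid, [(1, 2, path)], **kwargs)


def kinked_bundle_phantom(grid=(11, 31, 31), kink_deg: float = 90.0, **kwargs):
    """A bundle with a single in-plane kink of ``kink_deg`` degrees.

    Runs along +z then turns toward +y; at 90 degrees, tracking with a
    45-degree turning threshold must terminate at the kink.
    """
    c = grid[0] // 2
    leg = 12.0
    start = np.array([c, 5.0, 3.0])
    kink = start + np.array([0.0, 0.0, leg])
    rad = np.radians(kink_deg)
    d2 = np.array([0.0, np.sin(rad), np.cos(rad)])
    end = kink + leg * d2
    path = np.vstack([start, kink, end])
    kwargs.setdefault("max_bend_deg", kink_deg)
    return generate_tract_phantom(grid, [(1, 2, path)], **kwargs)


def two_bundle_phantom(grid=(21, 11, 36), **kwargs):
    """Two disjoint straight bundles: regions 1-2 and 3-4."""
    z0, z1 = 3.0, grid[2] - 4.0
    p1 = np.array([[5.0, 5.0, z0], [5.0, 5.0, z1]])
    p2 = np.array([[15.0, 5.0, z0], [15.0, 5.0, z1]])
    return generate_tract_phantom(grid, [(1, 2, p1), (3, 4, p2)], **kwargs)


# ---------------------------------------------------------------------------
# Cohort simulator
# ---------------------------------------------------------------------------

@dataclass
class CohortParams:
    """Parameters of the simulated two-group cohort.

    Group order in all per-group tuples is (NC, VCI) -- normal cognition
    first.  The mediation structural model is

        ALPS ~ Normal(alps_mean[g], alps_sd[g])
        Eg   = eg_intercept + a * ALPS + Normal(0, sd_eg)
        MoCA = moca_intercept + c_prime * ALPS + b * Eg
               + beta_age * age + beta_sex * sex + beta_edu * education
               + Normal(0, sd_moca), clipped to [0, 30]

    so the true indirect effect of ALPS on MoCA through Eg is a * b and the
    true total effect is c_prime + a * b.  When ``eg_intercept`` /
    ``moca_intercept`` are None they are calibrated so the expected Eg and
    MoCA of the NC group equal ``eg_target_nc`` / ``moca_target_nc``
    regardless of the structural coefficients chosen.
    """

    n: tuple[int, int] = (77, 79)
    alps_mean: tuple[float, float] = (1.95, 1.80)
    alps_sd: tuple[float, float] = (0.11, 0.16)
    # structural coefficients
    a: float = 0.05
    b: float = 150.0
    c_prime: float = 15.0
    eg_intercept: float | None = None
    moca_intercept: float | None = None
    eg_target_nc: float = 0.204
    moca_target_nc: float = 26.38
    sd_eg: float = 0.008
    sd_moca: float = 2.5
    beta_age: float = -0.05
    beta_sex: float = 0.0
    beta_edu: float = 0.1
    # covariate distributions per group
    age_mean: tuple[float, float] = (60.48, 61.65)
    age_sd: tuple[float, float] = (4.51, 5.35)
    edu_mean: tuple[float, float] = (12.84, 12.47)
    edu_sd: tuple[float, float] = (2.52, 2.71)
    p_female: tuple[float, float] = (0.324, 0.253)
    p_hypertension: tuple[float, float] = (0.415, 0.708)
    p_diabetes: tuple[float, float] = (0.285, 0.443)
    p_hyperlipemia: tuple[float, float] = (0.597, 0.405)
    p_smoking: tuple[float, float] = (0.324, 0.594)
    fsrp_mean: tuple[float, float] = (6.69, 10.46)
    fsrp_sd: tuple[float, float] = (3.65, 4.30)
    lacune_mean: tuple[float, float] = (0.7, 5.0)
    wmh_log_mean: tuple[float, float] = (-0.8, 1.45)
    wmh_log_sd: tuple[float, float] = (1.1, 1.1)
    epvs_bg_probs: tuple = (
        (0.05, 0.30, 0.50, 0.10, 0.05),
        (0.02, 0.13, 0.70, 0.10, 0.05),
    )
    epvs_cs_probs: tuple = (
        (0.30, 0.50, 0.15, 0.04, 0.01),
        (0.25, 0.50, 0.18, 0.05, 0.02),
    )
    seed: int | None = None

    def validate(self) -> None:
        if min(self.n) < 3:
            raise ValueError("at least 3 subjects per group are required")
        for s in (self.sd_eg, self.sd_moca, *self.alps_sd):
            if s < 0:
                raise ValueError("residual / group SDs must be >= 0")

    def resolved_intercepts(self) -> tuple[float, float]:
        """(eg_intercept, moca_intercept), calibrating Nones to NC targets."""
        alps0 = self.alps_mean[0]
        eg0 = self.eg_intercept
        if eg0 is None:
            eg0 = self.eg_target_nc - self.a * alps0
        moca0 = self.moca_intercept
        if moca0 is None:
            eg_nc = eg0 + self.a * alps0
            moca0 = (
                self.moca_target_nc
                - self.c_prime * alps0
                - self.b * eg_nc
                - self.beta_age * self.age_mean[0]
                - self.beta_sex * self.p_female[0]
                - self.beta_edu * self.edu_mean[0]
            )
        return float(eg0), float(moca0)


_SUBGROUPS = {0: (("HC", 30), ("SVDN", 33), ("PSCN", 14)), 1: (("SVCI", 40), ("PSCI", 39))}


def _subgroup_labels(group_idx: int, n: int) -> list[str]:
    specs = _SUBGROUPS[group_idx]
    total = sum(w for _, w in specs)
    counts = [int(round(n * w / total)) for _, w in specs]
    counts[-1] = n - sum(counts[:-1])
    out = []
    for (name, _), c in zip(specs, counts):
        out.extend([name] * c)
    return out


def simulate_cohort(params: CohortParams) -> pd.DataFrame:
    """Simulate the per-subject covariate table (see :class:`CohortParams`).

    Deterministic under a fixed ``params.seed``.  Columns: id, group,
    subgroup, age, sex (1 = female), education, hypertension, diabetes,
    hyperlipemia, smoking, fsrp, lacune_count, wmh_volume_ml, epvs_bg,
    epvs_cs, mean_alps, Eg, MoCA.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    eg0, moca0 = params.resolved_intercepts()

    frames = []
    for g, gname in enumerate(("NC", "VCI")):
        n = params.n[g]
        alps = rng.normal(params.alps_mean[g], params.alps_sd[g], n)
        age = rng.normal(params.age_mean[g], params.age_sd[g], n)
        sex = (rng.random(n) < params.p_female[g]).astype(int)
        edu = rng.normal(params.edu_mean[g], params.edu_sd[g], n)
        hyp = (rng.random(n) < params.p_hypertension[g]).astype(int)
        dia = (rng.random(n) < params.p_diabetes[g]).astype(int)
        lip = (rng.random(n) < params.p_hyperlipemia[g]).astype(int)
        smo = (rng.random(n) < params.p_smoking[g]).astype(int)
        fsrp = rng.normal(params.fsrp_mean[g], params.fsrp_sd[g], n)
        lac = rng.poisson(params.lacune_mean[g], n)
        wmh = np.exp(rng.normal(params.wmh_log_mean[g], params.wmh_log_sd[g], n))
        epvs_bg = rng.choice(5, size=n, p=params.epvs_bg_probs[g])
        epvs_cs = rng.choice(5, size=n, p=params.epvs_cs_probs[g])

        eg = eg0 + params.a * alps + rng.normal(0.0, params.sd_eg, n)
        moca = (
            moca0
            + params.c_prime * alps
            + params.b * eg
            + params.beta_age * age
            + params.beta_sex * sex
            + params.beta_edu * edu
            + rng.normal(0.0, params.sd_moca, n)
        )
        moca = np.clip(moca, 0.0, 30.0)

        frames.append(
            pd.DataFrame(
                {
                    "group": gname,
                    "subgroup": _subgroup_labels(g, n),
                    "age": age,
                    "sex": sex,
                    "education": edu,
                    "hypertension": hyp,
                    "diabetes": dia,
                    "hyperlipemia": lip,
                    "smoking": smo,
                    "fsrp": fsrp,
                    "lacune_count": lac,
                    "wmh_volume_ml": wmh,
                    "epvs_bg": epvs_bg,
                    "epvs_cs": epvs_cs,
                    "mean_alps": alps,
                    "Eg": eg,
                    "MoCA": moca,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "id", [f"S{i:04d}" for i in range(len(df))])
    return df


# ---------------------------------------------------------------------------
# Serialization helpers
# ---------------------------------------------------------------------------

def save_phantom_truth(truth: PhantomTruth, path) -> None:
    """Write the (non-array) truth summary as JSON; tensors go to .npy."""
    path = Path(path)
    payload = {
        "roi_centers": {k: list(v) for k, v in truth.roi_centers.items()},
        "bundle_diffusivities": {
            k: list(v) for k, v in truth.bundle_diffusivities.items()
        },
        "voxel_size_mm": list(truth.voxel_size_mm),
        "analytic_alps": truth.analytic_alps(),
    }
    path.write_text(json.dumps(payload, indent=2))


def save_phantom_config(config: PhantomConfig, path) -> None:
    d = asdict(config)
    d["snr"] = None if np.isinf(config.snr) else config.snr
    d.pop("directions", None)
    Path(path).write_text(json.dumps(d, indent=2, default=list))
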