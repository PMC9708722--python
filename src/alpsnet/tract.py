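"""FACT deterministic tractography and structural connectome assembly.

Fiber Assignment by Continuous Tracking (FACT) steps along the principal
eigenvector of the voxel containing the current point (nearest-neighbour
lookup, no interpolation), sign-aligned with the current heading, and
terminates when the local FA falls below a threshold, the turn between
successive step directions exceeds an angle threshold, or the track leaves
the grid.  Tracking is bidirectional from each seed; the two half-tracks
are concatenated.  Defaults follow the common deterministic-tractography
protocol: FA threshold 0.2, turning angle 45 degrees, 1 mm steps (half a
voxel), streamlines kept when 10 mm <= length <= 300 mm.

A streamline contributes one count to region pair (A, B) of the connectome
when its two endpoints fall in voxels labeled A and B (A != B) of the
parcellation; streamlines with an unlabeled endpoint are discarded.  Three
symmetric matrices are accumulated per pair: fiber number, mean streamline
FA, and mean streamline length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dti import TensorField

log = logging.getLogger(__name__)


@dataclass
class TrackingParams:
    fa_threshold: float = 0.2
    angle_threshold_deg: float = 45.0
    step_mm: float = 1.0
    min_length_mm: float = 10.0
    max_length_mm: float = 300.0
    seeds_per_voxel: int = 1
    seed: int | None = None  # RNG for seed-point jitter when seeds_per_voxel > 1

    def validate(self) -> None:
        if not 0.0 < self.fa_threshold < 1.0:
            raise ValueError("fa_threshold must be in (0, 1)")
        if not 0.0 < self.angle_threshold_deg <= 90.0:
            raise ValueError("angle_threshold_deg must be in (0, 90]")
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")
        if self.min_length_mm < 0 or self.max_length_mm <= self.min_length_mm:
            raise ValueError("require 0 <= min_length_mm < max_length_mm")
        if self.seeds_per_voxel < 1:
            raise ValueError("seeds_per_voxel must be >= 1")


@dataclass
class Streamline:
    points: np.ndarray  # (N, 3) mm coordinates
    fa: np.ndarray  # (N,) FA sampled at the containing voxel

    @property
    def length_mm(self) -> float:
        return streamline_length(self)

    @property
    def mean_fa(self) -> float:
        return float(self.fa.mean())


def streamline_length(s: Streamline | np.ndarray) -> float:
    """Sum of Euclidean segment lengths in mm (requires >= 2 points)."""
    pts = s.points if isinstance(s, Streamline) else np.asarray(s, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("a streamline needs at least 2 points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _walk(
    start_mm: np.ndarray,
    heading: np.ndarray,
    fa: np.ndarray,
    e1: np.ndarray,
    voxel: np.ndarray,
    grid: np.ndarray,
    params: TrackingParams,
    max_steps: int,
) -> list[np.ndarray]:
    """One half-track from ``start_mm`` along ``heading``; returns the point
    list including the start."""
    cos_thresh = np.cos(np.radians(params.angle_threshold_deg))
    pts = [start_mm]
    p = start_mm
    h = heading
    upper = grid * voxel
    for _ in range(max_steps):
        idx = np.floor(p / voxel).astype(int)
        d = e1[idx[0], idx[1], idx[2]]
        if d @ h < 0:
            d = -d
        if d @ h < cos_thresh:  # turning angle exceeded
            break
        p_new = p + d * params.step_mm
        if np.any(p_new < 0) or np.any(p_new >= upper):
            break
        idx_new = np.floor(p_new / voxel).astype(int)
        if fa[idx_new[0], idx_new[1], idx_new[2]] < params.fa_threshold:
            break
        pts.append(p_new)
        p, h = p_new, d
    return pts


def fact_track(
    tf: TensorField,
    params: TrackingParams | None = None,
    seed_mask: np.ndarray | None = None,
) -> list[Streamline]:
    """Whole-volume FACT tracking.

    Seeds are placed at the center of every voxel with FA >= the threshold
    (restricted to ``seed_mask`` if given); ``seeds_per_voxel > 1`` adds
    uniformly jittered seeds using ``params.seed``.  Streamlines outside the
    [min, max] length window are dropped.
    """
    params = params or TrackingParams()
    params.validate()
    voxel = np.asarray(tf.voxel_size_mm, dtype=float)
    grid = np.asarray(tf.grid_shape, dtype=int)
    fa = tf.fa
    e1 = tf.e1
    max_steps = int(np.ceil(params.max_length_mm / params.step_mm)) + 1

    mask = fa >= params.fa_threshold
    if seed_mask is not None:
        mask = mask & np.asarray(seed_mask, dtype=bool)
    seeds_idx = np.argwhere(mask)
    if seeds_idx.size == 0:
        log.warning("fact_track: no seed voxels above FA %.2f", params.fa_threshold)
        return []

    rng = np.random.default_rng(params.seed)
    seed_points = []
    for rep in range(params.seeds_per_voxel):
        if rep == 0:  # first pass always at voxel centers (deterministic)
            offs = np.full((len(seeds_idx), 3), 0.5)
        else:
            offs = rng.random((len(seeds_idx), 3))
        seed_points.append((seeds_idx + offs) * voxel)
    seed_points = np.concatenate(seed_points, axis=0)
    seed_dirs = np.concatenate(
        [e1[seeds_idx[:, 0], seeds_idx[:, 1], seeds_idx[:, 2]]] * params.seeds_per_voxel,
        axis=0,
    )

    streamlines = []
    for p0, d0 in zip(seed_points, seed_dirs):
        fwd = _walk(p0, d0, fa, e1, voxel, grid, params, max_steps)
        bwd = _walk(p0, -d0, fa, e1, voxel, grid, params, max_steps)
        pts = np.array(bwd[::-1] + fwd[1:])
        if len(pts) < 2:
            continue
        length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        if not params.min_length_mm <= length <= params.max_length_mm:
            continue
        idx = np.floor(pts / voxel).astype(int)
        fas = fa[idx[:, 0], idx[:, 1], idx[:, 2]]
        streamlines.append(Streamline(points=pts, fa=fas))
    return streamlines


@dataclass
class Connectome:
    """Region-by-region structural connectivity matrices (zero diagonal)."""

    region_ids: np.ndarray  # sorted positive labels
    fiber_number: np.ndarray  # int counts, symmetric
    mean_fa: np.ndarray  # mean over streamlines of per-streamline mean FA
    mean_length: np.ndarray  # mean streamline length, mm
    n_unassigned: int = 0  # streamlines with an unlabeled endpoint
    region_index: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.region_index:
            self.region_index = {int(r): i for i, r in enumerate(self.region_ids)}


def build_connectome(
    streamlines: list[Streamline],
    parcellation: np.ndarray,
    tf: TensorField,
) -> Connectome:
    """Assemble fiber-number / mean-FA / mean-length matrices.

    Endpoint-to-region assignment uses the label of the voxel containing
    each endpoint only (no dilation); labels must be positive integers with
    0 meaning unlabeled.
    """
    parcellation = np.asarray(parcellation)
    if parcellation.shape != tf.grid_shape:
        raise ValueError(
            f"parcellation grid {parcellation.shape} != tensor grid {tf.grid_shape}"
        )
    if parcellation.min() < 0:
        raise ValueError("parcellation labels must be non-negative integers")
    region_ids = np.unique(parcellation)
    region_ids = region_ids[region_ids > 0]
    n = len(region_ids)
    index = {int(r): i for i, r in enumerate(region_ids)}
    voxel = np.asarray(tf.voxel_size_mm, dtype=float)

    count = np.zeros((n, n), dtype=int)
    fa_sum = np.zeros((n, n))
    len_sum = np.zeros((n, n))
    unassigned = 0
    for s in streamlines:
        ends = np.floor(s.points[[0, -1]] / voxel).astype(int)
        la = int(parcellation[ends[0, 0], ends[0, 1], ends[0, 2]])
        lb = int(parcellation[ends[1, 0], ends[1, 1], ends[1, 2]])
        if la == 0 or lb == 0 or la == lb:
            unassigned += 1
            continue
        i, j = index[la], index[lb]
        count[i, j] += 1
        count[j, i] += 1
        fa_sum[i, j] += s.mean_fa
        fa_sum[j, i] += s.mean_fa
        L = s.length_mm
        len_sum[i, j] += L
        len_sum[j, i] += L

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_fa = np.where(count > 0, fa_sum / np.maximum(count, 1), 0.0)
        mean_length = np.where(count > 0, len_sum / np.maximum(count, 1), 0.0)
    return Connectome(
        region_ids=region_ids,
        fiber_number=count,
        mean_fa=mean_fa,
        mean_length=mean_length,
        n_unassigned=unassigned,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_connectome(conn: Connectome, out_dir, stem: str = "connectome") -> dict[str, Path]:
    """Write the three matrices as TSV with a region-id header row/column."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    ids = [int(r) for r in conn.region_ids]
    for name, mat in (
        ("fiber_number", conn.fiber_number),
        ("mean_fa", conn.mean_fa),
        ("mean_length", conn.mean_length),
    ):
        p = out / f"{stem}_{name}.tsv"
        pd.DataFrame(mat, index=ids, columns=ids).to_csv(p, sep="\t")
        paths[name] = p
    return paths


def load_connectome_matrix(path) -> tuple[np.ndarray, np.ndarray]:
    """Read one connectome TSV; returns (region_ids, matrix)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.index.to_numpy(dtype=int), df.to_numpy(dtype=float)


def save_streamlines_jsonl(streamlines: list[Streamline], path) -> None:
    """Streamlines as JSON-lines polylines (one object per line)."""
    import json

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for s in streamlines:
            fh.write(
                json.dumps(
                    {"points_mm": s.points.round(6).tolist(),
                     "fa": s.fa.round(6).tolist()}
                )
                + "\n"
            )
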