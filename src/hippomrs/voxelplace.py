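"""Voxel-iteration placement of a fixed-size MRS box on a hippocampus mask.

The placement scheme mirrors the in-house iterative procedure: candidate box
positions are scanned on a regular translation grid (optionally with
rotations), the overlap between the box and the labelled hippocampus cells is
recorded for each candidate, and the position with the largest overlapping
volume wins.  Overlap is measured by counting mask grid cells whose centres
fall inside the (possibly rotated) box, times the cell volume — matching the
discretisation of the segmentation itself.

Ties are broken deterministically: minimal Euclidean distance from the box
centre to the mask centroid, then lexicographic (x, y, z) order.

All geometry is done in world millimetres via the NIfTI affine; the
orientation string (default "LAS") is carried verbatim for the location-file
round trip only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .volumes import EmptyMaskError, LabelVolume

__all__ = [
    "VoxelPlacement",
    "SearchConfig",
    "OverlapReport",
    "InvalidConfigError",
    "InvalidTransformError",
    "OutOfBoundsError",
    "VoxelLocationParseError",
    "optimize_placement",
    "overlap_between",
    "map_placement",
    "simulate_repeat_sessions",
    "tissue_fractions",
    "write_voxel_location",
    "read_voxel_location",
]


class InvalidConfigError(ValueError):
    pass


class InvalidTransformError(ValueError):
    pass


class OutOfBoundsError(ValueError):
    pass


class VoxelLocationParseError(ValueError):
    pass


@dataclass
class VoxelPlacement:
    """An oriented box in world mm: centre, edge lengths, Euler rotations
    (degrees, about the x/y/z world axes, applied in x-y-z order)."""

    center_mm: tuple
    size_mm: tuple = (10.0, 10.0, 15.0)
    rotation_deg: tuple = (0.0, 0.0, 0.0)
    orientation: str = "LAS"
    label: str = "left"
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.center_mm = tuple(float(v) for v in self.center_mm)
        self.size_mm = tuple(float(v) for v in self.size_mm)
        self.rotation_deg = tuple(float(v) for v in self.rotation_deg)
        if any(s <= 0 for s in self.size_mm):
            raise InvalidConfigError("size_mm must be positive componentwise")
        if any(not (-180.0 < r <= 180.0) for r in self.rotation_deg):
            raise InvalidConfigError("rotation angles must lie in (-180, 180]")

    @property
    def volume_mm3(self) -> float:
        return float(np.prod(self.size_mm))

    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()

    def contains(self, points_mm: np.ndarray, eps: float = 1e-9) -> np.ndarray:
        """Boolean mask of world points inside the box.

        Faces are half-open (``-s/2 <= d < s/2`` per axis) so that a lattice
        of cell centres aligned with the box is counted exactly once per
        cell and the counted volume never exceeds the box volume."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        local = (pts - np.asarray(self.center_mm)) @ self.rotation_matrix()
        half = np.asarray(self.size_mm) / 2.0
        return np.all((local >= -half - eps) & (local < half - eps), axis=1)


@dataclass(frozen=True)
class SearchConfig:
    """Candidate grid: translations at ``step_mm`` over the mask bounding box
    padded by one box length; rotations off by default, otherwise scanned in
    ``rotation_step_deg`` increments within ±``rotation_range_deg`` about
    each axis."""

    step_mm: float = 1.0
    search_rotations: bool = False
    rotation_step_deg: float = 5.0
    rotation_range_deg: float = 10.0

    def __post_init__(self) -> None:
        if self.step_mm <= 0:
            raise InvalidConfigError("step_mm must be positive")
        if self.search_rotations and self.rotation_step_deg <= 0:
            raise InvalidConfigError("rotation_step_deg must be positive")

    def rotation_candidates(self):
        if not self.search_rotations:
            return [(0.0, 0.0, 0.0)]
        steps = np.arange(
            -self.rotation_range_deg,
            self.rotation_range_deg + 1e-9,
            self.rotation_step_deg,
        )
        return [(float(a), float(b), float(c)) for a in steps for b in steps for c in steps]


@dataclass
class OverlapReport:
    overlap_volume_mm3: float
    overlap_fraction_pct: float
    n_candidates_evaluated: int


def _candidate_axes(points: np.ndarray, size_mm, step_mm: float) -> list:
    """Per-axis candidate coordinates, anchored at the mask centroid and
    covering the mask's bounding box padded by one box length on each side."""
    centroid = points.mean(axis=0)
    size = np.asarray(size_mm, dtype=float)
    lo = points.min(axis=0) - size
    hi = points.max(axis=0) + size
    axes = []
    for a in range(3):
        n_lo = int(np.ceil((centroid[a] - lo[a]) / step_mm))
        n_hi = int(np.ceil((hi[a] - centroid[a]) / step_mm))
        axes.append(centroid[a] + step_mm * np.arange(-n_lo, n_hi + 1))
    return axes


def _counts_axis_aligned(points: np.ndarray, axes: list, size_mm) -> np.ndarray:
    """Cells-inside-box counts for every axis-aligned candidate on the grid.

    The box-membership test factorises over axes, so the count over the whole
    candidate lattice is a single contraction of three incidence matrices."""
    half = np.asarray(size_mm, dtype=float) / 2.0
    eps = 1e-9
    inc = []
    for a in range(3):
        d = points[None, :, a] - axes[a][:, None]
        inc.append(((d >= -half[a] - eps) & (d < half[a] - eps)).astype(np.float32))
    counts = np.einsum("ip,jp,kp->ijk", inc[0], inc[1], inc[2], optimize=True)
    return np.rint(counts).astype(np.int64)


def optimize_placement(
    mask: LabelVolume,
    size_mm=(10.0, 10.0, 15.0),
    search: SearchConfig | None = None,
    label_value: int | None = None,
    side: str = "left",
    subject_id: str = "unknown",
) -> tuple[VoxelPlacement, OverlapReport]:
    """Exhaustively scan the candidate grid and return the placement with the
    maximal labelled volume inside the box.

    ``mask`` is a label volume; cells equal to ``label_value`` (default: any
    non-zero cell) count as hippocampus.
    """
    search = search if search is not None else SearchConfig()
    data = mask.data if label_value is None else (mask.data == label_value)
    idx = np.argwhere(data != 0 if label_value is None else data)
    if idx.size == 0:
        raise EmptyMaskError("mask contains no labelled cells")
    size = np.asarray(size_mm, dtype=float)
    grid_extent = np.asarray(mask.shape) * mask.voxel_size_mm
    if np.any(size > grid_extent):
        raise InvalidConfigError("box is larger than the grid extent")
    points = mask.world_coords(idx)
    cell_vol = mask.cell_volume_mm3
    centroid = points.mean(axis=0)

    axes = _candidate_axes(points, size, search.step_mm)
    centers = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    rotations = search.rotation_candidates()

    best = None  # (key, center, rotation, count)
    n_evaluated = 0
    for rot in rotations:
        if rot == (0.0, 0.0, 0.0):
            counts = _counts_axis_aligned(points, axes, size).reshape(-1)
        else:
            rmat = Rotation.from_euler("xyz", rot, degrees=True).as_matrix()
            half = size / 2.0
            counts = np.empty(centers.shape[0], dtype=np.int64)
            for i, c in enumerate(centers):
                local = (points - c) @ rmat
                inside = np.all(
                    (local >= -half - 1e-9) & (local < half - 1e-9), axis=1
                )
                counts[i] = int(inside.sum())
        n_evaluated += centers.shape[0]
        cmax = counts.max()
        tied = np.flatnonzero(counts == cmax)
        d2 = np.sum((centers[tied] - centroid) ** 2, axis=1)
        order = np.lexsort(
            (centers[tied, 2], centers[tied, 1], centers[tied, 0], np.round(d2, 9))
        )
        pick = tied[order[0]]
        key = (
            -int(cmax),
            round(float(np.sum((centers[pick] - centroid) ** 2)), 9),
            tuple(np.round(centers[pick], 9)),
        )
        if best is None or key < best[0]:
            best = (key, centers[pick], rot, int(cmax))

    _, center, rot, count = best
    placement = VoxelPlacement(
        center_mm=tuple(center),
        size_mm=tuple(size),
        rotation_deg=rot,
        label=side,
        subject_id=subject_id,
    )
    overlap_vol = count * cell_vol
    report = OverlapReport(
        overlap_volume_mm3=float(overlap_vol),
        overlap_fraction_pct=float(100.0 * overlap_vol / placement.volume_mm3),
        n_candidates_evaluated=n_evaluated,
    )
    return placement, report


def overlap_between(
    reference: VoxelPlacement, follow_up: VoxelPlacement, resolution_mm: float = 0.5
) -> float:
    """Percentage of the reference-box volume encompassed by the follow-up
    box, estimated by dense point sampling at ``resolution_mm``."""
    if resolution_mm <= 0:
        raise InvalidConfigError("resolution_mm must be positive")
    size = np.asarray(reference.size_mm)
    n = np.maximum(np.round(size / resolution_mm).astype(int), 1)
    axes = [
        (np.arange(n[a]) + 0.5) / n[a] * size[a] - size[a] / 2.0 for a in range(3)
    ]
    local = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    world = local @ reference.rotation_matrix().T + np.asarray(reference.center_mm)
    inside = follow_up.contains(world)
    return float(100.0 * inside.mean())


def map_placement(p: VoxelPlacement, transform: np.ndarray) -> VoxelPlacement:
    """Apply a 4x4 homogeneous affine (atlas mm -> subject mm) to a placement.

    The rotational part of the affine (polar decomposition) composes with the
    placement's rotation.  Rigid transforms preserve the edge lengths; a
    non-rigid affine rescales them by its singular values and emits a warning.
    """
    transform = np.asarray(transform, dtype=float)
    if transform.shape != (4, 4) or not np.allclose(transform[3], [0, 0, 0, 1]):
        raise InvalidTransformError("transform must be 4x4 homogeneous")
    linear = transform[:3, :3]
    det = np.linalg.det(linear)
    if abs(det) < 1e-12:
        raise InvalidTransformError("transform matrix is singular")
    center = linear @ np.asarray(p.center_mm) + transform[:3, 3]
    u, s, vt = np.linalg.svd(linear)
    rot_part = u @ vt
    if np.linalg.det(rot_part) < 0:  # reflection: fold the flip into the scales
        u[:, -1] *= -1
        s = s.copy()
        s[-1] *= -1
        rot_part = u @ vt
    size = np.asarray(p.size_mm)
    if not np.allclose(np.abs(s), 1.0, atol=1e-8):
        size = np.abs(s) * size
        warnings.warn(
            "non-rigid affine: voxel edge lengths rescaled by singular values",
            UserWarning,
        )
    composed = rot_part @ p.rotation_matrix()
    angles = Rotation.from_matrix(composed).as_euler("xyz", degrees=True)
    angles = tuple(180.0 if np.isclose(a, -180.0) else float(a) for a in angles)
    return replace(
        p, center_mm=tuple(center), size_mm=tuple(size), rotation_deg=angles
    )


def tissue_fractions(p: VoxelPlacement, seg: LabelVolume, labels=None) -> dict:
    """Volumes (mm³) of CSF / GM / WM inside the box, by counting segmentation
    cell centres; ``V_total`` is the analytic box volume."""
    from .volumes import LABELS

    labels = labels if labels is not None else LABELS
    corners_local = (
        np.array(
            [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
            dtype=float,
        )
        * np.asarray(p.size_mm)
        / 2.0
    )
    corners = corners_local @ p.rotation_matrix().T + np.asarray(p.center_mm)
    inv_aff = np.linalg.inv(seg.affine)
    corner_idx = corners @ inv_aff[:3, :3].T + inv_aff[:3, 3]
    if np.any(corner_idx < -0.5) or np.any(
        corner_idx > np.asarray(seg.shape) - 0.5
    ):
        raise OutOfBoundsError("voxel box extends outside the segmented volume")

    # restrict to the cells inside the box's bounding region for speed
    lo = np.maximum(np.floor(corner_idx.min(axis=0)).astype(int) - 1, 0)
    hi = np.minimum(
        np.ceil(corner_idx.max(axis=0)).astype(int) + 2, np.asarray(seg.shape)
    )
    sub = seg.data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    idx = np.stack(
        np.meshgrid(*(np.arange(lo[a], hi[a]) for a in range(3)), indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    pts = seg.world_coords(idx)
    inside = p.contains(pts)
    vals = sub.reshape(-1)[inside]
    cell_vol = seg.cell_volume_mm3
    out = {"V_total": p.volume_mm3}
    # hippocampi are gray-matter structures: count them with GM
    tissue_labels = {
        "CSF": (labels["CSF"],),
        "GM": (labels["GM"], labels.get("hippoL"), labels.get("hippoR")),
        "WM": (labels["WM"],),
    }
    for tissue, lab_vals in tissue_labels.items():
        out[f"V_{tissue}"] = float(
            np.isin(vals, [v for v in lab_vals if v is not None]).sum() * cell_vol
        )
    out["V_other"] = float(
        inside.sum() * cell_vol - out["V_CSF"] - out["V_GM"] - out["V_WM"]
    )
    return out


def simulate_repeat_sessions(
    reference: VoxelPlacement,
    n_sessions: int = 6,
    seed: int = 0,
    translation_sd_mm: float = 0.5,
    rotation_sd_deg: float = 1.0,
    resolution_mm: float = 0.5,
) -> np.ndarray:
    """Cross-session geometric overlap of a re-prescribed voxel.

    At follow-up the recorded week-0 placement is re-prescribed on the
    scanner; residual repositioning error is modelled as a small rigid
    perturbation (independent per-axis Gaussian translation and rotation).
    Returns the percentage of the week-0 voxel volume encompassed by each
    follow-up voxel.
    """
    rng = np.random.default_rng(seed)
    overlaps = np.empty(n_sessions)
    for s in range(n_sessions):
        shift = rng.normal(0.0, translation_sd_mm, 3)
        tilt = rng.normal(0.0, rotation_sd_deg, 3)
        follow = replace(
            reference,
            center_mm=tuple(np.asarray(reference.center_mm) + shift),
            rotation_deg=tuple(
                float(np.clip(r + dr, -179.999, 180.0))
                for r, dr in zip(reference.rotation_deg, tilt)
            ),
        )
        overlaps[s] = overlap_between(reference, follow, resolution_mm)
    return overlaps


# ---------------------------------------------------------------------------
# Voxel_Location.txt round trip


_REQUIRED_KEYS = ("subject_id", "side", "center_mm", "size_mm", "rotation_deg", "orientation")


def write_voxel_location(placements, path) -> None:
    """Write one or more placements as UTF-8 key=value blocks separated by
    blank lines; floats carry 6 decimals."""
    if isinstance(placements, VoxelPlacement):
        placements = [placements]
    blocks = []
    for p in placements:
        fmt = lambda v: ",".join(f"{x:.6f}" for x in v)
        blocks.append(
            "\n".join(
                [
                    f"subject_id={p.subject_id}",
                    f"side={p.label}",
                    f"center_mm={fmt(p.center_mm)}",
                    f"size_mm={fmt(p.size_mm)}",
                    f"rotation_deg={fmt(p.rotation_deg)}",
                    f"orientation={p.orientation}",
                ]
            )
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n\n".join(blocks) + "\n")


def read_voxel_location(path):
    """Parse a voxel-location file; returns a list of placements (or a single
    placement if the file holds exactly one block)."""
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    placements = []
    for block in [b for b in text.split("\n\n") if b.strip()]:
        fields = {}
        for lineno, line in enumerate(block.strip().splitlines(), start=1):
            if not line.strip():
                continue
            if "=" not in line:
                raise VoxelLocationParseError(
                    f"malformed line {lineno!r}: {line.strip()!r} (expected key=value)"
                )
            key, _, value = line.partition("=")
            fields[key.strip()] = value.strip()
        missing = [k for k in _REQUIRED_KEYS if k not in fields]
        if missing:
            raise VoxelLocationParseError(
                f"block missing required field(s): {', '.join(missing)}"
            )

        def triple(key):
            parts = fields[key].split(",")
            if len(parts) != 3:
                raise VoxelLocationParseError(
                    f"field {key} must have 3 comma-separated floats, got {fields[key]!r}"
                )
            try:
                return tuple(float(v) for v in parts)
            except ValueError as exc:
                raise VoxelLocationParseError(f"field {key}: {exc}") from exc

        placements.append(
            VoxelPlacement(
                center_mm=triple("center_mm"),
                size_mm=triple("size_mm"),
                rotation_deg=triple("rotation_deg"),
                orientation=fields["orientation"],
                label=fields["side"],
                subject_id=fields["subject_id"],
            )
        )
    if not placements:
        raise VoxelLocationParseError("file contains no placement blocks")
    return placements[0] if len(placements) == 1 else placements
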