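"""Volume-normalized membrane-proximity enrichment profiles.

The central statistic of the package: each RNA molecule is assigned a
*normalized distance* to the nearest membrane of its enclosing cell
(Euclidean distance transform, scaled by the cell's maximum interior
distance so the deepest point maps to 1.0), molecules are binned in 10%
distance increments, and per-bin counts are divided by the volume fraction
of the concentric shell they occupy.  A value of 1 in a bin means the bin
holds exactly as many molecules as a uniformly random sample would; values
above 1 indicate enrichment toward the membrane (bin 1 = outermost 10%).

Cell geometry enters either as a 3D label mask or as manually drawn
per-slice polygons (rasterized here), mirroring how cell outlines are
annotated on real micrographs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage as ndi
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationConflictError",
    "CellAnnotation",
    "DegenerateCellError",
    "DistanceField",
    "EnrichmentProfile",
    "ProfileSet",
    "assign_and_profile",
    "auto_exclude_slices",
    "distance_field",
    "membrane_fraction",
    "rasterize_annotation",
]


class AnnotationConflictError(ValueError):
    """Two cell annotations claim overlapping interior area."""


class DegenerateCellError(ValueError):
    """A cell label has no usable interior."""


# --------------------------------------------------------------------------
# Annotations
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CellAnnotation:
    """Per-cell outlines: per-slice polygons *or* a 3D label mask.

    Parameters
    ----------
    polygons:
        ``{cell_id: {z_index: (n, 2) array of (y, x) vertices}}`` in pixel
        coordinates (pixel centers at integer coordinates).  Cell ids must
        be positive.  Mutually exclusive with ``label_mask``.
    label_mask:
        3D integer array, 0 = background, k > 0 = cell k.
    excluded_slices:
        z indices to drop entirely (e.g. top/bottom slices of the stack
        where cells are flattened or out of focus).
    """

    polygons: Mapping[int, Mapping[int, np.ndarray]] | None = None
    label_mask: np.ndarray | None = None
    excluded_slices: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        if (self.polygons is None) == (self.label_mask is None):
            raise ValueError("provide exactly one of polygons or label_mask")
        if self.polygons is not None and any(k <= 0 for k in self.polygons):
            raise ValueError("cell ids must be positive integers")


def rasterize_annotation(annotation: CellAnnotation, shape: tuple[int, int, int]) -> np.ndarray:
    """Rasterize an annotation into a 3D label volume of the given shape.

    Polygon fill uses the pixel-center convention with half-open edges:
    a pixel belongs to a cell iff the point just inside its center
    (center + epsilon on both axes) lies within the polygon, so an
    axis-aligned square of side ``s`` covers exactly ``s**2`` pixels and
    edge-sharing cells do not double-claim boundary pixels.  When two
    polygons share boundary pixels anyway, the first-listed cell wins
    (deterministic); overlapping *interiors* raise
    :class:`AnnotationConflictError`.
    """
    nz, ny, nx = shape
    if annotation.excluded_slices and max(annotation.excluded_slices) >= nz:
        raise ValueError("excluded_slices outside available z range")

    if annotation.label_mask is not None:
        if annotation.label_mask.shape != tuple(shape):
            raise ValueError(f"label_mask shape {annotation.label_mask.shape} != {tuple(shape)}")
        labels = np.asarray(annotation.label_mask, dtype=np.int32).copy()
        for z in annotation.excluded_slices:
            labels[z] = 0
        return labels

    labels = np.zeros(shape, dtype=np.int32)
    eps = 1e-7
    # Per-slice shapely polygons, validated once.
    polys: dict[int, dict[int, Polygon]] = {}
    for cell_id, slices in annotation.polygons.items():
        polys[cell_id] = {}
        for z, verts in slices.items():
            if not (0 <= z < nz):
                raise ValueError(f"cell {cell_id}: slice {z} outside stack of depth {nz}")
            p = Polygon(np.asarray(verts, dtype=float))
            if not p.is_valid:
                raise ValueError(f"cell {cell_id}, slice {z}: polygon is not simple")
            miny, minx, maxy, maxx = p.bounds
            if miny < -0.5 or minx < -0.5 or maxy > ny - 0.5 or maxx > nx - 0.5:
                raise ValueError(f"cell {cell_id}, slice {z}: polygon exceeds image bounds")
            polys[cell_id][z] = p

    # Disjointness of interiors, per slice.
    ids = list(polys)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            for z in set(polys[a]) & set(polys[b]):
                inter = polys[a][z].intersection(polys[b][z])
                if inter.area > 1e-9:
                    raise AnnotationConflictError(
                        f"cells {a} and {b} overlap in slice {z} (area {inter.area:.3g} px^2)"
                    )

    yy, xx = np.mgrid[0:ny, 0:nx]
    for cell_id in ids:  # insertion order == first-listed priority
        for z, p in polys[cell_id].items():
            if z in annotation.excluded_slices:
                continue
            miny, minx, maxy, maxx = p.bounds
            y0, y1 = max(int(np.floor(miny)), 0), min(int(np.ceil(maxy)) + 1, ny)
            x0, x1 = max(int(np.floor(minx)), 0), min(int(np.ceil(maxx)) + 1, nx)
            ys = yy[y0:y1, x0:x1]
            xs = xx[y0:y1, x0:x1]
            inside = shapely.contains_xy(p, ys + eps, xs + eps)
            sub = labels[z, y0:y1, x0:x1]
            sub[inside & (sub == 0)] = cell_id

    for z in annotation.excluded_slices:
        labels[z] = 0
    return labels


def auto_exclude_slices(labels: np.ndarray, min_area_fraction: float = 0.5) -> dict[int, set[int]]:
    """Per-cell z slices whose cross-sectional area is below a fraction of the
    cell's maximal slice area — a proxy for the flattened top/bottom slices
    that are excluded when annotating real stacks."""
    out: dict[int, set[int]] = {}
    for cell_id in np.unique(labels):
        if cell_id == 0:
            continue
        areas = (labels == cell_id).sum(axis=(1, 2))
        amax = areas.max()
        out[int(cell_id)] = {
            int(z) for z in np.nonzero((areas > 0) & (areas < min_area_fraction * amax))[0]
        }
    return out


# --------------------------------------------------------------------------
# Distance field
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceField:
    """Per-voxel distance (µm) to the nearest non-cell voxel, and the same
    distance normalized by the per-cell maximum interior distance.

    The raw distance follows the voxel-center convention of
    :func:`scipy.ndimage.distance_transform_edt`: a cell voxel face-adjacent
    to background in z has raw distance equal to the z spacing.  Voxels of
    neighboring cells count as boundary, so distances never cross cells.
    """

    distance: np.ndarray          # µm, 0 outside cells
    normalized: np.ndarray        # in (0, 1] inside cells, 0 outside
    max_distance: dict[int, float]  # per-cell normalization constant, µm
    voxel_size: tuple[float, float, float]


def distance_field(
    labels: np.ndarray,
    voxel_size: Sequence[float],
    normalization: str = "per_cell_max",
    fixed_radius: float | None = None,
) -> DistanceField:
    """Anisotropy-aware Euclidean distance transform inside each cell.

    Parameters
    ----------
    normalization:
        ``"per_cell_max"`` (default) divides by each cell's maximum interior
        distance, making bins comparable across cells of different size;
        ``"fixed_radius"`` divides by ``fixed_radius`` (µm) everywhere.
    """
    voxel_size = tuple(float(v) for v in voxel_size)
    if any(v <= 0 for v in voxel_size):
        raise ValueError("voxel_size components must be strictly positive")
    if normalization not in ("per_cell_max", "fixed_radius"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if normalization == "fixed_radius" and not (fixed_radius and fixed_radius > 0):
        raise ValueError("fixed_radius normalization requires a positive fixed_radius")

    labels = np.asarray(labels)
    cell_ids = [int(k) for k in np.unique(labels) if k > 0]
    if not cell_ids:
        raise DegenerateCellError("label volume contains no cells")

    dist = np.zeros(labels.shape, dtype=np.float64)
    norm = np.zeros(labels.shape, dtype=np.float64)
    dmax: dict[int, float] = {}
    objects = ndi.find_objects(labels)
    for cell_id in cell_ids:
        sl = objects[cell_id - 1]
        # pad by one voxel so the cell always sees background at its crop edge
        sl = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, n))
            for s, n in zip(sl, labels.shape)
        )
        mask = labels[sl] == cell_id
        d = ndi.distance_transform_edt(mask, sampling=voxel_size)
        m = float(d.max())
        if m <= 0:
            raise DegenerateCellError(f"cell {cell_id} has no interior voxels")
        dmax[cell_id] = m
        denom = m if normalization == "per_cell_max" else float(fixed_radius)
        dist[sl][mask] = d[mask]
        norm[sl][mask] = np.minimum(d[mask] / denom, 1.0)
    return DistanceField(distance=dist, normalized=norm, max_distance=dmax, voxel_size=voxel_size)


# --------------------------------------------------------------------------
# Profiles
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentProfile:
    """Binned, shell-volume-normalized radial profile for one cell (or pooled).

    ``normalized_frequency[b] = (counts[b]/total) / (shell_volumes[b]/cell_volume)``
    so a uniformly random sample gives 1 in every bin, and
    ``sum(freq * volume_fraction) == 1`` exactly whenever ``total > 0``.
    """

    cell_id: int | str
    n_bins: int
    counts: np.ndarray            # molecule-weighted spot counts per bin
    shell_volumes: np.ndarray     # µm^3 per bin

    def __post_init__(self):
        if len(self.counts) != self.n_bins or len(self.shell_volumes) != self.n_bins:
            raise ValueError("counts/shell_volumes length must equal n_bins")

    @property
    def total_count(self) -> float:
        return float(self.counts.sum())

    @property
    def cell_volume(self) -> float:
        return float(self.shell_volumes.sum())

    @property
    def volume_fractions(self) -> np.ndarray:
        return self.shell_volumes / self.cell_volume

    @property
    def normalized_frequency(self) -> np.ndarray:
        total = self.total_count
        freq = np.zeros(self.n_bins)
        if total <= 0:
            return freq
        vf = self.volume_fractions
        nonzero = vf > 0
        freq[nonzero] = (self.counts[nonzero] / total) / vf[nonzero]
        return freq


@dataclass(frozen=True)
class ProfileSet:
    """Per-cell profiles plus the pooled profile (counts and shell volumes
    summed across cells before renormalizing), and the per-spot assignments."""

    per_cell: dict[int, EnrichmentProfile]
    pooled: EnrichmentProfile
    assignments: pd.DataFrame     # columns: z_um, y_um, x_um, weight, cell_id, norm_dist, bin
    n_discarded: int
    n_reassigned: int

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (cell, bin), plus the pooled rows."""
        rows = []
        for key, prof in [*self.per_cell.items(), ("pooled", self.pooled)]:
            freq = prof.normalized_frequency
            for b in range(prof.n_bins):
                rows.append({
                    "cell_id": key,
                    "bin": b + 1,
                    "count": prof.counts[b],
                    "shell_volume_um3": prof.shell_volumes[b],
                    "norm_freq": freq[b],
                })
        return pd.DataFrame(rows)


def _positions_weights(spots) -> tuple[np.ndarray, np.ndarray]:
    """Accept a (n, 3) array, a GroundTruth-like object (``.positions``), or a
    sequence of CountedSpot/Spot objects."""
    if isinstance(spots, np.ndarray):
        pos = np.atleast_2d(np.asarray(spots, dtype=float))
        return pos, np.ones(len(pos))
    if hasattr(spots, "positions"):
        pos = np.atleast_2d(np.asarray(spots.positions, dtype=float))
        return pos, np.ones(len(pos))
    pos, w = [], []
    for s in spots:
        if hasattr(s, "spot"):  # CountedSpot
            pos.append(s.spot.position)
            w.append(s.molecule_count)
        else:
            pos.append(s.position)
            w.append(1.0)
    if not pos:
        return np.zeros((0, 3)), np.zeros(0)
    return np.asarray(pos, dtype=float), np.asarray(w, dtype=float)


def _bin_of(nd: np.ndarray, n_bins: int) -> np.ndarray:
    """Half-open bins [b/n, (b+1)/n) with the last bin closed at 1."""
    return np.minimum((nd * n_bins).astype(int), n_bins - 1)


def assign_and_profile(
    spots,
    dist: DistanceField,
    labels: np.ndarray,
    n_bins: int = 10,
) -> ProfileSet:
    """Assign spots to cells and build per-cell + pooled enrichment profiles.

    Spots falling on background are rescued to the adjacent cell if a labeled
    voxel exists within one voxel step in every axis (membrane-hugging spots
    are the signal of interest); otherwise they are discarded and counted in
    the discard report.  Counts are weighted by each spot's molecule count.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    labels = np.asarray(labels)
    if dist.normalized.shape != labels.shape:
        raise ValueError("distance field and label volume shapes differ")
    voxel = np.asarray(dist.voxel_size)
    shape = np.asarray(labels.shape)

    positions, weights = _positions_weights(spots)
    n_spots = len(positions)

    # Shell volumes per cell per bin from the voxelized normalized-distance field.
    cell_ids = [int(k) for k in np.unique(labels) if k > 0]
    voxel_volume = float(np.prod(voxel))
    shell: dict[int, np.ndarray] = {}
    for cid in cell_ids:
        nd_vals = dist.normalized[labels == cid]
        bins = _bin_of(nd_vals, n_bins)
        shell[cid] = np.bincount(bins, minlength=n_bins).astype(float) * voxel_volume

    rows = []
    n_discarded = 0
    n_reassigned = 0
    if n_spots:
        idx = np.floor(positions / voxel).astype(int)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        offsets = np.array(
            [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
             if (dz, dy, dx) != (0, 0, 0)]
        )
        for i in range(n_spots):
            if not inside[i]:
                n_discarded += 1
                continue
            v = idx[i]
            cid = int(labels[tuple(v)])
            if cid > 0:
                nd = float(dist.normalized[tuple(v)])
            else:
                # rescue: nearest labeled voxel within one voxel step
                cand = v + offsets
                ok = np.all((cand >= 0) & (cand < shape), axis=1)
                cand = cand[ok]
                lab = labels[cand[:, 0], cand[:, 1], cand[:, 2]]
                hit = lab > 0
                if not hit.any():
                    n_discarded += 1
                    continue
                cand = cand[hit]
                lab = lab[hit]
                centers = (cand + 0.5) * voxel
                j = int(np.argmin(np.sum((centers - positions[i]) ** 2, axis=1)))
                cid = int(lab[j])
                nd = float(dist.normalized[tuple(cand[j])])
                n_reassigned += 1
            rows.append((*positions[i], weights[i], cid, nd, int(min(nd * n_bins, n_bins - 1))))

    assignments = pd.DataFrame(
        rows, columns=["z_um", "y_um", "x_um", "weight", "cell_id", "norm_dist", "bin"]
    )
    per_cell: dict[int, EnrichmentProfile] = {}
    for cid in cell_ids:
        counts = np.zeros(n_bins)
        sub = assignments[assignments.cell_id == cid]
        if len(sub):
            counts = np.bincount(sub["bin"], weights=sub["weight"], minlength=n_bins).astype(float)
        per_cell[cid] = EnrichmentProfile(cid, n_bins, counts, shell[cid])
    pooled = EnrichmentProfile(
        "pooled",
        n_bins,
        np.sum([p.counts for p in per_cell.values()], axis=0),
        np.sum([p.shell_volumes for p in per_cell.values()], axis=0),
    )
    if n_discarded:
        logger.info("assign_and_profile: discarded %d of %d spots (background/out of volume)",
                    n_discarded, n_spots)
    return ProfileSet(per_cell, pooled, assignments, n_discarded, n_reassigned)


def membrane_fraction(profile: EnrichmentProfile, cutoff: float = 0.1) -> float:
    """Fraction of molecules within ``cutoff`` of the membrane (raw counts,
    not volume-normalized).  ``cutoff`` must align with a bin edge."""
    k = cutoff * profile.n_bins
    if abs(k - round(k)) > 1e-9 or not (0 < round(k) <= profile.n_bins):
        raise ValueError(f"cutoff {cutoff} does not align with a bin edge (n_bins={profile.n_bins})")
    total = profile.total_count
    if total <= 0:
        raise ValueError("membrane fraction undefined: profile has zero spots")
    return float(profile.counts[: int(round(k))].sum() / total)
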