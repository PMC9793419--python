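"""Ground-truthed synthetic embryo image stacks.

Emulates early C. elegans embryos (1/2/4/8-cell stages) imaged by smFISH:
cells are packed convex compartments inside an ellipsoidal eggshell, single
mRNA molecules are placed under a chosen localization model (membrane-
enriched, uniform, or clustered), and a multi-channel 3D stack is rendered
with an anisotropic Gaussian PSF plus Poisson shot noise and Gaussian read
noise.  Every stochastic operation takes an explicit integer seed; there is
no global random state.

Defaults follow the imaged system: voxel spacing 0.2 µm axial x 0.1 µm
lateral, ~2400 molecules per four-cell embryo for a strongly expressed
transcript, PSF sigma (0.35, 0.13, 0.13) µm (typical widefield 60x/1.42 NA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .enrich import DistanceField, distance_field

__all__ = [
    "EmbryoGeometry",
    "GroundTruth",
    "ImageStack",
    "LocalizationModel",
    "NoiseModel",
    "PlacementError",
    "RenderError",
    "SizingError",
    "generate_geometry",
    "place_spots",
    "render_stack",
]

DEFAULT_PSF_SIGMA = (0.35, 0.13, 0.13)  # µm (z, y, x)

_STAGES = (1, 2, 4, 8)

# Anchor points per stage, as fractions of the eggshell semi-axes (z, y, x).
_ANCHORS = {
    1: [(0.0, 0.0, 0.0)],
    2: [(0.0, 0.0, -0.42), (0.0, 0.0, 0.42)],
    4: [(0.0, -0.42, -0.45), (0.0, 0.42, -0.15), (0.0, -0.42, 0.15), (0.0, 0.42, 0.45)],
    8: [(sz, sy, sx) for sz in (-0.38, 0.38) for sy in (-0.40, 0.40) for sx in (-0.42, 0.42)],
}


class SizingError(ValueError):
    """The requested voxel grid cannot hold the requested cells."""


class PlacementError(ValueError):
    """Molecules cannot be placed under the requested model."""


class RenderError(ValueError):
    """Ground-truth positions fall outside the renderable volume."""


@dataclass(frozen=True)
class EmbryoGeometry:
    """Synthetic embryo: 3D cell label volume with physical voxel spacing.

    ``label_volume`` is 0 outside the embryo and k > 0 inside cell k; the
    membrane of a cell is implicitly the interface between its label and
    anything else.  ``nuclei_centers`` (µm, one per cell) seed the DAPI
    channel.
    """

    stage: int
    label_volume: np.ndarray
    voxel_size: tuple[float, float, float]
    nuclei_centers: np.ndarray  # (stage, 3) µm

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.label_volume.shape

    @property
    def extent_um(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.voxel_size)

    def cell_ids(self) -> list[int]:
        return [int(k) for k in np.unique(self.label_volume) if k > 0]


@dataclass(frozen=True)
class LocalizationModel:
    """How molecules distribute within cells.

    ``membrane``: a fraction ``membrane_fraction`` of molecules is placed
    uniformly within the shell of normalized distance < ``membrane_shell``;
    the remainder uniformly in the complement, so the planted fraction is
    exactly the expected raw membrane fraction.  ``uniform``: every voxel of
    a cell is equally likely.  ``clustered``: ``n_clusters`` isotropic
    Gaussian clusters of ``molecules_per_cluster`` molecules each (sigma
    ``cluster_sigma`` µm); molecules beyond the cluster budget are placed
    uniformly as singletons.
    """

    mode: str = "membrane"
    membrane_shell: float = 0.1
    membrane_fraction: float = 0.5
    n_clusters: int = 5
    molecules_per_cluster: int = 20
    cluster_sigma: float = 0.1  # µm

    def __post_init__(self):
        if self.mode not in ("membrane", "uniform", "clustered"):
            raise ValueError(f"unknown localization mode {self.mode!r}")
        if not (0 < self.membrane_shell <= 1):
            raise ValueError("membrane_shell must lie in (0, 1]")
        if not (0 <= self.membrane_fraction <= 1):
            raise ValueError("membrane_fraction must lie in [0, 1]")
        if self.mode == "clustered" and (self.n_clusters < 1 or self.molecules_per_cluster < 1):
            raise ValueError("clustered mode requires n_clusters >= 1 and molecules_per_cluster >= 1")
        if self.cluster_sigma <= 0:
            raise ValueError("cluster_sigma must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Planted molecule positions (µm) with their cell, their normalized
    membrane distance (from the same distance field the quantification
    uses), and a cluster id (0 = singleton)."""

    positions: np.ndarray            # (n, 3) µm
    cell_id: np.ndarray              # (n,)
    true_normalized_distance: np.ndarray
    cluster_id: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class NoiseModel:
    """Camera model: Poisson shot noise on (baseline + signal) photons plus
    additive Gaussian read noise."""

    poisson: bool = True
    gaussian_sd: float = 2.0
    baseline: float = 100.0


@dataclass(frozen=True)
class ImageStack:
    """Multi-channel 3D stack, axes (C, Z, Y, X), with physical spacing."""

    data: np.ndarray
    channel_names: tuple[str, ...]
    voxel_size: tuple[float, float, float]

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]


# --------------------------------------------------------------------------
# Geometry
# --------------------------------------------------------------------------

def generate_geometry(
    stage: int,
    shape: Sequence[int],
    voxel_size: Sequence[float],
    seed: int,
    semi_axes_um: Sequence[float] | None = None,
    jitter: float = 0.05,
) -> EmbryoGeometry:
    """Generate a packed-cell embryo inside an ellipsoidal eggshell.

    Cells are the anisotropic (µm-metric) Voronoi compartments of the
    eggshell around per-stage anchor points, jittered by ``jitter`` x the
    semi-axes; they are convex, connected and disjoint by construction.
    ``semi_axes_um`` overrides the default eggshell half-extent of 0.46 x
    the grid extent (useful for exact digital spheres in tests).
    Deterministic for a fixed seed.
    """
    if stage not in _STAGES:
        raise ValueError(f"stage must be one of {_STAGES}, got {stage}")
    shape = tuple(int(n) for n in shape)
    voxel = np.asarray([float(v) for v in voxel_size])
    if len(shape) != 3 or any(n < 8 for n in shape):
        raise SizingError(f"shape {shape} too small to hold an embryo")
    if np.any(voxel <= 0):
        raise ValueError("voxel_size components must be strictly positive")

    extent = np.asarray(shape) * voxel
    center = extent / 2.0
    semi = np.asarray(semi_axes_um, dtype=float) if semi_axes_um is not None else 0.46 * extent
    if np.any(semi <= voxel):
        raise SizingError("eggshell semi-axes smaller than one voxel")

    # voxel centers, µm
    zc = (np.arange(shape[0]) + 0.5) * voxel[0]
    yc = (np.arange(shape[1]) + 0.5) * voxel[1]
    xc = (np.arange(shape[2]) + 0.5) * voxel[2]
    zz, yy, xx = np.meshgrid(zc, yc, xc, indexing="ij", sparse=True)
    # boundary-inclusive digital ellipsoid; the epsilon keeps voxels lying
    # exactly on the surface inside despite float rounding
    egg = (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    ) <= 1.0 + 1e-9

    rng = np.random.default_rng(seed)
    anchors = np.asarray(_ANCHORS[stage], dtype=float)
    anchors = anchors + rng.uniform(-jitter, jitter, size=anchors.shape)
    # keep anchors well inside the eggshell
    norms = np.linalg.norm(anchors, axis=1, keepdims=True)
    anchors = np.where(norms > 0.85, anchors * 0.85 / norms, anchors)
    seeds_um = center + anchors * semi

    labels = np.zeros(shape, dtype=np.int32)
    if stage == 1:
        labels[egg] = 1
    else:
        vox_idx = np.argwhere(egg)
        pts = (vox_idx + 0.5) * voxel
        d2 = np.sum((pts[:, None, :] - seeds_um[None, :, :]) ** 2, axis=2)
        labels[tuple(vox_idx.T)] = np.argmin(d2, axis=1).astype(np.int32) + 1

    nuclei = []
    for k in range(1, stage + 1):
        vox = np.argwhere(labels == k)
        if len(vox) < 30:
            raise SizingError(f"shape {shape} too small: cell {k} has {len(vox)} voxels")
        centroid = (vox.mean(axis=0) + 0.5) * voxel
        cvox = np.floor(centroid / voxel).astype(int)
        if labels[tuple(cvox)] != k:  # pathological jitter; snap to nearest cell voxel
            j = np.argmin(np.sum(((vox + 0.5) * voxel - centroid) ** 2, axis=1))
            centroid = (vox[j] + 0.5) * voxel
        nuclei.append(centroid)
        n_comp = ndi.label(labels == k)[1]
        if n_comp != 1:
            raise SizingError(f"cell {k} is not connected ({n_comp} components)")

    return EmbryoGeometry(
        stage=stage,
        label_volume=labels,
        voxel_size=tuple(voxel),
        nuclei_centers=np.asarray(nuclei),
    )


# --------------------------------------------------------------------------
# Molecule placement
# --------------------------------------------------------------------------

def _sample_in_voxels(rng, vox_idx: np.ndarray, n: int, voxel: np.ndarray):
    """Uniform positions: pick voxels uniformly, then uniform within each voxel."""
    pick = rng.integers(0, len(vox_idx), size=n)
    chosen = vox_idx[pick]
    pos = (chosen + rng.uniform(0.0, 1.0, size=(n, 3))) * voxel
    return pos, chosen


def place_spots(
    geometry: EmbryoGeometry,
    model: LocalizationModel,
    n_molecules: int,
    seed: int,
    dist: DistanceField | None = None,
    min_distance: float | None = None,
) -> GroundTruth:
    """Place ``n_molecules`` molecules under the localization model.

    The per-molecule ``true_normalized_distance`` is read from the same
    distance field used by the enrichment statistic (self-consistency), at
    the molecule's containing voxel.  Molecules are allotted to cells with
    probability proportional to cell volume.  A precomputed ``dist`` field
    may be passed to avoid recomputation.

    ``min_distance`` (µm) enforces a minimum pairwise separation by
    rejection (uniform/membrane modes only) — used by detection benchmarks,
    where unresolvable doublets are a counting problem, not a detection one.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    labels = geometry.label_volume
    voxel = np.asarray(geometry.voxel_size)
    if dist is None:
        dist = distance_field(labels, geometry.voxel_size)

    rng = np.random.default_rng(seed)
    cell_ids = geometry.cell_ids()
    vox_by_cell = {k: np.argwhere(labels == k) for k in cell_ids}
    for k, v in vox_by_cell.items():
        if len(v) == 0:
            raise PlacementError(f"cell {k} has an empty label")
    volumes = np.asarray([len(vox_by_cell[k]) for k in cell_ids], dtype=float)
    p_cell = volumes / volumes.sum()

    positions = np.empty((n_molecules, 3))
    cell_of = np.empty(n_molecules, dtype=np.int32)
    nd_of = np.empty(n_molecules)
    cluster_of = np.zeros(n_molecules, dtype=np.int32)

    def nd_at(vox: np.ndarray) -> np.ndarray:
        return dist.normalized[vox[:, 0], vox[:, 1], vox[:, 2]]

    if model.mode in ("uniform", "membrane"):
        which = rng.choice(len(cell_ids), size=n_molecules, p=p_cell)
        if model.mode == "membrane":
            in_shell = rng.uniform(size=n_molecules) < model.membrane_fraction
        for ci, k in enumerate(cell_ids):
            sel = np.nonzero(which == ci)[0]
            if len(sel) == 0:
                continue
            vox = vox_by_cell[k]
            if model.mode == "uniform":
                pos, chosen = _sample_in_voxels(rng, vox, len(sel), voxel)
            else:
                nd_vox = nd_at(vox)
                shell_vox = vox[nd_vox < model.membrane_shell]
                core_vox = vox[nd_vox >= model.membrane_shell]
                if len(shell_vox) == 0:
                    raise PlacementError(
                        f"cell {k}: no voxels within membrane_shell={model.membrane_shell}"
                    )
                if len(core_vox) == 0:
                    raise PlacementError(f"cell {k}: membrane_shell covers the whole cell")
                pos = np.empty((len(sel), 3))
                chosen = np.empty((len(sel), 3), dtype=int)
                m = in_shell[sel]
                if m.any():
                    pos[m], chosen[m] = _sample_in_voxels(rng, shell_vox, int(m.sum()), voxel)
                if (~m).any():
                    pos[~m], chosen[~m] = _sample_in_voxels(rng, core_vox, int((~m).sum()), voxel)
            positions[sel] = pos
            cell_of[sel] = k
            nd_of[sel] = nd_at(chosen)
    else:  # clustered
        n_clustered = model.n_clusters * model.molecules_per_cluster
        if n_clustered > n_molecules:
            raise PlacementError(
                f"n_molecules={n_molecules} < n_clusters*molecules_per_cluster={n_clustered}"
            )
        min_sep = max(8.0 * model.cluster_sigma, 1.0)  # keep planted clusters resolvable
        centers: list[np.ndarray] = []
        center_cell: list[int] = []
        attempts = 0
        while len(centers) < model.n_clusters:
            attempts += 1
            if attempts > 2000:
                raise PlacementError("could not place cluster centers with required separation")
            k = cell_ids[rng.choice(len(cell_ids), p=p_cell)]
            vox = vox_by_cell[k]
            deep = vox[dist.distance[vox[:, 0], vox[:, 1], vox[:, 2]] >= 2.0 * model.cluster_sigma]
            if len(deep) == 0:
                continue
            c = (deep[rng.integers(0, len(deep))] + 0.5) * voxel
            if centers and np.min(np.linalg.norm(np.asarray(centers) - c, axis=1)) < min_sep:
                continue
            centers.append(c)
            center_cell.append(k)
        i = 0
        for ci, (c, k) in enumerate(zip(centers, center_cell), start=1):
            placed = 0
            while placed < model.molecules_per_cluster:
                p = c + rng.normal(0.0, model.cluster_sigma, size=3)
                v = np.floor(p / voxel).astype(int)
                if np.any(v < 0) or np.any(v >= labels.shape) or labels[tuple(v)] != k:
                    continue
                positions[i] = p
                cell_of[i] = k
                nd_of[i] = dist.normalized[tuple(v)]
                cluster_of[i] = ci
                placed += 1
                i += 1
        n_extra = n_molecules - n_clustered
        if n_extra:
            which = rng.choice(len(cell_ids), size=n_extra, p=p_cell)
            for ci, k in enumerate(cell_ids):
                sel = np.nonzero(which == ci)[0] + i
                if len(sel) == 0:
                    continue
                pos, chosen = _sample_in_voxels(rng, vox_by_cell[k], len(sel), voxel)
                positions[sel] = pos
                cell_of[sel] = k
                nd_of[sel] = nd_at(chosen)

    if min_distance is not None and model.mode != "clustered" and n_molecules > 1:
        positions, cell_of, nd_of, cluster_of = _thin_to_min_distance(
            geometry, model, n_molecules, rng, dist, min_distance,
            positions, cell_of, nd_of, cluster_of,
        )
    return GroundTruth(positions, cell_of, nd_of, cluster_of)


def _thin_to_min_distance(geometry, model, n_molecules, rng, dist, min_distance,
                          positions, cell_of, nd_of, cluster_of):
    """Rejection: keep molecules at pairwise distance >= min_distance,
    redrawing replacements until the budget is met."""
    from scipy.spatial import cKDTree

    kept_pos: list[np.ndarray] = []
    kept = []
    pool = list(range(n_molecules))
    attempts = 0
    while len(kept) < n_molecules:
        if not pool:
            attempts += 1
            if attempts > 200:
                raise PlacementError(
                    f"cannot place {n_molecules} molecules at min_distance={min_distance}"
                )
            extra = place_spots(geometry, model, n_molecules, seed=int(rng.integers(2**31)),
                                dist=dist)
            positions = np.concatenate([positions, extra.positions])
            cell_of = np.concatenate([cell_of, extra.cell_id])
            nd_of = np.concatenate([nd_of, extra.true_normalized_distance])
            cluster_of = np.concatenate([cluster_of, extra.cluster_id])
            pool = list(range(len(positions) - n_molecules, len(positions)))
        i = pool.pop(0)
        p = positions[i]
        if kept_pos:
            tree = cKDTree(np.asarray(kept_pos))
            if tree.query_ball_point(p, min_distance):
                continue
        kept_pos.append(p)
        kept.append(i)
    kept = np.asarray(kept)
    return positions[kept], cell_of[kept], nd_of[kept], cluster_of[kept]


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

def add_gaussian_spots(
    image: np.ndarray,
    positions: np.ndarray,
    amplitude: float,
    sigma_um: Sequence[float],
    voxel_size: Sequence[float],
    truncate: float = 4.0,
) -> None:
    """Add peak-normalized anisotropic Gaussian kernels (peak = amplitude) at
    continuous µm positions, sampling at voxel centers.  In place."""
    voxel = np.asarray(voxel_size, dtype=float)
    sigma = np.asarray(sigma_um, dtype=float)
    shape = np.asarray(image.shape)
    half = np.ceil(truncate * sigma / voxel).astype(int)
    for p in np.atleast_2d(positions):
        c = np.floor(p / voxel).astype(int)
        lo = np.maximum(c - half, 0)
        hi = np.minimum(c + half + 1, shape)
        if np.any(lo >= hi):
            continue
        axes = [
            (np.arange(lo[a], hi[a]) + 0.5) * voxel[a] - p[a]
            for a in range(3)
        ]
        g = np.exp(
            -(axes[0][:, None, None] ** 2) / (2 * sigma[0] ** 2)
            - (axes[1][None, :, None] ** 2) / (2 * sigma[1] ** 2)
            - (axes[2][None, None, :] ** 2) / (2 * sigma[2] ** 2)
        )
        image[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amplitude * g


def _membrane_mask(labels: np.ndarray) -> np.ndarray:
    """Cell voxels face-adjacent to a different label or background."""
    mask = np.zeros(labels.shape, dtype=bool)
    for axis in range(3):
        d = np.diff(labels, axis=axis) != 0
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(0, -1)
        sl_hi[axis] = slice(1, None)
        mask[tuple(sl_lo)] |= d
        mask[tuple(sl_hi)] |= d
    return mask & (labels > 0)


def render_stack(
    geometry: EmbryoGeometry,
    truth: GroundTruth,
    psf_sigma: Sequence[float] = DEFAULT_PSF_SIGMA,
    spot_amplitude: float = 150.0,
    noise: NoiseModel | None = None,
    seed: int = 0,
    gfp_amplitude: float | None = None,
) -> ImageStack:
    """Render a multi-channel stack: smFISH spots, membrane marker, DAPI,
    and optionally a nuclear GFP reporter.

    The smFISH channel is the sum of anisotropic Gaussian kernels (peak
    ``spot_amplitude`` photons) at the true molecule positions; the membrane
    channel highlights label interfaces; DAPI (and GFP, if requested) are
    Gaussian nuclear blobs at the nuclei centers.  Noise: Poisson on
    baseline+signal, then additive Gaussian.  Deterministic for fixed seed.
    """
    psf_sigma = tuple(float(s) for s in psf_sigma)
    if any(s <= 0 for s in psf_sigma):
        raise ValueError("psf_sigma components must be positive")
    if spot_amplitude <= 0:
        raise ValueError("spot_amplitude must be positive")
    noise = noise or NoiseModel()
    voxel = np.asarray(geometry.voxel_size)
    extent = geometry.extent_um
    pos = np.atleast_2d(truth.positions)
    if len(pos) and (np.any(pos < 0) or np.any(pos >= extent)):
        raise RenderError("ground-truth positions outside the image volume")

    shape = geometry.shape
    fish = np.zeros(shape, dtype=np.float64)
    add_gaussian_spots(fish, pos, spot_amplitude, psf_sigma, voxel)

    membrane = _membrane_mask(geometry.label_volume).astype(np.float64) * 120.0
    membrane = ndi.gaussian_filter(membrane, sigma=1.0)

    dapi = np.zeros(shape, dtype=np.float64)
    add_gaussian_spots(dapi, geometry.nuclei_centers, 150.0, (1.0, 1.0, 1.0), voxel)

    channels = [fish, membrane, dapi]
    names = ["smFISH", "membrane", "DAPI"]
    if gfp_amplitude is not None:
        gfp = np.zeros(shape, dtype=np.float64)
        add_gaussian_spots(gfp, geometry.nuclei_centers, gfp_amplitude, (1.0, 1.0, 1.0), voxel)
        channels.append(gfp)
        names.append("GFP")

    rng = np.random.default_rng(seed)
    out = np.empty((len(channels), *shape), dtype=np.float32)
    for i, ch in enumerate(channels):
        y = ch + noise.baseline
        if noise.poisson:
            y = rng.poisson(np.maximum(y, 0.0)).astype(np.float64)
        if noise.gaussian_sd > 0:
            y = y + rng.normal(0.0, noise.gaussian_sd, size=ch.shape)
        out[i] = y.astype(np.float32)
    return ImageStack(data=out, channel_names=tuple(names), voxel_size=tuple(voxel))
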