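"""End-to-end orchestration: simulate -> detect -> decompose -> profile -> stats.

A :class:`RunConfig` (YAML-serializable, losslessly round-tripping) drives
three library entry points:

* :func:`run_simulate` writes ground-truthed synthetic embryos to disk
  (OME-TIFF stack, label-mask TIFF, ground-truth CSV, manifest JSON);
* :func:`run_quantify` turns stacks + cell annotations into spot tables,
  per-cell/pooled enrichment profiles and per-embryo records;
* :func:`run_report` aggregates records into condition proportion tables and
  pairwise Welch comparisons on bin-1 frequencies.

These are plain functions rather than shell subcommands; the example scripts
under ``examples/`` show each stage in a few lines.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .decompose import count_clusters, decompose, estimate_reference, total_molecules
from .detect import detect_spots
from .enrich import ProfileSet, assign_and_profile, distance_field
from .simulate import (
    DEFAULT_PSF_SIGMA,
    EmbryoGeometry,
    ImageStack,
    LocalizationModel,
    NoiseModel,
    generate_geometry,
    place_spots,
    render_stack,
)
from .stats import EmbryoRecord, classify_localization, condition_summary, welch_test

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionConfig",
    "EnrichmentConfig",
    "RunConfig",
    "SimulationConfig",
    "StatsConfig",
    "configure_logging",
    "quantify_embryo",
    "run_report",
    "run_quantify",
    "run_simulate",
]


def configure_logging(level: str = "INFO") -> None:
    """Timestamped logging to stderr for pipeline runs."""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    stage: int = 4
    shape: tuple[int, int, int] = (40, 256, 256)
    voxel_size: tuple[float, float, float] = (0.2, 0.1, 0.1)
    n_embryos: int = 1
    n_molecules: int = 2400          # erm-1-scale abundance per 4-cell embryo
    model: LocalizationModel = field(default_factory=LocalizationModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    spot_amplitude: float = 150.0
    psf_sigma: tuple[float, float, float] = DEFAULT_PSF_SIGMA
    seed: int = 0

    def __post_init__(self):
        if self.stage not in (1, 2, 4, 8):
            raise ValueError(f"stage must be one of (1, 2, 4, 8), got {self.stage}")
        if self.n_embryos < 1:
            raise ValueError("n_embryos must be >= 1")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")


@dataclass(frozen=True)
class DetectionConfig:
    threshold: float = 5.0           # in robust noise SDs of the band-passed volume
    min_separation: float = 0.6      # µm
    fit_window: tuple[int, int, int] = (9, 9, 9)
    psf_sigma: tuple[float, float, float] = DEFAULT_PSF_SIGMA


@dataclass(frozen=True)
class EnrichmentConfig:
    n_bins: int = 10
    cutoff: float = 0.1              # membrane-fraction cutoff, bin-edge aligned
    normalization: str = "per_cell_max"


@dataclass(frozen=True)
class StatsConfig:
    classification_threshold: float = 1.5
    min_spots: int = 50


@dataclass(frozen=True)
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    condition: str = "control"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(klass, sub):
            sub = dict(sub)
            for name, inner in (("model", LocalizationModel), ("noise", NoiseModel)):
                if name in sub and isinstance(sub[name], dict):
                    sub[name] = inner(**sub[name])
            for f in dataclasses.fields(klass):
                if f.name in sub and isinstance(sub[f.name], list):
                    sub[f.name] = tuple(sub[f.name])
            return klass(**sub)

        return cls(
            simulation=build(SimulationConfig, d.get("simulation", {})),
            detection=build(DetectionConfig, d.get("detection", {})),
            enrichment=build(EnrichmentConfig, d.get("enrichment", {})),
            stats=build(StatsConfig, d.get("stats", {})),
            condition=d.get("condition", "control"),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _embryo_seeds(base_seed: int, embryo_index: int) -> tuple[int, int, int]:
    """Independent (geometry, placement, render) seeds below 2**31."""
    ss = np.random.SeedSequence([int(base_seed), int(embryo_index)])
    return tuple(int(s % (2**31)) for s in ss.generate_state(3))


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def simulate_embryo(config: RunConfig, embryo_index: int = 0):
    """Generate one embryo in memory: (geometry, truth, stack)."""
    sim = config.simulation
    gseed, pseed, rseed = _embryo_seeds(sim.seed, embryo_index)
    geometry = generate_geometry(sim.stage, sim.shape, sim.voxel_size, seed=gseed)
    dist = distance_field(geometry.label_volume, geometry.voxel_size,
                          normalization=config.enrichment.normalization)
    truth = place_spots(geometry, sim.model, sim.n_molecules, seed=pseed, dist=dist)
    stack = render_stack(
        geometry, truth,
        psf_sigma=sim.psf_sigma,
        spot_amplitude=sim.spot_amplitude,
        noise=sim.noise,
        seed=rseed,
    )
    return geometry, truth, stack


def run_simulate(config: RunConfig, out_dir) -> dict:
    """Write a fixture set: per embryo an OME-TIFF stack, a label-mask TIFF
    and a ground-truth CSV, plus a manifest listing every output and seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"condition": config.condition, "embryos": []}
    for e in range(config.simulation.n_embryos):
        geometry, truth, stack = simulate_embryo(config, e)
        name = f"embryo_{e:03d}"
        files = {
            "stack": str(mio.write_ome_tiff(stack, out_dir / f"{name}.ome.tif")),
            "labels": str(mio.write_labels_tiff(geometry.label_volume, out_dir / f"{name}_labels.tif")),
            "truth": str(mio.write_ground_truth_csv(truth, out_dir / f"{name}_truth.csv")),
        }
        manifest["embryos"].append(
            {"embryo_id": name, "seeds": _embryo_seeds(config.simulation.seed, e), "files": files}
        )
        logger.info("simulated %s (%d molecules, %s mode)", name,
                    len(truth), config.simulation.model.mode)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    manifest["manifest"] = str(manifest_path)
    return manifest


def quantify_embryo(
    stack: ImageStack,
    labels: np.ndarray,
    config: RunConfig,
    embryo_id: str = "embryo",
) -> tuple[pd.DataFrame, ProfileSet, EmbryoRecord]:
    """Quantify a single embryo: detect spots on the smFISH channel, decompose
    intensities into molecule counts, profile membrane proximity, classify."""
    det, enr, st = config.detection, config.enrichment, config.stats
    channel = stack.channel("smFISH") if "smFISH" in stack.channel_names else stack.data[0]
    spots = detect_spots(
        channel,
        stack.voxel_size,
        threshold=det.threshold,
        min_separation=det.min_separation,
        fit_window=det.fit_window,
        psf_sigma=det.psf_sigma,
    )
    counted = []
    if len(spots):
        ref = estimate_reference(spots)
        counted = decompose(spots, ref)
    dist = distance_field(labels, stack.voxel_size, normalization=enr.normalization)
    profiles = assign_and_profile(counted, dist, labels, n_bins=enr.n_bins)
    call = classify_localization(profiles.pooled, st.classification_threshold, st.min_spots)
    record = EmbryoRecord(
        embryo_id=embryo_id,
        stage=int(config.simulation.stage),
        condition=config.condition,
        profile=profiles.pooled,
        total_molecules=total_molecules(counted),
        cluster_count=count_clusters(counted),
        localization=call,
    )
    spot_table = spots.to_dataframe()
    if len(spot_table):
        spot_table["count"] = [c.molecule_count for c in counted]
        assign = profiles.assignments
        spot_table["cell_id"] = assign["cell_id"].reindex(spot_table.index)
        spot_table["norm_dist"] = assign["norm_dist"].reindex(spot_table.index)
        spot_table["bin"] = assign["bin"].reindex(spot_table.index)
    return spot_table, profiles, record


def _records_frame(records: list[EmbryoRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "embryo_id": [r.embryo_id for r in records],
            "stage": [r.stage for r in records],
            "condition": [r.condition for r in records],
            "total_molecules": [r.total_molecules for r in records],
            "cluster_count": [r.cluster_count for r in records],
            "bin1_frequency": [r.bin1_frequency for r in records],
            "membrane_fraction": [
                (r.profile.counts[0] / r.profile.total_count) if r.profile.total_count else np.nan
                for r in records
            ],
            "localization": [r.localization for r in records],
        }
    )


def run_quantify(config: RunConfig, inputs, out_dir=None) -> tuple[pd.DataFrame, list[EmbryoRecord]]:
    """Quantify a set of embryos.

    ``inputs`` is an iterable of ``(embryo_id, stack, labels)`` where ``stack``
    is an :class:`ImageStack` or a path to an OME-TIFF and ``labels`` a label
    volume, a path to a label TIFF, or ``None`` (skipped with a warning).
    Writes per-embryo ``spots.csv``/``profile.csv`` and a pooled
    ``records.csv`` when ``out_dir`` is given.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    records: list[EmbryoRecord] = []
    n_skipped = 0
    for embryo_id, stack, labels in inputs:
        if labels is None:
            logger.warning("%s: missing annotation, skipped", embryo_id)
            n_skipped += 1
            continue
        if not isinstance(stack, ImageStack):
            stack = mio.read_image_stack(stack)
        if not isinstance(labels, np.ndarray):
            labels = mio.read_labels_tiff(labels)
        spot_table, profiles, record = quantify_embryo(stack, labels, config, embryo_id)
        records.append(record)
        if out is not None:
            mio.write_csv(spot_table, out / f"{embryo_id}_spots.csv")
            mio.write_csv(profiles.to_frame(), out / f"{embryo_id}_profile.csv")
    if not records:
        raise ValueError("no embryos quantified")
    df = _records_frame(records)
    df.attrs["n_skipped"] = n_skipped
    if out is not None:
        mio.write_csv(df, out / "records.csv")
    return df, records


def run_report(records: pd.DataFrame | list[EmbryoRecord], out_dir=None):
    """Condition summary proportions plus pairwise Welch comparisons of the
    bin-1 frequencies between conditions (within each stage)."""
    if isinstance(records, list):
        if not records:
            raise ValueError("no records to report")
        summary = condition_summary(records)
        df = _records_frame(records)
    else:
        df = records
        if df.empty:
            raise ValueError("no records to report")
        rows = []
        for (stage, cond), g in df.groupby(["stage", "condition"]):
            n_loc = int((g.localization == "localized").sum())
            n_unloc = int((g.localization == "unlocalized").sum())
            n_eff = n_loc + n_unloc
            rows.append(
                {
                    "stage": stage, "condition": cond, "n": len(g),
                    "n_effective": n_eff,
                    "n_indeterminate": int((g.localization == "indeterminate").sum()),
                    "frac_localized": n_loc / n_eff if n_eff else np.nan,
                    "frac_unlocalized": n_unloc / n_eff if n_eff else np.nan,
                }
            )
        summary = pd.DataFrame(rows)

    comparisons = []
    for stage, g in df.groupby("stage"):
        conds = sorted(g.condition.unique())
        if len(conds) < 2:
            logger.info("stage %s: single condition, comparisons skipped", stage)
            continue
        for i, ca in enumerate(conds):
            for cb in conds[i + 1:]:
                a = g.loc[g.condition == ca, "bin1_frequency"].to_numpy()
                b = g.loc[g.condition == cb, "bin1_frequency"].to_numpy()
                try:
                    cmp = welch_test(a, b, label_a=ca, label_b=cb)
                except ValueError as exc:
                    logger.warning("stage %s, %s vs %s: %s", stage, ca, cb, exc)
                    continue
                comparisons.append(
                    {
                        "stage": stage, "group_a": ca, "group_b": cb,
                        "n_a": cmp.n_a, "n_b": cmp.n_b,
                        "mean_a": cmp.mean_a, "mean_b": cmp.mean_b,
                        "t": cmp.t, "df": cmp.df, "p": cmp.p, "stars": cmp.stars,
                    }
                )
    comparisons = pd.DataFrame(
        comparisons,
        columns=["stage", "group_a", "group_b", "n_a", "n_b",
                 "mean_a", "mean_b", "t", "df", "p", "stars"],
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        mio.write_csv(summary, out / "condition_summary.csv")
        mio.write_csv(comparisons, out / "comparisons.csv")
    return summary, comparisons
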