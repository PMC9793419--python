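"""File I/O: OME-TIFF stacks, label masks, ground-truth/spot/profile CSVs,
annotation JSON and FASTA coding sequences.

CSVs carry a header row and floats with six significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enrich import CellAnnotation
from .simulate import GroundTruth, ImageStack

__all__ = [
    "read_annotation_json",
    "read_fasta",
    "read_ground_truth_csv",
    "read_image_stack",
    "read_labels_tiff",
    "write_annotation_json",
    "write_csv",
    "write_fasta",
    "write_ground_truth_csv",
    "write_labels_tiff",
    "write_ome_tiff",
]

FLOAT_FORMAT = "%.6g"


def write_ome_tiff(stack: ImageStack, path) -> Path:
    """Write a multi-channel stack as OME-TIFF (axes CZYX, spacing in µm)."""
    path = Path(path)
    vz, vy, vx = stack.voxel_size
    tifffile.imwrite(
        path,
        stack.data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "Channel": {"Name": list(stack.channel_names)},
            "PhysicalSizeZ": vz,
            "PhysicalSizeY": vy,
            "PhysicalSizeX": vx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
        },
    )
    return path


def read_image_stack(path, voxel_size=None, channel_names=None) -> ImageStack:
    """Read a (C,Z,Y,X) OME-TIFF; voxel size and channel names are taken from
    the OME metadata when present, else must be supplied."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        if data.ndim == 3:
            data = data[None]
        meta = tf.ome_metadata
    names = channel_names
    voxel = voxel_size
    if meta and (voxel is None or names is None):
        import xml.etree.ElementTree as ET

        root = ET.fromstring(meta)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        px = root.find(".//ome:Pixels", ns)
        if px is not None and voxel is None:
            voxel = (
                float(px.get("PhysicalSizeZ", 1.0)),
                float(px.get("PhysicalSizeY", 1.0)),
                float(px.get("PhysicalSizeX", 1.0)),
            )
        if names is None:
            chans = root.findall(".//ome:Channel", ns)
            if chans:
                names = tuple(c.get("Name") or f"ch{i}" for i, c in enumerate(chans))
    if voxel is None:
        raise ValueError("voxel_size not found in metadata; pass it explicitly")
    if names is None:
        names = tuple(f"ch{i}" for i in range(data.shape[0]))
    return ImageStack(data=np.asarray(data), channel_names=tuple(names), voxel_size=tuple(voxel))


def write_labels_tiff(labels: np.ndarray, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int32))
    return path


def read_labels_tiff(path) -> np.ndarray:
    return tifffile.imread(Path(path))


def write_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def write_ground_truth_csv(truth: GroundTruth, path) -> Path:
    df = pd.DataFrame(
        {
            "mol_id": np.arange(len(truth)),
            "z_um": truth.positions[:, 0],
            "y_um": truth.positions[:, 1],
            "x_um": truth.positions[:, 2],
            "cell_id": truth.cell_id,
            "norm_dist": truth.true_normalized_distance,
            "cluster_id": truth.cluster_id,
        }
    )
    return write_csv(df, path)


def read_ground_truth_csv(path) -> GroundTruth:
    df = pd.read_csv(Path(path))
    return GroundTruth(
        positions=df[["z_um", "y_um", "x_um"]].to_numpy(float),
        cell_id=df["cell_id"].to_numpy(int),
        true_normalized_distance=df["norm_dist"].to_numpy(float),
        cluster_id=df["cluster_id"].to_numpy(int),
    )


def write_annotation_json(annotation: CellAnnotation, path) -> Path:
    """Polygon annotations as JSON: {cell_id: {z: [[y, x], ...]}}."""
    if annotation.polygons is None:
        raise ValueError("only polygon annotations serialize to JSON")
    payload = {
        "polygons": {
            str(cid): {str(z): np.asarray(v).tolist() for z, v in slices.items()}
            for cid, slices in annotation.polygons.items()
        },
        "excluded_slices": sorted(annotation.excluded_slices),
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_annotation_json(path) -> CellAnnotation:
    payload = json.loads(Path(path).read_text())
    polygons = {
        int(cid): {int(z): np.asarray(v, dtype=float) for z, v in slices.items()}
        for cid, slices in payload["polygons"].items()
    }
    return CellAnnotation(
        polygons=polygons,
        excluded_slices=frozenset(payload.get("excluded_slices", [])),
    )


def write_fasta(sequences: dict[str, str], path) -> Path:
    path = Path(path)
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, path, "fasta")
    return path


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(Path(path), "fasta")}
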