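"""Image-stack and table I/O plus the shared per-nucleus data model.

All volumes are ordered ``(z, y, x)`` and all physical quantities are in
micrometres (µm, µm², µm³). Coordinates are voxel-center and 0-based in
memory; exported tables carry physical µm coordinates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VoxelGrid",
    "LabelVolume",
    "NucleusRecord",
    "CellCycleCall",
    "FUCCI_CLASSES",
    "read_stack",
    "write_stack",
    "read_labels",
    "write_labels",
    "write_records",
    "read_records",
    "records_to_table",
]

#: Legal cell-cycle class names used throughout the package.
FUCCI_CLASSES = ("G1", "G1S", "SG2", "NONTRANSFECTED", "UNCLASSIFIED")


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must be (dz, dy, dx), got {spacing!r}")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"all spacings must be strictly positive, got {spacing!r}")
    return spacing


@dataclass
class VoxelGrid:
    """A 3D scalar fluorescence volume with physical voxel spacing.

    Parameters
    ----------
    data
        3D array of non-negative intensities, axis order ``(z, y, x)``.
    spacing
        Voxel spacing ``(dz, dy, dx)`` in µm, all strictly positive.
    channel_name
        Name of the fluorescence channel (e.g. ``"dapi"``).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"data must have exactly 3 axes (z, y, x), got {self.data.ndim}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        dz, dy, dx = self.spacing
        return dz * dy * dx

    @property
    def is_isotropic(self) -> bool:
        dz, dy, dx = self.spacing
        return np.isclose(dz, dx) and np.isclose(dy, dx)


@dataclass
class LabelVolume:
    """3D integer segmentation labels sharing a grid's geometry (0 = background)."""

    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must have exactly 3 axes, got {self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def ids(self) -> np.ndarray:
        """Sorted positive label identifiers present in the volume."""
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class NucleusRecord:
    """Volumetric and intensity measurements for one segmented nucleus.

    ``e1``/``e2``/``e3`` are the unit orientation vectors of the major,
    intermediate and minor principal axes (mutually orthogonal within
    numerical tolerance), in ``(z, y, x)`` component order.
    """

    label: int
    centroid: tuple[float, float, float]  # (z, y, x) µm
    volume: float  # µm³
    surface_area: float  # µm²
    extent: float  # in (0, 1]
    p_major: float  # µm, full axis length
    p_intermediate: float
    p_minor: float
    e1: tuple[float, float, float]
    e2: tuple[float, float, float]
    e3: tuple[float, float, float]
    sphericity: float
    integrated_intensity: dict[str, float] = field(default_factory=dict)
    spheroid_id: str = ""

    @property
    def depth(self) -> float:
        """Imaging depth of the centroid (its z-coordinate) in µm."""
        return self.centroid[0]


@dataclass
class CellCycleCall:
    """Per-nucleus cell-cycle assignment and normalized DNA content."""

    label: int
    fucci_class: str = "UNCLASSIFIED"
    dna_content: float = float("nan")
    predicted_class: str = "UNCLASSIFIED"

    def __post_init__(self) -> None:
        for name in (self.fucci_class, self.predicted_class):
            if name not in FUCCI_CLASSES:
                raise ValueError(f"unknown cell-cycle class {name!r}")


# ---------------------------------------------------------------------------
# TIFF stack I/O
# ---------------------------------------------------------------------------

def _spacing_from_tiff(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Extract (dz, dy, dx) µm from OME-XML or ImageJ-style TIFF metadata."""
    # OME-TIFF metadata is preferred.
    if tif.ome_metadata:
        import re

        xml = tif.ome_metadata
        vals = {}
        for axis in ("X", "Y", "Z"):
            m = re.search(rf'PhysicalSize{axis}="([\d.eE+-]+)"', xml)
            if m:
                vals[axis] = float(m.group(1))
        if {"X", "Y", "Z"} <= set(vals):
            return (vals["Z"], vals["Y"], vals["X"])
    # ImageJ-style fallback: XResolution/YResolution + ImageJ "spacing" tag.
    ij = tif.imagej_metadata
    page = tif.pages[0]
    try:
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        dx = xres[1] / xres[0]
        dy = yres[1] / yres[0]
    except (KeyError, ZeroDivisionError):
        return None
    if ij and "spacing" in ij:
        return (float(ij["spacing"]), float(dy), float(dx))
    return None


def read_stack(path, channel: str = "", spacing=None) -> VoxelGrid:
    """Read a 3D TIFF/OME-TIFF stack into a :class:`VoxelGrid`.

    Parameters
    ----------
    path
        TIFF or OME-TIFF file with a single-channel z-stack.
    channel
        Channel name to attach to the grid.
    spacing
        Optional ``(dz, dy, dx)`` µm override. Required when the file
        carries no voxel-size metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta_spacing = _spacing_from_tiff(tif)
    data = np.squeeze(data)
    if data.ndim == 2:
        raise ValueError(f"{path} is a 2D image; a 3D z-stack is required")
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3 axes after squeeze, got {data.ndim}")
    if spacing is None:
        spacing = meta_spacing
    if spacing is None:
        raise ValueError(
            f"{path} carries no voxel-size metadata; pass spacing=(dz, dy, dx) explicitly"
        )
    return VoxelGrid(data=data, spacing=spacing, channel_name=channel)


def write_stack(grid: VoxelGrid, path) -> None:
    """Write a :class:`VoxelGrid` as an OME-TIFF with voxel-size metadata."""
    dz, dy, dx = grid.spacing
    tifffile.imwrite(
        path,
        grid.data,
        ome=True,
        photometric="minisblack",  # a trailing axis of ≤4 is not RGB samples
        metadata={
            "axes": "ZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeY": dy,
            "PhysicalSizeX": dx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
        },
    )


def read_labels(path, spacing=None) -> LabelVolume:
    """Read an integer label volume from TIFF."""
    grid = read_stack(path, spacing=spacing)
    labels = grid.data
    if not np.issubdtype(labels.dtype, np.integer):
        if not np.allclose(labels, np.round(labels)):
            raise ValueError(f"{path} does not contain integer labels")
        labels = labels.astype(np.uint32)
    return LabelVolume(labels=labels, spacing=grid.spacing)


def write_labels(labels: LabelVolume, path) -> None:
    """Write a label volume as uint16/uint32 OME-TIFF (lossless)."""
    arr = labels.labels
    dtype = np.uint16 if arr.max(initial=0) < 2**16 else np.uint32
    grid = VoxelGrid(arr.astype(dtype), labels.spacing, channel_name="labels")
    write_stack(grid, path)


# ---------------------------------------------------------------------------
# Feature-table I/O
# ---------------------------------------------------------------------------

_SCALAR_COLUMNS = [
    ("volume", "µm³"),
    ("surface_area", "µm²"),
    ("extent", ""),
    ("p_major", "µm"),
    ("p_intermediate", "µm"),
    ("p_minor", "µm"),
    ("sphericity", ""),
]


def records_to_table(
    records: list[NucleusRecord],
    calls: list[CellCycleCall] | None = None,
) -> pd.DataFrame:
    """Flatten records (and optional matched calls) into one row per nucleus.

    Columns: ``label``, ``spheroid_id``, ``centroid_z/y/x`` and ``depth``
    (µm), the scalar volumetrics, ``e{1,2,3}_{z,y,x}`` orientation
    components, one ``ii_<channel>`` column per intensity channel and —
    when calls are supplied — ``fucci_class``, ``dna_content`` and
    ``predicted_class``.
    """
    if not records:
        raise ValueError("record list is empty")
    rows = []
    for rec in records:
        row: dict = {"label": rec.label, "spheroid_id": rec.spheroid_id}
        row["centroid_z"], row["centroid_y"], row["centroid_x"] = rec.centroid
        row["depth"] = rec.depth
        for name, _unit in _SCALAR_COLUMNS:
            row[name] = getattr(rec, name)
        for i, vec in enumerate((rec.e1, rec.e2, rec.e3), start=1):
            row[f"e{i}_z"], row[f"e{i}_y"], row[f"e{i}_x"] = vec
        for ch, val in rec.integrated_intensity.items():
            row[f"ii_{ch}"] = val
        rows.append(row)
    df = pd.DataFrame(rows)
    if calls is not None:
        by_label = {c.label: c for c in calls}
        df["fucci_class"] = [by_label[l].fucci_class if l in by_label else "UNCLASSIFIED" for l in df["label"]]
        df["dna_content"] = [by_label[l].dna_content if l in by_label else np.nan for l in df["label"]]
        df["predicted_class"] = [
            by_label[l].predicted_class if l in by_label else "UNCLASSIFIED" for l in df["label"]
        ]
    return df


def write_records(records, path, calls=None) -> None:
    """Write nucleus records (and optional cell-cycle calls) as CSV.

    One row per nucleus; physical quantities in µm/µm²/µm³ and class
    labels serialized literally (e.g. ``UNCLASSIFIED``). Reload with
    :func:`read_records` is lossless to float precision.
    """
    if isinstance(records, pd.DataFrame):
        df = records
        if df.empty:
            raise ValueError("record table is empty")
    else:
        df = records_to_table(list(records), calls)
    df.to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    """Reload a feature CSV written by :func:`write_records`."""
    df = pd.read_csv(path, dtype={"spheroid_id": str})
    if "spheroid_id" in df.columns:
        df["spheroid_id"] = df["spheroid_id"].fillna("")
    return df


def table_to_records(df: pd.DataFrame) -> list[NucleusRecord]:
    """Rebuild :class:`NucleusRecord` objects from a feature table."""
    records = []
    channel_cols = [c for c in df.columns if c.startswith("ii_") and not c.endswith("_corrected")]
    for _, row in df.iterrows():
        records.append(
            NucleusRecord(
                label=int(row["label"]),
                centroid=(row["centroid_z"], row["centroid_y"], row["centroid_x"]),
                volume=row["volume"],
                surface_area=row["surface_area"],
                extent=row["extent"],
                p_major=row["p_major"],
                p_intermediate=row["p_intermediate"],
                p_minor=row["p_minor"],
                e1=(row["e1_z"], row["e1_y"], row["e1_x"]),
                e2=(row["e2_z"], row["e2_y"], row["e2_x"]),
                e3=(row["e3_z"], row["e3_y"], row["e3_x"]),
                sphericity=row["sphericity"],
                integrated_intensity={c[3:]: row[c] for c in channel_cols},
                spheroid_id=str(row.get("spheroid_id", "")),
            )
        )
    return records
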