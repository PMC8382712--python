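"""Spheroid geometry and radial-organization metrics.

The spheroid body is approximated by morphologically closing the union
of all segmented nuclei; each nucleus is then characterized by its
distance to the spheroid perimeter, either binned into concentric 10 µm
layers (S/G2 counts and fractions per layer) or used as a continuous
variable (5 µm radial trends of volume, alignment angle and axis
ratios). The alignment angle α ∈ [0°, 90°] is the angle between the
center-to-nucleus vector and the plane spanned by the nucleus's major
and intermediate principal axes: 0° ⇒ the long axis points along the
spheroid radius, 90° ⇒ tangential organization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .stack_io import LabelVolume

__all__ = [
    "SpheroidGeometry",
    "approximate_surface",
    "filter_detached",
    "perimeter_distance",
    "assign_layers",
    "layer_stats",
    "alignment_angle",
    "alignment_angles",
    "z_alignment_angle",
    "z_alignment_angles",
    "axis_ratios",
    "radial_trend",
    "fit_z_artifact",
]


@dataclass
class SpheroidGeometry:
    """Closed spheroid body mask, its centroid and voxel spacing."""

    surface_mask: np.ndarray
    center: tuple[float, float, float]  # (z, y, x) µm
    spacing: tuple[float, float, float]

    def centroid_inside(self, centroid_um) -> bool:
        vox = self._to_voxel(centroid_um)
        if any(v < 0 or v >= n for v, n in zip(vox, self.surface_mask.shape)):
            return False
        return bool(self.surface_mask[vox])

    def _to_voxel(self, centroid_um) -> tuple[int, int, int]:
        return tuple(int(round(c / s)) for c, s in zip(centroid_um, self.spacing))


def _ball_erode_dilate(mask: np.ndarray, radius_um: float, spacing, dilate: bool) -> np.ndarray:
    """Exact Euclidean-ball dilation/erosion via a distance transform."""
    if dilate:
        d = ndimage.distance_transform_edt(~mask, sampling=spacing)
        return d <= radius_um
    d = ndimage.distance_transform_edt(mask, sampling=spacing)
    return d > radius_um


def approximate_surface(labels: LabelVolume, closing_radius: float = 10.0) -> SpheroidGeometry:
    """Approximate the spheroid body by closing the union of all nuclei.

    Morphological closing with a Euclidean ball of ``closing_radius`` µm
    (implemented with distance transforms, so the ball is exact and
    anisotropy-aware), hole filling, then the largest connected
    component. The center is the centroid of the resulting mask.
    """
    mask = labels.labels > 0
    if not mask.any():
        raise ValueError("label volume is empty")
    dilated = _ball_erode_dilate(mask, closing_radius, labels.spacing, dilate=True)
    closed = _ball_erode_dilate(dilated, closing_radius, labels.spacing, dilate=False)
    closed |= mask  # closing is extensive; guard against voxel rounding
    closed = ndimage.binary_fill_holes(closed)
    comp, n = ndimage.label(closed)
    if n > 1:
        sizes = np.bincount(comp.ravel())[1:]
        closed = comp == (np.argmax(sizes) + 1)
    center_vox = ndimage.center_of_mass(closed)
    center = tuple(float(c * s) for c, s in zip(center_vox, labels.spacing))
    return SpheroidGeometry(surface_mask=closed, center=center, spacing=tuple(labels.spacing))


def filter_detached(df: pd.DataFrame, geometry: SpheroidGeometry) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split nuclei into those inside the spheroid body and detached ones.

    Satellite cells whose centroid falls outside the closed body mask
    are excluded from spatial statistics. Kept + detached = input.
    """
    inside = np.array(
        [
            geometry.centroid_inside((row["centroid_z"], row["centroid_y"], row["centroid_x"]))
            for _, row in df.iterrows()
        ],
        dtype=bool,
    )
    return df[inside].copy(), df[~inside].copy()


def perimeter_distance(df: pd.DataFrame, geometry: SpheroidGeometry) -> pd.Series:
    """Euclidean distance (µm) from each nucleus centroid to the perimeter.

    The interior distance transform of the body mask sampled at the
    centroid voxel. Centroids outside the mask (which should have been
    filtered) raise an error.
    """
    interior = ndimage.distance_transform_edt(geometry.surface_mask, sampling=geometry.spacing)
    out = np.empty(len(df))
    for i, (_, row) in enumerate(df.iterrows()):
        vox = geometry._to_voxel((row["centroid_z"], row["centroid_y"], row["centroid_x"]))
        if any(v < 0 or v >= n for v, n in zip(vox, geometry.surface_mask.shape)) or not geometry.surface_mask[vox]:
            raise ValueError(f"nucleus {row.get('label', i)} centroid lies outside the spheroid mask")
        out[i] = interior[vox]
    return pd.Series(out, index=df.index, name="perimeter_distance")


def assign_layers(distances, width: float = 10.0, max_depth: float = 60.0) -> np.ndarray:
    """Concentric layer index per nucleus (0 = outermost).

    Layer i covers [i·width, (i+1)·width) (half-open, lower-inclusive);
    distances at or beyond ``max_depth`` pool into the innermost layer.
    """
    d = np.asarray(distances, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    n_layers = int(np.ceil(max_depth / width))
    return np.minimum((d // width).astype(int), n_layers - 1)


def layer_stats(
    classes,
    layers,
    spheroid_ids,
    positive: str = "SG2",
    n_layers: int = 6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-layer S/G2 counts and fractions, per spheroid and aggregated.

    Each spheroid is treated individually: per layer the number of
    positive nuclei and the positive/total fraction (NaN-flagged when
    the layer holds no cells — deep layers have tiny volumes and
    volatile fractions). The aggregate table reports mean ± SD across
    spheroids, empty layers excluded from the mean.
    """
    df = pd.DataFrame({
        "spheroid_id": np.asarray(spheroid_ids),
        "layer": np.asarray(layers),
        "positive": np.asarray(classes) == positive,
    })
    rows = []
    for sid, grp in df.groupby("spheroid_id", sort=True):
        for layer in range(n_layers):
            sub = grp[grp["layer"] == layer]
            total = len(sub)
            count = int(sub["positive"].sum())
            rows.append({
                "spheroid_id": sid,
                "layer": layer,
                "n_total": total,
                "n_positive": count,
                "fraction": count / total if total else np.nan,
                "empty": total == 0,
            })
    per = pd.DataFrame(rows)
    agg = (
        per.groupby("layer")
        .agg(
            count_mean=("n_positive", "mean"),
            count_sd=("n_positive", "std"),
            fraction_mean=("fraction", "mean"),
            fraction_sd=("fraction", "std"),
            n_spheroids=("fraction", "count"),
        )
        .reset_index()
    )
    return per, agg


# ---------------------------------------------------------------------------
# Orientation metrics
# ---------------------------------------------------------------------------

def alignment_angle(centroid, center, e3) -> float:
    """Angle (degrees, [0, 90]) between r_center and the e1–e2 plane.

    Computed as arcsin|r̂ · ê3| with ê3 the minor axis (the plane
    normal) — numerically stable near both 0° and 90°. 0° means the
    nucleus's long axes contain the radial direction; 90° means the long
    axis is perpendicular to the spheroid radius.
    """
    r = np.asarray(centroid, dtype=float) - np.asarray(center, dtype=float)
    norm = np.linalg.norm(r)
    if norm == 0:
        raise ValueError("nucleus centroid coincides with the spheroid center")
    e3 = np.asarray(e3, dtype=float)
    e3 = e3 / np.linalg.norm(e3)
    return float(np.degrees(np.arcsin(np.clip(abs(r @ e3) / norm, 0.0, 1.0))))


def alignment_angles(df: pd.DataFrame, center) -> pd.Series:
    """Vectorized :func:`alignment_angle` over a feature table."""
    r = df[["centroid_z", "centroid_y", "centroid_x"]].to_numpy(dtype=float) - np.asarray(center, dtype=float)
    norms = np.linalg.norm(r, axis=1)
    if (norms == 0).any():
        raise ValueError("a nucleus centroid coincides with the spheroid center")
    e3 = df[["e3_z", "e3_y", "e3_x"]].to_numpy(dtype=float)
    e3 = e3 / np.linalg.norm(e3, axis=1, keepdims=True)
    dots = np.abs(np.einsum("ij,ij->i", r, e3)) / norms
    return pd.Series(np.degrees(np.arcsin(np.clip(dots, 0.0, 1.0))), index=df.index, name="alignment_angle")


def z_alignment_angle(e3) -> float:
    """Angle between the optical z-axis and the e1–e2 plane (degrees)."""
    e3 = np.asarray(e3, dtype=float)
    e3 = e3 / np.linalg.norm(e3)
    return float(np.degrees(np.arcsin(np.clip(abs(e3[0]), 0.0, 1.0))))


def z_alignment_angles(df: pd.DataFrame) -> pd.Series:
    e3 = df[["e3_z", "e3_y", "e3_x"]].to_numpy(dtype=float)
    e3 = e3 / np.linalg.norm(e3, axis=1, keepdims=True)
    return pd.Series(
        np.degrees(np.arcsin(np.clip(np.abs(e3[:, 0]), 0.0, 1.0))), index=df.index, name="z_alignment_angle"
    )


def axis_ratios(p_major, p_intermediate, p_minor) -> tuple[float, float]:
    """(major/minor, major/intermediate) aspect ratios, both ≥ 1."""
    return float(np.asarray(p_major) / np.asarray(p_minor)), float(
        np.asarray(p_major) / np.asarray(p_intermediate)
    )


# ---------------------------------------------------------------------------
# Radial trends and z-artifact fit
# ---------------------------------------------------------------------------

def radial_trend(
    values,
    distances,
    bin_width: float = 5.0,
    stat: str = "mean",
    min_count: int = 3,
) -> pd.DataFrame:
    """Central value ± dispersion of a feature in concentric distance bins.

    Half-open, lower-inclusive ``bin_width`` µm bins on perimeter
    distance; ``stat`` selects mean ± SD or median ± MAD. Bins with
    fewer than ``min_count`` nuclei are flagged.
    """
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    v = np.asarray(values, dtype=float)
    d = np.asarray(distances, dtype=float)
    idx = (d // bin_width).astype(int)
    rows = []
    for b in range(int(idx.max()) + 1 if idx.size else 0):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            rows.append({"bin_lo": b * bin_width, "bin_center": (b + 0.5) * bin_width,
                         "n": 0, "center_value": np.nan, "dispersion": np.nan, "flagged": True})
            continue
        vb = v[sel]
        if stat == "mean":
            c, disp = float(vb.mean()), float(vb.std())
        else:
            med = np.median(vb)
            c, disp = float(med), float(np.median(np.abs(vb - med)))
        rows.append({"bin_lo": b * bin_width, "bin_center": (b + 0.5) * bin_width,
                     "n": n, "center_value": c, "dispersion": disp, "flagged": n < min_count})
    return pd.DataFrame(rows)


def fit_z_artifact(df: pd.DataFrame, min_records: int = 30, min_spread: float = 20.0) -> pd.DataFrame:
    """Linear fit of each principal-axis length against the z-alignment angle.

    Axial blur in confocal stacks stretches extents along z, so axis
    lengths drift with nucleus orientation relative to the optical axis.
    Returns per axis the least-squares slope (µm/degree), intercept and
    the implied length difference between a 0°- and a 90°-aligned
    nucleus. Warns when the angle spread is too narrow to constrain the
    fit. The fit is order-invariant.
    """
    angles = z_alignment_angles(df).to_numpy()
    if len(df) < min_records or (angles.max() - angles.min()) < min_spread:
        warnings.warn(
            f"{len(df)} records spanning {angles.max() - angles.min():.1f}° of z-alignment — "
            "fit poorly constrained"
        )
    rows = []
    for axis in ("p_major", "p_intermediate", "p_minor"):
        slope, intercept = np.polyfit(angles, df[axis].to_numpy(dtype=float), 1)
        rows.append({
            "axis": axis,
            "slope_um_per_degree": float(slope),
            "intercept_um": float(intercept),
            "difference_0_to_90_um": float(slope * 90.0),
        })
    return pd.DataFrame(rows)
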