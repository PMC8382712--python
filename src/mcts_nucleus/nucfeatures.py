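"""Per-nucleus volumetric and intensity measurements and the volume gate.

Volumes are voxel counts times the physical voxel volume; surface areas
come from a marching-cubes mesh of each nucleus (voxel-face counting
overestimates a sphere's area by ~50% and would break the sphericity ≤ 1
contract); principal axes are those of the constant-density ellipsoid
with the same second central moments as the voxel region, matching the
same convention as MATLAB's regionprops3.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes, mesh_surface_area

from .stack_io import LabelVolume, NucleusRecord, VoxelGrid

__all__ = ["measure_nuclei", "principal_axes", "sphericity", "volume_gate"]


def sphericity(volume: float, surface_area: float) -> float:
    """Sphericity π^(1/3)·(6V)^(2/3)/A — exactly 1 for a perfect sphere."""
    if volume <= 0 or surface_area <= 0:
        raise ValueError("volume and surface area must be positive")
    return np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / surface_area


def _sign_fix(vec: np.ndarray) -> np.ndarray:
    """Flip so the first nonzero component is positive (deterministic sign)."""
    for c in vec:
        if abs(c) > 1e-12:
            return vec if c > 0 else -vec
    return vec


def principal_axes(coords_um: np.ndarray, spacing=None):
    """Principal axis lengths and orientations of a voxel region.

    Parameters
    ----------
    coords_um
        (n, 3) voxel-center coordinates in µm, order (z, y, x).
    spacing
        Optional (dz, dy, dx) µm; when given, the voxel's own second
        moment (spacing²/12 per axis) is added to the covariance, the
        regionprops3 finite-voxel correction.

    Returns
    -------
    (p_major, p_intermediate, p_minor, e1, e2, e3)
        Full axis lengths (descending, µm) of the constant-density
        ellipsoid with the region's second central moments — a solid
        ellipsoid of semi-axis a has moment λ = a²/5, so the full axis
        along eigenvalue λ is 2√(5λ) — and the matching sign-fixed unit
        eigenvectors.
    """
    coords = np.asarray(coords_um, dtype=float)
    if coords.shape[0] < 4:
        raise ValueError("need at least 4 voxels for principal axes")
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / coords.shape[0]
    # coplanarity check on the raw (uncorrected) moments
    raw_eig = np.linalg.eigvalsh(cov)
    if raw_eig[0] < 1e-9 * max(raw_eig[-1], 1.0):
        raise ValueError("degenerate (coplanar) voxel region")
    if spacing is not None:
        cov = cov + np.diag(np.asarray(spacing, dtype=float) ** 2 / 12.0)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    lengths = 2.0 * np.sqrt(5.0 * eigval)
    vecs = [_sign_fix(eigvec[:, i].copy()) for i in range(3)]
    return (
        float(lengths[0]),
        float(lengths[1]),
        float(lengths[2]),
        tuple(map(float, vecs[0])),
        tuple(map(float, vecs[1])),
        tuple(map(float, vecs[2])),
    )


def _surface_area(region_mask: np.ndarray, spacing) -> float:
    """Marching-cubes surface area (µm²) of a padded binary region.

    The binary mask is smoothed with a 0.8-voxel Gaussian before
    meshing at the 0.5 level: meshing the raw staircase surface
    overestimates a sphere's area by ~8–10%, while this light
    anti-aliasing brings it within ~1% for nucleus-sized objects.
    """
    padded = np.pad(region_mask, 2).astype(np.float32)
    smoothed = ndimage.gaussian_filter(padded, sigma=0.8)
    if smoothed.max() <= 0.5:
        smoothed = padded  # object of a few voxels: mesh the raw mask
    verts, faces, _, _ = marching_cubes(smoothed, level=0.5, spacing=tuple(spacing))
    return float(mesh_surface_area(verts, faces))


def measure_nuclei(
    labels: LabelVolume,
    channels: dict[str, VoxelGrid] | None = None,
    spheroid_id: str = "",
) -> list[NucleusRecord]:
    """Measure every labelled nucleus.

    Per label: volume (voxel count × voxel volume), marching-cubes
    surface area, centroid in µm, extent (volume / axis-aligned bounding
    box volume), principal axis lengths and orientations, sphericity,
    and the per-channel integrated intensity (sum of raw voxel values
    under the label — intensities should come from the *unsmoothed*
    stack, since smoothing redistributes intensity across boundaries).
    """
    channels = channels or {}
    for name, ch in channels.items():
        if ch.shape != labels.shape:
            raise ValueError(
                f"channel {name!r} shape {ch.shape} does not match labels {labels.shape}"
            )
        if not np.allclose(ch.spacing, labels.spacing):
            raise ValueError(f"channel {name!r} spacing differs from labels")
    arr = labels.labels
    ids = labels.ids()
    spacing = np.asarray(labels.spacing, dtype=float)
    voxvol = labels.voxel_volume
    slices = ndimage.find_objects(arr)
    # integrated intensities in one pass per channel
    intensities = {
        name: ndimage.sum_labels(ch.data, labels=arr, index=ids) for name, ch in channels.items()
    }
    records: list[NucleusRecord] = []
    for k, lab in enumerate(ids):
        slc = slices[lab - 1]
        region = arr[slc] == lab
        nvox = int(region.sum())
        volume = nvox * voxvol
        bbox_vox = int(np.prod([s.stop - s.start for s in slc]))
        extent = nvox / bbox_vox
        coords_vox = np.argwhere(region) + np.array([s.start for s in slc])
        coords_um = coords_vox * spacing
        centroid = tuple(map(float, coords_um.mean(axis=0)))
        area = _surface_area(region, labels.spacing)
        try:
            p1, p2, p3, e1, e2, e3 = principal_axes(coords_um, spacing=labels.spacing)
        except ValueError:
            # tiny/coplanar region: fall back to the finite-voxel moments
            # alone (axes of a single voxel's constant-density ellipsoid)
            centered = coords_um - coords_um.mean(axis=0)
            cov = centered.T @ centered / coords_um.shape[0]
            cov = cov + np.diag(spacing**2 / 12.0)
            eigval, eigvec = np.linalg.eigh(cov)
            order = np.argsort(eigval)[::-1]
            lengths = 2.0 * np.sqrt(5.0 * eigval[order])
            vecs = [tuple(map(float, _sign_fix(eigvec[:, i].copy()))) for i in order]
            p1, p2, p3 = map(float, lengths)
            e1, e2, e3 = vecs
        records.append(
            NucleusRecord(
                label=int(lab),
                centroid=centroid,
                volume=float(volume),
                surface_area=area,
                extent=float(extent),
                p_major=p1,
                p_intermediate=p2,
                p_minor=p3,
                e1=e1,
                e2=e2,
                e3=e3,
                sphericity=sphericity(volume, area),
                integrated_intensity={name: float(vals[k]) for name, vals in intensities.items()},
                spheroid_id=spheroid_id,
            )
        )
    return records


def volume_gate(
    records: list[NucleusRecord],
    low_fraction: float = 0.6,
    high_fraction: float = 1.8,
) -> tuple[list[NucleusRecord], list[NucleusRecord]]:
    """Split records into volume-gated keepers and discards.

    Keeps nuclei whose volume lies within [low_fraction, high_fraction]
    of the median volume (inclusive at both bounds). The discarded
    partition — fused clusters, debris and polyploid outliers — is
    returned too rather than dropped, since the large-volume tail is
    itself of interest in ploidy studies.
    """
    if not records:
        raise ValueError("record list is empty")
    vols = np.array([r.volume for r in records])
    med = float(np.median(vols))
    lo, hi = low_fraction * med, high_fraction * med
    kept = [r for r in records if lo <= r.volume <= hi]
    discarded = [r for r in records if not (lo <= r.volume <= hi)]
    return kept, discarded
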