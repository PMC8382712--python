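"""Ground-truthed synthetic spheroid phantoms.

Generates confocal-like z-stacks of a DNA-stained multicellular
spheroid: ellipsoidal nuclei packed by dart-throwing inside a sphere,
stoichiometric DNA intensity (2N at content 1, 4N at content 2, S cells
in between), linear depth attenuation, anisotropic blur, an explicit
axial-elongation artifact mimicking the poorer z-resolution of confocal
stacks, and detector noise — together with the exact ground-truth label
volume and a per-nucleus truth table, so every downstream stage can be
validated by parameter recovery.

The phantom is a statistical emulation, not an optical simulation: there
is no physical PSF model, no spectral bleed-through and no necrotic core
(spheroids this size, 120–150 µm across, do not develop one).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .stack_io import LabelVolume, VoxelGrid

__all__ = [
    "PhantomSpec",
    "PackingError",
    "generate_phantom",
    "regenerate",
    "generate_cohort",
    "match_detections",
    "overlap_jaccard",
]


class PackingError(RuntimeError):
    """Raised when dart-throwing cannot place all requested nuclei."""

    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(f"packed only {placed} of {requested} nuclei before giving up")


@dataclass
class PhantomSpec:
    """Full parameterization of one synthetic spheroid.

    Defaults mirror the imaging and population structure the analysis
    assumes: a ~140 µm spheroid of ~300 nuclei with principal axis
    lengths 16.3/11.8/8.2 µm, voxels 0.4393 µm laterally and 0.9 µm
    axially, a diploid G1 majority, an S/G2 minority spread between
    content 1 and 2, and ~25% of nuclei carrying FUCCI reporters.
    """

    spheroid_radius: float = 70.0  # µm
    n_nuclei: int = 300
    nucleus_axes_mean: tuple[float, float, float] = (16.3, 11.8, 8.2)  # full lengths, µm
    nucleus_axes_sd: tuple[float, float, float] = (2.3, 1.4, 1.2)
    orientation_mode: str = "isotropic"  # or "tangential"
    tangential_strength: float = 0.8  # only for tangential mode, in [0, 1]
    radial_volume_gradient: float = 0.0  # fractional volume change per µm toward center
    g1_fraction: float = 0.813
    g1s_fraction: float = 0.070
    sg2_fraction: float = 0.117
    sg2_g2_fraction: float = 0.5  # of SG2 cells, fraction already at 4N
    s_content_range: tuple[float, float] = (1.1, 1.9)  # uniform S-phase content law
    content_jitter_sd: float = 0.06  # stain stoichiometry noise (fractional)
    # Bright-tail staining/segmentation artifacts: a fraction of nuclei get
    # their DNA intensity inflated by 1 + Exp(scale), a monotonically
    # decaying tail toward 4N. Calibrated so ~6% of 2N nuclei exceed
    # content 1.25 (the false-positive tail a plain threshold suffers).
    intensity_artifact_fraction: float = 0.12
    intensity_artifact_scale: float = 0.4
    intensity_per_content: float = 1.0e6  # integrated units per 1 content at depth 0
    fucci_intensity: float = 5.0e5
    attenuation_slope: float = 0.004  # fractional intensity loss per µm depth
    transfection_rate: float = 0.252
    noise_sd: float = 4.0
    poisson_noise: bool = False
    blur_sigma: tuple[float, float, float] = (0.6, 0.3, 0.3)  # (z, y, x) µm
    z_elongation: float = 2.0  # µm added to each nucleus's z-extent (axial artifact)
    spacing: tuple[float, float, float] = (0.9, 0.4393, 0.4393)  # (dz, dy, dx) µm
    margin: float = 8.0  # µm of empty space around the spheroid
    packing_shrink: float = 0.9  # linear shrink of the collision ellipsoid
    max_attempts_per_nucleus: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.g1_fraction, self.g1s_fraction, self.sg2_fraction)
        if any(f < 0 or f > 1 for f in fr) or not np.isclose(sum(fr), 1.0, atol=1e-6):
            raise ValueError(f"class fractions must lie in [0, 1] and sum to 1, got {fr}")
        if self.spheroid_radius <= 0 or self.n_nuclei <= 0:
            raise ValueError("radius and nucleus count must be positive")
        if self.orientation_mode not in ("isotropic", "tangential"):
            raise ValueError(f"unknown orientation mode {self.orientation_mode!r}")

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        d = yaml.safe_load(Path(path).read_text())
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in d.items():
            if k not in fields:
                raise ValueError(f"unknown phantom parameter {k!r}")
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Sampling helpers
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (via a normalized quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _orientation(rng: np.random.Generator, spec: PhantomSpec, radial_unit: np.ndarray) -> np.ndarray:
    """Columns e1, e2, e3 (major, intermediate, minor) in (z, y, x) frame."""
    if spec.orientation_mode == "isotropic":
        return _random_rotation(rng)
    # tangential: bias the minor axis toward the (signed) radial direction
    s = float(np.clip(spec.tangential_strength, 0.0, 1.0))
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    r = radial_unit if u @ radial_unit >= 0 else -radial_unit
    e3 = (1.0 - s) * u + s * r
    e3 /= np.linalg.norm(e3)
    # random in-plane direction for the major axis
    a = rng.normal(size=3)
    e1 = a - (a @ e3) * e3
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(e3, e1)
    return np.column_stack([e1, e2, e3])


def _sample_content(rng: np.random.Generator, spec: PhantomSpec, cls: str) -> float:
    if cls in ("G1", "G1S"):
        return 1.0
    if rng.random() < spec.sg2_g2_fraction:
        return 2.0
    lo, hi = spec.s_content_range
    return float(rng.uniform(lo, hi))


def _shape_matrix(axes_full: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Ellipsoid shape matrix M = Σ (Lᵢ/2)² êᵢêᵢᵀ (x M⁻¹ x ≤ 1 inside)."""
    half = axes_full / 2.0
    return R @ np.diag(half**2) @ R.T


def _elongate_z(M: np.ndarray, delta_full: float) -> np.ndarray:
    """Stretch an ellipsoid's z-extent by ``delta_full`` µm (axial artifact)."""
    if delta_full <= 0:
        return M
    d = delta_full / 2.0  # half-extent growth
    h_z = np.sqrt(M[0, 0])  # current half-extent along z
    out = M.copy()
    out[0, 0] += 2.0 * h_z * d + d * d
    return out


def _principal_from_shape(M: np.ndarray):
    """Full axis lengths (desc) and sign-fixed unit vectors from a shape matrix."""
    eigval, eigvec = np.linalg.eigh(M)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    lengths = 2.0 * np.sqrt(eigval)
    vecs = []
    for i in range(3):
        v = eigvec[:, i]
        for c in v:
            if abs(c) > 1e-12:
                v = v if c > 0 else -v
                break
        vecs.append(v)
    return lengths, vecs


def _rasterize(Minv: np.ndarray, center_um: np.ndarray, spacing: np.ndarray, shape) -> tuple:
    """Voxel indices (z, y, x arrays) of the ellipsoid on the given grid."""
    half_ext = np.sqrt(np.diag(np.linalg.inv(Minv)))  # extent along each grid axis
    lo = np.maximum(np.floor((center_um - half_ext) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((center_um + half_ext) / spacing).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return (np.array([], int),) * 3
    zz, yy, xx = np.meshgrid(
        *[np.arange(lo[a], hi[a]) * spacing[a] - center_um[a] for a in range(3)], indexing="ij"
    )
    pts = np.stack([zz, yy, xx], axis=-1)
    q = np.einsum("...i,ij,...j->...", pts, Minv, pts)
    idx = np.nonzero(q <= 1.0)
    return tuple(idx[a] + lo[a] for a in range(3))


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

def generate_phantom(
    spec: PhantomSpec,
    seed: int | None = None,
    spheroid_id: str = "phantom",
) -> tuple[dict[str, VoxelGrid], LabelVolume, pd.DataFrame]:
    """Generate one phantom spheroid.

    Returns ``(channels, truth_labels, truth)``: the intensity channels
    (``dapi`` always; ``rfp``/``gfp`` when transfection_rate > 0), the
    ground-truth label volume on the same raw anisotropic grid, and the
    per-nucleus truth table (one row per label: true class, true and
    stained DNA content, transfection/artifact flags, center, nominal
    axes and the effective — axially elongated — principal axes and
    orientation vectors).

    All randomness derives from ``seed`` (default ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    spacing = np.asarray(spec.spacing, dtype=float)
    extent = 2.0 * (spec.spheroid_radius + spec.margin)
    shape = tuple(int(np.ceil(extent / s)) + 1 for s in spacing)
    center0 = (np.asarray(shape) - 1) * spacing / 2.0

    # --- sample nuclei and pack them by dart throwing ---------------------
    coarse_pitch = 1.0  # µm occupancy grid for collision tests
    coarse_shape = tuple(int(np.ceil(extent / coarse_pitch)) + 1 for _ in range(3))
    occupancy = np.zeros(coarse_shape, dtype=bool)
    classes = rng.choice(
        ["G1", "G1S", "SG2"],
        size=spec.n_nuclei,
        p=[spec.g1_fraction, spec.g1s_fraction, spec.sg2_fraction],
    )
    nuclei = []
    for i in range(spec.n_nuclei):
        cls = str(classes[i])
        content = _sample_content(rng, spec, cls)
        axes = np.sort(rng.normal(spec.nucleus_axes_mean, spec.nucleus_axes_sd))[::-1]
        axes = np.clip(axes, 2.0, None)
        # larger nuclei for higher DNA content (volume ∝ 1 + 0.5·(content − 1))
        axes = axes * (1.0 + 0.5 * (content - 1.0)) ** (1.0 / 3.0)
        placed = False
        for _ in range(spec.max_attempts_per_nucleus):
            # uniform position inside the allowed ball
            r_max = spec.spheroid_radius - axes[2] / 2.0
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            radius = r_max * rng.random() ** (1.0 / 3.0)
            center = center0 + radius * u
            radial_unit = u
            R = _orientation(rng, spec, radial_unit)
            if spec.radial_volume_gradient:
                depth_in = spec.spheroid_radius - radius
                scale = max(1.0 - spec.radial_volume_gradient * depth_in, 0.2) ** (1.0 / 3.0)
                axes_here = axes * scale
            else:
                axes_here = axes
            M = _shape_matrix(axes_here, R)
            # collision uses the rendered (z-elongated) shape, shrunk 10% linearly
            M_coll = spec.packing_shrink**2 * _elongate_z(M, spec.z_elongation)
            idx = _rasterize(
                np.linalg.inv(M_coll), center, np.full(3, coarse_pitch), coarse_shape
            )
            if idx[0].size == 0 or occupancy[idx].any():
                continue
            occupancy[idx] = True
            nuclei.append({
                "center": center, "axes": axes_here, "R": R, "class": cls, "content": content,
            })
            placed = True
            break
        if not placed:
            raise PackingError(placed=len(nuclei), requested=spec.n_nuclei)

    # --- per-nucleus stain/reporter amounts --------------------------------
    n = len(nuclei)
    transfected = rng.random(n) < spec.transfection_rate
    jitter = 1.0 + rng.normal(0.0, spec.content_jitter_sd, size=n)
    artifact = rng.random(n) < spec.intensity_artifact_fraction
    art_mult = np.where(
        artifact, 1.0 + rng.exponential(spec.intensity_artifact_scale, size=n), 1.0
    )
    fucci_jitter = np.exp(rng.normal(0.0, 0.2, size=(n, 2)))

    # --- rasterize labels and pristine intensities -------------------------
    labels = np.zeros(shape, dtype=np.int32)
    dapi = np.zeros(shape, dtype=np.float32)
    make_fucci = spec.transfection_rate > 0
    rfp = np.zeros(shape, dtype=np.float32) if make_fucci else None
    gfp = np.zeros(shape, dtype=np.float32) if make_fucci else None
    truth_rows = []
    for i, nuc in enumerate(nuclei):
        lab = i + 1
        M = _shape_matrix(nuc["axes"], nuc["R"])
        M_eff = _elongate_z(M, spec.z_elongation)
        idx = _rasterize(np.linalg.inv(M_eff), nuc["center"], spacing, shape)
        free = labels[idx] == 0
        idx = tuple(a[free] for a in idx)
        nvox = idx[0].size
        if nvox == 0:
            continue
        labels[idx] = lab
        stain_content = max(nuc["content"] * jitter[i] * art_mult[i], 0.05)
        dapi[idx] += np.float32(stain_content * spec.intensity_per_content / nvox)
        if make_fucci and transfected[i]:
            levels = {"G1": (1.0, 0.0), "G1S": (0.6, 0.6), "SG2": (0.0, 1.0)}[nuc["class"]]
            if levels[0] > 0:
                rfp[idx] += np.float32(levels[0] * fucci_jitter[i, 0] * spec.fucci_intensity / nvox)
            if levels[1] > 0:
                gfp[idx] += np.float32(levels[1] * fucci_jitter[i, 1] * spec.fucci_intensity / nvox)
        lengths, vecs = _principal_from_shape(M_eff)
        row = {
            "label": lab,
            "class": nuc["class"],
            "transfected": bool(transfected[i]),
            "artifact": bool(artifact[i]),
            "dna_content": nuc["content"],
            "stain_content": stain_content,
            "center_z": nuc["center"][0], "center_y": nuc["center"][1], "center_x": nuc["center"][2],
            "axis_major_nominal": nuc["axes"][0],
            "axis_intermediate_nominal": nuc["axes"][1],
            "axis_minor_nominal": nuc["axes"][2],
            "p_major": lengths[0], "p_intermediate": lengths[1], "p_minor": lengths[2],
            "voxel_count": nvox,
        }
        for j, v in enumerate(vecs, start=1):
            row[f"e{j}_z"], row[f"e{j}_y"], row[f"e{j}_x"] = map(float, v)
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)

    # --- depth attenuation, blur, noise ------------------------------------
    z_um = (np.arange(shape[0]) * spacing[0]).astype(np.float32)
    atten = np.clip(1.0 - spec.attenuation_slope * z_um, 0.05, None)[:, None, None]
    sig_vox = np.asarray(spec.blur_sigma) / spacing
    channels: dict[str, VoxelGrid] = {}
    for name, vol in (("dapi", dapi), ("rfp", rfp), ("gfp", gfp)):
        if vol is None:
            continue
        vol = vol * atten
        if np.any(sig_vox > 0):
            vol = ndimage.gaussian_filter(vol, sigma=sig_vox)
        if spec.poisson_noise:
            vol = rng.poisson(np.clip(vol, 0, None)).astype(np.float32)
        if spec.noise_sd > 0:
            vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape).astype(np.float32)
        vol = np.clip(vol, 0.0, None).astype(np.float32)
        channels[name] = VoxelGrid(vol, tuple(spacing), channel_name=name)

    truth.attrs["spheroid_id"] = spheroid_id
    truth.attrs["center_um"] = tuple(map(float, center0))
    return channels, LabelVolume(labels, tuple(spacing)), truth


def regenerate(spec: PhantomSpec, seed: int):
    """Re-run :func:`generate_phantom`; same spec + seed ⇒ bit-identical output."""
    return generate_phantom(spec, seed=seed)


def generate_cohort(
    spec: PhantomSpec,
    n_spheroids: int,
    base_seed: int = 0,
    id_prefix: str = "mcts",
):
    """Yield ``(spheroid_id, channels, truth_labels, truth)`` for a cohort.

    Spheroid i uses seed ``base_seed + i`` so cohorts are reproducible
    and individually regenerable.
    """
    for i in range(n_spheroids):
        sid = f"{id_prefix}{i:02d}"
        channels, labels, truth = generate_phantom(spec, seed=base_seed + i, spheroid_id=sid)
        yield sid, channels, labels, truth


# ---------------------------------------------------------------------------
# Ground-truth evaluation
# ---------------------------------------------------------------------------

def match_detections(
    truth: pd.DataFrame,
    found_centroids_um: np.ndarray,
    radius: float | None = None,
) -> dict[str, float]:
    """Match detected nuclei to truth by centroid distance.

    Greedy nearest-pair matching (closest pairs first, one-to-one); a
    detection matches a truth nucleus when their centroids lie within
    one nuclear radius (default: the truth nucleus's volume-equivalent
    sphere radius). Returns precision/recall/F1 of detection plus the
    raw counts.
    """
    tc = truth[["center_z", "center_y", "center_x"]].to_numpy(dtype=float)
    fc = np.atleast_2d(np.asarray(found_centroids_um, dtype=float))
    if radius is None:
        vol = (
            np.pi / 6.0
            * truth["axis_major_nominal"]
            * truth["axis_intermediate_nominal"]
            * truth["axis_minor_nominal"]
        ).to_numpy()
        radii = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
    else:
        radii = np.full(len(tc), float(radius))
    if fc.size == 0:
        return {"tp": 0, "fp": 0, "fn": len(tc), "precision": 0.0, "recall": 0.0, "f1": 0.0}
    d = np.linalg.norm(tc[:, None, :] - fc[None, :, :], axis=2)
    pairs = np.argwhere(d <= radii[:, None])
    order = np.argsort(d[pairs[:, 0], pairs[:, 1]])
    used_t, used_f = set(), set()
    tp = 0
    for ti, fi in pairs[order]:
        if ti in used_t or fi in used_f:
            continue
        used_t.add(ti)
        used_f.add(fi)
        tp += 1
    fp = fc.shape[0] - tp
    fn = tc.shape[0] - tp
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return {"tp": tp, "fp": fp, "fn": fn, "precision": precision, "recall": recall, "f1": f1}


def overlap_jaccard(truth_labels: LabelVolume, found_labels: LabelVolume) -> pd.DataFrame:
    """Best-overlap Jaccard index per truth nucleus.

    For each truth label the segmentation label with the largest voxel
    intersection is its match; J = |∩| / |∪| (0 for undetected nuclei).
    The two volumes must share a grid; resample first if they do not.
    """
    if truth_labels.shape != found_labels.shape:
        raise ValueError("label volumes must share a voxel grid")
    t = truth_labels.labels.ravel().astype(np.int64)
    f = found_labels.labels.ravel().astype(np.int64)
    sel = (t > 0) | (f > 0)
    t, f = t[sel], f[sel]
    pair = t * (f.max() + 1) + f
    uniq, counts = np.unique(pair, return_counts=True)
    tt, ff = uniq // (f.max() + 1), uniq % (f.max() + 1)
    t_sizes = {int(i): int(c) for i, c in zip(*np.unique(t, return_counts=True)) if i > 0}
    f_sizes = {int(i): int(c) for i, c in zip(*np.unique(f, return_counts=True)) if i > 0}
    rows = []
    for lab, size in t_sizes.items():
        m = (tt == lab) & (ff > 0)
        if not m.any():
            rows.append({"truth_label": lab, "match_label": 0, "jaccard": 0.0})
            continue
        k = np.argmax(counts[m])
        inter = int(counts[m][k])
        match = int(ff[m][k])
        union = size + f_sizes[match] - inter
        rows.append({"truth_label": lab, "match_label": match, "jaccard": inter / union})
    return pd.DataFrame(rows).sort_values("truth_label", ignore_index=True)


def truth_seed_replacements(
    truth: pd.DataFrame,
    labels: LabelVolume,
    cluster_ids,
) -> dict[int, list[tuple[int, int, int]]]:
    """Seed replacements for merged clusters from the truth table.

    The headless analogue of the operator clicking once per nucleus
    inside each flagged cluster: for every cluster id, the truth nuclei
    whose centers fall inside that label become its replacement seeds
    (voxel coordinates on the labels' grid). Centers that do not land in
    the cluster are skipped, like clicks outside the displayed object.
    """
    cluster_ids = set(int(i) for i in cluster_ids)
    spacing = np.asarray(labels.spacing, dtype=float)
    out: dict[int, list[tuple[int, int, int]]] = {}
    for _, row in truth.iterrows():
        c = np.array([row["center_z"], row["center_y"], row["center_x"]])
        vox = np.round(c / spacing).astype(int)
        if np.any(vox < 0) or np.any(vox >= labels.shape):
            continue
        lab = int(labels.labels[tuple(vox)])
        if lab in cluster_ids:
            out.setdefault(lab, []).append(tuple(int(v) for v in vox))
    return out
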