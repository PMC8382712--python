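"""Shared fixtures: synthetic phantoms and measured cohorts.

Heavy objects (the full-size 300-nucleus phantom, the 20-spheroid
cohort) are session-scoped so each is generated exactly once per run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import mcts_nucleus.cellcycle as cc
import mcts_nucleus.synthetic_mcts as syn
from mcts_nucleus.nucfeatures import measure_nuclei, volume_gate
from mcts_nucleus.stack_io import records_to_table


def measure_phantom(channels, truth_labels, truth, spheroid_id):
    """Measure ground-truth labels and merge truth annotations."""
    records = measure_nuclei(truth_labels, channels, spheroid_id=spheroid_id)
    kept, _ = volume_gate(records)
    df = records_to_table(kept)
    tt = truth.set_index("label")
    df["true_class"] = tt.loc[df["label"], "class"].values
    df["true_content"] = tt.loc[df["label"], "dna_content"].values
    df["true_transfected"] = tt.loc[df["label"], "transfected"].values
    return df


def build_measured_cohort(n_spheroids: int, base_seed: int, **spec_kwargs) -> pd.DataFrame:
    """Generate a cohort, measure truth labels, classify FUCCI, correct
    depth and normalize DNA content — the standard analysis route with
    the segmentation stage bypassed via ground-truth labels."""
    spec = syn.PhantomSpec(spheroid_radius=50.0, n_nuclei=110, **spec_kwargs)
    frames = []
    for sid, channels, labels, truth in syn.generate_cohort(spec, n_spheroids, base_seed=base_seed):
        frames.append(measure_phantom(channels, labels, truth, sid))
    df = pd.concat(frames, ignore_index=True)
    df["fucci_class"] = cc.classify_fucci(df)
    df, _ = cc.depth_correct(df)
    return cc.normalize_dna(df)


@pytest.fixture(scope="session")
def default_phantom():
    """The full-size default phantom: ~300 nuclei, 140 µm spheroid."""
    spec = syn.PhantomSpec()
    channels, labels, truth = syn.generate_phantom(spec, seed=1, spheroid_id="default")
    return spec, channels, labels, truth


@pytest.fixture(scope="session")
def default_phantom_measured(default_phantom):
    """Depth-corrected feature table measured on the default phantom's
    ground-truth labels (DNA channel only)."""
    spec, channels, labels, truth = default_phantom
    df = measure_phantom({"dapi": channels["dapi"]}, labels, truth, "default")
    df, fits = cc.depth_correct(df)
    return spec, df, fits, truth


@pytest.fixture(scope="session")
def cohort20():
    """20 mid-size phantom spheroids measured on truth labels."""
    return build_measured_cohort(20, base_seed=0)


@pytest.fixture(scope="session")
def sparse_phantom():
    """A phantom of non-touching nuclei (inflated collision shapes keep
    every pair separated) for segmentation unit tests."""
    spec = syn.PhantomSpec(
        spheroid_radius=35.0, n_nuclei=12, transfection_rate=0.0, packing_shrink=1.3
    )
    channels, labels, truth = syn.generate_phantom(spec, seed=4, spheroid_id="sparse")
    return spec, channels, labels, truth


def resample_labels_to_iso(truth_labels, iso_shape, iso_spacing):
    """Nearest-neighbor z-resampling of raw-grid labels onto the
    isotropic grid the segmentation works on."""
    from mcts_nucleus.stack_io import LabelVolume

    zpos = np.arange(iso_shape[0]) * iso_spacing[0] / truth_labels.spacing[0]
    zidx = np.clip(np.round(zpos).astype(int), 0, truth_labels.shape[0] - 1)
    return LabelVolume(truth_labels.labels[zidx], iso_spacing)


def voxel_sphere(radius_vox: int, pad: int = 2) -> np.ndarray:
    """Binary digital ball of the given voxel radius."""
    n = 2 * radius_vox + 2 * pad + 1
    zz, yy, xx = np.mgrid[:n, :n, :n]
    c = (n - 1) / 2
    return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius_vox**2
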