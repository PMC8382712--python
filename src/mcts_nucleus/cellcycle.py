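"""DNA-content cell-cycle analysis.

A stoichiometric DNA counterstain makes the integrated nuclear intensity
a per-cell DNA-content proxy: G1 cells carry 2N (content 1 after
normalization), G2/M cells 4N (content 2) and S cells fall in between.
This module turns integrated intensities into cell-cycle calls along the
route: FUCCI-reporter ground-truth labelling → linear depth correction →
per-spheroid median normalization → either a TPR−FPR-optimal DNA-content
threshold or an RBF-kernel SVM trained on DNA content plus
neighbor-normalized volumetrics.

All operations act on the per-nucleus feature table (one row per
nucleus; see :mod:`mcts_nucleus.stack_io` for the column contract) and
every stochastic step takes an explicit seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "PositivityRule",
    "DnaHistogramFit",
    "fit_dna_histogram",
    "ThresholdCurve",
    "ClassifierModel",
    "EvalReport",
    "classify_fucci",
    "transfection_efficacy",
    "depth_correct",
    "normalize_dna",
    "optimal_threshold",
    "threshold_classify",
    "neighbor_normalize",
    "train_svm",
    "evaluate",
]

#: Volumetric features that are neighbor-normalized before SVM training.
VOLUMETRIC_FEATURES = (
    "volume",
    "surface_area",
    "extent",
    "p_major",
    "p_intermediate",
    "p_minor",
    "sphericity",
)


# ---------------------------------------------------------------------------
# FUCCI ground-truth classing
# ---------------------------------------------------------------------------

@dataclass
class PositivityRule:
    """Decides per-channel reporter positivity.

    With explicit ``thresholds`` (channel → intensity) a nucleus is
    positive when its integrated intensity is *strictly* above the
    threshold (ties count as negative — the documented tie rule).
    Otherwise the threshold is estimated per channel as
    mean + k·SD of the background population, where the background is
    taken as intensities up to twice the histogram mode (the
    non-transfected majority forms the low-intensity mode).
    """

    thresholds: dict[str, float] | None = None
    k: float = 3.0
    bins: int = 128

    def threshold_for(self, channel: str, values: np.ndarray) -> float:
        if self.thresholds is not None and channel in self.thresholds:
            return float(self.thresholds[channel])
        values = np.asarray(values, dtype=float)
        hist, edges = np.histogram(values, bins=self.bins)
        mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        cut = 2.0 * mode if mode > 0 else edges[1]
        bg = values[values <= cut]
        if bg.size < 2:
            bg = values
        return float(bg.mean() + self.k * bg.std())


def classify_fucci(
    df: pd.DataFrame,
    rfp_channel: str = "rfp",
    gfp_channel: str = "gfp",
    rule: PositivityRule | None = None,
) -> pd.Series:
    """FUCCI class per nucleus from reporter integrated intensities.

    RFP-only ⇒ G1 (cdt1), GFP-only ⇒ SG2 (geminin), both ⇒ G1S
    transition, neither ⇒ NONTRANSFECTED.
    """
    rule = rule or PositivityRule()
    cols = {}
    for ch in (rfp_channel, gfp_channel):
        col = f"ii_{ch}"
        if col not in df.columns:
            raise ValueError(f"channel {ch!r} missing from the feature table ({col})")
        cols[ch] = col
    rfp = df[cols[rfp_channel]].to_numpy(dtype=float)
    gfp = df[cols[gfp_channel]].to_numpy(dtype=float)
    t_r = rule.threshold_for(rfp_channel, rfp)
    t_g = rule.threshold_for(gfp_channel, gfp)
    rpos, gpos = rfp > t_r, gfp > t_g
    out = np.where(
        rpos & gpos, "G1S", np.where(rpos, "G1", np.where(gpos, "SG2", "NONTRANSFECTED"))
    )
    return pd.Series(out, index=df.index, name="fucci_class")


def transfection_efficacy(classes, definition: str = "positive_to_negative") -> float:
    """Transfection efficacy in percent from FUCCI classes (or a count map).

    Two definitions exist in the field and both are provided:
    ``positive_to_negative`` = FUCCI-positive / non-transfected and
    ``positive_to_total`` = FUCCI-positive / all nuclei.
    """
    if isinstance(classes, dict):
        counts = classes
    else:
        counts = pd.Series(classes).value_counts().to_dict()
    positive = sum(counts.get(c, 0) for c in ("G1", "G1S", "SG2"))
    negative = counts.get("NONTRANSFECTED", 0)
    if definition == "positive_to_negative":
        if negative == 0:
            raise ValueError("no non-transfected nuclei")
        return 100.0 * positive / negative
    if definition == "positive_to_total":
        total = positive + negative
        if total == 0:
            raise ValueError("no nuclei")
        return 100.0 * positive / total
    raise ValueError(f"unknown definition {definition!r}")


# ---------------------------------------------------------------------------
# Depth correction and normalization
# ---------------------------------------------------------------------------

def depth_correct(
    df: pd.DataFrame,
    channel: str = "dapi",
    bin_width: float = 5.0,
    min_nuclei: int = 10,
    min_span: float = 20.0,
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Linearly correct integrated intensity for imaging depth, per spheroid.

    Deeper optical sections lose signal even in cleared specimens, so
    the integrated intensity is fitted against centroid depth by least
    squares — on 5 µm median-binned intensities, which resists
    ploidy-driven outliers — and each nucleus is rescaled by
    fit(z_ref)/fit(z) with z_ref the shallowest nucleus of its spheroid.
    After correction the fitted slope is ≈ 0.

    Returns the table with an added ``ii_<channel>_corrected`` column
    and, per spheroid, the fit ``{"slope", "intercept", "relative_slope"}``
    (relative slope = slope / fit(z_ref), the fractional loss per µm).

    Spheroids with fewer than ``min_nuclei`` nuclei or a depth span
    below ``min_span`` µm get a warning and an identity correction.
    """
    col = f"ii_{channel}"
    if col not in df.columns:
        raise ValueError(f"column {col} missing")
    out = df.copy()
    out[f"{col}_corrected"] = out[col].astype(float)
    fits: dict[str, dict[str, float]] = {}
    for sid, grp in df.groupby("spheroid_id", sort=True):
        depth = grp["depth"].to_numpy(dtype=float)
        inten = grp[col].to_numpy(dtype=float)
        span = depth.max() - depth.min() if depth.size else 0.0
        if depth.size < min_nuclei or span < min_span:
            warnings.warn(
                f"spheroid {sid!r}: {depth.size} nuclei over {span:.1f} µm depth — "
                "insufficient for depth correction, applying identity"
            )
            fits[str(sid)] = {"slope": 0.0, "intercept": float(np.median(inten)) if inten.size else 0.0,
                              "relative_slope": 0.0}
            continue
        # median intensity in 5 µm depth bins, fitted by least squares
        # weighted by bin occupancy (sparse end bins otherwise dominate
        # the fit through their leverage)
        bins = np.floor((depth - depth.min()) / bin_width).astype(int)
        centers, medians, counts = [], [], []
        for b in np.unique(bins):
            sel = bins == b
            centers.append(depth.min() + (b + 0.5) * bin_width)
            medians.append(np.median(inten[sel]))
            counts.append(int(sel.sum()))
        slope, intercept = np.polyfit(centers, medians, 1, w=np.sqrt(counts))
        z_ref = depth.min()
        ref = slope * z_ref + intercept
        fit_at = slope * depth + intercept
        fit_at = np.clip(fit_at, 1e-12 * max(abs(ref), 1.0), None)
        out.loc[grp.index, f"{col}_corrected"] = inten * ref / fit_at
        fits[str(sid)] = {
            "slope": float(slope),
            "intercept": float(intercept),
            # fractional intensity change per µm relative to zero depth
            "relative_slope": float(slope / intercept) if intercept else float("nan"),
        }
    return out, fits


def normalize_dna(df: pd.DataFrame, channel: str = "dapi", min_nuclei: int = 3) -> pd.DataFrame:
    """Normalize (depth-corrected) integrated intensity per spheroid.

    ``dna_content`` = corrected intensity / per-spheroid median, so the
    diploid G1 mode sits at 1 and the 4N mode at 2 regardless of stain
    or detector gain; only after this normalization may spheroids be
    pooled. Spheroids with fewer than ``min_nuclei`` nuclei are dropped
    with a warning.
    """
    col = f"ii_{channel}_corrected"
    if col not in df.columns:
        col = f"ii_{channel}"
        if col not in df.columns:
            raise ValueError(f"no intensity column for channel {channel!r}")
    out = df.copy()
    keep = np.ones(len(out), dtype=bool)
    content = np.full(len(out), np.nan)
    for sid, grp in out.groupby("spheroid_id", sort=True):
        vals = grp[col].to_numpy(dtype=float)
        if vals.size < min_nuclei:
            warnings.warn(f"spheroid {sid!r} has only {vals.size} nuclei — excluded")
            keep[out.index.get_indexer(grp.index)] = False
            continue
        med = np.median(vals)
        content[out.index.get_indexer(grp.index)] = vals / med
    out["dna_content"] = content
    return out[keep].copy()


# ---------------------------------------------------------------------------
# DNA-content histogram decomposition
# ---------------------------------------------------------------------------

@dataclass
class DnaHistogramFit:
    """Mixture decomposition of a pooled normalized DNA-content histogram.

    Follows the classic univariate cell-cycle model for DNA cytometry:
    a Gaussian G0/G1 (2N) peak, a Gaussian G2/M (4N) peak, a flat
    S-phase plateau spanning the two peaks and a broad uniform
    background absorbing debris/doublet-like outliers. ``g1_mode`` and
    ``g2_mode`` are the fitted peak positions (in median-normalized
    content units, so ≈ 1 and ≈ 2 for a diploid line).
    """

    g1_mode: float
    g2_mode: float
    g1_sigma: float
    g2_sigma: float
    weights: dict[str, float]
    n_iter: int
    converged: bool


def fit_dna_histogram(
    dna_content,
    g1_window: tuple[float, float] = (0.7, 1.4),
    g2_ratio_bounds: tuple[float, float] = (1.85, 2.15),
    max_iter: int = 500,
    tol: float = 1e-8,
) -> DnaHistogramFit:
    """Locate the 2N and 4N peaks of a DNA-content distribution by EM.

    KDE/histogram argmax systematically mislocates a small G2 peak that
    sits on the shoulder of the S-phase tail; the mixture fit separates
    the Gaussian peak from the plateau underneath it. Initialization is
    deterministic (histogram mode in ``g1_window`` for G1; twice that
    for G2). Following common cytometry practice the G2/G1 mean ratio
    is constrained to ``g2_ratio_bounds`` — stoichiometric staining
    pins replicated DNA at twice the diploid amount — and the S plateau
    stops one G1/G2 sigma short of each peak so it cannot absorb them.
    """
    x = np.asarray(dna_content, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 20:
        raise ValueError("need at least 20 nuclei to fit the DNA histogram")
    lo, hi = float(x.min()), float(x.max())
    hist, edges = np.histogram(x[(x >= g1_window[0]) & (x <= g1_window[1])], bins=60)
    mu1 = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
    mu2 = 2.0 * mu1
    s1 = s2 = 0.08 * mu1
    w = np.array([0.75, 0.06, 0.10, 0.09])  # G1, G2, S, background

    def norm_pdf(v, mu, s):
        return np.exp(-0.5 * ((v - mu) / s) ** 2) / (s * np.sqrt(2 * np.pi))

    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        s_lo, s_hi = mu1 + s1, mu2 - s2
        span = max(s_hi - s_lo, 1e-6)
        comp = np.stack([
            norm_pdf(x, mu1, s1),
            norm_pdf(x, mu2, s2),
            np.where((x >= s_lo) & (x <= s_hi), 1.0 / span, 0.0),
            np.full_like(x, 1.0 / max(hi - lo, 1e-6)),
        ])
        weighted = w[:, None] * comp + 1e-300
        total = weighted.sum(axis=0)
        resp = weighted / total
        ll = float(np.log(total).sum())
        w = resp.sum(axis=1) / x.size
        w = np.maximum(w, 1e-4)
        w /= w.sum()
        r1, r2 = resp[0], resp[1]
        mu1 = float(np.sum(r1 * x) / np.sum(r1))
        mu1 = float(np.clip(mu1, *g1_window))
        mu2 = float(np.sum(r2 * x) / np.sum(r2))
        mu2 = float(np.clip(mu2, g2_ratio_bounds[0] * mu1, g2_ratio_bounds[1] * mu1))
        s1 = float(np.sqrt(np.sum(r1 * (x - mu1) ** 2) / np.sum(r1)))
        s2 = float(np.sqrt(np.sum(r2 * (x - mu2) ** 2) / np.sum(r2)))
        s1 = float(np.clip(s1, 0.01 * mu1, 0.2 * mu1))
        s2 = float(np.clip(s2, 0.01 * mu2, 0.2 * mu2))
        if abs(ll - ll_old) < tol * abs(ll):
            converged = True
            break
        ll_old = ll
    return DnaHistogramFit(
        g1_mode=mu1,
        g2_mode=mu2,
        g1_sigma=s1,
        g2_sigma=s2,
        weights={"g1": w[0], "g2": w[1], "s": w[2], "background": w[3]},
        n_iter=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Threshold classifier
# ---------------------------------------------------------------------------

@dataclass
class ThresholdCurve:
    """TPR/FPR over a grid of DNA-content thresholds, plus the optimum.

    The optimum maximizes TPR − FPR (Youden's J) over the grid; ties are
    broken toward the largest threshold.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    optimum: float


def optimal_threshold(
    dna_content: np.ndarray,
    fucci_classes: np.ndarray,
    grid: np.ndarray | None = None,
) -> ThresholdCurve:
    """Scan DNA-content thresholds for S/G2 detection against FUCCI truth.

    At each candidate t a nucleus is called SG2 iff content > t. TPR is
    computed over FUCCI-SG2 nuclei, FPR over FUCCI G1 ∪ G1S nuclei;
    other classes are ignored.
    """
    if grid is None:
        grid = np.round(np.arange(0.5, 3.0 + 1e-9, 0.01), 10)
    grid = np.asarray(grid, dtype=float)
    content = np.asarray(dna_content, dtype=float)
    classes = np.asarray(fucci_classes)
    pos = content[classes == "SG2"]
    neg = content[np.isin(classes, ("G1", "G1S"))]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need both SG2 and G1/G1S nuclei to build a threshold curve")
    tpr = np.array([(pos > t).mean() for t in grid])
    fpr = np.array([(neg > t).mean() for t in grid])
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())[-1]  # ties toward the largest threshold
    return ThresholdCurve(thresholds=grid, tpr=tpr, fpr=fpr, optimum=float(grid[best]))


def threshold_classify(dna_content: np.ndarray, threshold: float) -> np.ndarray:
    """SG2 iff dna_content strictly exceeds the threshold, else G1."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    content = np.asarray(dna_content, dtype=float)
    return np.where(content > threshold, "SG2", "G1")


# ---------------------------------------------------------------------------
# Neighbor-normalized features and SVM
# ---------------------------------------------------------------------------

def neighbor_normalize(df: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Normalize volumetrics to the mean of the k nearest neighbors.

    Nucleus size and shape vary systematically with position inside a
    spheroid; dividing each volumetric feature by its mean over the k
    closest nuclei (Euclidean centroid distance, same spheroid, self
    excluded) removes that spatial trend so the classifier cannot learn
    position instead of cell state. The normalized DNA content is
    appended unchanged. Requires at least k + 1 nuclei per spheroid.
    """
    feats = [f for f in VOLUMETRIC_FEATURES if f in df.columns]
    missing = set(VOLUMETRIC_FEATURES) - set(feats)
    if missing:
        raise ValueError(f"missing volumetric columns: {sorted(missing)}")
    out = pd.DataFrame(index=df.index)
    for f in feats:
        out[f"nn_{f}"] = np.nan
    for sid, grp in df.groupby("spheroid_id", sort=True):
        if len(grp) < k + 1:
            raise ValueError(f"spheroid {sid!r} has {len(grp)} nuclei; need at least {k + 1}")
        pts = grp[["centroid_z", "centroid_y", "centroid_x"]].to_numpy(dtype=float)
        tree = cKDTree(pts)
        _, idx = tree.query(pts, k=k + 1)
        nb = idx[:, 1:]  # drop self (nearest at distance 0)
        for f in feats:
            vals = grp[f].to_numpy(dtype=float)
            out.loc[grp.index, f"nn_{f}"] = vals / vals[nb].mean(axis=1)
    if "dna_content" in df.columns:
        out["dna_content"] = df["dna_content"].to_numpy(dtype=float)
    return out


@dataclass
class EvalReport:
    """Confusion counts and derived rates with SG2 as the positive class.

    Rates are fractions in [0, 1]; ``precision`` is NaN (and
    ``precision_defined`` False) when nothing was predicted positive.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) else float("nan")

    @property
    def tnr(self) -> float:
        return self.tn / (self.fp + self.tn) if (self.fp + self.tn) else float("nan")

    @property
    def precision_defined(self) -> bool:
        return (self.tp + self.fp) > 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.precision_defined else float("nan")

    @property
    def accuracy(self) -> float:
        n = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / n if n else float("nan")

    @property
    def balanced_accuracy(self) -> float:
        return 0.5 * (self.tpr + self.tnr)

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "tpr": self.tpr, "fpr": self.fpr, "tnr": self.tnr,
            "precision": self.precision, "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
        }


def evaluate(predicted, truth, positive: str = "SG2") -> EvalReport:
    """Confusion counts and rates for a two-class prediction."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError(f"length mismatch: {predicted.shape} vs {truth.shape}")
    p = predicted == positive
    t = truth == positive
    return EvalReport(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


@dataclass
class ClassifierModel:
    """A fitted RBF-SVM cell-cycle classifier plus its training metadata."""

    pipeline: Pipeline
    feature_names: list[str]
    classes: tuple[str, str] = ("G1", "SG2")
    seed: int = 0
    folds: int = 5
    search_results: dict = field(default_factory=dict)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        X = features[self.feature_names].to_numpy(dtype=float)
        return self.pipeline.predict(X)


def train_svm(
    features: pd.DataFrame,
    fucci_classes,
    test_size: float = 0.2,
    folds: int = 5,
    seed: int = 0,
    c_grid: np.ndarray | None = None,
    gamma_grid: np.ndarray | None = None,
) -> tuple[ClassifierModel, EvalReport]:
    """Train an RBF-kernel soft-margin SVM on G1/SG2 FUCCI truth.

    The data are split 80/20 stratified by class; hyperparameters
    (margin penalty C and kernel width γ) are chosen by k-fold
    cross-validated grid search over log-spaced ranges maximizing
    balanced accuracy (class weights balanced because G1 ≫ SG2); the
    final model is refitted on the full training split and the report is
    computed on the untouched test split. Identical seeds give identical
    models and reports.
    """
    y = np.asarray(fucci_classes)
    keep = np.isin(y, ("G1", "SG2"))
    X = features.loc[keep]
    y = y[keep]
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both G1 and SG2 nuclei")
    feature_names = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    X_tr, X_te, y_tr, y_te = train_test_split(
        Xa, y, test_size=test_size, stratify=y, random_state=seed
    )
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training split is single-class")
    if c_grid is None:
        c_grid = np.logspace(-1, 3, 5)
    if gamma_grid is None:
        gamma_grid = np.logspace(-3, 1, 5)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        Pipeline([
            ("scale", StandardScaler()),
            ("svc", SVC(kernel="rbf", class_weight="balanced")),
        ]),
        param_grid={"svc__C": c_grid, "svc__gamma": gamma_grid},
        scoring="balanced_accuracy",
        cv=cv,
        n_jobs=1,
    )
    search.fit(X_tr, y_tr)
    model = ClassifierModel(
        pipeline=search.best_estimator_,
        feature_names=feature_names,
        seed=seed,
        folds=folds,
        search_results={
            "best_params": search.best_params_,
            "best_cv_balanced_accuracy": float(search.best_score_),
            "train_balanced_accuracy": float(
                balanced_accuracy_score(y_tr, search.best_estimator_.predict(X_tr))
            ),
            "n_train": int(len(y_tr)),
            "n_test": int(len(y_te)),
        },
    )
    report = evaluate(search.best_estimator_.predict(X_te), y_te)
    model.search_results["test_indices_seed"] = seed
    return model, report
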