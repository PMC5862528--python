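"""Supervised voxel classification of GFP clones and DAPI tissue masking.

The clone segmenter mirrors a trained pixel-classification workflow: each
voxel is described by a small bank of intensity features (raw value,
Gaussian-smoothed intensity, gradient magnitude and Laplacian response at
two or more physical scales), a random-forest classifier is trained on
labelled voxels from a handful of training discs, and the resulting
per-voxel clone probability is thresholded and cleaned up by a physical
minimum object size. All scales are specified in micrometres and converted
to anisotropic per-axis sigmas, so the features are invariant to the voxel
grid's anisotropy.

The tissue mask is a reproducible automatic procedure: Otsu threshold on
smoothed DAPI, morphological hole filling, and removal of components below
a physical size floor.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .io import ImageStack

__all__ = [
    "VoxelFeatureSet",
    "VoxelClassifier",
    "SegmentationMasks",
    "compute_voxel_features",
    "train_voxel_classifier",
    "predict_clone_mask",
    "compute_tissue_mask",
    "save_classifier",
    "load_classifier",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)

CLONE_LABEL = 1
NOT_CLONE_LABEL = 2
UNLABELLED = 0


@dataclass
class VoxelFeatureSet:
    """Per-voxel feature volumes of shape (F, Z, Y, X) with stable ordering."""

    features: np.ndarray
    feature_names: list[str]
    channel: str
    scales_um: tuple[float, ...]
    voxel_size_um: tuple[float, float, float]

    def matrix(self) -> np.ndarray:
        """Features flattened to an (n_voxels, F) design matrix (C order)."""
        f = self.features
        return f.reshape(f.shape[0], -1).T

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return self.features.shape[1:]


def _sigma_vox(scale_um: float, voxel: tuple[float, float, float]) -> tuple[float, ...]:
    return tuple(scale_um / v for v in voxel)


def compute_voxel_features(
    stack: ImageStack, channel: str = "GFP", scales_um: tuple[float, ...] = (1.0, 2.5)
) -> VoxelFeatureSet:
    """Feature bank for one channel: raw + (smooth, |grad|, Laplacian) per scale.

    Smoothing sigmas are ``scale_um / voxel_size_um[axis]`` per axis, so a
    given physical scale behaves identically on anisotropic grids.
    """
    if any(s <= 0 for s in scales_um):
        raise ValueError("all feature scales must be > 0 um")
    img = stack.channel(channel).astype(np.float32)
    voxel = stack.voxel_size_um
    feats: list[np.ndarray] = [img]
    names = ["raw"]
    for s in scales_um:
        sig = _sigma_vox(s, voxel)
        feats.append(ndimage.gaussian_filter(img, sig))
        names.append(f"gauss_{s:g}um")
        # derivatives per um, not per voxel, so anisotropic grids behave alike
        grad2 = np.zeros_like(img)
        lap = np.zeros_like(img)
        for ax in range(3):
            order = [0, 0, 0]
            order[ax] = 1
            grad2 += (ndimage.gaussian_filter(img, sig, order=order) / voxel[ax]) ** 2
            order[ax] = 2
            lap += ndimage.gaussian_filter(img, sig, order=order) / voxel[ax] ** 2
        feats.append(np.sqrt(grad2))
        names.append(f"gradmag_{s:g}um")
        feats.append(lap)
        names.append(f"laplace_{s:g}um")
    return VoxelFeatureSet(
        features=np.stack(feats).astype(np.float32),
        feature_names=names,
        channel=channel,
        scales_um=tuple(float(s) for s in scales_um),
        voxel_size_um=stack.voxel_size_um,
    )


@dataclass
class VoxelClassifier:
    """A trained clone/not-clone voxel classifier plus its training metadata."""

    model: RandomForestClassifier
    feature_names: list[str]
    channel: str
    scales_um: tuple[float, ...]
    n_training_stacks: int
    n_labelled_voxels: int
    seed: int
    holdout_accuracy: float

    def predict_probability(self, features: VoxelFeatureSet) -> np.ndarray:
        """Per-voxel probability of class 'clone' as a (Z, Y, X) volume."""
        x = features.matrix()
        if x.shape[1] != self.model.n_features_in_:
            raise ValueError(
                f"feature dimensionality mismatch: classifier expects "
                f"{self.model.n_features_in_} features, got {x.shape[1]}"
            )
        clone_col = list(self.model.classes_).index(CLONE_LABEL)
        prob = self.model.predict_proba(x)[:, clone_col]
        return prob.reshape(features.volume_shape)


def train_voxel_classifier(
    training: list[tuple[VoxelFeatureSet, np.ndarray]],
    seed: int = 0,
    max_voxels_per_class: int = 50_000,
    holdout_fraction: float = 0.25,
    n_estimators: int = 60,
) -> VoxelClassifier:
    """Train the clone classifier on labelled voxels from >= 1 discs.

    Label volumes use 0 = unlabelled, 1 = clone, 2 = not-clone; only
    labelled voxels enter training. Each class is subsampled (seeded) to at
    most ``max_voxels_per_class`` voxels, a stratified fraction is held out,
    and the held-out accuracy is stored on the returned classifier.
    """
    if not training:
        raise ValueError("need at least one training disc")
    ref = training[0][0]
    xs, ys = [], []
    for fs, labels in training:
        if fs.feature_names != ref.feature_names:
            raise ValueError("all training feature sets must share the same feature bank")
        labels = np.asarray(labels)
        if labels.shape != fs.volume_shape:
            raise ValueError("label volume shape does not match the feature volume")
        sel = labels != UNLABELLED
        xs.append(fs.matrix()[sel.ravel()])
        ys.append(labels[sel])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    classes = np.unique(y)
    if not (CLONE_LABEL in classes and NOT_CLONE_LABEL in classes):
        raise ValueError("training labels must contain both 'clone' and 'not-clone' voxels")

    rng = np.random.default_rng(seed)
    keep = []
    for c in (CLONE_LABEL, NOT_CLONE_LABEL):
        idx = np.flatnonzero(y == c)
        if idx.size > max_voxels_per_class:
            idx = rng.choice(idx, size=max_voxels_per_class, replace=False)
        keep.append(idx)
    keep = np.concatenate(keep)
    x, y = x[keep], y[keep]

    x_tr, x_ho, y_tr, y_ho = train_test_split(
        x, y, test_size=holdout_fraction, random_state=seed, stratify=y
    )
    model = RandomForestClassifier(
        n_estimators=n_estimators,
        min_samples_leaf=2,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(x_tr, y_tr)
    acc = float((model.predict(x_ho) == y_ho).mean())
    return VoxelClassifier(
        model=model,
        feature_names=list(ref.feature_names),
        channel=ref.channel,
        scales_um=ref.scales_um,
        n_training_stacks=len(training),
        n_labelled_voxels=int(y.size),
        seed=seed,
        holdout_accuracy=acc,
    )


@dataclass
class SegmentationMasks:
    tissue_mask: np.ndarray
    clone_mask: np.ndarray
    clone_probability: np.ndarray


def _remove_small(mask: np.ndarray, min_size_um3: float, voxel_volume_um3: float) -> np.ndarray:
    """Drop 26-connected components with physical volume < min_size_um3."""
    if min_size_um3 <= 0 or not mask.any():
        return mask
    labels, n = ndimage.label(mask, structure=_CONN26)
    if n == 0:
        return mask
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts * voxel_volume_um3 < min_size_um3)
    small = small[small != 0]
    if small.size:
        mask = mask & ~np.isin(labels, small)
    return mask


def compute_tissue_mask(
    stack: ImageStack,
    dapi_channel: str = "DAPI",
    smooth_um: float = 0.8,
    min_component_um3: float = 100.0,
) -> np.ndarray:
    """DAPI-defined tissue support: Otsu on smoothed DAPI + hole fill.

    All connected components above the ``min_component_um3`` size floor are
    kept, so multi-lobed discs survive intact. A constant DAPI channel has
    no defined threshold and raises.
    """
    img = stack.channel(dapi_channel).astype(np.float32)
    if float(img.max() - img.min()) == 0.0:
        raise ValueError(f"channel {dapi_channel!r} is constant; Otsu threshold undefined")
    smoothed = ndimage.gaussian_filter(img, _sigma_vox(smooth_um, stack.voxel_size_um))
    mask = smoothed > threshold_otsu(smoothed)
    mask = ndimage.binary_fill_holes(mask)
    return _remove_small(mask, min_component_um3, stack.voxel_volume_um3)


def predict_clone_mask(
    stack: ImageStack,
    clf: VoxelClassifier,
    threshold: float = 0.5,
    min_size_um3: float = 50.0,
    dapi_channel: str = "DAPI",
    tissue_mask: np.ndarray | None = None,
) -> SegmentationMasks:
    """Apply a trained classifier to one stack.

    clone_mask = (P(clone) >= threshold) inside the tissue mask, with
    26-connected objects smaller than ``min_size_um3`` removed. The raw
    probability volume is retained for auditing.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    if min_size_um3 < 0:
        raise ValueError("min_size_um3 must be >= 0")
    if tissue_mask is None:
        tissue_mask = compute_tissue_mask(stack, dapi_channel=dapi_channel)
    feats = compute_voxel_features(stack, channel=clf.channel, scales_um=clf.scales_um)
    prob = clf.predict_probability(feats)
    clone = (prob >= threshold) & tissue_mask
    clone = _remove_small(clone, min_size_um3, stack.voxel_volume_um3)
    return SegmentationMasks(
        tissue_mask=tissue_mask, clone_mask=clone, clone_probability=prob
    )


BUNDLE_VERSION = 1


def save_classifier(clf: VoxelClassifier, path: str | Path) -> Path:
    """Serialize a classifier to a bundle directory with a JSON manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    joblib.dump(clf.model, path / "model.joblib")
    manifest = {
        "bundle_version": BUNDLE_VERSION,
        "feature_names": clf.feature_names,
        "channel": clf.channel,
        "scales_um": list(clf.scales_um),
        "n_training_stacks": clf.n_training_stacks,
        "n_labelled_voxels": clf.n_labelled_voxels,
        "seed": clf.seed,
        "holdout_accuracy": clf.holdout_accuracy,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return path


def load_classifier(path: str | Path) -> VoxelClassifier:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest.get("bundle_version") != BUNDLE_VERSION:
        warnings.warn(
            f"classifier bundle version {manifest.get('bundle_version')} != {BUNDLE_VERSION}"
        )
    model = joblib.load(path / "model.joblib")
    return VoxelClassifier(
        model=model,
        feature_names=manifest["feature_names"],
        channel=manifest["channel"],
        scales_um=tuple(manifest["scales_um"]),
        n_training_stacks=manifest["n_training_stacks"],
        n_labelled_voxels=manifest["n_labelled_voxels"],
        seed=manifest["seed"],
        holdout_accuracy=manifest["holdout_accuracy"],
    )
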