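"""Bouton identification and removal with a trainable voxel classifier.

Boutons — swellings along or at the tip of an axon — are locally blob-like
and brighter than the shaft. Left in place they thicken the binary mask and
inflate the skeletonized length, so the first pipeline stage classifies
every voxel as bouton / axon / background from a hand-crafted multi-scale
feature stack (raw intensity, Hessian eigenvalues, derivatives, Laplacian,
difference of Gaussians, neighbourhood mean and variance) with a random
forest, then zeroes the bouton voxels by mask multiplication.

Training labels never need manual annotation here: they are derived from
the synthetic ground truth (:func:`labels_from_truth`), which knows exactly
which voxels belong to bouton spheres, axon shafts, or background.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from sklearn.ensemble import RandomForestClassifier

from .simulate import GroundTruth, _sample_polyline
from .stack import VolumeStack

__all__ = [
    "BACKGROUND",
    "AXON",
    "BOUTON",
    "FeatureStack",
    "BoutonClassifier",
    "compute_feature_stack",
    "default_scales_um",
    "train_bouton_classifier",
    "segment_boutons",
    "remove_boutons",
    "labels_from_truth",
]

# voxel label classes; 0 is reserved for "unlabelled"
BACKGROUND, AXON, BOUTON = 1, 2, 3

_N_FIXED_FEATURES = 7  # raw, smoothed, |grad|, Laplacian, DoG, nbh mean, nbh var


@dataclass
class FeatureStack:
    """Per-voxel feature vectors for voxel classification.

    ``features`` has shape ``(n_features, *stack_shape)``;
    ``n_features == 7 + 3 * len(scales_um)`` (seven single-scale features
    plus the three sorted Hessian eigenvalues at every scale).
    """

    features: np.ndarray
    names: list[str]
    scales_um: list[float]
    voxel_size_um: float

    @property
    def n_features(self) -> int:
        return self.features.shape[0]


def default_scales_um(voxel_size_um: float) -> list[float]:
    """Multi-scale analysis at 1, 2 and 4 voxel widths."""
    return [voxel_size_um, 2 * voxel_size_um, 4 * voxel_size_um]


def compute_feature_stack(stack: VolumeStack, scales_um: list[float] | None = None) -> FeatureStack:
    """Deterministic per-voxel features with mirrored boundary handling.

    Seven base features at the smallest scale (raw intensity, Gaussian
    smoothing, gradient magnitude, Laplacian of Gaussian, difference of
    Gaussians between the smallest scale and twice it, and the mean and
    variance of the 3x3x3 neighbourhood) plus the three Hessian eigenvalues
    (sorted ascending) at every requested scale.
    """
    if scales_um is None:
        scales_um = default_scales_um(stack.voxel_size_um)
    if not scales_um:
        raise ValueError("scales_um must be non-empty")
    vs = stack.voxel_size_um
    for s in scales_um:
        if s < vs:
            raise ValueError(f"scale {s} um below voxel size {vs} um")
    largest = max(scales_um) / vs
    kernel_radius = int(np.ceil(4 * largest))
    if min(stack.shape) < 2 * kernel_radius + 1:
        raise ValueError(
            f"stack shape {stack.shape} smaller than twice the smoothing kernel "
            f"for scale {max(scales_um)} um ({kernel_radius} voxel radius)"
        )
    img = stack.astype_float()
    s0 = min(scales_um) / vs

    feats: list[np.ndarray] = []
    names: list[str] = []

    smoothed = ndimage.gaussian_filter(img, s0, mode="mirror")
    grad = np.stack(
        [ndimage.gaussian_filter(img, s0, order=tuple(int(a == i) for i in range(3)),
                                 mode="mirror") for a in range(3)]
    )
    feats += [img, smoothed, np.sqrt(np.sum(grad**2, axis=0))]
    names += ["raw", "gaussian", "gradient_magnitude"]

    feats.append(ndimage.gaussian_laplace(img, s0, mode="mirror"))
    names.append("laplacian")

    feats.append(smoothed - ndimage.gaussian_filter(img, 2 * s0, mode="mirror"))
    names.append("dog")

    mean = ndimage.uniform_filter(img, size=3, mode="mirror")
    sqmean = ndimage.uniform_filter(img**2, size=3, mode="mirror")
    var = np.maximum(sqmean - mean**2, 0.0)
    feats += [mean, var]
    names += ["neighborhood_mean", "neighborhood_variance"]

    for s in scales_um:
        H = hessian_matrix(img, sigma=s / vs, mode="mirror", order="rc",
                           use_gaussian_derivatives=True)
        eig = hessian_matrix_eigvals(H)  # descending
        for k in range(3):
            feats.append(eig[2 - k])  # re-order ascending
            names.append(f"hessian_eig{k}_s{s:g}")

    features = np.stack(feats)
    assert features.shape[0] == _N_FIXED_FEATURES + 3 * len(scales_um)
    return FeatureStack(features, names, list(scales_um), vs)


@dataclass
class BoutonClassifier:
    """A trained voxel classifier plus the feature configuration it expects."""

    model: RandomForestClassifier
    scales_um: list[float]
    voxel_size_um: float
    seed: int

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "BoutonClassifier":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, cls):
            raise ValueError(f"{path} does not contain a BoutonClassifier")
        return obj


def train_bouton_classifier(
    features: FeatureStack,
    labels: np.ndarray,
    n_estimators: int = 100,
    seed: int = 0,
    **rf_kwargs,
) -> BoutonClassifier:
    """Fit a random forest on sparsely labelled voxels.

    ``labels`` is an integer volume matching the stack shape: 0 means
    unlabelled (ignored); BACKGROUND / AXON / BOUTON mark training voxels.
    At least two classes must be present. Training is reproducible given
    ``seed``.
    """
    labels = np.asarray(labels)
    if labels.shape != features.features.shape[1:]:
        raise ValueError("labels shape must match the feature stack")
    sel = labels > 0
    if not sel.any():
        raise ValueError("no labelled voxels")
    y = labels[sel]
    if np.unique(y).size < 2:
        raise ValueError("need at least two label classes to train")
    X = features.features[:, sel].T
    model = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1, **rf_kwargs
    )
    model.fit(X, y)
    return BoutonClassifier(model, features.scales_um, features.voxel_size_um, seed)


def segment_boutons(stack: VolumeStack, clf: BoutonClassifier) -> np.ndarray:
    """Classify every voxel and return the bouton mask (0 = bouton, 1 = keep)."""
    if abs(clf.voxel_size_um - stack.voxel_size_um) > 1e-9:
        raise ValueError(
            f"classifier trained at {clf.voxel_size_um} um voxels, "
            f"stack has {stack.voxel_size_um} um: feature configuration mismatch"
        )
    features = compute_feature_stack(stack, clf.scales_um)
    X = features.features.reshape(features.n_features, -1).T
    pred = clf.model.predict(X).reshape(stack.shape)
    return (pred != BOUTON).astype(np.uint8)


def remove_boutons(stack: VolumeStack, mask: np.ndarray) -> VolumeStack:
    """Zero the bouton voxels: output = input * mask, voxel size preserved."""
    mask = np.asarray(mask)
    if mask.shape != stack.shape:
        raise ValueError(f"mask shape {mask.shape} != stack shape {stack.shape}")
    if not np.all(np.isin(np.unique(mask), (0, 1))):
        raise ValueError("mask must be binary with convention 0 = bouton, 1 = keep")
    return VolumeStack(
        stack.voxels * mask.astype(stack.voxels.dtype),
        stack.voxel_size_um,
        stack.channel_name,
    )


def labels_from_truth(
    stack: VolumeStack,
    truth: GroundTruth,
    axon_radius_um: float,
    background_margin_um: float | None = None,
    background_fraction: float = 0.02,
    seed: int = 0,
) -> np.ndarray:
    """Sparse training labels derived from synthetic ground truth.

    Voxels inside a bouton sphere are labelled BOUTON; voxels within the
    axon radius of a centerline (and outside all boutons) AXON; a random
    subsample of voxels far from both is BACKGROUND. Unlabelled voxels stay 0.
    """
    vs = stack.voxel_size_um
    shape = stack.shape
    zz, yy, xx = np.meshgrid(*(np.arange(s) * vs for s in shape), indexing="ij")
    pts = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])
    labels = np.zeros(shape, dtype=np.int8).ravel()

    if background_margin_um is None:
        background_margin_um = 3 * axon_radius_um

    d_axon = np.full(pts.shape[0], np.inf)
    if truth.centerlines:
        dense = np.concatenate(
            [_sample_polyline(np.asarray(c), spacing_um=vs / 3) for c in truth.centerlines]
        )
        d_axon, _ = cKDTree(dense).query(pts, workers=-1)

    d_bouton = np.full(pts.shape[0], np.inf)
    radius_b = 0.0
    if truth.boutons:
        centers = np.array([c for c, _ in truth.boutons])
        radius_b = max(r for _, r in truth.boutons)
        d_bouton, _ = cKDTree(centers).query(pts, workers=-1)

    in_bouton = d_bouton <= radius_b
    on_axon = (d_axon <= axon_radius_um) & ~in_bouton
    far = (d_axon > background_margin_um) & (d_bouton > radius_b + background_margin_um)

    labels[in_bouton] = BOUTON
    labels[on_axon] = AXON
    rng = np.random.default_rng(seed)
    far_idx = np.flatnonzero(far)
    n_bg = max(int(background_fraction * far_idx.size), 1)
    labels[rng.choice(far_idx, size=min(n_bg, far_idx.size), replace=False)] = BACKGROUND
    return labels.reshape(shape)
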