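"""Phase 2: SVM on membership vectors, plus baseline and weight localization.

The phase-1 membership vector (one probability per cell position) is the
subject-level feature for a support vector machine. With a linear kernel the
fitted primal weight vector w assigns one weight per cell position; the
magnitudes |w_p| indicate where the two classes differ most, and painting
them back over each cell's voxel footprint yields a discriminant map in the
cohort's native voxel space.

The baseline method skips phase 1 entirely and feeds the raw concatenation
of all cell histograms (P*N numbers) to the same SVM — the classical
whole-image HOG representation the two-phase transform is compared against.
"""

from __future__ import annotations

import dataclasses
import pickle
from pathlib import Path
from typing import Literal, Sequence

import nibabel as nib
import numpy as np
from sklearn.svm import SVC

from ._utils import config_hash
from .fuzzy import FcmConfig, FuzzyPhaseModel, MembershipVector, fit_phase1, transform
from .hog import HogConfig, SubjectDescriptorSet


@dataclasses.dataclass(frozen=True)
class SvmConfig:
    kernel: Literal["linear", "rbf"] = "linear"
    C: float = 1.0
    gamma: float | str = "scale"
    class_weight: Literal["none", "balanced"] = "balanced"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")

    @property
    def hash(self) -> str:
        return config_hash(self)


@dataclasses.dataclass
class TrainedModel:
    """Fitted two-phase (or baseline) classifier with its geometry.

    ``weights``/``bias`` are materialized for the linear kernel only; the
    geometry fields allow weights to be painted back into voxel space.
    """

    svm: SVC
    svm_config: SvmConfig
    feature_mode: Literal["twophase", "baseline_concat"]
    phase1: FuzzyPhaseModel | None
    transform_mode: Literal["soft", "hard"]
    grid: tuple[int, int, int]
    hog_config: HogConfig
    volume_shape: tuple[int, int, int]

    @property
    def weights(self) -> np.ndarray:
        if self.svm_config.kernel != "linear":
            raise ValueError("primal weights exist only for the linear kernel")
        return np.asarray(self.svm.coef_).ravel()

    @property
    def bias(self) -> float:
        if self.svm_config.kernel != "linear":
            raise ValueError("primal bias exists only for the linear kernel")
        return float(self.svm.intercept_[0])


@dataclasses.dataclass(frozen=True)
class DiscriminantMap:
    """Voxel-space rendering of |w_p| for the retained cell positions."""

    data: np.ndarray
    kept_positions: np.ndarray
    threshold: float


def _as_matrix(vectors: Sequence[MembershipVector] | np.ndarray) -> np.ndarray:
    if isinstance(vectors, np.ndarray):
        return np.asarray(vectors, dtype=np.float64)
    return np.stack([np.asarray(v.values, dtype=np.float64) for v in vectors])


def _fit_svm(features: np.ndarray, labels: np.ndarray, config: SvmConfig) -> SVC:
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("training requires subjects from both classes")
    if not set(classes) <= {0, 1}:
        raise ValueError(f"labels must be binary 0/1, got {classes}")
    svm = SVC(
        kernel=config.kernel,
        C=config.C,
        gamma=config.gamma,
        class_weight=None if config.class_weight == "none" else "balanced",
        random_state=config.seed,
    )
    svm.fit(features, labels)
    return svm


def train(
    vectors: Sequence[MembershipVector] | np.ndarray,
    labels: Sequence[int],
    config: SvmConfig,
    *,
    phase1: FuzzyPhaseModel | None = None,
    feature_mode: Literal["twophase", "baseline_concat"] = "twophase",
    transform_mode: Literal["soft", "hard"] = "soft",
    grid: tuple[int, int, int] | None = None,
    hog_config: HogConfig | None = None,
    volume_shape: tuple[int, int, int] | None = None,
) -> TrainedModel:
    """Fit the phase-2 SVM on per-subject feature vectors.

    ``vectors`` may be phase-1 :class:`MembershipVector` objects or a plain
    (n_subjects, n_features) matrix (the baseline path). Geometry defaults
    are taken from ``phase1`` when available.
    """
    features = _as_matrix(vectors)
    svm = _fit_svm(features, np.asarray(labels), config)
    if phase1 is not None:
        grid = grid or phase1.grid
    if grid is None or hog_config is None or volume_shape is None:
        raise ValueError("grid, hog_config and volume_shape are required")
    return TrainedModel(
        svm=svm,
        svm_config=config,
        feature_mode=feature_mode,
        phase1=phase1,
        transform_mode=transform_mode,
        grid=grid,
        hog_config=hog_config,
        volume_shape=volume_shape,
    )


def fit_two_phase(
    train_subjects: Sequence[SubjectDescriptorSet],
    labels: Sequence[int],
    fcm_config: FcmConfig,
    svm_config: SvmConfig,
    *,
    feature_mode: Literal["twophase", "baseline_concat"] = "twophase",
    transform_mode: Literal["soft", "hard"] = "soft",
) -> TrainedModel:
    """End-to-end fit from descriptor sets: phase 1 (if used) then the SVM."""
    geometry = dict(
        grid=train_subjects[0].grid,
        hog_config=train_subjects[0].config,
        volume_shape=train_subjects[0].volume_shape,
    )
    if feature_mode == "twophase":
        phase1 = fit_phase1(train_subjects, fcm_config)
        vectors = [transform(phase1, s, mode=transform_mode) for s in train_subjects]
        return train(
            vectors, labels, svm_config, phase1=phase1,
            feature_mode="twophase", transform_mode=transform_mode, **geometry,
        )
    features = np.stack([baseline_features(s) for s in train_subjects])
    return train(
        features, labels, svm_config, phase1=None,
        feature_mode="baseline_concat", transform_mode=transform_mode, **geometry,
    )


def _subject_features(model: TrainedModel, subject: SubjectDescriptorSet) -> np.ndarray:
    if subject.grid != model.grid:
        raise ValueError(
            f"subject {subject.subject_id!r}: grid {subject.grid} does not "
            f"match model grid {model.grid}"
        )
    if subject.config_hash != model.hog_config.hash:
        raise ValueError(
            f"subject {subject.subject_id!r}: HOG config hash mismatch with model"
        )
    if model.feature_mode == "twophase":
        return transform(model.phase1, subject, mode=model.transform_mode).values
    return baseline_features(subject)


def decision_score(model: TrainedModel, subject: SubjectDescriptorSet) -> float:
    """Signed SVM decision value for one subject (positive favors class 1)."""
    features = _subject_features(model, subject)
    return float(model.svm.decision_function(features[None])[0])


def predict(model: TrainedModel, subject: SubjectDescriptorSet) -> tuple[int, float]:
    """Predict a subject's class; returns (label, signed decision score).

    A score of exactly zero is assigned to the positive class (label 1) by
    convention.
    """
    score = decision_score(model, subject)
    return (1 if score >= 0 else 0), score


def baseline_features(subject: SubjectDescriptorSet) -> np.ndarray:
    """Direct concatenation of all cell histograms in canonical order (P*N)."""
    return subject.histograms.ravel().copy()


def discriminant_map(
    model: TrainedModel,
    threshold: float | None = None,
    top_k: int | None = None,
) -> DiscriminantMap:
    """Paint |w_p| of the retained positions over their voxel footprints.

    Exactly one of ``threshold`` (keep positions with |w_p| >= threshold) or
    ``top_k`` (keep the k largest |w_p|) must be given. Requires the linear
    kernel (the rbf kernel has no primal weight vector) and the two-phase
    feature mode, whose weights are one per cell position.
    """
    if (threshold is None) == (top_k is None):
        raise ValueError("give exactly one of threshold or top_k")
    if model.feature_mode != "twophase":
        raise ValueError("discriminant maps require the two-phase feature mode")
    w = np.abs(model.weights)
    if top_k is not None:
        if not 1 <= top_k <= w.size:
            raise ValueError(f"top_k must be in [1, {w.size}]")
        kept = np.sort(np.argsort(-w, kind="stable")[:top_k])
        effective_threshold = float(w[kept].min())
    else:
        kept = np.flatnonzero(w >= threshold)
        effective_threshold = float(threshold)

    data = np.zeros(model.volume_shape, dtype=np.float64)
    c = model.hog_config.cell_size
    axis = model.hog_config.slice_axis
    plane_axes = [i for i in range(3) if i != axis]
    for p in kept:
        s, r, q = np.unravel_index(p, model.grid)
        index: list[slice | int] = [slice(None)] * 3
        index[axis] = int(s)
        index[plane_axes[0]] = slice(r * c, (r + 1) * c)
        index[plane_axes[1]] = slice(q * c, (q + 1) * c)
        data[tuple(index)] = w[p]
    return DiscriminantMap(
        data=data, kept_positions=np.asarray(kept), threshold=effective_threshold
    )


def write_map(dmap: DiscriminantMap, path: str | Path, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(dmap.data, affine), str(path))


def save_trained(model: TrainedModel, path: str | Path) -> None:
    """Serialize a trained model (phase-1 arrays + pickled SVM) to one file."""
    with open(path, "wb") as fh:
        pickle.dump({"format": "gliograd-model-v1", "model": model}, fh)


def load_trained(path: str | Path) -> TrainedModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format") != "gliograd-model-v1":
        raise ValueError(f"not a trained-model archive: {path}")
    return payload["model"]
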