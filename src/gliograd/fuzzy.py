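"""Phase 1: per-position fuzzy C-means over subjects' cell descriptors.

At every cell position of the aligned grid, the descriptors of the training
subjects form a small point cloud in N-dimensional orientation-histogram
space. Fuzzy C-means (FCM) with K clusters (default K=2) partitions that
cloud softly: each subject receives a membership in [0, 1] for each cluster,
summing to one. The membership of a designated cluster becomes the subject's
single scalar feature at that position, so a subject's whole volume collapses
from P*N histogram numbers to P membership probabilities.

FCM minimizes J = sum_i sum_k u_ik^m ||x_i - v_k||^2 subject to row-stochastic
memberships, by alternating the centroid update
    v_k = sum_i u_ik^m x_i / sum_i u_ik^m
and the membership update
    u_ik = 1 / sum_j (d_ik / d_jk)^(2/(m-1)),
with Euclidean d and fuzzifier m > 1. A point coinciding with a centroid gets
full membership there. The objective is non-increasing across iterations.

Cluster identity is arbitrary in unsupervised clustering, so a deterministic
convention fixes which cluster's membership is "the" feature: clusters are
ordered by descending centroid Euclidean norm. Any stable convention works —
the downstream linear SVM learns the sign per position — it must only agree
between training and prediction.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from ._utils import config_hash, derive_seed
from .hog import SubjectDescriptorSet

_FORMAT_TAG = "gliograd-fcm-v1"
#: squared-distance floor below which a point is deemed coincident with a centroid
_D2_EPS = 1e-24
#: point-cloud spread below which a position is degenerate (single effective cluster)
_SPREAD_EPS = 1e-12


@dataclasses.dataclass(frozen=True)
class FcmConfig:
    K: int = 2
    fuzzifier: float = 2.0
    tol: float = 1e-5
    max_iter: int = 300
    n_init: int = 3
    seed: int = 0
    scope: Literal["per_position", "global"] = "per_position"

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.fuzzifier <= 1.0:
            raise ValueError("fuzzifier must be > 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.scope not in ("per_position", "global"):
            raise ValueError(f"unknown scope {self.scope!r}")

    @property
    def hash(self) -> str:
        return config_hash(self)


@dataclasses.dataclass(frozen=True)
class FcmResult:
    """Outcome of one FCM fit on a single point cloud."""

    centroids: np.ndarray  # (K, N)
    memberships: np.ndarray  # (n, K), row-stochastic
    objective: float
    objective_history: tuple[float, ...]
    n_iter: int
    degenerate: bool


@dataclasses.dataclass(frozen=True)
class FuzzyPhaseModel:
    """Frozen phase-1 model: per-position centroids plus ordering metadata.

    ``centroids[p]`` is the K x N centroid matrix at position p, rows already
    permuted so row 0 is the designated (largest-norm) cluster;
    ``reference_order[p]`` records the permutation applied to the raw fit.
    Degenerate positions (all training descriptors identical, or coincident
    centroids) are flagged and always emit membership 0.5.
    """

    centroids: np.ndarray  # (P, K, N)
    degenerate: np.ndarray  # (P,) bool
    reference_order: np.ndarray  # (P, K) int
    grid: tuple[int, int, int]
    fcm_config: FcmConfig
    hog_config_hash: str

    @property
    def n_positions(self) -> int:
        return int(self.centroids.shape[0])


@dataclasses.dataclass(frozen=True)
class MembershipVector:
    """One subject's P membership probabilities, in canonical cell order."""

    values: np.ndarray
    subject_id: str

    def __post_init__(self) -> None:
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError(f"{self.subject_id}: memberships outside [0, 1]")


def _membership_from_d2(d2: np.ndarray, fuzzifier: float) -> np.ndarray:
    """Membership update from squared distances; last axis indexes clusters."""
    coincident = d2 < _D2_EPS
    with np.errstate(divide="ignore"):
        inv = d2 ** (-1.0 / (fuzzifier - 1.0))
    # coincident points: full membership split over the coinciding centroids
    any_co = coincident.any(axis=-1, keepdims=True)
    inv = np.where(any_co, coincident.astype(np.float64), inv)
    return inv / inv.sum(axis=-1, keepdims=True)


def _fcm_iterate(
    points: np.ndarray, u0: np.ndarray, config: FcmConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float], int]:
    """Run FCM to convergence on a batch of point clouds.

    points: (B, n, N); u0: (B, n, K). Returns (centroids (B, K, N),
    memberships (B, n, K), objective (B,), history of summed objective, iters).
    Convergence requires max |delta u| < tol across the whole batch.
    """
    m = config.fuzzifier
    B, n, _ = points.shape
    K = u0.shape[-1]
    u = u0.copy()
    centroids = np.zeros((B, K, points.shape[-1]))
    d2_all = np.zeros((B, n, K))
    active = np.arange(B)  # batch elements not yet converged
    history: list[float] = []
    it = 0
    for it in range(1, config.max_iter + 1):
        x = points[active]
        ua = u[active]
        um = ua**m
        weight = um.sum(axis=1)  # (b, K)
        cents = np.einsum("bnk,bnd->bkd", um, x) / np.maximum(
            weight[:, :, None], 1e-300
        )
        diff = x[:, :, None, :] - cents[:, None, :, :]
        d2 = np.einsum("bnkd,bnkd->bnk", diff, diff)
        u_new = _membership_from_d2(d2, m)
        centroids[active] = cents
        d2_all[active] = d2
        u[active] = u_new
        history.append(float(np.sum(u**m * d2_all)))
        delta = np.max(np.abs(u_new - ua), axis=(1, 2))
        active = active[delta >= config.tol]
        if active.size == 0:
            break
    objective = np.sum(u**m * d2_all, axis=(1, 2))
    return centroids, u, objective, history, it


def _init_memberships(
    rng: np.random.Generator, batch: int, n: int, k: int
) -> np.ndarray:
    u0 = rng.uniform(size=(batch, n, k))
    return u0 / u0.sum(axis=-1, keepdims=True)


def fcm_fit(points: Sequence | np.ndarray, config: FcmConfig) -> FcmResult:
    """Fuzzy C-means on one point cloud, best of ``n_init`` seeded restarts."""
    x = np.asarray(points, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError(f"points must be a 2D (n, N) array, got shape {x.shape}")
    n = x.shape[0]
    if n < config.K:
        raise ValueError(f"need at least K={config.K} points, got {n}")
    degenerate = bool(np.ptp(x, axis=0).max() < _SPREAD_EPS)

    best: FcmResult | None = None
    for init in range(config.n_init):
        rng = np.random.default_rng(derive_seed(config.seed, init))
        u0 = _init_memberships(rng, 1, n, config.K)
        centroids, u, objective, history, n_iter = _fcm_iterate(
            x[None], u0, config
        )
        result = FcmResult(
            centroids=centroids[0],
            memberships=u[0],
            objective=float(objective[0]),
            objective_history=tuple(history),
            n_iter=n_iter,
            degenerate=degenerate,
        )
        if best is None or result.objective < best.objective:
            best = result
    return best


def _order_clusters(centroids: np.ndarray) -> np.ndarray:
    """Permutation ordering clusters by descending centroid norm (stable)."""
    norms = np.linalg.norm(centroids, axis=-1)  # (P, K)
    return np.argsort(-norms, axis=-1, kind="stable")


def fit_phase1(
    train: Sequence[SubjectDescriptorSet], config: FcmConfig
) -> FuzzyPhaseModel:
    """Fit the per-position (or pooled global) FCM over training subjects.

    ``per_position`` scope runs one FCM per cell position, each over one
    descriptor per training subject; all positions are iterated as a single
    batched computation. ``global`` scope pools every position of every
    subject into one cloud and shares the resulting centroids across
    positions.
    """
    if len(train) < config.K:
        raise ValueError(f"need at least K={config.K} training subjects")
    grid = train[0].grid
    hog_hash = train[0].config_hash
    for s in train[1:]:
        if s.grid != grid or s.config_hash != hog_hash:
            raise ValueError(
                f"subject {s.subject_id!r}: descriptor grid/config does not "
                "match the rest of the training set"
            )
    stack = np.stack([s.histograms for s in train])  # (n_subj, P, N)
    n_subj, P, N = stack.shape

    if config.scope == "global":
        pooled = stack.reshape(n_subj * P, N)
        res = fcm_fit(pooled, config)
        centroids = np.broadcast_to(res.centroids, (P, config.K, N)).copy()
        degenerate = np.full(P, res.degenerate)
    else:
        points = stack.transpose(1, 0, 2)  # (P, n_subj, N)
        degenerate = np.ptp(points, axis=1).max(axis=-1) < _SPREAD_EPS
        best_obj = np.full(P, np.inf)
        centroids = np.zeros((P, config.K, N))
        for init in range(config.n_init):
            rng = np.random.default_rng(derive_seed(config.seed, init))
            u0 = _init_memberships(rng, P, n_subj, config.K)
            cents, _, obj, _, _ = _fcm_iterate(points, u0, config)
            better = obj < best_obj
            best_obj = np.where(better, obj, best_obj)
            centroids[better] = cents[better]

    # positions whose fitted centroids coincide carry no contrast either
    if config.K == 2:
        sep = np.linalg.norm(centroids[:, 0] - centroids[:, 1], axis=-1)
        degenerate = degenerate | (sep < 1e-9)
    order = _order_clusters(centroids)
    centroids = np.take_along_axis(centroids, order[:, :, None], axis=1)
    return FuzzyPhaseModel(
        centroids=centroids,
        degenerate=np.asarray(degenerate, dtype=bool),
        reference_order=order,
        grid=grid,
        fcm_config=config,
        hog_config_hash=hog_hash,
    )


def transform(
    model: FuzzyPhaseModel,
    subject: SubjectDescriptorSet,
    mode: Literal["soft", "hard"] = "soft",
) -> MembershipVector:
    """Score a subject's descriptors against the frozen per-position centroids.

    ``soft`` evaluates the FCM membership formula (continuous probability of
    the designated cluster); ``hard`` is literal nearest-centroid assignment
    (0/1, ties to the designated cluster). Degenerate positions emit 0.5.
    """
    if subject.grid != model.grid:
        raise ValueError(
            f"subject {subject.subject_id!r}: grid {subject.grid} does not "
            f"match model grid {model.grid}"
        )
    if subject.config_hash != model.hog_config_hash:
        raise ValueError(
            f"subject {subject.subject_id!r}: HOG config hash mismatch with model"
        )
    x = subject.histograms  # (P, N)
    diff = x[:, None, :] - model.centroids  # (P, K, N)
    d2 = np.einsum("pkd,pkd->pk", diff, diff)
    if mode == "soft":
        u = _membership_from_d2(d2, model.fcm_config.fuzzifier)
        values = u[:, 0]
    elif mode == "hard":
        values = (np.argmin(d2, axis=1) == 0).astype(np.float64)
    else:
        raise ValueError(f"unknown transform mode {mode!r}")
    values = np.where(model.degenerate, 0.5, values)
    return MembershipVector(values=values, subject_id=subject.subject_id)


def save_model(model: FuzzyPhaseModel, path: str | Path) -> None:
    """Serialize the phase-1 model to a single ``.npz`` archive."""
    meta = {
        "format": _FORMAT_TAG,
        "grid": list(model.grid),
        "fcm_config": dataclasses.asdict(model.fcm_config),
        "hog_config_hash": model.hog_config_hash,
    }
    np.savez(
        path,
        centroids=model.centroids,
        degenerate=model.degenerate,
        reference_order=model.reference_order,
        meta=np.frombuffer(json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8),
    )


def load_model(path: str | Path) -> FuzzyPhaseModel:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["meta"]).decode())
        if meta.get("format") != _FORMAT_TAG:
            raise ValueError(f"not a phase-1 model archive: {path}")
        return FuzzyPhaseModel(
            centroids=archive["centroids"],
            degenerate=archive["degenerate"],
            reference_order=archive["reference_order"],
            grid=tuple(meta["grid"]),
            fcm_config=FcmConfig(**meta["fcm_config"]),
            hog_config_hash=meta["hog_config_hash"],
        )
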