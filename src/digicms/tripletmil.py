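"""Triplet-ranking multiple-instance learning for digital-CMS scoring.

Each patient is a bag of patch embeddings with a bag-level molecular-subtype
label (0 = C1, 1 = C2).  A small multi-layer perceptron maps each 1024-dim
patch embedding to a patch-level digital-CMS score in [0, 1] (sigmoid of the
patch logit); the patient-level score is the arithmetic mean of its patch
scores.  Training draws triplets of one C2 bag and two distinct C1 bags and
minimises a ranking loss

    L = [a1 - (x_p - x_n1)]_+ + [a1 - (x_p - x_n2)]_+ + [(x_n1 - x_n2)^2 - a2]_+

with inter-class margin ``a1`` (default 0.5) and intra-class bound ``a2``
(default 0.1), where ``x_p`` is the C2 bag score and ``x_n1``, ``x_n2`` the
two C1 bag scores.  The loss pushes C2 scores above every C1 score by at
least ``a1`` while keeping C1 scores within ``sqrt(a2)`` of each other.

Optimisation is plain SGD with momentum 0.9, weight decay 1e-4, learning rate
3e-3 decayed by 0.1 every 10 epochs, at most 20 epochs with early stopping on
the monitoring fold's loss.  The implementation is pure numpy: the network is
two dense layers, gradients are derived by hand, and every source of
randomness flows from one seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .cohort_io import FEATURE_DIM, CohortManifest, read_clinical_table, read_feature_store

__all__ = [
    "Bag",
    "TripletLossParams",
    "TrainSchedule",
    "TrainedScorer",
    "CVPlan",
    "build_bags",
    "bags_from_cohort",
    "score_patches",
    "bag_score",
    "aggregate_slide_score",
    "triplet_loss",
    "sample_triplets",
    "train",
    "run_cross_cohort",
]


@dataclass
class Bag:
    """One patient's bag: K patch embeddings, coords, optional subtype label."""

    patient_id: str
    features: np.ndarray  # (K, 1024) float32
    label: int | None = None  # 0 = C1, 1 = C2
    coords: np.ndarray | None = None  # (K, 4) x, y, w, h
    slide_ids: list[str] | None = None  # per-patch slide of origin

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float32)
        if self.features.ndim != 2 or self.features.shape[1] != FEATURE_DIM:
            raise ValueError(
                f"bag {self.patient_id!r}: features must be K x {FEATURE_DIM}, "
                f"got {self.features.shape}"
            )
        if self.features.shape[0] < 1:
            raise ValueError(f"bag {self.patient_id!r} is empty")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"bag {self.patient_id!r}: label must be 0 or 1")

    @property
    def n_patches(self) -> int:
        return int(self.features.shape[0])


@dataclass(frozen=True)
class TripletLossParams:
    """Margins of the ranking loss: inter-class ``alpha1``, intra-class ``alpha2``."""

    alpha1: float = 0.5
    alpha2: float = 0.1

    def __post_init__(self) -> None:
        if self.alpha1 <= 0:
            raise ValueError("alpha1 must be > 0")
        if self.alpha2 < 0:
            raise ValueError("alpha2 must be >= 0")


@dataclass(frozen=True)
class TrainSchedule:
    """SGD schedule; defaults follow the published training recipe."""

    epochs: int = 20
    learning_rate: float = 3e-3
    momentum: float = 0.9
    weight_decay: float = 1e-4
    lr_decay: float = 0.1
    lr_step: int = 10
    patience: int = 3
    hidden_dim: int = 512
    #: triplets drawn per epoch; None = one per labelled C2 bag in training
    triplets_per_epoch: int | None = None


@dataclass
class TrainedScorer:
    """Learned instance scorer: MLP 1024 -> hidden -> 1, sigmoid transform.

    ``W1`` is (1024, hidden), ``W2`` (hidden,); patch score = sigmoid(logit),
    so patch and patient scores live in [0, 1] and averaging a constant score
    returns that constant.
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: float
    training_log: list[dict] = field(default_factory=list)

    def patch_logits(self, features: np.ndarray) -> np.ndarray:
        f = np.asarray(features, dtype=np.float64)
        h = np.maximum(f @ self.W1 + self.b1, 0.0)
        return h @ self.W2 + self.b2

    def patch_scores(self, features: np.ndarray) -> np.ndarray:
        return _sigmoid(self.patch_logits(features))


def _sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=np.float64)))


def init_scorer(rng: np.random.Generator, hidden_dim: int = 512,
                in_dim: int = FEATURE_DIM) -> TrainedScorer:
    """He-initialised hidden layer, small-output head (initial scores near 0.5)."""
    W1 = rng.standard_normal((in_dim, hidden_dim)) * np.sqrt(2.0 / in_dim)
    W2 = rng.standard_normal(hidden_dim) * (0.1 / np.sqrt(hidden_dim))
    return TrainedScorer(W1=W1, b1=np.zeros(hidden_dim), W2=W2, b2=0.0)


# ---------------------------------------------------------------------------
# scoring and aggregation

def score_patches(scorer: TrainedScorer, bag: Bag) -> np.ndarray:
    """Patch-level digital-CMS scores in [0, 1], aligned with bag rows."""
    if bag.features.shape[1] != scorer.W1.shape[0]:
        raise ValueError(
            f"bag feature dim {bag.features.shape[1]} != scorer input dim {scorer.W1.shape[0]}"
        )
    return scorer.patch_scores(bag.features)


def aggregate_slide_score(patch_scores: Sequence[float] | np.ndarray) -> float:
    """Patient-level digital-CMS score: arithmetic mean of patch scores."""
    scores = np.asarray(patch_scores, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("cannot aggregate an empty patch-score vector")
    return float(scores.mean())


def bag_score(scorer: TrainedScorer, bag: Bag) -> float:
    return aggregate_slide_score(score_patches(scorer, bag))


# ---------------------------------------------------------------------------
# loss

def triplet_loss(x_p: float, x_n1: float, x_n2: float,
                 params: TripletLossParams = TripletLossParams()) -> float:
    """Ranking loss of one (C2, C1, C1) score triple.

    Zero exactly when both inter-class gaps reach ``alpha1`` and the squared
    C1-C1 gap is at most ``alpha2``.
    """
    if not (np.isfinite(x_p) and np.isfinite(x_n1) and np.isfinite(x_n2)):
        raise ValueError("triplet scores must be finite")
    h1 = max(params.alpha1 - (x_p - x_n1), 0.0)
    h2 = max(params.alpha1 - (x_p - x_n2), 0.0)
    h3 = max((x_n1 - x_n2) ** 2 - params.alpha2, 0.0)
    return h1 + h2 + h3


def _triplet_loss_batch(xp: np.ndarray, xn1: np.ndarray, xn2: np.ndarray,
                        params: TripletLossParams) -> np.ndarray:
    h1 = np.maximum(params.alpha1 - (xp - xn1), 0.0)
    h2 = np.maximum(params.alpha1 - (xp - xn2), 0.0)
    h3 = np.maximum((xn1 - xn2) ** 2 - params.alpha2, 0.0)
    return h1 + h2 + h3


def sample_triplets(bags: Sequence[Bag], n_triplets: int,
                    rng: np.random.Generator) -> list[tuple[int, int, int]]:
    """Uniformly sample (C2 index, C1 index, C1 index) triples with replacement.

    The two C1 bags are distinct within each triplet.
    """
    c1 = [i for i, b in enumerate(bags) if b.label == 0]
    c2 = [i for i, b in enumerate(bags) if b.label == 1]
    if len(c2) < 1:
        raise ValueError("triplet sampling requires at least 1 C2 bag; found 0")
    if len(c1) < 2:
        raise ValueError(f"triplet sampling requires at least 2 C1 bags; found {len(c1)}")
    triplets = []
    for _ in range(n_triplets):
        p = int(rng.choice(c2))
        n1, n2 = rng.choice(c1, size=2, replace=False)
        triplets.append((p, int(n1), int(n2)))
    return triplets


# ---------------------------------------------------------------------------
# training

def _bag_forward(scorer: TrainedScorer, bag: Bag):
    f = bag.features.astype(np.float64)
    pre = f @ scorer.W1 + scorer.b1
    h = np.maximum(pre, 0.0)
    z = h @ scorer.W2 + scorer.b2
    s = _sigmoid(z)
    return f, pre, h, s, float(s.mean())


def _bag_backward(scorer: TrainedScorer, cache, dloss_dx: float, grads) -> None:
    # bag score x = mean_k sigmoid(z_k); chain rule through the shared MLP
    f, pre, h, s, _ = cache
    k = len(s)
    dz = (dloss_dx / k) * s * (1.0 - s)
    grads["W2"] += h.T @ dz
    grads["b2"] += dz.sum()
    dh = np.outer(dz, scorer.W2)
    dh[pre <= 0.0] = 0.0
    grads["W1"] += f.T @ dh
    grads["b1"] += dh.sum(axis=0)


def _mean_loss(scorer: TrainedScorer, bags: Sequence[Bag],
               params: TripletLossParams, max_pairs: int = 4000,
               rng: np.random.Generator | None = None) -> float:
    """Mean triplet loss over all (or a seeded subsample of) score triples."""
    scores = np.array([bag_score(scorer, b) for b in bags])
    labels = np.array([b.label for b in bags])
    xp = scores[labels == 1]
    xn = scores[labels == 0]
    if len(xp) == 0 or len(xn) < 2:
        raise ValueError("monitoring set needs >= 1 C2 and >= 2 C1 bags")
    i, j = np.triu_indices(len(xn), k=1)
    pp, ii = np.meshgrid(np.arange(len(xp)), np.arange(len(i)), indexing="ij")
    pp, ii = pp.ravel(), ii.ravel()
    if len(pp) > max_pairs:
        sub_rng = np.random.default_rng(0) if rng is None else rng
        pick = sub_rng.choice(len(pp), size=max_pairs, replace=False)
        pp, ii = pp[pick], ii[pick]
    return float(_triplet_loss_batch(xp[pp], xn[i[ii]], xn[j[ii]], params).mean())


def _auc(scores: np.ndarray, labels: np.ndarray) -> float:
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(labels, scores))


def train(
    bags: Sequence[Bag],
    params: TripletLossParams = TripletLossParams(),
    schedule: TrainSchedule = TrainSchedule(),
    monitor_bags: Sequence[Bag] | None = None,
    seed: int = 0,
) -> TrainedScorer:
    """Train the instance scorer by SGD on sampled triplets.

    ``monitor_bags`` (the left-out fold) drives early stopping (no reduction
    of its mean triplet loss for ``patience`` epochs) and best-model selection
    (highest monitoring AUC); without a monitoring fold the training loss is
    monitored instead.  Deterministic under a fixed seed.
    """
    labelled = [b for b in bags if b.label is not None]
    n_c2 = sum(b.label == 1 for b in labelled)
    n_c1 = sum(b.label == 0 for b in labelled)
    if n_c2 == 0 or n_c1 < 2:
        raise ValueError(
            f"training needs >= 2 C1 and >= 1 C2 labelled bags (got C1={n_c1}, C2={n_c2})"
        )
    rng = np.random.default_rng(seed)
    scorer = init_scorer(rng, hidden_dim=schedule.hidden_dim)
    velocity = {k: np.zeros_like(v) if isinstance(v, np.ndarray) else 0.0
                for k, v in (("W1", scorer.W1), ("b1", scorer.b1), ("W2", scorer.W2), ("b2", scorer.b2))}
    n_triplets = schedule.triplets_per_epoch or n_c2

    best_state = None
    best_auc = -np.inf
    best_loss = np.inf
    epochs_without_improvement = 0
    monitor = list(monitor_bags) if monitor_bags is not None else None

    for epoch in range(1, schedule.epochs + 1):
        lr = schedule.learning_rate * schedule.lr_decay ** ((epoch - 1) // schedule.lr_step)
        triplets = sample_triplets(labelled, n_triplets, rng)
        epoch_loss = 0.0
        for p_i, n1_i, n2_i in triplets:
            caches = [_bag_forward(scorer, labelled[idx]) for idx in (p_i, n1_i, n2_i)]
            x_p, x_n1, x_n2 = (c[4] for c in caches)
            epoch_loss += triplet_loss(x_p, x_n1, x_n2, params)
            # subgradients of the three hinges w.r.t. the bag scores
            d = [0.0, 0.0, 0.0]
            if params.alpha1 - (x_p - x_n1) > 0:
                d[0] -= 1.0
                d[1] += 1.0
            if params.alpha1 - (x_p - x_n2) > 0:
                d[0] -= 1.0
                d[2] += 1.0
            if (x_n1 - x_n2) ** 2 - params.alpha2 > 0:
                d[1] += 2.0 * (x_n1 - x_n2)
                d[2] -= 2.0 * (x_n1 - x_n2)
            grads = {"W1": np.zeros_like(scorer.W1), "b1": np.zeros_like(scorer.b1),
                     "W2": np.zeros_like(scorer.W2), "b2": 0.0}
            for cache, dx in zip(caches, d):
                if dx != 0.0:
                    _bag_backward(scorer, cache, dx, grads)
            # SGD with momentum; decoupled-style weight decay folded into grad
            for name, param in (("W1", scorer.W1), ("b1", scorer.b1),
                                ("W2", scorer.W2)):
                g = grads[name] + schedule.weight_decay * param
                velocity[name] = schedule.momentum * velocity[name] + g
                param -= lr * velocity[name]
            velocity["b2"] = schedule.momentum * velocity["b2"] + grads["b2"]
            scorer.b2 -= lr * velocity["b2"]

        entry = {"epoch": epoch, "lr": lr, "train_loss": epoch_loss / max(len(triplets), 1)}
        if monitor is not None:
            entry["val_loss"] = _mean_loss(scorer, monitor, params)
            val_scores = np.array([bag_score(scorer, b) for b in monitor])
            val_labels = np.array([b.label for b in monitor])
            entry["val_auc"] = _auc(val_scores, val_labels)
            monitored_loss, monitored_auc = entry["val_loss"], entry["val_auc"]
        else:
            monitored_loss = entry["train_loss"]
            monitored_auc = -entry["train_loss"]  # lower loss = better model
        scorer.training_log.append(entry)

        if monitored_auc > best_auc:
            best_auc = monitored_auc
            best_state = (scorer.W1.copy(), scorer.b1.copy(), scorer.W2.copy(), scorer.b2)
        if monitored_loss < best_loss - 1e-12:
            best_loss = monitored_loss
            epochs_without_improvement = 0
        else:
            epochs_without_improvement += 1
            if epochs_without_improvement >= schedule.patience:
                scorer.training_log.append({"epoch": epoch, "early_stop": True})
                break

    if best_state is not None:
        scorer.W1, scorer.b1, scorer.W2, scorer.b2 = (
            best_state[0], best_state[1], best_state[2], best_state[3]
        )
    return scorer


# ---------------------------------------------------------------------------
# bag construction and cross-cohort orchestration

def build_bags(manifest: CohortManifest) -> list[Bag]:
    """Build one bag per patient, concatenating the patches of all its slides.

    Bag labels come from the cohort's clinical table (``cms_label``); patients
    without a label get ``label=None``.
    """
    labels: dict[str, int] = {}
    if manifest.clinical_path is not None:
        clinical = read_clinical_table(manifest.resolve(manifest.clinical_path))
        for _, row in clinical.iterrows():
            if pd.notna(row["cms_label"]):
                labels[row["patient_id"]] = int(row["cms_label"])
    bags = []
    for p in manifest.patients:
        feats, coords, slide_ids = [], [], []
        for s in p.slides:
            store = read_feature_store(manifest.resolve(s.features_path))
            feats.append(store.features)
            coords.append(store.coords)
            slide_ids.extend([s.slide_id] * store.n_patches)
        if not feats:
            continue
        bags.append(Bag(
            patient_id=p.patient_id,
            features=np.concatenate(feats, axis=0),
            coords=np.concatenate(coords, axis=0),
            label=labels.get(p.patient_id),
            slide_ids=slide_ids,
        ))
    return bags


def bags_from_cohort(cohort) -> list[Bag]:
    """Bags directly from an in-memory synthetic cohort (no disk round trip)."""
    labels = cohort.labels()
    return [
        Bag(patient_id=pid, features=store.features, coords=store.coords,
            label=labels.get(pid), slide_ids=[store.slide_id] * store.n_patches)
        for pid, store in cohort.feature_stores.items()
    ]


@dataclass(frozen=True)
class CVPlan:
    """Cross-cohort experimental plan: (train cohorts, test cohort) settings."""

    settings: tuple[tuple[tuple[str, ...], str], ...]
    n_folds: int = 3
    seed: int = 0

    @staticmethod
    def leave_one_cohort_out(cohort_ids: Sequence[str], n_folds: int = 3, seed: int = 0) -> "CVPlan":
        settings = tuple(
            (tuple(c for c in cohort_ids if c != test), test) for test in cohort_ids
        )
        return CVPlan(settings=settings, n_folds=n_folds, seed=seed)


@dataclass
class SettingResult:
    train_cohorts: tuple[str, ...]
    test_cohort: str
    fold_scorers: list[TrainedScorer]
    fold_val_aucs: list[float]
    best_fold: int
    best_scorer: TrainedScorer
    discovery_scores: pd.DataFrame  # best-model scores on the merged train cohorts
    score_table: pd.DataFrame  # held-out cohort scores


def stratified_folds(labels: Sequence[int], n_folds: int, seed: int) -> list[np.ndarray]:
    """Index arrays of class-stratified folds (per-fold class counts within 1)."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    y = np.asarray(labels)
    return [test_idx for _, test_idx in skf.split(np.zeros(len(y)), y)]


def run_cross_cohort(
    plan: CVPlan,
    cohorts: Mapping[str, Sequence[Bag]],
    params: TripletLossParams = TripletLossParams(),
    schedule: TrainSchedule = TrainSchedule(),
) -> list[SettingResult]:
    """Run every cross-cohort setting of the plan.

    Per setting: merge the training cohorts, split into stratified folds,
    train one model per fold (trained on the others, monitored on the left-out
    fold), select the fold model with the highest monitoring AUC, and score
    every patient of the held-out cohort with it.
    """
    results = []
    for train_cohorts, test_cohort in plan.settings:
        for name in (*train_cohorts, test_cohort):
            if name not in cohorts:
                raise KeyError(f"cohort {name!r} named in the plan is not provided")
        merged: list[Bag] = []
        merged_cohort: list[str] = []
        for name in train_cohorts:
            labelled = [b for b in cohorts[name] if b.label is not None]
            merged.extend(labelled)
            merged_cohort.extend([name] * len(labelled))
        labels = [b.label for b in merged]
        folds = stratified_folds(labels, plan.n_folds, plan.seed)

        fold_scorers, fold_aucs = [], []
        for k, val_idx in enumerate(folds):
            val_set = set(val_idx.tolist())
            train_bags = [b for i, b in enumerate(merged) if i not in val_set]
            val_bags = [merged[i] for i in val_idx]
            scorer = train(train_bags, params, schedule, monitor_bags=val_bags,
                           seed=plan.seed * 1000 + k)
            val_scores = np.array([bag_score(scorer, b) for b in val_bags])
            fold_scorers.append(scorer)
            fold_aucs.append(_auc(val_scores, np.array([b.label for b in val_bags])))
        best_fold = int(np.argmax(fold_aucs))
        best = fold_scorers[best_fold]

        discovery = pd.DataFrame({
            "patient_id": [b.patient_id for b in merged],
            "cohort": merged_cohort,
            "digital_cms_score": [bag_score(best, b) for b in merged],
            "cms_label": labels,
        })
        test_bags = cohorts[test_cohort]
        score_table = pd.DataFrame({
            "patient_id": [b.patient_id for b in test_bags],
            "cohort": test_cohort,
            "digital_cms_score": [bag_score(best, b) for b in test_bags],
            "cms_label": [b.label for b in test_bags],
        })
        results.append(SettingResult(
            train_cohorts=tuple(train_cohorts), test_cohort=test_cohort,
            fold_scorers=fold_scorers, fold_val_aucs=fold_aucs,
            best_fold=best_fold, best_scorer=best,
            discovery_scores=discovery, score_table=score_table,
        ))
    return results
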