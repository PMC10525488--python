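"""Training and evaluation: labels, loss, Adam, LOSO cross-validation.

Label schemes follow the standard affective-computing conventions for 1-9
self-assessment ratings:

* two-level: ratings 1-5 -> Low, 6-9 -> High (per axis);
* three-level: 1-3 / 4-6 / 7-9 (e.g. Negative / Neutral / Positive valence);
* four-level: the cross of two-level valence and arousal — HVHA, LVHA, LVLA,
  HVLA (in that class-index order);
* seed_three: categorical -1 / 0 / 1 -> class 0 / 1 / 2.

Training minimises L2-regularised cross-entropy
``-(1/Z) sum log p(true class) + (lambda/2) ||theta||^2`` with Adam.
Subject-independent evaluation uses leave-one-subject-out (LOSO)
cross-validation: each subject is the test set exactly once, the model is
re-initialised and trained on all remaining subjects, and per-fold accuracies
are summarised by their mean and standard deviation.  Feature standardisation
(z-score) is fit on training trials only, so no test-subject statistics leak
into training.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sstats

from .autodiff import Tensor
from .features import EncoderInputs
from .model import (
    ModelConfig,
    forward_batch,
    init_params,
    iter_parameters,
)
from .montage import REGION_IDS

logger = logging.getLogger(__name__)


class EvalError(ValueError):
    pass


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

SCHEME_NAMES = ("two_level", "three_level", "four_level_VA", "seed_three")

TWO_LEVEL_CLASSES = ("Low", "High")
THREE_LEVEL_CLASSES = {
    "valence": ("Negative", "Neutral", "Positive"),
    "arousal": ("Activated", "Moderate", "Deactivated"),
    "dominance": ("Controlled", "Moderate", "Overpowered"),
}
FOUR_LEVEL_CLASSES = ("HVHA", "LVHA", "LVLA", "HVLA")
SEED_CLASSES = ("Negative", "Neutral", "Positive")


@dataclass
class RatingRecord:
    """One trial's self-assessment ratings (1-9 scales, or -1/0/1 for seed_three)."""

    subject_id: str
    trial_id: str
    valence: float
    arousal: float = 5.0
    dominance: float = 5.0


@dataclass(frozen=True)
class LabelScheme:
    """A mapping from ratings to class indices.

    ``axis`` selects the rating dimension for two/three-level schemes and is
    ignored by ``four_level_VA`` (which always combines valence and arousal)
    and ``seed_three``.
    """

    name: str
    axis: str = "valence"

    def __post_init__(self) -> None:
        if self.name not in SCHEME_NAMES:
            raise EvalError(f"unknown scheme {self.name!r}; choose from {SCHEME_NAMES}")
        if self.axis not in ("valence", "arousal", "dominance"):
            raise EvalError(f"unknown rating axis {self.axis!r}")

    @property
    def n_classes(self) -> int:
        return {"two_level": 2, "three_level": 3, "four_level_VA": 4, "seed_three": 3}[
            self.name
        ]

    @property
    def class_names(self) -> tuple[str, ...]:
        if self.name == "two_level":
            return TWO_LEVEL_CLASSES
        if self.name == "three_level":
            return THREE_LEVEL_CLASSES[self.axis]
        if self.name == "four_level_VA":
            return FOUR_LEVEL_CLASSES
        return SEED_CLASSES


def _rating_to_int(value: float) -> int:
    # Continuous SAM ratings are floored into the printed integer ranges.
    if not 1.0 <= value <= 9.0:
        raise EvalError(f"rating {value} outside the 1-9 scale")
    return int(np.floor(value))


def _two_level(value: float) -> int:
    return 0 if _rating_to_int(value) <= 5 else 1  # 0 = Low, 1 = High


def _three_level(value: float) -> int:
    rv = _rating_to_int(value)
    return 0 if rv <= 3 else (1 if rv <= 6 else 2)


def map_label(record: RatingRecord, scheme: LabelScheme) -> int:
    """Class index of a rating record under a label scheme (deterministic)."""
    if scheme.name == "seed_three":
        cat = int(record.valence)
        if cat not in (-1, 0, 1):
            raise EvalError(f"seed_three expects -1/0/1, got {record.valence}")
        return cat + 1
    value = getattr(record, scheme.axis)
    if scheme.name == "two_level":
        return _two_level(value)
    if scheme.name == "three_level":
        return _three_level(value)
    # four_level_VA: cross of two-level valence and arousal
    v_high = _two_level(record.valence) == 1
    a_high = _two_level(record.arousal) == 1
    if v_high and a_high:
        return 0  # HVHA
    if not v_high and a_high:
        return 1  # LVHA
    if not v_high and not a_high:
        return 2  # LVLA
    return 3  # HVLA


# ---------------------------------------------------------------------------
# loss / metrics
# ---------------------------------------------------------------------------


def l2_penalty(params) -> Tensor:
    """``||theta||^2`` summed over every parameter leaf (in-graph)."""
    total: Tensor | None = None
    for p in iter_parameters(params):
        term = (p * p).sum()
        total = term if total is None else total + term
    assert total is not None
    return total


def loss(
    probabilities: Tensor, labels: np.ndarray, params=None, lambda_reg: float = 0.0
) -> Tensor:
    """L2-regularised mean cross-entropy of a probability batch.

    ``-(1/Z) sum_z log p_z(y_z) + (lambda/2) ||theta||^2``.  ``probabilities``
    is (Z, c) and already on the simplex (softmax output).
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise EvalError("empty batch")
    picked = probabilities[np.arange(labels.size), labels]
    out = -(picked.log().mean())
    if lambda_reg > 0.0 and params is not None:
        out = out + l2_penalty(params) * (lambda_reg / 2.0)
    return out


def accuracy(predictions: Sequence[int], labels: Sequence[int]) -> float:
    """Fraction of correctly classified trials, ``(TP + TN) / total``."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.size == 0 or predictions.shape != labels.shape:
        raise EvalError("predictions and labels must be equal-length and non-empty")
    return float(np.mean(predictions == labels))


def paired_ttest(acc_a: Sequence[float], acc_b: Sequence[float]) -> float:
    """Two-sided paired t-test p-value between per-subject accuracy vectors.

    Degenerate cases: identical vectors raise (the statistic is undefined);
    identical nonzero differences report p = 0 with a warning (the statistic
    diverges).
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise EvalError("paired t-test needs two equal-length vectors, n >= 2")
    diff = a - b
    if np.all(diff == 0):
        raise EvalError("all pairwise differences are zero: t statistic undefined")
    if np.ptp(diff) == 0:
        warnings.warn(
            "pairwise differences identical and nonzero; t statistic diverges, "
            "reporting p = 0",
            stacklevel=2,
        )
        return 0.0
    return float(sstats.ttest_rel(a, b).pvalue)


# ---------------------------------------------------------------------------
# datasets and batching
# ---------------------------------------------------------------------------


@dataclass
class TrialDataset:
    """Encoder inputs + integer labels + subject ids for a set of trials."""

    inputs: list[EncoderInputs]
    labels: np.ndarray
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.inputs) == self.labels.size == len(self.subject_ids)):
            raise EvalError("inputs, labels and subject_ids must align")

    def __len__(self) -> int:
        return len(self.inputs)

    def subset(self, idx: Sequence[int]) -> "TrialDataset":
        idx = list(idx)
        return TrialDataset(
            [self.inputs[i] for i in idx],
            self.labels[idx],
            [self.subject_ids[i] for i in idx],
        )

    def batch_arrays(self) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
        """Stack trials into per-region arrays H (B, d, N_r) and U (B, d, T)."""
        H = {
            rid: np.stack([inp.H[rid] for inp in self.inputs]) for rid in REGION_IDS
        }
        U = {
            rid: np.stack([inp.U[rid] for inp in self.inputs]) for rid in REGION_IDS
        }
        return H, U


@dataclass
class Standardizer:
    """Per-feature z-scoring fit on training trials only (no test leakage)."""

    h_stats: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    u_stats: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def fit(self, H: Mapping[str, np.ndarray], U: Mapping[str, np.ndarray]) -> "Standardizer":
        for rid in REGION_IDS:
            self.h_stats[rid] = (H[rid].mean(axis=0), H[rid].std(axis=0) + 1e-12)
            self.u_stats[rid] = (U[rid].mean(axis=0), U[rid].std(axis=0) + 1e-12)
        return self

    def transform(
        self, H: Mapping[str, np.ndarray], U: Mapping[str, np.ndarray]
    ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
        Hs = {rid: (H[rid] - m) / s for rid, (m, s) in self.h_stats.items()}
        Us = {rid: (U[rid] - m) / s for rid, (m, s) in self.u_stats.items()}
        return Hs, Us


# ---------------------------------------------------------------------------
# Adam training
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    val_fraction: float = 0.1
    stop_loss: float = 0.0  # stop once the epoch loss falls below (0 = never)
    seed: int = 0


class AdamOptimizer:
    """Standard Adam with bias correction over a list of parameter leaves."""

    def __init__(self, params: list[Tensor], config: TrainConfig):
        self.params = params
        self.cfg = config
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        c = self.cfg
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = c.beta1 * self.m[i] + (1 - c.beta1) * p.grad
            self.v[i] = c.beta2 * self.v[i] + (1 - c.beta2) * p.grad**2
            m_hat = self.m[i] / (1 - c.beta1**self.t)
            v_hat = self.v[i] / (1 - c.beta2**self.t)
            p.data -= c.learning_rate * m_hat / (np.sqrt(v_hat) + c.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


def _epoch_loss(
    H: Mapping, U: Mapping, labels: np.ndarray, params, lambda_reg: float
) -> float:
    probs = forward_batch(H, U, params)
    return float(loss(probs, labels, params, lambda_reg).data)


def train(
    params,
    dataset: TrialDataset,
    model_config: ModelConfig,
    train_config: TrainConfig | None = None,
    standardizer: Standardizer | None = None,
) -> TrainHistory:
    """Train the parameter tree in place with minibatch Adam.

    A ``val_fraction`` of trials (seeded split) monitors generalisation;
    training stops when the validation loss has not improved for ``patience``
    epochs, restoring the best parameters.  With fewer than 10 trials, or
    ``val_fraction == 0``, early stopping monitors the training loss instead;
    ``stop_loss`` additionally ends training once the monitored loss drops
    below a convergence floor.  Fixed seeds give bit-reproducible histories.
    """
    tc = train_config or TrainConfig()
    if len(dataset) == 0:
        raise EvalError("empty training set")
    rng = np.random.default_rng(tc.seed)

    order = rng.permutation(len(dataset))
    n_val = int(round(tc.val_fraction * len(dataset)))
    use_val = n_val >= 1 and len(dataset) >= 10
    val_idx = order[:n_val] if use_val else np.array([], dtype=int)
    tr_idx = order[n_val:] if use_val else order

    tr = dataset.subset(tr_idx)
    H_tr, U_tr = tr.batch_arrays()
    if standardizer is not None:
        standardizer.fit(H_tr, U_tr)
        H_tr, U_tr = standardizer.transform(H_tr, U_tr)
    if use_val:
        va = dataset.subset(val_idx)
        H_va, U_va = va.batch_arrays()
        if standardizer is not None:
            H_va, U_va = standardizer.transform(H_va, U_va)

    leaves = iter_parameters(params)
    opt = AdamOptimizer(leaves, tc)
    history = TrainHistory()
    best = np.inf
    best_state = [p.data.copy() for p in leaves]
    stall = 0

    n_tr = len(tr)
    for epoch in range(tc.max_epochs):
        perm = rng.permutation(n_tr)
        batch_losses = []
        for start in range(0, n_tr, tc.batch_size):
            idx = perm[start : start + tc.batch_size]
            Hb = {rid: H_tr[rid][idx] for rid in REGION_IDS}
            Ub = {rid: U_tr[rid][idx] for rid in REGION_IDS}
            opt.zero_grad()
            probs = forward_batch(Hb, Ub, params)
            batch_loss = loss(
                probs, tr.labels[idx], params, model_config.lambda_reg
            )
            if not np.isfinite(batch_loss.data):
                raise EvalError(
                    f"non-finite loss at epoch {epoch}: {batch_loss.data!r}"
                )
            batch_loss.backward()
            opt.step()
            batch_losses.append(float(batch_loss.data) * idx.size)

        tr_loss = float(np.sum(batch_losses) / n_tr)  # epoch mean over minibatches
        history.train_loss.append(tr_loss)
        monitored = tr_loss
        if use_val:
            va_loss = _epoch_loss(
                H_va, U_va, va.labels, params, model_config.lambda_reg
            )
            history.val_loss.append(va_loss)
            monitored = va_loss
        if monitored < best - 1e-12:
            best = monitored
            history.best_epoch = epoch
            best_state = [p.data.copy() for p in leaves]
            stall = 0
        else:
            stall += 1
            if stall > tc.patience:
                break
        if tc.stop_loss > 0.0 and monitored < tc.stop_loss:
            break
    for p, saved in zip(leaves, best_state):
        p.data = saved
    return history


# ---------------------------------------------------------------------------
# LOSO protocol
# ---------------------------------------------------------------------------


@dataclass
class FoldPlan:
    """One (test_subject, train_subjects) pair per subject."""

    folds: list[tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        for test, train_subjects in self.folds:
            if test in train_subjects:
                raise EvalError(f"test subject {test} leaked into its training set")

    def __len__(self) -> int:
        return len(self.folds)


def loso_split(subject_ids: Sequence[str]) -> FoldPlan:
    """Leave-one-subject-out folds over the distinct subjects, in sorted order."""
    subjects = sorted(set(subject_ids))
    if len(subjects) < 2:
        raise EvalError("LOSO needs at least 2 distinct subjects")
    folds = [
        (test, tuple(s for s in subjects if s != test)) for test in subjects
    ]
    return FoldPlan(folds)


@dataclass
class EvalResult:
    """Per-fold LOSO accuracies and their summary statistics."""

    fold_subjects: list[str]
    fold_accuracies: list[float]
    histories: list[TrainHistory] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=0))

    def to_dict(self) -> dict:
        return {
            "folds": [
                {"subject": s, "accuracy": a}
                for s, a in zip(self.fold_subjects, self.fold_accuracies)
            ],
            "mean_accuracy": self.mean,
            "std_accuracy": self.std,
        }


def run_loso_experiment(
    dataset: TrialDataset,
    model_config: ModelConfig,
    train_config: TrainConfig | None = None,
    standardize: bool = True,
) -> EvalResult:
    """Full LOSO evaluation: one freshly initialised model per fold.

    Each fold trains on all other subjects' trials (with z-scoring fit on
    those trials only) and reports accuracy on the held-out subject.
    """
    tc = train_config or TrainConfig()
    plan = loso_split(dataset.subject_ids)
    result = EvalResult([], [])
    subj = np.asarray(dataset.subject_ids)
    for k, (test_subject, _train_subjects) in enumerate(plan.folds):
        te_idx = np.flatnonzero(subj == test_subject)
        tr_idx = np.flatnonzero(subj != test_subject)
        assert test_subject not in {dataset.subject_ids[i] for i in tr_idx}
        tr_set = dataset.subset(tr_idx)
        te_set = dataset.subset(te_idx)

        params = init_params(
            ModelConfig(**{**model_config.__dict__, "seed": model_config.seed + k})
        )
        std = Standardizer() if standardize else None
        fold_tc = TrainConfig(**{**tc.__dict__, "seed": tc.seed + k})
        history = train(params, tr_set, model_config, fold_tc, standardizer=std)

        H_te, U_te = te_set.batch_arrays()
        if std is not None:
            H_te, U_te = std.transform(H_te, U_te)
        probs = forward_batch(H_te, U_te, params).data
        preds = probs.argmax(axis=-1)
        result.fold_subjects.append(test_subject)
        result.fold_accuracies.append(accuracy(preds, te_set.labels))
        result.histories.append(history)
        logger.info(
            "fold %d/%d (subject %s): accuracy %.3f",
            k + 1,
            len(plan),
            test_subject,
            result.fold_accuracies[-1],
        )
    return result
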