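"""Classification of single-cell spectra, full and discretized.

Implements the evaluation protocol used to compare representations:
k-nearest-neighbour and linear discriminant analysis on either the full
spectrum (intensity vector over the shift grid, Pearson-correlation
similarity) or the discrete spectrum (peak records, combined
sqrt(s1)*s2 similarity for k-NN; a peak-vocabulary intensity vector for
LDA), scored by stratified random 60/40 train/test splits repeated 10
times.

For LDA on discrete spectra a fixed feature dimension is required, so
all unique peak positions of the *training* spectra are pooled into a
:class:`PeakVocabulary` (single-linkage merge of positions closer than
delta), and every spectrum is vectorized as the intensity of its peak
nearest to each vocabulary position (0 when none lies within delta).
The vocabulary and all LDA parameters are fitted on the training side
only.

The LDA itself is the classical multi-class Fisher discriminant with a
pooled within-class covariance regularized by ``ridge * I`` — the
regularization is needed for full spectra, whose dimension (>1,000)
exceeds the sample count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import linalg

from .errors import ConfigError, DataError
from .similarity import combined_similarity
from .spectra_io import DiscreteSpectrum, RamanSpectrum

__all__ = [
    "LabeledDataset",
    "PeakVocabulary",
    "EvaluationReport",
    "build_vocabulary",
    "vectorize",
    "pearson_full",
    "knn_predict",
    "LDAModel",
    "lda_fit",
    "lda_predict",
    "evaluate",
]

Representation = Literal["full", "discrete"]
Method = Literal["knn", "lda"]


@dataclass
class LabeledDataset:
    """Homogeneous collection of (spectrum, class label) pairs."""

    items: list[tuple[RamanSpectrum | DiscreteSpectrum, str]]
    representation: Representation

    def __post_init__(self) -> None:
        want = RamanSpectrum if self.representation == "full" else DiscreteSpectrum
        for spec, _ in self.items:
            if not isinstance(spec, want):
                raise DataError(
                    f"representation '{self.representation}' expects {want.__name__}, "
                    f"got {type(spec).__name__}"
                )

    def __len__(self) -> int:
        return len(self.items)

    @property
    def labels(self) -> list[str]:
        return [label for _, label in self.items]

    def subset(self, idx: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset([self.items[i] for i in idx], self.representation)


@dataclass(frozen=True)
class PeakVocabulary:
    """Reference peak positions (strictly increasing, pairwise > delta apart)."""

    positions: tuple[float, ...]
    delta: float

    def __post_init__(self) -> None:
        pos = self.positions
        if any(b - a <= self.delta for a, b in zip(pos, pos[1:])):
            raise DataError("adjacent vocabulary positions must differ by > delta")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class EvaluationReport:
    """Per-repeat accuracies and their mean for one classifier/representation."""

    per_repeat_accuracy: list[float]
    mean_accuracy: float
    method: Method
    representation: Representation
    seed: int

    def __post_init__(self) -> None:
        if abs(self.mean_accuracy - float(np.mean(self.per_repeat_accuracy))) > 1e-12:
            raise DataError("mean_accuracy must equal the mean of per-repeat values")


def build_vocabulary(training: LabeledDataset, delta: float = 10.0) -> PeakVocabulary:
    """Pool, sort and single-linkage merge all training peak positions.

    Runs of positions whose adjacent gaps are <= delta collapse to their
    mean; the resulting reference positions are pairwise more than delta
    apart.
    """
    if training.representation != "discrete":
        raise DataError("vocabulary requires the discrete representation")
    if len(training) == 0:
        raise DataError("empty training set")
    pooled = np.sort(
        np.concatenate([spec.positions for spec, _ in training.items])
        if any(len(spec.peaks) for spec, _ in training.items)
        else np.array([])
    )
    if len(pooled) == 0:
        raise DataError("no peaks in training set")
    merged: list[float] = []
    start = 0
    for i in range(1, len(pooled) + 1):
        if i == len(pooled) or pooled[i] - pooled[i - 1] > delta:
            merged.append(float(np.mean(pooled[start:i])))
            start = i
    return PeakVocabulary(tuple(merged), delta)


def vectorize(d: DiscreteSpectrum, vocab: PeakVocabulary) -> np.ndarray:
    """Intensity vector over the vocabulary positions.

    Entry j is the intensity of the peak of ``d`` nearest to vocabulary
    position j within delta, or 0 when no peak lies that close.  Peaks
    matching no vocabulary position are ignored.
    """
    out = np.zeros(len(vocab))
    if len(d.peaks) == 0:
        return out
    pos = d.positions
    inten = d.intensities
    for j, v in enumerate(vocab.positions):
        dist = np.abs(pos - v)
        i = int(np.argmin(dist))
        if dist[i] <= vocab.delta:
            out[j] = inten[i]
    return out


def pearson_full(a: RamanSpectrum, b: RamanSpectrum) -> float:
    """Pearson correlation of two full spectra's intensity vectors.

    Spectra on different grids are linearly interpolated onto the grid of
    ``a`` first.
    """
    ya = a.intensities
    if len(b) == len(a) and np.array_equal(b.shifts, a.shifts):
        yb = b.intensities
    else:
        yb = np.interp(a.shifts, b.shifts, b.intensities)
    if np.ptp(ya) == 0 or np.ptp(yb) == 0:
        return 0.0
    return float(np.corrcoef(ya, yb)[0, 1])


def knn_predict(
    query: RamanSpectrum | DiscreteSpectrum,
    references: LabeledDataset,
    k: int = 1,
    measure: Callable[..., float] | None = None,
) -> str:
    """Majority label among the k most similar reference spectra.

    Similarity ties are broken by earlier dataset order (stable sort);
    vote ties by the single nearest neighbour's label.  The default
    measure is Pearson correlation for full spectra and the combined
    sqrt(s1)*s2 score for discrete spectra.
    """
    if len(references) == 0:
        raise ConfigError("empty reference set")
    if not 1 <= k <= len(references):
        raise ConfigError(f"k={k} outside [1, {len(references)}]")
    if measure is None:
        measure = pearson_full if references.representation == "full" else combined_similarity
    sims = np.array([measure(query, ref) for ref, _ in references.items])
    # stable sort descending: earlier dataset order wins similarity ties
    order = np.argsort(-sims, kind="stable")[:k]
    votes: dict[str, int] = {}
    labels = references.labels
    for i in order:
        votes[labels[i]] = votes.get(labels[i], 0) + 1
    top = max(votes.values())
    winners = [lab for lab, v in votes.items() if v == top]
    if len(winners) == 1:
        return winners[0]
    for i in order:  # vote tie: nearest neighbour among tied labels
        if labels[i] in winners:
            return labels[i]
    raise AssertionError("unreachable")


@dataclass
class LDAModel:
    """Fitted regularized Fisher discriminant (equal priors by default)."""

    classes: list[str]
    means: np.ndarray  # (C, p)
    coef: np.ndarray  # (C, p): Sigma^-1 mu_c
    intercept: np.ndarray  # (C,): -0.5 mu_c^T Sigma^-1 mu_c + log pi_c
    ridge: float = 0.0


def lda_fit(
    X: np.ndarray,
    labels: Sequence[str],
    ridge: float = 1e-3,
    priors: dict[str, float] | None = None,
) -> LDAModel:
    """Multi-class Fisher LDA with ridge-regularized pooled covariance.

    The pooled within-class covariance ``S_w`` (denominator n - C) is
    replaced by ``S_w + ridge * I``; class c scores
    ``x^T S^-1 mu_c - 0.5 mu_c^T S^-1 mu_c + log pi_c`` with equal priors
    unless ``priors`` maps class -> frequency.
    """
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise DataError("LDA needs >= 2 classes")
    n, p = X.shape
    means = np.empty((len(classes), p))
    scatter = np.zeros((p, p))
    for ci, c in enumerate(classes):
        rows = X[[i for i, l in enumerate(labels) if l == c]]
        if len(rows) < 2:
            raise DataError(f"class {c!r} has < 2 training samples")
        means[ci] = rows.mean(axis=0)
        centered = rows - means[ci]
        scatter += centered.T @ centered
    cov = scatter / (n - len(classes)) + ridge * np.eye(p)
    try:
        cho = linalg.cho_factor(cov)
        coef = linalg.cho_solve(cho, means.T).T
    except linalg.LinAlgError as exc:
        raise DataError(
            "singular within-class covariance; increase ridge > 0"
        ) from exc
    if priors is None:
        log_priors = np.zeros(len(classes))  # equal priors
    else:
        log_priors = np.log([priors[c] for c in classes])
    intercept = -0.5 * np.sum(coef * means, axis=1) + log_priors
    return LDAModel(classes, means, coef, intercept, ridge)


def lda_predict(model: LDAModel, x: np.ndarray) -> str:
    """Class with the highest linear discriminant score (deterministic)."""
    scores = model.coef @ np.asarray(x, float) + model.intercept
    return model.classes[int(np.argmax(scores))]


def _stratified_split(
    labels: Sequence[str], split: float, rng: np.random.Generator
) -> tuple[list[int], list[int]]:
    """Per-class shuffled indices split at the given training fraction."""
    train: list[int] = []
    test: list[int] = []
    by_class: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(i)
    for lab in sorted(by_class):
        idx = np.array(by_class[lab])
        if len(idx) < 2:
            raise DataError(f"class {lab!r} has < 2 members; cannot stratify")
        rng.shuffle(idx)
        n_train = max(1, min(len(idx) - 1, int(round(split * len(idx)))))
        train.extend(idx[:n_train].tolist())
        test.extend(idx[n_train:].tolist())
    return sorted(train), sorted(test)


def evaluate(
    dataset: LabeledDataset,
    method: Method = "knn",
    representation: Representation | None = None,
    split: float = 0.6,
    repeats: int = 10,
    seed: int = 0,
    k: int = 1,
    ridge: float = 1e-3,
    delta: float = 10.0,
) -> EvaluationReport:
    """Repeated stratified train/test evaluation.

    Per repeat: a seeded stratified random split at ``split`` training
    fraction; the vocabulary (discrete LDA) and all model parameters are
    fitted on the training side only; accuracy is correct/total on the
    test side.  The report lists every repeat and their mean, and is
    bit-reproducible from (dataset, parameters, seed).
    """
    if not 0 < split < 1:
        raise ConfigError("split must be in (0, 1)")
    if repeats < 1:
        raise ConfigError("repeats must be >= 1")
    representation = representation or dataset.representation
    if representation != dataset.representation:
        raise DataError("representation tag does not match the dataset")
    if len(set(dataset.labels)) < 2:
        raise DataError("classification needs >= 2 classes")
    accuracies: list[float] = []
    root = np.random.SeedSequence(seed)
    for child in root.spawn(repeats):
        rng = np.random.default_rng(child)
        train_idx, test_idx = _stratified_split(dataset.labels, split, rng)
        train = dataset.subset(train_idx)
        test = dataset.subset(test_idx)
        if method == "knn":
            correct = sum(
                knn_predict(spec, train, k=k) == lab for spec, lab in test.items
            )
        elif method == "lda":
            if representation == "discrete":
                vocab = build_vocabulary(train, delta)
                Xtr = np.array([vectorize(s, vocab) for s, _ in train.items])
                Xte = np.array([vectorize(s, vocab) for s, _ in test.items])
            else:
                Xtr = np.array([s.intensities for s, _ in train.items])
                Xte = np.array([s.intensities for s, _ in test.items])
            model = lda_fit(Xtr, train.labels, ridge=ridge)
            correct = sum(
                lda_predict(model, x) == lab for x, (_, lab) in zip(Xte, test.items)
            )
        else:
            raise ConfigError(f"unknown method {method!r}")
        accuracies.append(correct / len(test))
    return EvaluationReport(
        per_repeat_accuracy=accuracies,
        mean_accuracy=float(np.mean(accuracies)),
        method=method,
        representation=representation,
        seed=seed,
    )
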