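"""Pool-based active learning: least-confidence scoring, batch query
selection, and the iterative label-and-retrain loop, plus a random-sampling
baseline.

The loop keeps a labeled/unlabeled partition of the target pool.  Each
iteration scores the unlabeled pool with the current model, moves the most
uncertain batch to the labeled set with oracle labels, retrains with a warm
start, and records metrics on the target and combined test sets.  After the
final iteration the whole pool is labeled and the weights are tagged ``w12``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .classifier import ClassifierState, TrainConfig, predict_proba, train
from .data_io import CLASS0, CLASS1, DomainDataset, ImageSample
from .errors import ConfigurationError, StateError
from .evaluation import COMBINED_TAG, MetricsRecord, evaluate_classifier

STRATEGIES = ("least_confidence", "random")


@dataclass(frozen=True)
class ALConfig:
    """Budget parameters of the query loop.

    ``N`` is the pool size, ``l`` the initial labeled count, ``m`` the number
    of query iterations; the per-iteration batch is ``n = (N - l) // m`` with
    the final iteration absorbing any remainder so labeling ends at exactly N.
    """

    N: int
    l: int
    m: int
    strategy: str = "least_confidence"
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.l < self.N:
            raise ConfigurationError(f"need 0 < l < N, got l={self.l}, N={self.N}")
        if self.m < 1:
            raise ConfigurationError(f"m must be >= 1, got {self.m}")
        if self.batch_n < 1:
            raise ConfigurationError(
                f"derived batch n = (N - l) // m = {self.batch_n} must be >= 1"
            )
        if self.strategy not in STRATEGIES:
            raise ConfigurationError(f"strategy must be one of {STRATEGIES}")

    @property
    def batch_n(self) -> int:
        return (self.N - self.l) // self.m


@dataclass
class ALHistoryEntry:
    iteration: int  # 0 = initial fit on l labels, i >= 1 after query batch i
    n_labeled: int
    fraction_labeled: float
    metrics: dict[str, MetricsRecord]  # keyed by test-set tag


@dataclass
class ALState:
    """Evolving labeled/unlabeled partition with per-iteration metrics."""

    iteration: int
    labeled_ids: set[str]
    unlabeled_ids: set[str]
    scores: dict[str, float] = field(default_factory=dict)
    history: list[ALHistoryEntry] = field(default_factory=list)
    queried_batches: list[list[str]] = field(default_factory=list)

    def check_partition(self, pool_ids: set[str]) -> None:
        if self.labeled_ids & self.unlabeled_ids:
            raise StateError("labeled and unlabeled sets overlap")
        if self.labeled_ids | self.unlabeled_ids != pool_ids:
            raise StateError("labeled/unlabeled sets do not partition the pool")


def least_confidence(p_k):
    """Least-confidence score ``min(P, 1 - P)`` in [0, 0.5].

    Accepts a scalar or an array; symmetric under ``P -> 1 - P``.
    """
    p = np.asarray(p_k, dtype=np.float64)
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    out = np.minimum(p, 1.0 - p)
    return float(out) if np.isscalar(p_k) else out


def select_queries(scores: Mapping[str, float], n_query: int) -> list[str]:
    """Ids of the ``n_query`` most uncertain samples (largest score).

    Ties break by ascending sample_id; the result is ordered by
    (descending score, ascending id).  Requests beyond the pool size return
    the whole pool in that order.
    """
    if n_query < 1:
        raise ValueError(f"n_query must be >= 1, got {n_query}")
    if not scores:
        raise StateError("pool exhausted: no unlabeled samples to query")
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [sid for sid, _ in ranked[:n_query]]


def random_query_baseline(
    unlabeled_ids: Sequence[str] | set[str], n_query: int, seed: int
) -> list[str]:
    """Seeded uniform draw without replacement (control strategy)."""
    if n_query < 1:
        raise ValueError(f"n_query must be >= 1, got {n_query}")
    ids = sorted(unlabeled_ids)
    if not ids:
        raise StateError("pool exhausted: no unlabeled samples to query")
    rng = np.random.default_rng(seed)
    k = min(n_query, len(ids))
    picked = rng.choice(len(ids), size=k, replace=False)
    return [ids[i] for i in picked]


def make_oracle(pool: DomainDataset) -> Callable[[str], int]:
    """Oracle that reveals the pool's true labels (the simulated annotator)."""
    lookup = {s.sample_id: s.label for s in pool.train}

    def oracle(sample_id: str) -> int:
        if sample_id not in lookup:
            raise StateError(f"oracle has no label for sample {sample_id!r}")
        return lookup[sample_id]

    return oracle


def _stratified_initial(
    pool_samples: Sequence[ImageSample],
    oracle: Callable[[str], int],
    l: int,
    rng: np.random.Generator,
) -> list[str]:
    """Class-stratified uniform draw of the initial labeled set."""
    by_class: dict[int, list[str]] = {CLASS0: [], CLASS1: []}
    for s in pool_samples:
        by_class[oracle(s.sample_id)].append(s.sample_id)
    want = {CLASS0: l // 2 + l % 2, CLASS1: l // 2}
    chosen: list[str] = []
    for cls in (CLASS0, CLASS1):
        ids = sorted(by_class[cls])
        k = min(want[cls], len(ids))
        picked = rng.choice(len(ids), size=k, replace=False)
        chosen.extend(ids[i] for i in picked)
    # top up from the other class if one side ran short
    if len(chosen) < l:
        rest = sorted(set(s.sample_id for s in pool_samples) - set(chosen))
        extra = rng.choice(len(rest), size=l - len(chosen), replace=False)
        chosen.extend(rest[i] for i in extra)
    return chosen


def run_active_learning(
    classifier_w1: ClassifierState,
    pool: DomainDataset,
    test_target: Sequence[ImageSample],
    test_combined: Sequence[ImageSample],
    config: ALConfig,
    train_config: TrainConfig,
    oracle: Callable[[str], int] | None = None,
) -> tuple[ClassifierState, ALState]:
    """Run the m-iteration query loop starting from source weights.

    The classifier is trained warm-start on the initial ``l`` stratified
    labels, then each iteration transfers the top-``n`` most uncertain
    unlabeled samples (or a random batch under the baseline strategy) to the
    labeled set and retrains.  History carries one entry for the initial fit
    and one per iteration; the final entry is the model trained on 100% of
    the pool, whose weights are tagged ``w12``.
    """
    config.validate()
    pool_samples = list(pool.train)
    if len(pool_samples) != config.N:
        raise ConfigurationError(
            f"config.N = {config.N} but the pool has {len(pool_samples)} samples"
        )
    pool_ids = {s.sample_id for s in pool_samples}
    by_id = {s.sample_id: s for s in pool_samples}
    test_ids = {s.sample_id for s in test_target} | {s.sample_id for s in test_combined}
    if test_ids & pool_ids:
        raise ConfigurationError("test samples must not appear in the training pool")
    if oracle is None:
        oracle = make_oracle(pool)

    rng = np.random.default_rng([config.seed, 17])
    labeled = set(
        _stratified_initial(pool_samples, oracle, config.l, rng)
    )
    state = ALState(
        iteration=0,
        labeled_ids=labeled,
        unlabeled_ids=pool_ids - labeled,
    )
    state.check_partition(pool_ids)

    def labeled_training_set() -> list[ImageSample]:
        # oracle labels stand in for whatever labels the pool carries
        return [by_id[sid].with_label(oracle(sid)) for sid in sorted(state.labeled_ids)]

    def record(iteration: int) -> None:
        metrics = {
            "T2": evaluate_classifier(classifier_w1, test_target, test_set_tag="T2"),
            COMBINED_TAG: evaluate_classifier(
                classifier_w1, test_combined, test_set_tag=COMBINED_TAG
            ),
        }
        state.history.append(
            ALHistoryEntry(
                iteration=iteration,
                n_labeled=len(state.labeled_ids),
                fraction_labeled=len(state.labeled_ids) / config.N,
                metrics=metrics,
            )
        )

    train(classifier_w1, labeled_training_set(), train_config)
    record(iteration=0)

    n = config.batch_n
    for i in range(1, config.m + 1):
        unlabeled = sorted(state.unlabeled_ids)
        if not unlabeled:
            raise StateError("pool exhausted before the final iteration")
        batch_size = n if i < config.m else len(unlabeled)  # remainder absorbed
        if config.strategy == "least_confidence":
            samples = [by_id[sid] for sid in unlabeled]
            probs = predict_proba(classifier_w1, samples)
            state.scores = dict(zip(unlabeled, least_confidence(probs)))
            batch = select_queries(state.scores, batch_size)
        else:
            batch = random_query_baseline(state.unlabeled_ids, batch_size, seed=int(
                np.random.default_rng([config.seed, 23, i]).integers(2**31)
            ))
        state.queried_batches.append(batch)
        state.labeled_ids |= set(batch)
        state.unlabeled_ids -= set(batch)
        state.iteration = i
        state.check_partition(pool_ids)

        train(classifier_w1, labeled_training_set(), train_config)
        record(iteration=i)

    assert state.labeled_ids == pool_ids
    classifier_w1.weights_tag = "w12"
    return classifier_w1, state
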