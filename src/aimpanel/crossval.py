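"""Repeated stratified Monte-Carlo holdout cross-validation around the DAPC
classifier.

Each replicate splits every population independently into a training
fraction (default 75%) and a held-out test fraction (25%), fits the DAPC on
the training individuals, assigns the test individuals, and scores the
correct-assignment rate under a posterior threshold.  A test individual
counts as correctly assigned when its argmax group equals its true
population AND the winning posterior reaches the threshold (the stricter
reading; ``threshold_on="true_pop"`` instead thresholds the true
population's posterior).

Replicate seeds are derived deterministically from
``(base_seed, sorted combination, replicate index)``, so results are
bit-identical regardless of execution order or worker count.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np

from .dapc import DegenerateFitError, fit_dapc, impute_missing, predict_assignments
from .genotypes import GenotypeSet, subset_loci, to_allele_counts

__all__ = [
    "CvConfig",
    "ReplicateResult",
    "CvResult",
    "DegenerateFitWarning",
    "stratified_split",
    "replicate_seed",
    "cv_replicate",
    "run_cv",
]


class DegenerateFitWarning(UserWarning):
    """A replicate's DAPC fit was degenerate (e.g. zero training variance);
    the replicate scores all test individuals as incorrect."""


@dataclass(frozen=True)
class CvConfig:
    """Cross-validation run parameters.

    train_fraction : fraction of each population used for training (0.75
        reproduces the standard 75/25 split).
    n_replicates : number of independent random splits.
    assignment_threshold : minimum posterior for a successful assignment.
    n_pca : principal-axis retention override (None = default rule).
    scale : unit-variance column scaling in the DAPC.
    threshold_on : "winner" thresholds the winning posterior, "true_pop"
        the true population's posterior.
    base_seed : root of the deterministic per-replicate seeding contract.
    """

    train_fraction: float = 0.75
    n_replicates: int = 100
    assignment_threshold: float = 0.9
    n_pca: int | None = None
    scale: bool = False
    threshold_on: str = "winner"
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 <= self.assignment_threshold <= 1.0:
            raise ValueError("assignment_threshold must be in [0, 1]")
        if self.threshold_on not in ("winner", "true_pop"):
            raise ValueError("threshold_on must be 'winner' or 'true_pop'")


@dataclass
class ReplicateResult:
    """One cross-validation replicate's outcome."""

    replicate_index: int
    n_test: int
    n_correct: int
    degenerate: bool = False

    @property
    def rate(self) -> float:
        return self.n_correct / self.n_test


@dataclass
class CvResult:
    """All replicates for one marker combination, plus their mean rate."""

    combination: tuple[str, ...]
    replicates: list[ReplicateResult] = field(repr=False)

    @property
    def rates(self) -> np.ndarray:
        return np.array([r.rate for r in self.replicates])

    @property
    def mean_rate(self) -> float:
        return float(self.rates.mean())

    @property
    def rate_sd(self) -> float:
        r = self.rates
        return float(r.std(ddof=1)) if len(r) > 1 else 0.0

    @property
    def n_degenerate(self) -> int:
        return sum(r.degenerate for r in self.replicates)


def stratified_split(
    pop_labels, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Split each population into training and test indices.

    Training size per population is ``floor(train_fraction * n)``, clamped
    to ``[2, n - 1]`` so the DAPC stays fittable and the test set non-empty.
    Populations with fewer than 3 members cannot satisfy both and raise.
    """
    labels = np.asarray(pop_labels)
    train: list[np.ndarray] = []
    test: list[np.ndarray] = []
    for pop in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == pop)
        n = len(idx)
        if n < 3:
            raise ValueError(
                f"population {pop!r} has {n} individual(s); >= 3 required for a "
                "train/test split"
            )
        n_train = min(max(int(np.floor(train_fraction * n)), 2), n - 1)
        perm = rng.permutation(idx)
        train.append(perm[:n_train])
        test.append(perm[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def replicate_seed(base_seed: int, combination, replicate_index: int) -> int:
    """Deterministic 32-bit seed for (base_seed, combination, replicate).

    Stable across processes and Python hash randomization, so exhaustive
    sweeps are reproducible under any parallel schedule.
    """
    key = f"{base_seed}|{'|'.join(sorted(map(str, combination)))}|{replicate_index}"
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little")


def cv_replicate(
    gset: GenotypeSet, config: CvConfig, rng: np.random.Generator,
    replicate_index: int = 0, counts=None,
) -> ReplicateResult:
    """One split-fit-assign-score replicate on a (restricted) genotype set.

    A degenerate DAPC fit (e.g. the combination is monomorphic in the
    training sample) scores every test individual as incorrect and records
    a :class:`DegenerateFitWarning` instead of raising, so exhaustive
    sweeps never abort on uninformative combinations.  ``counts`` lets the
    caller reuse one allele-count expansion across replicates.
    """
    train_idx, test_idx = stratified_split(
        gset.pop_labels, config.train_fraction, rng
    )
    if counts is None:
        counts = to_allele_counts(gset)
    labels = np.asarray(gset.pop_labels)
    train = counts.rows(train_idx)
    test = counts.rows(test_idx)
    n_test = len(test_idx)

    try:
        # Training means come from non-missing training entries and are
        # reused for the test matrix.
        present = ~train.missing_mask
        n_present = present.sum(axis=0)
        if np.any(n_present == 0):
            raise DegenerateFitError(
                "a column has no non-missing training entries"
            )
        train_means = np.where(train.missing_mask, 0.0, train.values).sum(
            axis=0
        ) / n_present
        train_full = impute_missing(train, column_means=train_means)
        test_full = impute_missing(test, column_means=train_means)
        model = fit_dapc(
            train_full,
            labels[train_idx],
            n_pca=config.n_pca,
            scale=config.scale,
        )
        outcome = predict_assignments(model, test_full)
    except DegenerateFitError as exc:
        warnings.warn(
            f"replicate {replicate_index}: degenerate fit ({exc}); "
            "all test individuals scored incorrect",
            DegenerateFitWarning,
            stacklevel=2,
        )
        return ReplicateResult(replicate_index, n_test, 0, degenerate=True)

    true_labels = labels[test_idx]
    argmax_ok = np.array(
        [a == t for a, t in zip(outcome.assigned_label, true_labels)]
    )
    if config.threshold_on == "winner":
        thresh_ok = outcome.max_posterior >= config.assignment_threshold
    else:
        label_pos = {g: k for k, g in enumerate(outcome.group_labels)}
        true_post = outcome.posterior[
            np.arange(n_test), [label_pos[t] for t in true_labels]
        ]
        thresh_ok = true_post >= config.assignment_threshold
    n_correct = int(np.sum(argmax_ok & thresh_ok))
    return ReplicateResult(replicate_index, n_test, n_correct)


def run_cv(
    gset: GenotypeSet, combination, config: CvConfig
) -> CvResult:
    """Run all replicates for one marker combination and average the rates.

    Each replicate draws its own RNG from the deterministic seeding
    contract, so the result is independent of execution order.
    """
    combination = tuple(sorted(map(str, combination)))
    sub = subset_loci(gset, list(combination))
    counts = to_allele_counts(sub)
    replicates = []
    for r in range(config.n_replicates):
        rng = np.random.default_rng(
            replicate_seed(config.base_seed, combination, r)
        )
        replicates.append(
            cv_replicate(sub, config, rng, replicate_index=r, counts=counts)
        )
    return CvResult(combination=combination, replicates=replicates)
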