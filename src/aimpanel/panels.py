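"""Exhaustive marker-combination search over a range of panel sizes.

Every combination of every panel size in the requested range is scored by
repeated cross-validation; rates are then aggregated per combination, per
panel size (the unweighted mean over that size's combinations), and per
marker (either the marker's singleton rate, or its marginal mean over all
evaluated combinations containing it).

Combinations are independent work units under the deterministic seeding
contract of :mod:`aimpanel.crossval`, so serial and parallel execution give
bit-identical results.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats

from .crossval import CvConfig, run_cv
from .genotypes import GenotypeSet

__all__ = [
    "PanelResult",
    "SizeSummary",
    "CombinationCapExceeded",
    "enumerate_combinations",
    "count_combinations",
    "evaluate_panel_range",
    "marker_rates",
    "compare_size_groups",
    "results_frame",
    "sizes_frame",
]


class CombinationCapExceeded(RuntimeError):
    """The requested sweep exceeds the combination cap and was not
    explicitly confirmed."""


@dataclass
class PanelResult:
    """One marker combination's cross-validated assignment rates."""

    combination: tuple[str, ...]
    replicate_rates: np.ndarray
    n_degenerate: int = 0

    @property
    def panel_size(self) -> int:
        return len(self.combination)

    @property
    def mean_rate(self) -> float:
        return float(np.mean(self.replicate_rates))

    @property
    def rate_sd(self) -> float:
        r = np.asarray(self.replicate_rates)
        return float(r.std(ddof=1)) if r.size > 1 else 0.0


@dataclass
class SizeSummary:
    """Aggregate over all combinations of one panel size."""

    panel_size: int
    n_combinations: int
    mean_rate: float
    combination_rate_sd: float


def enumerate_combinations(markers, size: int):
    """All C(n, size) marker combinations, in lexicographic index order."""
    markers = list(markers)
    if not 1 <= size <= len(markers):
        raise ValueError(
            f"panel size {size} out of range [1, {len(markers)}]"
        )
    return itertools.combinations(markers, size)


def count_combinations(n_markers: int, min_size: int, max_size: int) -> dict[int, int]:
    """Closed-form combination counts per size for a sweep plan."""
    return {k: comb(n_markers, k) for k in range(min_size, max_size + 1)}


def _evaluate_one(gset: GenotypeSet, combination, config: CvConfig) -> PanelResult:
    cv = run_cv(gset, combination, config)
    return PanelResult(
        combination=cv.combination,
        replicate_rates=cv.rates,
        n_degenerate=cv.n_degenerate,
    )


def evaluate_panel_range(
    gset: GenotypeSet,
    min_size: int,
    max_size: int,
    config: CvConfig,
    combination_cap: int = 100_000,
    override_cap: bool = False,
    n_jobs: int = 1,
) -> tuple[list[PanelResult], list[SizeSummary]]:
    """Score every combination of every panel size in [min_size, max_size].

    Refuses to start when the total combination count exceeds
    ``combination_cap`` unless ``override_cap`` is set.  ``n_jobs`` controls
    wall-clock only; the per-combination seeding contract makes results
    identical for any worker count.
    """
    n_markers = gset.n_loci
    if not 1 <= min_size <= max_size <= n_markers:
        raise ValueError(
            f"invalid size range [{min_size}, {max_size}] for {n_markers} markers"
        )
    plan = count_combinations(n_markers, min_size, max_size)
    total = sum(plan.values())
    if total > combination_cap and not override_cap:
        raise CombinationCapExceeded(
            f"{total} combinations requested (sizes {min_size}-{max_size} of "
            f"{n_markers} markers) exceed the cap of {combination_cap}; "
            "pass override_cap=True to proceed"
        )

    combos = [
        c
        for size in range(min_size, max_size + 1)
        for c in enumerate_combinations(gset.locus_names, size)
    ]
    if n_jobs == 1:
        results = [_evaluate_one(gset, c, config) for c in combos]
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(_evaluate_one)(gset, c, config) for c in combos
        )

    summaries = []
    for size in range(min_size, max_size + 1):
        rates = np.array([r.mean_rate for r in results if r.panel_size == size])
        summaries.append(
            SizeSummary(
                panel_size=size,
                n_combinations=len(rates),
                mean_rate=float(rates.mean()),
                combination_rate_sd=float(rates.std(ddof=1)) if rates.size > 1 else 0.0,
            )
        )
    return results, summaries


def marker_rates(results: list[PanelResult], mode: str = "singleton") -> pd.Series:
    """Per-marker assignment rate.

    ``singleton``: each marker's own size-1 mean rate.  ``marginal``: for
    each marker, the mean of mean rates over all evaluated combinations
    containing it (every panel size pooled, unweighted).
    """
    if not results:
        raise ValueError("no panel results supplied")
    if mode == "singleton":
        singles = {r.combination[0]: r.mean_rate for r in results if r.panel_size == 1}
        if not singles:
            raise ValueError("singleton mode requires size-1 results")
        return pd.Series(singles, name="rate").sort_index()
    if mode == "marginal":
        acc: dict[str, list[float]] = {}
        for r in results:
            for m in r.combination:
                acc.setdefault(m, []).append(r.mean_rate)
        return pd.Series(
            {m: float(np.mean(v)) for m, v in acc.items()}, name="rate"
        ).sort_index()
    raise ValueError("mode must be 'singleton' or 'marginal'")


def compare_size_groups(
    rates_a, rates_b, equal_var: bool = False
) -> tuple[float, float]:
    """Two-sample t-test on combination-level mean rates.

    Welch's unequal-variance form by default; ``equal_var=True`` gives the
    classical Student variant.  Degenerate zero-variance groups fall back
    to an exact rule: equal means -> (0, 1), different means -> (inf, 0).
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 combination rates")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def results_frame(results: list[PanelResult]) -> pd.DataFrame:
    """Per-combination table with stable columns."""
    return pd.DataFrame(
        {
            "combination": ["+".join(r.combination) for r in results],
            "panel_size": [r.panel_size for r in results],
            "mean_rate": [r.mean_rate for r in results],
            "rate_sd": [r.rate_sd for r in results],
            "n_replicates": [len(r.replicate_rates) for r in results],
            "n_degenerate": [r.n_degenerate for r in results],
        }
    )


def sizes_frame(summaries: list[SizeSummary]) -> pd.DataFrame:
    """Per-panel-size table with stable columns."""
    return pd.DataFrame(
        {
            "panel_size": [s.panel_size for s in summaries],
            "n_combinations": [s.n_combinations for s in summaries],
            "mean_rate": [s.mean_rate for s in summaries],
            "combination_rate_sd": [s.combination_rate_sd for s in summaries],
        }
    )
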