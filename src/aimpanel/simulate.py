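"""Balding-Nichols population simulation and Weir-Cockerham FST estimation.

The generator produces subdivided diploid populations at a target level of
differentiation: each locus draws an ancestral allele frequency p uniformly
on a configurable range, each subpopulation then draws its own frequency
from Beta(p(1-F)/F, (1-p)(1-F)/F) — the Balding-Nichols model, whose
frequency variance among subpopulations equals F * p(1-p) — and individuals
are formed from two independent allele copies at the subpopulation
frequency (Hardy-Weinberg within subpopulations, free recombination between
loci).  F = 0 degenerates to identical subpopulation frequencies.

Differentiation is estimated with the Weir & Cockerham (1984) variance
components: per locus and allele, `a` (among populations), `b` (among
individuals within populations) and `c` (within individuals) are formed
from sample sizes, allele frequencies and observed heterozygote
proportions; theta = a / (a + b + c).  The multilocus estimate is the
ratio of summed components over loci (never a mean of per-locus ratios),
and negative per-locus values are reported as computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeSet

__all__ = [
    "SimConfig",
    "FstEstimate",
    "simulate_populations",
    "weir_cockerham_fst",
    "fst_report_frame",
]


@dataclass(frozen=True)
class SimConfig:
    """Balding-Nichols generator parameters.

    n_subpops : number of subpopulations (>= 2).
    n_per_subpop : individuals per subpopulation (int, or one int per
        subpopulation); each must be >= 3 so downstream splits work.
    n_loci : number of unlinked biallelic loci.
    fst : target differentiation F in [0, 1).
    ancestral_freq_range : uniform support for the ancestral frequency;
        the (0.1, 0.9) default avoids near-fixed loci that make weakly
        differentiated datasets uninformative.
    seed : RNG seed; the dataset is fully reproducible from it.
    """

    n_subpops: int = 2
    n_per_subpop: int | tuple[int, ...] = 1000
    n_loci: int = 15
    fst: float = 0.10
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    seed: int = 0

    def sizes(self) -> list[int]:
        if isinstance(self.n_per_subpop, int):
            return [self.n_per_subpop] * self.n_subpops
        sizes = list(self.n_per_subpop)
        if len(sizes) != self.n_subpops:
            raise ValueError("n_per_subpop list length must equal n_subpops")
        return sizes

    def __post_init__(self) -> None:
        if self.n_subpops < 2:
            raise ValueError("n_subpops must be >= 2")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        low, high = self.ancestral_freq_range
        if not 0.0 < low < high < 1.0:
            raise ValueError("ancestral_freq_range must satisfy 0 < low < high < 1")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if any(s < 3 for s in self.sizes()):
            raise ValueError("every subpopulation needs >= 3 individuals")


@dataclass
class FstEstimate:
    """Weir-Cockerham variance components and theta estimates.

    per_locus_components holds (a, b, c) per locus (summed over alleles);
    per_locus_fst is a/(a+b+c), NaN where the locus is monomorphic;
    multilocus_fst is the ratio of summed components.
    """

    locus_names: list[str]
    per_locus_components: np.ndarray  # (n_loci, 3)
    per_locus_fst: np.ndarray         # (n_loci,), NaN where undefined
    multilocus_fst: float


def simulate_populations(config: SimConfig) -> GenotypeSet:
    """Draw one subdivided diploid dataset at the configured target FST.

    Allele codes are {1, 2}; individuals are labelled ``pop_1 .. pop_K``.
    """
    rng = np.random.default_rng(config.seed)
    sizes = config.sizes()
    K, L, F = config.n_subpops, config.n_loci, config.fst
    low, high = config.ancestral_freq_range
    p_anc = rng.uniform(low, high, size=L)

    if F == 0.0:
        p_sub = np.broadcast_to(p_anc, (K, L)).copy()
    else:
        shape = (1.0 - F) / F
        p_sub = rng.beta(p_anc * shape, (1.0 - p_anc) * shape, size=(K, L))

    blocks = []
    pop_labels: list[str] = []
    ids: list[str] = []
    for k in range(K):
        n_k = sizes[k]
        # Two independent allele copies per individual at the subpopulation
        # frequency; code 2 carries the frequency being tracked.
        draws = rng.random(size=(n_k, L, 2)) < p_sub[k][None, :, None]
        blocks.append(np.where(draws, 2, 1))
        pop_labels += [f"pop_{k + 1}"] * n_k
        ids += [f"pop{k + 1}_ind{i + 1:04d}" for i in range(n_k)]
    calls = np.concatenate(blocks, axis=0)
    locus_names = [f"locus_{j + 1}" for j in range(L)]
    return GenotypeSet(ids, pop_labels, locus_names, calls)


def weir_cockerham_fst(gset: GenotypeSet) -> FstEstimate:
    """Weir-Cockerham (1984) FST from a genotype set with >= 2 populations.

    Handles missing data through per-locus per-population sample sizes and
    multiallelic loci by summing per-allele components.  Raises when every
    locus is monomorphic.
    """
    pops = gset.populations
    r_all = len(pops)
    if r_all < 2:
        raise ValueError("at least 2 populations are required")
    pop_idx = {p: np.flatnonzero(np.asarray(gset.pop_labels) == p) for p in pops}

    L = gset.n_loci
    components = np.zeros((L, 3))
    per_locus = np.full(L, np.nan)
    for j in range(L):
        calls = gset.calls[:, j, :]
        miss = np.any(calls == gset.missing_code, axis=1)
        n_i, p_i, h_i, alleles = [], [], [], gset.allele_registry[j]
        for p in pops:
            rows = pop_idx[p]
            ok = rows[~miss[rows]]
            if ok.size == 0:
                continue
            g = calls[ok]
            n_i.append(ok.size)
            p_i.append([(g == a).sum() / (2 * ok.size) for a in alleles])
            h_i.append(
                [np.mean((g == a).sum(axis=1) == 1) for a in alleles]
            )
        r = len(n_i)
        if r < 2 or len(alleles) < 2:
            continue  # monomorphic or insufficient data: flagged NaN
        n_i = np.asarray(n_i, dtype=float)
        p_i = np.asarray(p_i, dtype=float)  # (r, n_alleles)
        h_i = np.asarray(h_i, dtype=float)

        n_bar = n_i.mean()
        n_c = (n_i.sum() - (n_i**2).sum() / n_i.sum()) / (r - 1)
        a_sum = b_sum = c_sum = 0.0
        for m in range(len(alleles)):
            p_bar = (n_i * p_i[:, m]).sum() / n_i.sum()
            s2 = (n_i * (p_i[:, m] - p_bar) ** 2).sum() / ((r - 1) * n_bar)
            h_bar = (n_i * h_i[:, m]).sum() / n_i.sum()
            a = (n_bar / n_c) * (
                s2
                - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4)
                / (n_bar - 1)
            )
            b = (n_bar / (n_bar - 1)) * (
                p_bar * (1 - p_bar)
                - (r - 1) / r * s2
                - (2 * n_bar - 1) / (4 * n_bar) * h_bar
            )
            c = h_bar / 2
            a_sum += a
            b_sum += b
            c_sum += c
        components[j] = (a_sum, b_sum, c_sum)
        denom = a_sum + b_sum + c_sum
        if denom != 0.0:
            per_locus[j] = a_sum / denom

    if np.all(np.isnan(per_locus)):
        raise ValueError("all loci are monomorphic; FST is undefined")
    total = components.sum(axis=0)
    multilocus = float(total[0] / total.sum())
    return FstEstimate(
        locus_names=list(gset.locus_names),
        per_locus_components=components,
        per_locus_fst=per_locus,
        multilocus_fst=multilocus,
    )


def fst_report_frame(est: FstEstimate) -> pd.DataFrame:
    """Per-locus component table plus a multilocus row."""
    df = pd.DataFrame(
        {
            "locus": est.locus_names,
            "a": est.per_locus_components[:, 0],
            "b": est.per_locus_components[:, 1],
            "c": est.per_locus_components[:, 2],
            "fst": est.per_locus_fst,
        }
    )
    total = est.per_locus_components.sum(axis=0)
    df.loc[len(df)] = ["MULTILOCUS", *total, est.multilocus_fst]
    return df
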