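"""Per-population diversity statistics and exact binomial intervals.

Statistics follow the standard estimators of molecular population genetics:

* haplotype (gene) diversity ``H = n/(n-1) * (1 - sum p_i^2)`` with Nei's
  sampling variance,
* nucleotide diversity ``pi`` as the mean pairwise difference per site with
  its total sampling variance,
* segregating-site counts,
* haplotype-sharing summaries within and between groups of populations,
* exact (Clopper-Pearson) binomial confidence intervals for haplogroup
  frequencies.

The variance formulas are stated in ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
import pandas as pd
from scipy.stats import beta

from .errors import MetadataError
from .seqdata import Alignment, HaplotypeTable, SampleRecord, pairwise_diff_matrix


@dataclass
class DiversityStats:
    population: str
    N: int
    n_hap: int
    S: int
    seq_div: float
    seq_div_sd: float
    pi: float
    pi_sd: float


@dataclass
class BinomialCI:
    k: int
    n: int
    level: float
    lower: float
    upper: float


@dataclass
class SharingSummary:
    groups: list[str]
    shared_within: dict[str, int]
    shared_between: dict[tuple[str, str], int]
    totals: dict[str, int]
    mode: str

    def to_json_dict(self) -> dict:
        return {
            "mode": self.mode,
            "groups": self.groups,
            "totals": self.totals,
            "shared_within": self.shared_within,
            "shared_between": {
                f"{a}|{b}": v for (a, b), v in self.shared_between.items()
            },
        }


def haplotype_diversity(counts) -> tuple[float, float]:
    """Gene diversity H and its standard deviation from haplotype counts.

    ``H = n/(n-1) * (1 - sum p_i^2)``; the variance is Nei's (1987)
    estimator
    ``V = 2/(n(n-1)) * [2(n-2)(sum p^3 - (sum p^2)^2) + sum p^2 - (sum p^2)^2]``.
    """
    counts = np.asarray(list(counts), dtype=float)
    if np.any(counts <= 0) or np.any(counts != np.floor(counts)):
        raise ValueError("haplotype counts must be positive integers")
    n = counts.sum()
    if n < 2:
        raise ValueError("gene diversity is undefined for n < 2")
    p = counts / n
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    h = n / (n - 1.0) * (1.0 - s2)
    v = 2.0 / (n * (n - 1.0)) * (2.0 * (n - 2.0) * (s3 - s2**2) + s2 - s2**2)
    return float(h), sqrt(max(v, 0.0))


def nucleotide_diversity(aln: Alignment, L: float | None = None) -> tuple[float, float]:
    """Nucleotide diversity per site and its standard deviation.

    ``pi`` is the mean number of pairwise differences divided by ``L``
    (default: the current column count).  The SD is the square root of the
    total sampling variance
    ``V(pi) = (n+1)/(3(n-1)L) * pi + 2(n^2+n+3)/(9n(n-1)) * pi^2``
    (stochastic plus sampling components, no-recombination case — the form
    appropriate for mtDNA).
    """
    if L is None:
        L = aln.n_columns
    if L <= 0:
        raise ValueError("comparable length L must be positive")
    n = aln.n_samples
    if n < 2:
        raise ValueError("nucleotide diversity needs at least two sequences")
    d = pairwise_diff_matrix(aln).condensed()
    pi = float(d.mean()) / L
    v = (n + 1.0) / (3.0 * (n - 1.0) * L) * pi + (
        2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    ) * pi**2
    return pi, sqrt(max(v, 0.0))


def segregating_sites(aln: Alignment) -> int:
    """Number of columns with at least two distinct non-missing bases."""
    s = 0
    for c in range(aln.n_columns):
        col = aln.bases[:, c]
        obs = {b for b in col if b in "ACGT"}
        if len(obs) >= 2:
            s += 1
    return s


def diversity_table(
    aln: Alignment,
    meta: list[SampleRecord],
    L: float | None = None,
) -> pd.DataFrame:
    """Per-population diversity summary (one row per population)."""
    pop_of = {r.sample_id: r.population for r in meta}
    missing = [s for s in aln.sample_ids if s not in pop_of]
    if missing:
        raise MetadataError(f"samples without metadata: {missing}")
    rows = []
    for pop in sorted({pop_of[s] for s in aln.sample_ids}):
        idx = [i for i, s in enumerate(aln.sample_ids) if pop_of[s] == pop]
        sub = Alignment(
            [aln.sample_ids[i] for i in idx], aln.bases[idx], aln.coord_map.copy()
        )
        hap_counts = pd.Series(sub.sequences()).value_counts()
        h, h_sd = haplotype_diversity(hap_counts.to_numpy())
        pi, pi_sd = nucleotide_diversity(sub, L=L)
        rows.append(
            DiversityStats(
                population=pop,
                N=len(idx),
                n_hap=int(hap_counts.size),
                S=segregating_sites(sub),
                seq_div=h,
                seq_div_sd=h_sd,
                pi=pi,
                pi_sd=pi_sd,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def sharing_summary(
    ht: HaplotypeTable,
    grouping: dict[str, str],
    mode: str = "between_populations",
) -> SharingSummary:
    """Count haplotypes shared within and between groups of populations.

    ``mode="between_populations"``: a haplotype is shared within group G if
    present in >=2 distinct populations of G.  ``mode="between_individuals"``:
    shared within G if carried by >=2 individuals of G irrespective of
    population.  In both modes a haplotype is shared between two groups if
    present in at least one population of each, and a group's total is the
    number of haplotypes present in >=1 of its populations.
    """
    if mode not in ("between_populations", "between_individuals"):
        raise ValueError(f"unknown sharing mode {mode!r}")
    unknown = [p for p in ht.counts.columns if p not in grouping]
    if unknown:
        raise MetadataError(f"populations not mapped to a group: {unknown}")
    groups = sorted(set(grouping.values()))
    pops_of_group = {g: [p for p in ht.counts.columns if grouping[p] == g] for g in groups}

    presence = ht.counts > 0
    totals = {
        g: int(presence[pops_of_group[g]].any(axis=1).sum()) for g in groups
    }
    shared_within: dict[str, int] = {}
    for g in groups:
        sub = ht.counts[pops_of_group[g]]
        if mode == "between_populations":
            shared_within[g] = int(((sub > 0).sum(axis=1) >= 2).sum())
        else:
            shared_within[g] = int((sub.sum(axis=1) >= 2).sum())
    shared_between: dict[tuple[str, str], int] = {}
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            in_a = presence[pops_of_group[a]].any(axis=1)
            in_b = presence[pops_of_group[b]].any(axis=1)
            shared_between[(a, b)] = int((in_a & in_b).sum())
    return SharingSummary(
        groups=groups,
        shared_within=shared_within,
        shared_between=shared_between,
        totals=totals,
        mode=mode,
    )


def clopper_pearson_ci(k: int, n: int, level: float = 0.95) -> BinomialCI:
    """Exact binomial confidence interval via beta quantiles.

    Boundary conventions: ``k=0`` gives lower bound 0 and ``k=n`` gives
    upper bound 1.
    """
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"invalid binomial data k={k}, n={n}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"invalid confidence level {level}")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(beta.ppf(alpha / 2.0, k, n - k + 1))
    upper = 1.0 if k == n else float(beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return BinomialCI(k=int(k), n=int(n), level=level, lower=lower, upper=upper)
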