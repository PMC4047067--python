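"""Drift-resampling test of shared ancestry for a focal haplogroup.

The model: an ancestral population of ``ne_ancestral`` individuals carries a
focal haplogroup (or single haplotype) at a chosen initial frequency.  It is
partitioned at random into two daughter populations of ``ne_daughter``
individuals each, which then evolve independently by Wright-Fisher
resampling (constant size, sampling parents with replacement) for
``split_years / generation_years`` generations.  After the final generation,
samples of the study sizes are drawn repeatedly from each daughter and the
probability that both sample frequencies fall simultaneously inside the two
populations' observed confidence intervals is recorded; the outer loop
repeats the whole history and the grand mean is reported.

The per-generation update on the marked count is a binomial draw — exactly
equivalent in distribution to resampling individuals with replacement, but
O(1) per generation.  A literal per-individual mode
(:func:`simulate_split_individuals`) is kept as a validation oracle.

Mutation of the focal haplotype (used when tracking a single shared
haplotype rather than a whole haplogroup) can be modelled two ways:

* ``mutation_model="event"`` (default): each generation, each daughter
  loses one marked carrier with probability ``generation_years /
  mutation_interval_years`` — a single mutation event at the stated rate.
* ``mutation_model="lineage"``: every marked lineage independently loses
  the mark each generation with that probability (a much stronger decay;
  retained for comparison — see docs/methods.md for why "event" is the
  default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError

MUTATION_MODELS = ("event", "lineage")
SAMPLING_MODES = ("hypergeometric", "binomial")


@dataclass
class Scenario:
    """Full parameterization of one drift-resampling test."""

    sample_size_1: int
    sample_size_2: int
    target_ci_1: tuple[float, float]
    target_ci_2: tuple[float, float]
    ne_ancestral: int = 2000
    ne_daughter: int = 1000
    generation_years: int = 25
    split_years: int = 500
    mutation_interval_years: float | None = None
    mutation_model: str = "event"
    final_sampling: str = "hypergeometric"
    n_outer: int = 10000
    n_inner: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        for lo, hi in (self.target_ci_1, self.target_ci_2):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigError(f"invalid target CI ({lo}, {hi})")
        if self.sample_size_1 > self.ne_daughter or self.sample_size_2 > self.ne_daughter:
            raise ConfigError("sample sizes cannot exceed the daughter population size")
        if self.ne_daughter * 2 > self.ne_ancestral:
            raise ConfigError(
                "two daughters of ne_daughter cannot be partitioned from ne_ancestral"
            )
        if self.mutation_model not in MUTATION_MODELS:
            raise ConfigError(f"unknown mutation model {self.mutation_model!r}")
        if self.final_sampling not in SAMPLING_MODES:
            raise ConfigError(f"unknown final sampling mode {self.final_sampling!r}")
        if self.mutation_interval_years is not None and (
            self.mutation_interval_years <= 0
        ):
            raise ConfigError("mutation interval must be positive")

    @property
    def n_generations(self) -> int:
        if self.split_years % self.generation_years != 0:
            raise ConfigError(
                f"split time {self.split_years} y is not a whole number of "
                f"{self.generation_years}-y generations"
            )
        return self.split_years // self.generation_years

    @property
    def mutation_prob(self) -> float:
        if self.mutation_interval_years is None:
            return 0.0
        return self.generation_years / self.mutation_interval_years

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["target_ci_1"] = list(self.target_ci_1)
        d["target_ci_2"] = list(self.target_ci_2)
        return d


@dataclass
class GridResult:
    """Probability grid over initial frequencies and split times."""

    initial_frequencies: list[float]
    split_years_list: list[int]
    probabilities: np.ndarray  # (n_splits, n_freqs)
    mc_standard_errors: np.ndarray
    scenario: Scenario
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.probabilities,
            index=[f"{y} ya" for y in self.split_years_list],
            columns=[f"{f:g}" for f in self.initial_frequencies],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="split")

    def write_json(self, path) -> None:
        payload = {
            "initial_frequencies": self.initial_frequencies,
            "split_years": self.split_years_list,
            "probabilities": self.probabilities.tolist(),
            "mc_standard_errors": self.mc_standard_errors.tolist(),
            "scenario": self.scenario.to_dict(),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def simulate_split(
    initial_freq: float,
    sc: Scenario,
    rng: np.random.Generator,
    size: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Final frequencies of the focal mark in the two daughters.

    Vectorized over ``size`` independent replicate histories; returns two
    arrays of population frequencies.
    """
    if not 0.0 <= initial_freq <= 1.0:
        raise ConfigError(f"initial frequency {initial_freq} outside [0, 1]")
    G = sc.n_generations
    ne_a, ne_d = sc.ne_ancestral, sc.ne_daughter
    m0 = int(round(initial_freq * ne_a))
    k1 = rng.hypergeometric(m0, ne_a - m0, ne_d, size=size)
    k2 = np.full(size, m0) - k1
    # the second daughter draws from the remaining ne_a - ne_d individuals
    if ne_a - ne_d > ne_d:
        k2 = rng.hypergeometric(k2, (ne_a - ne_d) - k2, ne_d, size=size)
    mu = sc.mutation_prob
    for _ in range(G):
        k1 = rng.binomial(ne_d, k1 / ne_d)
        k2 = rng.binomial(ne_d, k2 / ne_d)
        if mu > 0.0:
            if sc.mutation_model == "lineage":
                k1 = rng.binomial(k1, 1.0 - mu)
                k2 = rng.binomial(k2, 1.0 - mu)
            else:  # one mutation event per population per generation at rate mu
                k1 = np.maximum(k1 - rng.binomial(1, mu, size=size), 0)
                k2 = np.maximum(k2 - rng.binomial(1, mu, size=size), 0)
    return k1 / ne_d, k2 / ne_d


def simulate_split_individuals(
    initial_freq: float,
    sc: Scenario,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Per-individual validation oracle for :func:`simulate_split`.

    Tracks an explicit boolean mark per individual, draws parents with
    replacement each generation, and applies per-lineage mutation when the
    lineage model is selected.  One replicate per call; intended for small
    population sizes.
    """
    ne_a, ne_d = sc.ne_ancestral, sc.ne_daughter
    G = sc.n_generations
    m0 = int(round(initial_freq * ne_a))
    ancestor = np.zeros(ne_a, dtype=bool)
    ancestor[:m0] = True
    order = rng.permutation(ne_a)
    pop1 = ancestor[order[:ne_d]]
    pop2 = ancestor[order[ne_d : 2 * ne_d]]
    mu = sc.mutation_prob
    for _ in range(G):
        pop1 = pop1[rng.integers(0, ne_d, size=ne_d)]
        pop2 = pop2[rng.integers(0, ne_d, size=ne_d)]
        if mu > 0.0:
            if sc.mutation_model == "lineage":
                pop1 &= rng.random(ne_d) >= mu
                pop2 &= rng.random(ne_d) >= mu
            else:
                for pop in (pop1, pop2):
                    if rng.random() < mu:
                        marked = np.flatnonzero(pop)
                        if marked.size:
                            pop[rng.choice(marked)] = False
    return pop1.mean(), pop2.mean()


def _sample_freqs(
    k: np.ndarray, sc: Scenario, n_sample: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_inner, n_outer) sample frequencies drawn from daughter states k."""
    ne = sc.ne_daughter
    if sc.final_sampling == "hypergeometric":
        draws = rng.hypergeometric(
            k[None, :], ne - k[None, :], n_sample, size=(sc.n_inner, k.size)
        )
    else:
        draws = rng.binomial(n_sample, (k / ne)[None, :], size=(sc.n_inner, k.size))
    return draws / n_sample


def joint_ci_probability(
    initial_freq: float,
    sc: Scenario,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Mean probability that both sample frequencies fall inside their CIs.

    For each of ``n_outer`` replicate histories, ``n_inner`` samples of the
    study sizes are drawn from each daughter (without replacement by
    default) and the inner score is the fraction of draws where sample
    frequency 1 lies in ``target_ci_1`` AND sample frequency 2 lies in
    ``target_ci_2`` (inclusive endpoints).  Returns the mean inner score
    and its Monte-Carlo standard error over replicates.
    """
    if rng is None:
        rng = np.random.default_rng(sc.seed)
    f1, f2 = simulate_split(initial_freq, sc, rng, size=sc.n_outer)
    k1 = np.round(f1 * sc.ne_daughter).astype(np.int64)
    k2 = np.round(f2 * sc.ne_daughter).astype(np.int64)
    s1 = _sample_freqs(k1, sc, sc.sample_size_1, rng)
    s2 = _sample_freqs(k2, sc, sc.sample_size_2, rng)
    (lo1, hi1), (lo2, hi2) = sc.target_ci_1, sc.target_ci_2
    inside = (s1 >= lo1) & (s1 <= hi1) & (s2 >= lo2) & (s2 <= hi2)
    scores = inside.mean(axis=0)
    prob = float(scores.mean())
    se = float(scores.std(ddof=1) / np.sqrt(sc.n_outer)) if sc.n_outer > 1 else 0.0
    return prob, se


def run_grid(
    frequencies: list[float],
    split_years_list: list[int],
    sc: Scenario,
) -> GridResult:
    """Fill the probability matrix over initial frequencies and split times.

    Each cell re-runs :func:`joint_ci_probability` under a child RNG stream
    spawned deterministically from the scenario seed, so the same seed
    yields a bit-identical grid.
    """
    if not frequencies or not split_years_list:
        raise ConfigError("frequency and split lists must be non-empty")
    probs = np.zeros((len(split_years_list), len(frequencies)))
    ses = np.zeros_like(probs)
    root = np.random.default_rng(sc.seed)
    streams = root.spawn(len(split_years_list) * len(frequencies))
    for i, years in enumerate(split_years_list):
        cell_sc = replace(sc, split_years=int(years))
        for j, f in enumerate(frequencies):
            rng = streams[i * len(frequencies) + j]
            probs[i, j], ses[i, j] = joint_ci_probability(f, cell_sc, rng)
    return GridResult(
        initial_frequencies=[float(f) for f in frequencies],
        split_years_list=[int(y) for y in split_years_list],
        probabilities=probs,
        mc_standard_errors=ses,
        scenario=sc,
        seed=sc.seed,
    )


# ---------------------------------------------------------------------------
# Named presets: the four published scenarios for the Himba/Herero (HH),
# Damara, and Kuvale comparisons.  Confidence intervals are the printed 95%
# bounds for the observed haplogroup/haplotype frequencies:
#   a: shared L3d haplotype, HH 24% of 51 (CI 13-37%) vs Damara 32% of 38
#      (CI 18-49%), with one mutation event per 3533 years;
#   b: L3f retained in HH (31% of 51, CI 19-46%) and lost in Damara
#      (0 of 38, CI 0-9%);
#   c: L3f retained in HH (CI 19-46%) and at low frequency in Kuvale
#      (5.7% of 53, CI 1-16%);
#   d: L3d retained in HH (43% of 51, CI 29-58%) and lost in Kuvale
#      (0 of 53, CI 0-7%).
# ---------------------------------------------------------------------------

_FREQS_A = [round(0.09 + 0.04 * i, 2) for i in range(13)]
_FREQS_BCD = [0.01, 0.05, 0.09, 0.13, 0.17, 0.21, 0.25, 0.29, 0.32, 0.34, 0.36, 0.38, 0.40]

PRESETS: dict[str, dict] = {
    "a": {
        "scenario": dict(
            sample_size_1=51,
            sample_size_2=38,
            target_ci_1=(0.13, 0.37),
            target_ci_2=(0.18, 0.49),
            mutation_interval_years=3533.0,
        ),
        "frequencies": _FREQS_A,
    },
    "b": {
        "scenario": dict(
            sample_size_1=51,
            sample_size_2=38,
            target_ci_1=(0.19, 0.46),
            target_ci_2=(0.00, 0.09),
        ),
        "frequencies": _FREQS_BCD,
    },
    "c": {
        "scenario": dict(
            sample_size_1=51,
            sample_size_2=53,
            target_ci_1=(0.19, 0.46),
            target_ci_2=(0.01, 0.16),
        ),
        "frequencies": _FREQS_BCD,
    },
    "d": {
        "scenario": dict(
            sample_size_1=51,
            sample_size_2=53,
            target_ci_1=(0.29, 0.58),
            target_ci_2=(0.00, 0.07),
        ),
        "frequencies": _FREQS_BCD,
    },
}

SPLIT_YEARS_DEFAULT = [500, 1000, 2000]


def preset_scenario(name: str, **overrides) -> tuple[Scenario, list[float]]:
    """Scenario and frequency axis for one of the named presets a-d."""
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = dict(PRESETS[name]["scenario"])
    params.update(overrides)
    return Scenario(**params), list(PRESETS[name]["frequencies"])
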