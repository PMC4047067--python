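"""Synthetic mtDNA-like datasets with known truth for pipeline testing.

The generator emulates the statistical structure the analyses assume:
populations with specified haplogroup-frequency vectors, star-like
haplotype radiation within each haplogroup (founder plus Poisson-many
private mutations per lineage), optional haplotypes forced to be shared
identically across populations, and uniformly injected missing bases.
Mutation placement is infinite-sites (every mutation hits a fresh
position), which keeps pairwise-distance expectations analytic: two
lineages of the same haplogroup differ at ``2 * lambda`` sites on average.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .seqdata import Alignment, SampleRecord

BASES = np.array(list("ACGT"))


@dataclass
class HaplogroupSpec:
    """A haplogroup: founder divergence from the reference and the mean
    number of private mutations per lineage."""

    label: str
    divergence: int = 5
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.divergence < 0 or self.lam < 0:
            raise ConfigError(f"haplogroup {self.label}: negative parameters")


@dataclass
class PopulationSpec:
    name: str
    size: int
    hap_freqs: dict[str, float]
    language_branch: str = "WestBantu"
    subsistence: str = "agriculturalist"
    country: str = ""
    lat: float | None = None
    lon: float | None = None

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ConfigError(f"population {self.name}: size must be >= 2")
        total = sum(self.hap_freqs.values())
        if abs(total - 1.0) > 0.01:
            raise ConfigError(
                f"population {self.name}: haplogroup frequencies sum to {total:.3f}, "
                "not 1"
            )


@dataclass
class SharedHaplotypeSpec:
    """Force an identical haplotype of one haplogroup across populations."""

    haplogroup: str
    populations: list[str]
    frequency: float

    def __post_init__(self) -> None:
        if not 0.0 < self.frequency <= 1.0:
            raise ConfigError("shared-haplotype frequency must be in (0, 1]")


@dataclass
class SimConfig:
    populations: list[PopulationSpec]
    haplogroups: list[HaplogroupSpec]
    shared_haplotypes: list[SharedHaplotypeSpec] = field(default_factory=list)
    length: int = 1000
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing rate must be in [0, 1)")
        labels = {h.label for h in self.haplogroups}
        for p in self.populations:
            unknown = set(p.hap_freqs) - labels
            if unknown:
                raise ConfigError(
                    f"population {p.name} references unknown haplogroups {sorted(unknown)}"
                )
        for s in self.shared_haplotypes:
            if s.haplogroup not in labels:
                raise ConfigError(f"shared haplotype references unknown haplogroup "
                                  f"{s.haplogroup!r}")


@dataclass
class TruthRecord:
    """Ground truth emitted alongside a synthetic dataset."""

    haplogroup_of: dict[str, str]
    haplotype_of: dict[str, str]  # sample -> haplotype key
    mutated_positions: dict[str, list[int]]
    expected_frequencies: dict[str, dict[str, float]]
    reference: str

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "haplogroup_of": self.haplogroup_of,
                    "haplotype_of": self.haplotype_of,
                    "mutated_positions": self.mutated_positions,
                    "expected_frequencies": self.expected_frequencies,
                    "reference": self.reference,
                },
                fh,
                indent=2,
            )


class _PositionPool:
    """Infinite-sites bookkeeping: each mutation consumes a fresh column."""

    def __init__(self, length: int, rng: np.random.Generator) -> None:
        self.free = list(rng.permutation(length))

    def take(self, k: int) -> list[int]:
        if k > len(self.free):
            raise ConfigError(
                "requested mutations exceed available alignment positions; "
                "increase the alignment length"
            )
        out = self.free[:k]
        del self.free[:k]
        return out


def _mutate(seq: np.ndarray, positions: list[int], rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    for pos in positions:
        current = out[pos]
        out[pos] = rng.choice([b for b in BASES if b != current])
    return out


def generate_dataset(
    cfg: SimConfig,
) -> tuple[Alignment, list[SampleRecord], TruthRecord]:
    """Generate an alignment, metadata, and ground truth from a SimConfig.

    Deterministic for a fixed seed: the same config yields byte-identical
    FASTA/TSV output.
    """
    rng = np.random.default_rng(cfg.seed)
    reference = rng.choice(BASES, size=cfg.length)
    pool = _PositionPool(cfg.length, rng)

    founders: dict[str, np.ndarray] = {}
    founder_positions: dict[str, list[int]] = {}
    for hg in cfg.haplogroups:
        positions = pool.take(hg.divergence)
        founders[hg.label] = _mutate(reference, positions, rng)
        founder_positions[hg.label] = positions
    lam_of = {hg.label: hg.lam for hg in cfg.haplogroups}

    # pre-build each forced shared haplotype: founder + 2 tag mutations so
    # distinct shared specs on the same haplogroup stay distinguishable
    shared_seqs: list[np.ndarray] = []
    shared_positions: list[list[int]] = []
    for s in cfg.shared_haplotypes:
        positions = pool.take(2)
        shared_seqs.append(_mutate(founders[s.haplogroup], positions, rng))
        shared_positions.append(founder_positions[s.haplogroup] + positions)

    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    meta: list[SampleRecord] = []
    haplogroup_of: dict[str, str] = {}
    haplotype_of: dict[str, str] = {}
    mutated_positions: dict[str, list[int]] = {}
    expected: dict[str, dict[str, float]] = {}

    for pop in cfg.populations:
        expected[pop.name] = dict(pop.hap_freqs)
        n = pop.size
        # forced shared carriers first
        assignments: list[tuple[str, np.ndarray | None, list[int], str]] = []
        allocated: dict[str, int] = {h: 0 for h in pop.hap_freqs}
        for idx, s in enumerate(cfg.shared_haplotypes):
            if pop.name not in s.populations:
                continue
            k = int(round(s.frequency * n))
            for _ in range(k):
                assignments.append(
                    (s.haplogroup, shared_seqs[idx], shared_positions[idx],
                     f"shared_{idx}")
                )
            allocated[s.haplogroup] = allocated.get(s.haplogroup, 0) + k
        n_free = n - len(assignments)
        if n_free < 0:
            raise ConfigError(
                f"population {pop.name}: shared-haplotype carriers exceed size"
            )
        labels = list(pop.hap_freqs)
        residual = np.array(
            [max(pop.hap_freqs[h] * n - allocated.get(h, 0), 0.0) for h in labels]
        )
        if n_free > 0:
            if residual.sum() <= 0:
                residual = np.array([pop.hap_freqs[h] for h in labels])
            draws = rng.multinomial(n_free, residual / residual.sum())
            for h, count in zip(labels, draws):
                for _ in range(count):
                    assignments.append((h, None, [], ""))

        for j, (hg, forced_seq, forced_pos, tag) in enumerate(assignments):
            sid = f"{pop.name}_{j:03d}"
            if forced_seq is not None:
                seq = forced_seq.copy()
                positions = list(forced_pos)
                hap_key = tag
            else:
                k = int(rng.poisson(lam_of[hg]))
                private = pool.take(k)
                seq = _mutate(founders[hg], private, rng)
                positions = founder_positions[hg] + private
                hap_key = f"{hg}:{sid}" if k else hg
            sample_ids.append(sid)
            rows.append(seq)
            haplogroup_of[sid] = hg
            haplotype_of[sid] = hap_key
            mutated_positions[sid] = sorted(int(p) for p in positions)
            meta.append(
                SampleRecord(
                    sample_id=sid,
                    population=pop.name,
                    country=pop.country,
                    language_branch=pop.language_branch,
                    subsistence=pop.subsistence,
                    haplogroup=hg,
                    lat=pop.lat,
                    lon=pop.lon,
                )
            )

    bases = np.array(rows, dtype="<U1")
    if cfg.missing_rate > 0.0:
        mask = rng.random(bases.shape) < cfg.missing_rate
        bases[mask] = "N"
    aln = Alignment(sample_ids, bases)
    truth = TruthRecord(
        haplogroup_of=haplogroup_of,
        haplotype_of=haplotype_of,
        mutated_positions=mutated_positions,
        expected_frequencies=expected,
        reference="".join(reference),
    )
    return aln, meta, truth


def emulate_study_frequencies(
    table,
    sizes: dict[str, int] | int = 50,
    length: int = 2000,
    divergence: int = 5,
    lam: float = 1.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> SimConfig:
    """Build a SimConfig whose expected haplogroup frequencies match a
    populations x haplogroups frequency table.

    ``table`` is a pandas DataFrame (rows = populations, columns =
    haplogroup labels) or a path to such a TSV.  Rows must sum to 1
    (within 0.01).  Realized sample frequencies then match the table
    within multinomial sampling error.
    """
    import pandas as pd

    if not hasattr(table, "columns"):
        table = pd.read_csv(table, sep="\t", index_col=0)
    bad = [
        str(pop)
        for pop, row in table.iterrows()
        if abs(float(row.sum()) - 1.0) > 0.01
    ]
    if bad:
        raise ConfigError(f"frequency rows do not sum to 1: {bad}")
    haplogroups = [
        HaplogroupSpec(label=str(c), divergence=divergence, lam=lam)
        for c in table.columns
    ]
    populations = []
    for pop, row in table.iterrows():
        size = sizes[str(pop)] if isinstance(sizes, dict) else int(sizes)
        populations.append(
            PopulationSpec(
                name=str(pop),
                size=size,
                hap_freqs={str(c): float(v) for c, v in row.items() if v > 0},
            )
        )
    return SimConfig(
        populations=populations,
        haplogroups=haplogroups,
        length=length,
        missing_rate=missing_rate,
        seed=seed,
    )
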