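"""Alignment curation: reading, masking, imputation, haplotype collapsing.

The central container is :class:`Alignment`, a rectangular matrix of single
characters over ``{A, C, G, T, -, N}`` with a per-column map to 1-based
reference coordinates (rCRS convention for real mtDNA data).  Curation
follows the usual mtDNA workflow: drop unstable reference regions (the
poly-C stretches), drop indel columns, then impute sporadic missing bases
from otherwise-identical sequences before collapsing to haplotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .distance import DistMatrix
from .errors import AlignmentError, MetadataError

VALID_BASES = frozenset("ACGT-N")
NUCLEOTIDES = frozenset("ACGT")

#: coord_map sentinel for columns with no reference position
UNMAPPED = -1

LANGUAGE_BRANCHES = ("WestBantu", "EastBantu", "Khoisan")
SUBSISTENCE_MODES = (
    "agriculturalist",
    "agropastoralist",
    "pastoralist",
    "forager_small_stock",
)


@dataclass
class Alignment:
    """A multiple sequence alignment of equal-length sequences.

    Parameters
    ----------
    sample_ids
        Unique sequence identifiers, one per row.
    bases
        ``(n_samples, n_columns)`` array of dtype ``<U1`` over
        ``{A, C, G, T, -, N}``.
    coord_map
        Integer array of length ``n_columns`` giving the 1-based reference
        position of each column, or :data:`UNMAPPED` for unmapped columns.
        Defaults to ``1..n_columns``.
    """

    sample_ids: list[str]
    bases: np.ndarray
    coord_map: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.bases = np.asarray(self.bases, dtype="<U1")
        if self.bases.ndim != 2:
            raise AlignmentError("bases must be a 2-D matrix")
        n, L = self.bases.shape
        if len(self.sample_ids) != n:
            raise AlignmentError(
                f"{len(self.sample_ids)} sample ids for {n} alignment rows"
            )
        if len(set(self.sample_ids)) != n:
            dupes = sorted(
                {s for s in self.sample_ids if self.sample_ids.count(s) > 1}
            )
            raise MetadataError(f"duplicate sample ids: {dupes}")
        if self.coord_map is None:
            self.coord_map = np.arange(1, L + 1, dtype=np.int64)
        self.coord_map = np.asarray(self.coord_map, dtype=np.int64)
        if self.coord_map.shape != (L,):
            raise AlignmentError("coord_map length must equal n_columns")
        mapped = self.coord_map[self.coord_map != UNMAPPED]
        if mapped.size > 1 and np.any(np.diff(mapped) <= 0):
            raise AlignmentError("coord_map must be strictly increasing where mapped")
        bad = set(np.unique(self.bases)) - VALID_BASES
        if bad:
            raise AlignmentError(f"invalid characters in alignment: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.bases.shape[0]

    @property
    def n_columns(self) -> int:
        return self.bases.shape[1]

    def sequence(self, sample_id: str) -> str:
        return "".join(self.bases[self.sample_ids.index(sample_id)])

    def sequences(self) -> list[str]:
        return ["".join(row) for row in self.bases]

    def copy(self) -> "Alignment":
        return Alignment(list(self.sample_ids), self.bases.copy(), self.coord_map.copy())

    def write_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq("".join(row)), id=sid, description="")
            for sid, row in zip(self.sample_ids, self.bases)
        ]
        SeqIO.write(records, str(path), "fasta")


@dataclass
class SampleRecord:
    """Per-individual metadata attached to an alignment row."""

    sample_id: str
    population: str
    country: str = ""
    language_branch: str = ""
    subsistence: str = ""
    haplogroup: str = ""
    lat: float | None = None
    lon: float | None = None

    def __post_init__(self) -> None:
        if self.lat is not None and not -90.0 <= self.lat <= 90.0:
            raise MetadataError(f"{self.sample_id}: latitude {self.lat} out of range")
        if self.lon is not None and not -180.0 <= self.lon <= 180.0:
            raise MetadataError(f"{self.sample_id}: longitude {self.lon} out of range")


@dataclass
class MaskSpec:
    """Reference ranges to drop, plus optional removal of indel columns.

    ``ranges`` are inclusive 1-based reference coordinate intervals,
    normalized (sorted, merged) on construction.
    """

    ranges: list[tuple[int, int]] = field(default_factory=list)
    drop_indel_columns: bool = False

    def __post_init__(self) -> None:
        norm: list[tuple[int, int]] = []
        for start, end in sorted((int(a), int(b)) for a, b in self.ranges):
            if start > end:
                raise ValueError(f"mask range ({start}, {end}) has start > end")
            if norm and start <= norm[-1][1] + 1:
                norm[-1] = (norm[-1][0], max(norm[-1][1], end))
            else:
                norm.append((start, end))
        self.ranges = norm

    def contains(self, positions: np.ndarray) -> np.ndarray:
        """Boolean mask over reference positions that fall in any range."""
        hit = np.zeros(positions.shape, dtype=bool)
        for start, end in self.ranges:
            hit |= (positions >= start) & (positions <= end)
        hit &= positions != UNMAPPED
        return hit


#: Poly-C control-region stretches excluded from all mtDNA analyses
POLY_C_MASK = MaskSpec(ranges=[(303, 315), (16183, 16194)])


@dataclass
class ImputationReport:
    """Log of which missing bases were filled, and by how many donors."""

    sites_imputed: int
    samples_with_missing_before: int
    samples_with_missing_after: int
    log: list[tuple[str, int, str, int]]  # (sample_id, column, base, n_donors)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.log, columns=["sample_id", "column", "imputed_base", "n_donors"]
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class HaplotypeTable:
    """Distinct post-masking sequences with per-population counts."""

    haplotypes: list[str]
    counts: pd.DataFrame  # index: haplotype index, columns: populations
    members: dict[int, list[str]]
    excluded_samples: list[str] = field(default_factory=list)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def population_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def write_tsv(self, path) -> None:
        rows = []
        for idx in range(self.n_haplotypes):
            for pop in self.counts.columns:
                c = int(self.counts.loc[idx, pop])
                if c:
                    ids = self._members_by_pop.get((idx, pop), self.members[idx])
                    rows.append((idx, pop, c, ",".join(ids)))
        pd.DataFrame(
            rows, columns=["haplotype", "population", "count", "members"]
        ).to_csv(path, sep="\t", index=False)

    # populated by collapse_haplotypes for exact member/pop bookkeeping
    _members_by_pop: dict = field(default_factory=dict, repr=False)


def read_alignment(fasta_path) -> Alignment:
    """Read an aligned FASTA into an :class:`Alignment`.

    Bases are uppercased and ``?`` is normalized to ``N``.  IUPAC ambiguity
    codes are rejected rather than silently treated as missing.
    """
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper().replace("?", "N"))
    if not ids:
        raise AlignmentError(f"no sequences in {fasta_path}")
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise MetadataError(f"duplicate sequence ids in {fasta_path}: {dupes}")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise AlignmentError(
            f"sequences are not aligned: lengths {sorted(lengths)} in {fasta_path}"
        )
    chars = set("".join(seqs))
    bad = chars - VALID_BASES
    if bad:
        raise AlignmentError(
            f"invalid characters {sorted(bad)} (IUPAC ambiguity codes are not accepted; "
            "encode missing data as N or ?)"
        )
    bases = np.array([list(s) for s in seqs], dtype="<U1")
    return Alignment(ids, bases)


def read_metadata(tsv_path) -> list[SampleRecord]:
    """Read the sample metadata TSV (header: sample_id, population, country,
    language_branch, subsistence, haplogroup, lat, lon)."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "population"}
    missing = required - set(df.columns)
    if missing:
        raise MetadataError(f"metadata missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                population=row["population"],
                country=row.get("country", ""),
                language_branch=row.get("language_branch", ""),
                subsistence=row.get("subsistence", ""),
                haplogroup=row.get("haplogroup", ""),
                lat=float(row["lat"]) if row.get("lat", "") != "" else None,
                lon=float(row["lon"]) if row.get("lon", "") != "" else None,
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise MetadataError(f"duplicate sample ids in metadata: {dupes}")
    return records


def write_metadata(records: list[SampleRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "population": r.population,
                "country": r.country,
                "language_branch": r.language_branch,
                "subsistence": r.subsistence,
                "haplogroup": r.haplogroup,
                "lat": "" if r.lat is None else r.lat,
                "lon": "" if r.lon is None else r.lon,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def apply_mask(aln: Alignment, mask: MaskSpec) -> Alignment:
    """Drop columns whose reference position falls in a masked range, and
    (optionally) every column containing an indel in at least one sample.

    Idempotent: masking an already-masked alignment is a no-op.
    """
    drop = mask.contains(aln.coord_map)
    if mask.drop_indel_columns:
        drop |= (aln.bases == "-").any(axis=0)
    keep = ~drop
    return Alignment(list(aln.sample_ids), aln.bases[:, keep], aln.coord_map[keep])


def impute_missing(aln: Alignment) -> tuple[Alignment, ImputationReport]:
    """Fill missing bases from otherwise-identical sequences.

    For sample ``s`` missing at column ``c``: donors are the other samples
    that (i) are identical to ``s`` at every column where ``s`` is
    non-missing, and (ii) carry a non-missing base at ``c``.  The base is
    filled only when at least two donors exist and all donors agree.  The
    pass is computed entirely from the pre-imputation state, so the result
    does not depend on sample order and never chains through freshly
    imputed bases.  Non-imputable sites stay ``N``.
    """
    src = aln.bases
    out = src.copy()
    missing = src == "N"
    before = int((missing.any(axis=1)).sum())
    log: list[tuple[str, int, str, int]] = []
    for i in np.flatnonzero(missing.any(axis=1)):
        known = ~missing[i]
        # candidate donors: identical to s wherever s is known
        same = (src[:, known] == src[i, known]).all(axis=1)
        same[i] = False
        for c in np.flatnonzero(missing[i]):
            donors = same & ~missing[:, c]
            n_donors = int(donors.sum())
            if n_donors < 2:
                continue
            donor_bases = np.unique(src[donors, c])
            if donor_bases.size == 1:
                out[i, c] = donor_bases[0]
                log.append((aln.sample_ids[i], int(c), str(donor_bases[0]), n_donors))
    imputed = Alignment(list(aln.sample_ids), out, aln.coord_map.copy())
    after = int(((out == "N").any(axis=1)).sum())
    report = ImputationReport(
        sites_imputed=len(log),
        samples_with_missing_before=before,
        samples_with_missing_after=after,
        log=log,
    )
    return imputed, report


def collapse_haplotypes(
    aln: Alignment,
    meta: list[SampleRecord],
    drop_missing_samples: bool = False,
) -> HaplotypeTable:
    """Group identical sequences into haplotypes and tabulate them per
    population.  With ``drop_missing_samples`` samples still containing
    ``N`` are excluded (and reported) before grouping."""
    pop_of = {r.sample_id: r.population for r in meta}
    unknown = [s for s in aln.sample_ids if s not in pop_of]
    if unknown:
        raise MetadataError(f"samples without metadata: {unknown}")

    keep_idx = list(range(aln.n_samples))
    excluded: list[str] = []
    if drop_missing_samples:
        has_n = (aln.bases == "N").any(axis=1)
        excluded = [aln.sample_ids[i] for i in np.flatnonzero(has_n)]
        keep_idx = [i for i in keep_idx if not has_n[i]]

    seqs = aln.sequences()
    hap_index: dict[str, int] = {}
    haplotypes: list[str] = []
    members: dict[int, list[str]] = {}
    members_by_pop: dict[tuple[int, str], list[str]] = {}
    populations = sorted({pop_of[aln.sample_ids[i]] for i in keep_idx})
    counts = pd.DataFrame(
        0, index=pd.RangeIndex(0), columns=populations, dtype=int
    )
    rows: dict[int, dict[str, int]] = {}
    for i in keep_idx:
        seq = seqs[i]
        if seq not in hap_index:
            hap_index[seq] = len(haplotypes)
            haplotypes.append(seq)
        h = hap_index[seq]
        sid = aln.sample_ids[i]
        pop = pop_of[sid]
        members.setdefault(h, []).append(sid)
        members_by_pop.setdefault((h, pop), []).append(sid)
        rows.setdefault(h, {p: 0 for p in populations})[pop] += 1
    counts = pd.DataFrame.from_dict(rows, orient="index").reindex(
        range(len(haplotypes))
    )[populations].fillna(0).astype(int)
    table = HaplotypeTable(
        haplotypes=haplotypes,
        counts=counts,
        members=members,
        excluded_samples=excluded,
    )
    table._members_by_pop = members_by_pop
    return table


# base encoding used for fast pairwise difference counting
_CODE = {b: i for i, b in enumerate("ACGT")}


def _encode(bases: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map bases to small ints; returns (codes, valid) where valid marks A/C/G/T."""
    codes = np.zeros(bases.shape, dtype=np.int8)
    valid = np.zeros(bases.shape, dtype=bool)
    for b, i in _CODE.items():
        hit = bases == b
        codes[hit] = i
        valid |= hit
    return codes, valid


def pairwise_diff_matrix(aln: Alignment) -> DistMatrix:
    """Pairwise sequence differences with pairwise deletion of missing data.

    Entry ``(i, j)`` counts columns where both bases are nucleotides and
    differ; columns where either base is ``N`` are skipped for that pair.
    Indel columns must already have been masked out.
    """
    if (aln.bases == "-").any():
        raise AlignmentError(
            "alignment still contains indel columns; apply a mask with "
            "drop_indel_columns=True first"
        )
    codes, valid = _encode(aln.bases)
    n = aln.n_samples
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        diff = (codes[i] != codes[i + 1 :]) & both
        values[i, i + 1 :] = diff.sum(axis=1)
    values += values.T
    return DistMatrix(labels=list(aln.sample_ids), values=values, units="diff_count")
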