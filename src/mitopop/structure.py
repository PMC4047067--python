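"""Population structure: AMOVA variance components, pairwise Phi-ST,
Mantel correlation, great-circle geographic distances.

AMOVA decomposes squared inter-individual molecular distances into
hierarchical variance components (among groups / among populations within
groups / within populations) with the classical unequal-sample-size
coefficients; Phi statistics are ratios of those components and their
significance is assessed by permutation (individuals among populations,
individuals among populations within groups, or whole populations among
groups, depending on the statistic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .distance import DistMatrix
from .errors import MetadataError
from .seqdata import SampleRecord

EARTH_RADIUS_KM = 6371.0


@dataclass
class AmovaResult:
    grouping: str
    sigma2: dict[str, float]  # variance components
    percentages: dict[str, float]  # 100 * sigma2 / total
    phi: dict[str, float]  # phi_st (+ phi_sc, phi_ct for two-level)
    p_values: dict[str, float]
    n_permutations: int
    seed: int | None = None

    def to_json_dict(self) -> dict:
        return {
            "grouping": self.grouping,
            "variance_components": self.sigma2,
            "percent_of_total": self.percentages,
            "phi_statistics": self.phi,
            "p_values": self.p_values,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    tail: str = "greater"


def _ssd(d2: np.ndarray, idx: np.ndarray) -> float:
    """Sum of squared deviations for one set of individuals: the standard
    distance-matrix identity SSD = sum_{i<j} d^2 / n."""
    sub = d2[np.ix_(idx, idx)]
    return float(sub.sum()) / (2.0 * len(idx))


def _one_level_components(
    d2: np.ndarray, pop_indices: list[np.ndarray]
) -> tuple[float, float, float]:
    """(sigma2_a, sigma2_w, phi_st) for a one-level design."""
    sizes = np.array([len(ix) for ix in pop_indices], dtype=float)
    n_total = sizes.sum()
    n_pops = len(pop_indices)
    all_idx = np.concatenate(pop_indices)
    ssd_total = _ssd(d2, all_idx)
    ssd_wp = sum(_ssd(d2, ix) for ix in pop_indices)
    ssd_ap = ssd_total - ssd_wp
    df_ap = n_pops - 1
    df_wp = n_total - n_pops
    sigma_w = ssd_wp / df_wp
    n_c = (n_total - (sizes**2).sum() / n_total) / df_ap
    sigma_a = (ssd_ap / df_ap - sigma_w) / n_c
    total = sigma_a + sigma_w
    phi_st = sigma_a / total if total != 0 else 0.0
    return sigma_a, sigma_w, phi_st


def _two_level_components(
    d2: np.ndarray, group_pops: list[list[np.ndarray]]
) -> tuple[float, float, float, float, float, float]:
    """(sigma_a, sigma_b, sigma_c, phi_ct, phi_sc, phi_st) for a nested design.

    ``group_pops[g]`` is the list of per-population index arrays of group g.
    """
    sizes = [[len(ix) for ix in g] for g in group_pops]
    group_sizes = np.array([sum(s) for s in sizes], dtype=float)
    n_total = group_sizes.sum()
    n_pops = sum(len(g) for g in group_pops)
    n_groups = len(group_pops)

    all_idx = np.concatenate([ix for g in group_pops for ix in g])
    ssd_total = _ssd(d2, all_idx)
    ssd_wp = sum(_ssd(d2, ix) for g in group_pops for ix in g)
    ssd_wg = sum(
        _ssd(d2, np.concatenate(g)) for g in group_pops
    )
    ssd_ap_wg = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg

    df_ag = n_groups - 1
    df_ap = n_pops - n_groups
    df_wp = n_total - n_pops

    sum_npg2_over_ng = sum(
        sum(n_p**2 for n_p in s) / gs for s, gs in zip(sizes, group_sizes)
    )
    sum_np2_over_n = sum(n_p**2 for s in sizes for n_p in s) / n_total
    n1 = (n_total - sum_npg2_over_ng) / df_ap
    n2 = (sum_npg2_over_ng - sum_np2_over_n) / df_ag
    n3 = (n_total - (group_sizes**2).sum() / n_total) / df_ag

    sigma_c = ssd_wp / df_wp
    sigma_b = (ssd_ap_wg / df_ap - sigma_c) / n1
    sigma_a = (ssd_ag / df_ag - sigma_c - n2 * sigma_b) / n3
    total = sigma_a + sigma_b + sigma_c
    phi_ct = sigma_a / total if total != 0 else 0.0
    phi_st = (sigma_a + sigma_b) / total if total != 0 else 0.0
    denom_sc = sigma_b + sigma_c
    phi_sc = sigma_b / denom_sc if denom_sc != 0 else 0.0
    return sigma_a, sigma_b, sigma_c, phi_ct, phi_sc, phi_st


def _pop_indices(labels: list[str], pops: dict[str, str]) -> dict[str, np.ndarray]:
    missing = [l for l in labels if l not in pops]
    if missing:
        raise MetadataError(f"samples without population assignment: {missing}")
    out: dict[str, list[int]] = {}
    for i, l in enumerate(labels):
        out.setdefault(pops[l], []).append(i)
    return {p: np.array(ix, dtype=int) for p, ix in sorted(out.items())}


def amova(
    d: DistMatrix,
    pops: dict[str, str],
    groups: dict[str, str] | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """Hierarchical AMOVA on a matrix of inter-individual distances.

    With ``groups=None`` a one-level design (among / within populations) is
    fitted; otherwise populations are nested in groups.  Negative variance
    components are reported as computed.  Permutation p-values use the
    ``(b+1)/(m+1)`` estimator.
    """
    d2 = d.values**2
    by_pop = _pop_indices(d.labels, pops)
    small = [p for p, ix in by_pop.items() if len(ix) < 2]
    if small:
        raise ValueError(f"populations with fewer than 2 samples: {small}")
    rng = np.random.default_rng(seed)
    pop_names = list(by_pop)
    labels_pop = np.array([pops[l] for l in d.labels])

    if groups is None:
        sigma_a, sigma_w, phi_st = _one_level_components(d2, list(by_pop.values()))
        total = sigma_a + sigma_w
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(d.labels))
            perm_pops = [
                np.flatnonzero(labels_pop[perm] == p) for p in pop_names
            ]
            # equivalent: shuffle individuals, keep population sizes
            _, _, phi_perm = _one_level_components(d2, perm_pops)
            if phi_perm >= phi_st - 1e-12:
                count += 1
        p_st = (count + 1.0) / (n_perm + 1.0)
        sigma2 = {"among_populations": sigma_a, "within_populations": sigma_w}
        pct = {k: 100.0 * v / total for k, v in sigma2.items()}
        return AmovaResult(
            grouping="one-level",
            sigma2=sigma2,
            percentages=pct,
            phi={"phi_st": phi_st},
            p_values={"phi_st": p_st},
            n_permutations=n_perm,
            seed=seed,
        )

    unknown = [p for p in pop_names if p not in groups]
    if unknown:
        raise MetadataError(f"populations without group assignment: {unknown}")
    group_names = sorted(set(groups[p] for p in pop_names))
    pops_of_group = {g: [p for p in pop_names if groups[p] == g] for g in group_names}
    structure = [[by_pop[p] for p in pops_of_group[g]] for g in group_names]

    sigma_a, sigma_b, sigma_c, phi_ct, phi_sc, phi_st = _two_level_components(
        d2, structure
    )
    total = sigma_a + sigma_b + sigma_c

    def build(assign_group: dict[str, str], by_pop_ix: dict[str, np.ndarray]):
        return [
            [by_pop_ix[p] for p in pop_names if assign_group[p] == g]
            for g in group_names
        ]

    count_st = count_sc = count_ct = 0
    group_of_pop = {p: groups[p] for p in pop_names}
    labels_arr = np.arange(len(d.labels))
    for _ in range(n_perm):
        # phi_st: individuals permuted among populations (whole design)
        perm = rng.permutation(len(d.labels))
        perm_by_pop = {
            p: perm[by_pop[p]] for p in pop_names
        }
        *_, phi_st_p = _two_level_components(d2, build(group_of_pop, perm_by_pop))
        if phi_st_p >= phi_st - 1e-12:
            count_st += 1

        # phi_sc: individuals permuted among populations within their group
        perm_by_pop2 = {}
        for g in group_names:
            members = np.concatenate([by_pop[p] for p in pops_of_group[g]])
            shuffled = rng.permutation(members)
            off = 0
            for p in pops_of_group[g]:
                k = len(by_pop[p])
                perm_by_pop2[p] = shuffled[off : off + k]
                off += k
        _, sb, sc_, _, phi_sc_p, _ = _two_level_components(
            d2, build(group_of_pop, perm_by_pop2)
        )
        if phi_sc_p >= phi_sc - 1e-12:
            count_sc += 1

        # phi_ct: whole populations permuted among groups (sizes kept)
        perm_groups = rng.permutation([group_of_pop[p] for p in pop_names])
        assign = dict(zip(pop_names, perm_groups))
        if all(
            sum(1 for p in pop_names if assign[p] == g) >= 1 for g in group_names
        ):
            sa_p, sb_p, sc_p, phi_ct_p, _, _ = _two_level_components(
                d2,
                [
                    [by_pop[p] for p in pop_names if assign[p] == g]
                    for g in group_names
                ],
            )
            if phi_ct_p >= phi_ct - 1e-12:
                count_ct += 1

    sigma2 = {
        "among_groups": sigma_a,
        "among_populations_within_groups": sigma_b,
        "within_populations": sigma_c,
    }
    pct = {k: 100.0 * v / total for k, v in sigma2.items()}
    return AmovaResult(
        grouping="two-level",
        sigma2=sigma2,
        percentages=pct,
        phi={"phi_ct": phi_ct, "phi_sc": phi_sc, "phi_st": phi_st},
        p_values={
            "phi_ct": (count_ct + 1.0) / (n_perm + 1.0),
            "phi_sc": (count_sc + 1.0) / (n_perm + 1.0),
            "phi_st": (count_st + 1.0) / (n_perm + 1.0),
        },
        n_permutations=n_perm,
        seed=seed,
    )


def phi_st_pairwise(
    d: DistMatrix,
    pops: dict[str, str],
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[DistMatrix, DistMatrix]:
    """Pairwise Phi-ST between populations with permutation p-values.

    Each population pair is analysed as a one-level AMOVA restricted to the
    two populations; p-values count permutations of individuals between the
    pair with Phi-ST >= observed, with the (b+1)/(m+1) correction.
    """
    d2 = d.values**2
    by_pop = _pop_indices(d.labels, pops)
    small = [p for p, ix in by_pop.items() if len(ix) < 2]
    if small:
        raise ValueError(f"populations with fewer than 2 samples: {small}")
    pop_names = list(by_pop)
    k = len(pop_names)
    if k < 2:
        raise ValueError("need at least two populations")
    rng = np.random.default_rng(seed)
    phi = np.zeros((k, k))
    pvals = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a, b = by_pop[pop_names[i]], by_pop[pop_names[j]]
            _, _, obs = _one_level_components(d2, [a, b])
            phi[i, j] = phi[j, i] = obs
            pooled = np.concatenate([a, b])
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(pooled)
                _, _, stat = _one_level_components(
                    d2, [perm[: len(a)], perm[len(a) :]]
                )
                if stat >= obs - 1e-12:
                    count += 1
            pvals[i, j] = pvals[j, i] = (count + 1.0) / (n_perm + 1.0)
    return (
        DistMatrix(pop_names, phi, units="phi_st"),
        DistMatrix(pop_names, pvals, units="phi_st"),
    )


def haversine_km(lat1, lon1, lat2, lon2, radius: float = EARTH_RADIUS_KM):
    """Great-circle distance in km (vectorized)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * radius * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def geo_distance_matrix(meta: list[SampleRecord]) -> DistMatrix:
    """Between-population geographic distances, averaged over samples.

    Entry (A, B) is the mean great-circle distance over all sample pairs
    (a in A, b in B) with GPS coordinates.  Populations without any GPS
    data are excluded with a warning; the diagonal is zero by convention.
    """
    by_pop: dict[str, list[tuple[float, float]]] = {}
    skipped: set[str] = set()
    for r in meta:
        if r.lat is None or r.lon is None:
            skipped.add(r.population)
            continue
        by_pop.setdefault(r.population, []).append((r.lat, r.lon))
    dropped = sorted(skipped - set(by_pop))
    if dropped:
        warnings.warn(
            f"populations without GPS data excluded from geographic matrix: {dropped}"
        )
    pops = sorted(by_pop)
    if not pops:
        raise MetadataError("no population has GPS data")
    k = len(pops)
    values = np.zeros((k, k))
    coords = {p: np.array(by_pop[p]) for p in pops}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = coords[pops[i]], coords[pops[j]]
            la, lb = a[:, None, :], b[None, :, :]
            dists = haversine_km(la[..., 0], la[..., 1], lb[..., 0], lb[..., 1])
            values[i, j] = values[j, i] = float(dists.mean())
    return DistMatrix(pops, values, units="km")


def mantel(
    x: DistMatrix,
    y: DistMatrix,
    n_perm: int = 999,
    tail: str = "greater",
    seed: int | None = None,
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    ``r`` is the Pearson correlation of the off-diagonal upper-triangle
    entries; the p-value permutes the rows/columns of ``y`` jointly and
    uses the (b+1)/(m+1) estimator.  Tails: "greater" (default), "less",
    or "two-sided".
    """
    if x.labels != y.labels:
        raise ValueError("distance matrices must carry identical labels in order")
    if tail not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")
    if x.n < 3:
        raise ValueError("Mantel test needs at least three labels")
    xv = x.condensed()
    rng = np.random.default_rng(seed)

    def corr(yc: np.ndarray) -> float:
        return float(np.corrcoef(xv, yc)[0, 1])

    obs = corr(y.condensed())
    n = x.n
    iu = np.triu_indices(n, k=1)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = y.values[np.ix_(perm, perm)][iu]
        r = corr(yp)
        if tail == "greater":
            hit = r >= obs - 1e-12
        elif tail == "less":
            hit = r <= obs + 1e-12
        else:
            hit = abs(r) >= abs(obs) - 1e-12
        count += hit
    return MantelResult(
        r=obs, p=(count + 1.0) / (n_perm + 1.0), n_permutations=n_perm, tail=tail
    )
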