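"""AMOVA, pairwise Phi-ST, Mantel, geographic distances."""

import warnings

import numpy as np
import pytest
from scipy.stats import kstest

from mitopop import (
    Alignment,
    DistMatrix,
    SampleRecord,
    amova,
    geo_distance_matrix,
    mantel,
    pairwise_diff_matrix,
    phi_st_pairwise,
)
from mitopop.errors import MetadataError

from _oracles import brute_one_level, brute_two_level


def random_alignment(rng, pool, n, prefix):
    """n sequences drawn from a pool of haplotype strings."""
    picks = rng.integers(0, len(pool), size=n)
    ids = [f"{prefix}{i}" for i in range(n)]
    bases = np.array([list(pool[p]) for p in picks], dtype="<U1")
    return ids, bases


@pytest.fixture
def toy_pair():
    """Two 3-sample populations with hand-listed distances."""
    labels = ["a1", "a2", "a3", "b1", "b2", "b3"]
    d = np.array(
        [
            [0, 1, 2, 4, 5, 4],
            [1, 0, 1, 3, 4, 3],
            [2, 1, 0, 2, 3, 2],
            [4, 3, 2, 0, 1, 2],
            [5, 4, 3, 1, 0, 1],
            [4, 3, 2, 2, 1, 0],
        ],
        dtype=float,
    )
    pops = {l: l[0].upper() for l in labels}
    return DistMatrix(labels, d), pops


class TestPhiStPairwise:
    def test_matches_brute_force_sums_of_squares(self, toy_pair):
        d, pops = toy_pair
        phi, _ = phi_st_pairwise(d, pops, n_perm=99, seed=0)
        _, _, expected = brute_one_level(d.values, [[0, 1, 2], [3, 4, 5]])
        assert phi.values[0, 1] == pytest.approx(expected, abs=1e-9)

    def test_no_structure_gives_small_phi(self):
        rng = np.random.default_rng(7)
        pool = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(6)]
        ids_a, ba = random_alignment(rng, pool, 30, "a")
        ids_b, bb = random_alignment(rng, pool, 30, "b")
        aln = Alignment(ids_a + ids_b, np.vstack([ba, bb]))
        d = pairwise_diff_matrix(aln)
        pops = {s: ("A" if s.startswith("a") else "B") for s in aln.sample_ids}
        phi, _ = phi_st_pairwise(d, pops, n_perm=0)
        assert abs(phi.values[0, 1]) < 0.05

    def test_fixed_populations_give_phi_one(self, make_alignment):
        aln = make_alignment(
            {"a1": "AAATTT", "a2": "AAATTT", "b1": "AAAGGG", "b2": "AAAGGG"}
        )
        d = pairwise_diff_matrix(aln)
        phi, _ = phi_st_pairwise(d, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
                                 n_perm=0)
        assert phi.values[0, 1] == pytest.approx(1.0)

    def test_small_population_rejected_by_name(self, toy_pair):
        d, pops = toy_pair
        pops = dict(pops)
        pops["a3"] = "C"  # C now has a single sample
        with pytest.raises(ValueError, match="C"):
            phi_st_pairwise(d, pops, n_perm=0)

    def test_equals_two_population_amova(self, toy_pair):
        d, pops = toy_pair
        phi, _ = phi_st_pairwise(d, pops, n_perm=0)
        res = amova(d, pops, n_perm=0)
        assert phi.values[0, 1] == pytest.approx(res.phi["phi_st"], abs=1e-12)


class TestAmova:
    def test_one_level_matches_brute_force(self, toy_pair):
        d, pops = toy_pair
        res = amova(d, pops, n_perm=99, seed=1)
        sa, sw, phi = brute_one_level(d.values, [[0, 1, 2], [3, 4, 5]])
        assert res.sigma2["among_populations"] == pytest.approx(sa, abs=1e-9)
        assert res.sigma2["within_populations"] == pytest.approx(sw, abs=1e-9)
        assert res.phi["phi_st"] == pytest.approx(phi, abs=1e-9)
        assert sum(res.percentages.values()) == pytest.approx(100.0, abs=1e-9)
        assert 0.0 < res.p_values["phi_st"] <= 1.0

    def test_two_level_matches_brute_force(self):
        # 3 populations (3+3+2 samples) in 2 groups, unequal sizes
        rng = np.random.default_rng(11)
        n = 8
        x = rng.integers(0, 6, size=(n, 12))
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                d[i, j] = (x[i] != x[j]).sum()
        np.fill_diagonal(d, 0)
        labels = [f"s{i}" for i in range(n)]
        dm = DistMatrix(labels, d)
        pops = {
            "s0": "P1", "s1": "P1", "s2": "P1",
            "s3": "P2", "s4": "P2", "s5": "P2",
            "s6": "P3", "s7": "P3",
        }
        groups = {"P1": "G1", "P2": "G1", "P3": "G2"}
        res = amova(dm, pops, groups=groups, n_perm=49, seed=3)
        sa, sb, sc, phi_ct, phi_sc, phi_st = brute_two_level(
            d, [[[0, 1, 2], [3, 4, 5]], [[6, 7]]]
        )
        assert res.sigma2["among_groups"] == pytest.approx(sa, abs=1e-9)
        assert res.sigma2["among_populations_within_groups"] == pytest.approx(
            sb, abs=1e-9
        )
        assert res.sigma2["within_populations"] == pytest.approx(sc, abs=1e-9)
        assert res.phi["phi_ct"] == pytest.approx(phi_ct, abs=1e-9)
        assert res.phi["phi_sc"] == pytest.approx(phi_sc, abs=1e-9)
        assert res.phi["phi_st"] == pytest.approx(phi_st, abs=1e-9)
        assert sum(res.percentages.values()) == pytest.approx(100.0, abs=1e-9)
        for p in res.p_values.values():
            assert 0.0 < p <= 1.0

    def test_null_model_variance_sits_within_populations(self):
        rng = np.random.default_rng(5)
        pool = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(8)]
        ids, bases, pops = [], [], {}
        for p in range(3):
            pids, pb = random_alignment(rng, pool, 20, f"p{p}_")
            ids += pids
            bases.append(pb)
            pops.update({s: f"P{p}" for s in pids})
        aln = Alignment(ids, np.vstack(bases))
        res = amova(pairwise_diff_matrix(aln), pops, n_perm=0)
        assert res.percentages["among_populations"] == pytest.approx(0.0, abs=5.0)
        assert res.percentages["within_populations"] == pytest.approx(100.0, abs=5.0)

    def test_negative_components_reported_not_truncated(self):
        # groups that duplicate the composition of their populations make the
        # among-group component go negative; percentages still sum to 100
        rng = np.random.default_rng(13)
        pool = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(5)]
        ids, bases, pops = [], [], {}
        for p in range(4):
            pids, pb = random_alignment(rng, pool, 8, f"p{p}_")
            ids += pids
            bases.append(pb)
            pops.update({s: f"P{p}" for s in pids})
        aln = Alignment(ids, np.vstack(bases))
        groups = {"P0": "G1", "P1": "G2", "P2": "G1", "P3": "G2"}
        res = amova(pairwise_diff_matrix(aln), pops, groups=groups, n_perm=19, seed=2)
        assert sum(res.percentages.values()) == pytest.approx(100.0, abs=1e-9)

    def test_permutation_pvalues_approximately_uniform_under_null(self):
        # permuted-labels null: p-values should be close to uniform
        rng = np.random.default_rng(17)
        pvals = []
        for _ in range(200):
            x = rng.integers(0, 4, size=(6, 10))
            d = np.zeros((6, 6))
            for i in range(6):
                for j in range(6):
                    d[i, j] = (x[i] != x[j]).sum()
            np.fill_diagonal(d, 0)
            labels = [f"s{i}" for i in range(6)]
            pops = {l: ("A" if i < 3 else "B") for i, l in enumerate(labels)}
            res = amova(
                DistMatrix(labels, d), pops, n_perm=99,
                seed=int(rng.integers(2**31)),
            )
            pvals.append(res.p_values["phi_st"])
        # discrete, slightly conservative p-values: loose KS sanity bound
        assert kstest(pvals, "uniform").pvalue > 1e-3

    def test_group_with_missing_assignment_rejected(self, toy_pair):
        d, pops = toy_pair
        with pytest.raises(MetadataError):
            amova(d, pops, groups={"A": "G1"}, n_perm=0)


class TestGeoDistance:
    def _meta(self, spec):
        return [
            SampleRecord(sample_id=f"s{i}", population=p, lat=lat, lon=lon)
            for i, (p, lat, lon) in enumerate(spec)
        ]

    def test_single_point_zero_matrix(self):
        geo = geo_distance_matrix(
            self._meta([("A", 10.0, 20.0), ("B", 10.0, 20.0)])
        )
        assert np.allclose(geo.values, 0.0)

    def test_one_degree_on_equator(self):
        geo = geo_distance_matrix(self._meta([("A", 0.0, 0.0), ("B", 0.0, 1.0)]))
        # 2 * pi * 6371 / 360
        assert geo.values[0, 1] == pytest.approx(111.1949, abs=0.01)

    def test_mean_over_all_sample_pairs(self):
        spec = [("A", 0.0, 0.0), ("A", 0.0, 1.0), ("B", 1.0, 0.0), ("B", 1.0, 1.0)]
        geo = geo_distance_matrix(self._meta(spec))
        from mitopop.structure import haversine_km

        pairs = [
            haversine_km(la1, lo1, la2, lo2)
            for (_, la1, lo1) in spec[:2]
            for (_, la2, lo2) in spec[2:]
        ]
        assert geo.values[0, 1] == pytest.approx(np.mean(pairs), rel=1e-9)

    def test_population_without_gps_excluded_with_warning(self):
        meta = self._meta([("A", 0.0, 0.0), ("B", 1.0, 1.0)])
        meta.append(SampleRecord(sample_id="x", population="C"))
        with pytest.warns(UserWarning, match="C"):
            geo = geo_distance_matrix(meta)
        assert geo.labels == ["A", "B"]


class TestMantel:
    def _dm(self, values, labels=None):
        labels = labels or [f"s{i}" for i in range(values.shape[0])]
        return DistMatrix(labels, values)

    def test_affine_relation_gives_r_one(self):
        rng = np.random.default_rng(3)
        x = rng.random((6, 6))
        x = (x + x.T) / 2
        np.fill_diagonal(x, 0)
        y = 2 * x + 3
        np.fill_diagonal(y, 0)
        res = mantel(self._dm(x), self._dm(y), n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert 0.0 < res.p <= 1.0

    def test_negated_matrix_gives_r_minus_one(self):
        rng = np.random.default_rng(4)
        x = rng.random((6, 6))
        x = (x + x.T) / 2
        np.fill_diagonal(x, 0)
        y = -x
        res = mantel(self._dm(x), self._dm(y), n_perm=99, seed=0)
        assert res.r == pytest.approx(-1.0)

    def test_label_mismatch_rejected(self):
        x = np.zeros((3, 3))
        with pytest.raises(ValueError, match="labels"):
            mantel(
                self._dm(x, ["a", "b", "c"]),
                self._dm(x, ["a", "c", "b"]),
                n_perm=9,
            )

    def test_null_calibration(self):
        # independent random matrices: r near zero and false-positive rate
        # at the nominal level
        rng = np.random.default_rng(12345)
        rejected = 0
        rs = []
        reps = 200
        for _ in range(reps):
            mats = []
            for _ in range(2):
                m = rng.random((10, 10))
                m = (m + m.T) / 2
                np.fill_diagonal(m, 0)
                mats.append(self._dm(m))
            res = mantel(mats[0], mats[1], n_perm=199,
                         seed=int(rng.integers(2**31)))
            rs.append(res.r)
            rejected += res.p <= 0.05
        assert rejected / reps <= 0.10
        assert np.mean(np.abs(rs)) < 0.2

    def test_agrees_with_skbio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(9)
        a = rng.random((8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = a + rng.normal(0, 0.2, size=a.shape)
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        b = np.abs(b)
        ours = mantel(self._dm(a), self._dm(b), n_perm=999, seed=5)
        r_ref, p_ref, _ = skbio_stats.mantel(
            skbio_stats.DistanceMatrix(a),
            skbio_stats.DistanceMatrix(b),
            method="pearson",
            permutations=999,
            alternative="greater",
        )
        assert ours.r == pytest.approx(float(r_ref), abs=1e-9)
        assert ours.p == pytest.approx(float(p_ref), abs=0.05)
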