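import math

import numpy as np
import pytest

from barcodeval.distance_barcoding import (DistanceMatrix, abgd_partition,
                                           barcode_gap_assess,
                                           cluster_at_threshold,
                                           intra_inter_tests,
                                           max_intraspecific,
                                           p_distance_matrix,
                                           p_distance_pair)
from barcodeval.io_formats import MarkerAlignment, SpeciesMap

from .conftest import brute_force_p_distance


def _smap(assignments):
    return SpeciesMap({i: (sp, None, None) for i, sp in assignments.items()})


def _cluster_matrix(rng, n_species=3, n_ind=4, intra=0.01, inter=0.15):
    """Distance matrix with tight conspecific clusters, far apart."""
    ids, species = [], {}
    for s in range(n_species):
        for k in range(n_ind):
            i = f"s{s}_i{k}"
            ids.append(i)
            species[i] = f"s{s}"
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            same = species[ids[i]] == species[ids[j]]
            if same:
                d = intra * (0.5 + rng.random())
            else:
                d = inter * (0.9 + 0.2 * rng.random())
            D[i, j] = D[j, i] = d
    return DistanceMatrix(ids, D, np.full((n, n), 500)), _smap(species)


class TestPDistance:
    def test_examples(self):
        assert p_distance_pair("ACGT", "ACGA") == 0.25
        assert p_distance_pair("AC-T", "ACGT") == 0.0
        assert math.isnan(p_distance_pair("----", "ACGT"))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGTN-?RY"), 80))
        b = "".join(rng.choice(list("ACGTN-?RY"), 80))
        got = p_distance_pair(a, b)
        expected = brute_force_p_distance(a, b)
        if math.isnan(expected):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(expected)

    def test_matrix_symmetry_and_diagonal(self):
        rng = np.random.default_rng(1)
        rows = ["".join(rng.choice(list("ACGT-N"), 60)) for _ in range(8)]
        aln = MarkerAlignment("m", [f"i{k}" for k in range(8)], rows)
        dm = p_distance_matrix(aln)
        assert np.allclose(dm.d, dm.d.T, equal_nan=True)
        assert np.all(np.diag(dm.d) == 0)
        for i in range(8):
            for j in range(8):
                e = brute_force_p_distance(rows[i], rows[j]) if i != j else 0.0
                if math.isnan(e):
                    assert math.isnan(dm.d[i, j])
                else:
                    assert dm.d[i, j] == pytest.approx(e)


class TestMaxIntraspecific:
    def test_max_over_conspecific_pairs(self, two_species_alignment):
        aln, smap = two_species_alignment
        dm = p_distance_matrix(aln)
        d_max, se = max_intraspecific(dm, smap, aln, n_boot=100, seed=0)
        assert d_max == pytest.approx(1 / 8)
        assert se >= 0

    def test_identical_sequences_zero(self):
        aln = MarkerAlignment("m", ["a", "b"], ["ACGTACGT", "ACGTACGT"])
        smap = _smap({"a": "X", "b": "X"})
        dm = p_distance_matrix(aln)
        d_max, se = max_intraspecific(dm, smap, aln, n_boot=50, seed=0)
        assert (d_max, se) == (0.0, 0.0)

    def test_bootstrap_se_stable_across_seeds(self):
        rng = np.random.default_rng(3)
        rows = []
        for s in range(4):
            base = rng.choice(list("ACGT"), 400)
            for k in range(3):
                r = base.copy()
                flip = rng.choice(400, 6, replace=False)
                for c in flip:
                    r[c] = {"A": "C", "C": "G", "G": "T", "T": "A"}[r[c]]
                rows.append("".join(r))
        ids = [f"s{s}_i{k}" for s in range(4) for k in range(3)]
        aln = MarkerAlignment("m", ids, rows)
        smap = _smap({i: i.split("_")[0] for i in ids})
        dm = p_distance_matrix(aln)
        ses = [max_intraspecific(dm, smap, aln, n_boot=1000, seed=s)[1]
               for s in (1, 2)]
        assert ses[0] == pytest.approx(ses[1], rel=0.10)

    def test_no_conspecific_pair_raises(self):
        aln = MarkerAlignment("m", ["a", "b"], ["ACGT", "ACGA"])
        smap = _smap({"a": "X", "b": "Y"})
        dm = p_distance_matrix(aln)
        with pytest.raises(ValueError):
            max_intraspecific(dm, smap, aln, n_boot=10, seed=0)


class TestBarcodeGap:
    def test_gap_found_between_tight_clusters(self):
        rng = np.random.default_rng(5)
        dm, smap = _cluster_matrix(rng, intra=0.005, inter=0.15)
        ga = barcode_gap_assess(dm, smap)
        assert ga.gap_found
        lo, hi = ga.gap_interval
        assert lo >= ga.d_intra_max - 1e-12
        assert hi > lo

    def test_uniform_spread_has_no_gap(self):
        ids = [f"s{k // 2}_i{k % 2}" for k in range(10)]
        smap = _smap({i: i.split("_")[0] for i in ids})
        n = len(ids)
        D = np.zeros((n, n))
        vals = iter(np.linspace(0.01, 0.45, n * (n - 1) // 2))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = next(vals)
        dm = DistanceMatrix(ids, D, np.full((n, n), 500))
        assert not barcode_gap_assess(dm, smap).gap_found

    def test_overlapping_distributions_have_no_gap(self):
        rng = np.random.default_rng(6)
        dm, smap = _cluster_matrix(rng, intra=0.10, inter=0.12)
        assert not barcode_gap_assess(dm, smap).gap_found


class TestPartition:
    def test_three_planted_clusters_all_delimited(self):
        rng = np.random.default_rng(7)
        dm, smap = _cluster_matrix(rng, n_species=3, intra=0.01, inter=0.15)
        part = abgd_partition(dm, prior_P=0.02, species_map=smap)
        assert len(part.groups) == 3
        assert sorted(part.delimited_species) == ["s0", "s1", "s2"]

    def test_all_below_prior_single_group(self):
        rng = np.random.default_rng(8)
        dm, smap = _cluster_matrix(rng, n_species=2, intra=0.01, inter=0.02)
        part = abgd_partition(dm, prior_P=0.5, species_map=smap)
        assert len(part.groups) == 1
        assert part.delimited_species == []

    def test_split_species_not_delimited(self):
        # one species in two distant haplotype clusters is over-split
        ids = [f"x_i{k}" for k in range(6)]
        n = len(ids)
        D = np.full((n, n), 0.2)
        for i in range(3):
            for j in range(3):
                D[i, j] = 0.005 if i != j else 0.0
                D[i + 3, j + 3] = 0.005 if i != j else 0.0
        np.fill_diagonal(D, 0)
        dm = DistanceMatrix(ids, D, np.full((n, n), 500))
        smap = _smap({i: "x" for i in ids})
        part = abgd_partition(dm, prior_P=0.01, species_map=smap)
        assert len(part.groups) == 2
        assert part.delimited_species == []

    def test_groups_partition_individuals(self):
        rng = np.random.default_rng(9)
        dm, smap = _cluster_matrix(rng, n_species=4)
        part = abgd_partition(dm, prior_P=0.02, species_map=smap)
        seen = [i for g in part.groups for i in g]
        assert sorted(seen) == sorted(dm.ids)

    def test_prior_must_be_positive(self):
        rng = np.random.default_rng(10)
        dm, _ = _cluster_matrix(rng)
        with pytest.raises(ValueError):
            abgd_partition(dm, prior_P=0.0)

    def test_threshold_clustering_monotone(self):
        rng = np.random.default_rng(11)
        dm, _ = _cluster_matrix(rng)
        sizes = [len(cluster_at_threshold(dm, t))
                 for t in np.linspace(0.0, 0.5, 20)]
        assert sizes[0] == len(dm.ids)  # singletons at t=0
        assert sizes[-1] == 1           # one group once t covers everything
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestIntraInterTests:
    def test_separated_distributions_reject_strongly(self):
        ids = [f"s{k // 3}_i{k % 3}" for k in range(30)]
        smap = _smap({i: i.split("_")[0] for i in ids})
        n = len(ids)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                same = ids[i].split("_")[0] == ids[j].split("_")[0]
                D[i, j] = D[j, i] = 0.0 if same else 0.5
        dm = DistanceMatrix(ids, D, np.full((n, n), 500))
        res = intra_inter_tests(dm, smap)
        assert res.t_p < 1e-6 and res.w_p < 1e-6

    def test_type_one_error_calibrated_under_null(self):
        # intra and inter drawn from the same distribution
        rng = np.random.default_rng(42)
        ids = [f"s{a}_i{b}" for a in range(6) for b in range(3)]
        smap = _smap({i: i.split("_")[0] for i in ids})
        n = len(ids)
        iu = np.triu_indices(n, 1)
        reps, rej_t, rej_w = 1000, 0, 0
        for _ in range(reps):
            D = np.zeros((n, n))
            D[iu] = rng.normal(0.05, 0.01, size=iu[0].size)
            D = D + D.T
            dm = DistanceMatrix(ids, D, np.full((n, n), 100))
            res = intra_inter_tests(dm, smap)
            rej_t += res.t_p < 0.05
            rej_w += res.w_p < 0.05
        assert rej_t / reps <= 0.06
        assert rej_w / reps <= 0.06

    def test_power_on_shifted_normals(self):
        from scipy import stats
        rng = np.random.default_rng(13)
        rejections = 0
        for _ in range(200):
            x = rng.normal(0, 1, 50)
            y = rng.normal(1, 1, 50)
            _, p = stats.ttest_ind(x, y, equal_var=False)
            rejections += p < 0.05
        assert rejections / 200 > 0.99

    def test_empty_grouping_raises(self):
        aln = MarkerAlignment("m", ["a", "b"], ["ACGT", "ACGA"])
        smap = _smap({"a": "X", "b": "X"})  # no interspecific pair
        dm = p_distance_matrix(aln)
        with pytest.raises(ValueError, match="inter"):
            intra_inter_tests(dm, smap)

    def test_per_species_mode(self):
        rng = np.random.default_rng(14)
        dm, smap = _cluster_matrix(rng)
        res = intra_inter_tests(dm, smap, mode="per_species")
        assert res.mode == "per_species"
        assert res.t_p < 0.05  # clusters are well separated
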