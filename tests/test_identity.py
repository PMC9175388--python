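from fractions import Fraction as F

import pytest

import pedrel as pr
from oracles import enumerate_identity


class TestCondensed:
    def test_unrelated_noninbred(self, trio):
        d = pr.condensed_identity(trio, "1", "2")
        assert d == (0, 0, 0, 0, 0, 0, 0, 0, 1)

    def test_parent_offspring_delta8(self, trio):
        d = pr.condensed_identity(trio, "1", "3")
        assert d == (0, 0, 0, 0, 0, 0, 0, 1, 0)

    def test_full_siblings(self, full_sibs):
        d = pr.condensed_identity(full_sibs, "3", "4")
        assert d == (0, 0, 0, 0, 0, 0, F(1, 4), F(1, 2), F(1, 4))

    def test_habsburg_printed_vector(self, habsburg):
        d = pr.condensed_identity(habsburg, "Philip_IV", "Mariana")
        printed = (0.011, 0.004, 0.044, 0.024, 0.077, 0.044, 0.071, 0.498, 0.228)
        assert tuple(round(float(x), 3) for x in d) == printed

    def test_same_pair_rejected(self, trio):
        with pytest.raises(pr.SamePair):
            pr.condensed_identity(trio, "1", "1")

    @pytest.mark.parametrize("name", pr.FIXTURE_NAMES)
    def test_sums_to_one_and_phi_consistent(self, name):
        ped = pr.builtin(name)
        a, b = pr.FIXTURE_PAIRS[name]
        d = pr.condensed_identity(ped, a, b)
        assert sum(d) == 1
        assert pr.phi_from_condensed(d) == pr.kinship(ped, a, b)
        assert d[0] + d[1] + d[2] + d[3] == pr.inbreeding(ped, a)
        assert d[0] + d[1] + d[4] + d[5] == pr.inbreeding(ped, b)

    @pytest.mark.parametrize("name", ["fig1-example", "figS1-incest",
                                      "first-cousins", "aunt-nephew",
                                      "quadruple-half-first-cousins"])
    def test_matches_exhaustive_enumeration(self, name):
        ped = pr.builtin(name)
        a, b = pr.FIXTURE_PAIRS[name]
        phi, d9, d15 = enumerate_identity(ped, a, b)
        assert pr.kinship(ped, a, b) == phi
        assert pr.condensed_identity(ped, a, b) == d9
        assert pr.detailed_identity(ped, a, b) == d15


class TestDetailed:
    def test_unrelated_all_in_no_ibd_state(self, trio):
        d = pr.detailed_identity(trio, "1", "2")
        assert d[14] == 1 and sum(d) == 1

    def test_full_siblings_parental_states(self, full_sibs):
        d = pr.detailed_identity(full_sibs, "3", "4")
        # paternal-genes-only and maternal-genes-only IBD states
        assert d[10] == F(1, 4)   # delta_11: (1,3) | 2 | 4
        assert d[13] == F(1, 4)   # delta_14: (2,4) | 1 | 3
        assert sum(d) == 1

    @pytest.mark.parametrize("name", pr.FIXTURE_NAMES)
    def test_aggregation_reproduces_condensed(self, name):
        ped = pr.builtin(name)
        a, b = pr.FIXTURE_PAIRS[name]
        d15 = pr.detailed_identity(ped, a, b)
        assert sum(d15) == 1
        assert pr.aggregate_detailed(d15) == pr.condensed_identity(ped, a, b)


class TestKappa:
    def test_full_siblings_textbook(self, full_sibs):
        k = pr.kappa(full_sibs, "3", "4")
        assert k.defined and (k.k0, k.k1, k.k2) == (F(1, 4), F(1, 2), F(1, 4))

    def test_william_renata_second_cousins(self, habsburg):
        k = pr.kappa(habsburg, "William_V", "Renata")
        assert k.defined
        assert (k.k0, k.k1, k.k2) == (F(15, 16), F(1, 16), 0)

    def test_undefined_for_inbred_pair(self, habsburg):
        assert not pr.kappa(habsburg, "Philip_IV", "Mariana").defined

    def test_undefined_when_one_member_inbred(self, incest):
        # member 5 is inbred; 4 is not
        assert not pr.kappa(incest, "4", "5").defined

    def test_noninbred_reduction(self):
        ped = pr.builtin("first-cousins")
        d = pr.condensed_identity(ped, "7", "8")
        k = pr.kappa(ped, "7", "8")
        assert d[:6] == (0, 0, 0, 0, 0, 0)
        assert (k.k0, k.k1, k.k2) == (d[8], d[7], d[6])

    def test_thompson_inequality_on_fixture_pairs(self):
        for name in pr.FIXTURE_NAMES:
            ped = pr.builtin(name)
            a, b = pr.FIXTURE_PAIRS[name]
            k = pr.kappa(ped, a, b)
            if k.defined:
                assert k.k1 ** 2 >= 4 * k.k0 * k.k2


class TestCondensedX:
    def test_two_unrelated_males_single_no_ibd_state(self):
        ped = pr.read_ped("1 0 0 1\n2 0 0 1\n")
        d = pr.condensed_identity_x(ped, "1", "2")
        assert d == (0, 1, 0, 0, 0, 0, 0, 0, 0)

    def test_mother_son(self, trio):
        d = pr.condensed_identity_x(trio, "2", "3")
        assert d == (0, 0, 0, 0, 1, 0, 0, 0, 0)

    def test_full_sisters(self):
        ped = pr.read_ped("1 0 0 1\n2 0 0 2\n3 1 2 2\n4 1 2 2\n")
        d = pr.condensed_identity_x(ped, "3", "4")
        assert d == (0, 0, 0, 0, 0, 0, F(1, 2), F(1, 2), 0)
        assert pr.phi_from_condensed(d) == pr.kinship_x(ped, "3", "4") == F(3, 8)

    def test_sums_to_one_on_habsburg(self, habsburg):
        d = pr.condensed_identity_x(habsburg, "Philip_IV", "Mariana")
        assert sum(d) == 1
        assert pr.phi_from_condensed(d) == pr.kinship_x(habsburg, "Philip_IV", "Mariana")

    def test_unknown_sex_on_path_rejected(self):
        ped = pr.read_ped("1 0 0 1\n2 0 0 2\n3 1 2 0\n4 1 2 2\n")
        with pytest.raises(pr.UnknownSexOnPath):
            pr.condensed_identity_x(ped, "3", "4")


class TestGeneDrop:
    def test_unrelated_pair_exact(self, trio):
        gd = pr.gene_drop(trio, "1", "2", n=500, seed=7)
        assert gd.freq[8] == 1.0

    def test_reproducible_given_seed(self, fig1):
        a = pr.gene_drop(fig1, "6", "7", n=2000, seed=11)
        b = pr.gene_drop(fig1, "6", "7", n=2000, seed=11)
        assert a.freq == b.freq

    def test_fig1_phi_within_three_se(self, fig1):
        gd = pr.gene_drop(fig1, "6", "7", n=100_000, seed=3)
        assert abs(gd.phi - 0.3125) <= 3 * gd.phi_se

    def test_habsburg_delta8_within_three_se(self, habsburg):
        gd = pr.gene_drop(habsburg, "Philip_IV", "Mariana", n=100_000, seed=5)
        exact = float(pr.condensed_identity(habsburg, "Philip_IV", "Mariana")[7])
        assert abs(gd.freq[7] - exact) <= 3 * gd.se[7]

    def test_x_gene_drop_matches_recursion(self, habsburg):
        gd = pr.gene_drop(habsburg, "Charles_II", "Mariana", n=100_000,
                          seed=13, chromosome="X")
        exact = [float(x) for x in
                 pr.condensed_identity_x(habsburg, "Charles_II", "Mariana")]
        for est, ex, se in zip(gd.freq, exact, gd.se):
            assert abs(est - ex) <= 3 * se + 1e-12
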