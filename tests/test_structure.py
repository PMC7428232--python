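import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from galaxpop.errors import DegenerateInputError
from galaxpop.seq_io import Alignment, SampleTable
from galaxpop.structure import (
    amova3,
    gene_flow_from_fst,
    pairwise_distance_matrix,
    pairwise_structure_table,
    phi_st_pairwise,
)

from conftest import iid_alignment, random_alignment
from oracles import (
    brute_pairwise_differences,
    three_level_amova_reference,
    two_level_amova_reference,
)


def meta_for(aln, zones, localities=None, zoneset=("Z1", "Z2", "Z3", "Z4")):
    df = pd.DataFrame(
        {
            "sample_id": aln.ids,
            "species": "sp",
            "zone": zones,
            "locality": localities if localities is not None else zones,
        }
    )
    return SampleTable(df, zones=zoneset)


class TestDistanceMatrix:
    def test_single_difference(self):
        d = pairwise_distance_matrix(Alignment(["a", "b"], ["AAA", "AAT"]))
        assert d.tolist() == [[0, 1], [1, 0]]

    def test_identical_sequences_zero_matrix(self):
        d = pairwise_distance_matrix(Alignment(list("abc"), ["ACG"] * 3))
        assert not d.any()

    @pytest.mark.parametrize("policy", ["complete", "pairwise"])
    def test_matches_brute_force(self, rng, policy):
        aln = random_alignment(rng, 7, 30, p_missing=0.08)
        d = pairwise_distance_matrix(aln, policy=policy)
        assert np.allclose(d, d.T, equal_nan=True)
        if policy == "pairwise":
            expected = np.array(brute_pairwise_differences(aln.seqs))
            assert np.allclose(d, expected, equal_nan=True)
        else:
            from oracles import brute_pi_locus, complete_sites_of

            sites = complete_sites_of(aln.seqs)
            iu = np.triu_indices(aln.n, 1)
            assert d[iu].mean() == pytest.approx(
                brute_pi_locus(aln.seqs, sites)
            )


class TestPhiStPairwise:
    def test_fixed_between_zero_within(self):
        # two populations, identical within, 5 differences between
        aln = Alignment(
            list("abcd"), ["AAAAACCCCC", "AAAAACCCCC", "TTTTTCCCCC", "TTTTTCCCCC"]
        )
        res = phi_st_pairwise(aln, ["p1", "p1", "p2", "p2"], n_perms=0)
        assert res.phi_st == pytest.approx(1.0)
        assert math.isinf(res.nm) is False and res.nm < 1e-6

    def test_no_variation_guarded_zero(self):
        aln = Alignment(list("abcd"), ["ACGT"] * 4)
        res = phi_st_pairwise(aln, ["p1", "p1", "p2", "p2"], n_perms=0)
        assert res.phi_st == 0.0
        assert math.isinf(res.nm)

    def test_matches_variance_component_oracle(self, rng):
        for _ in range(5):
            aln = random_alignment(rng, 8, 40)
            labels = ["p1"] * 3 + ["p2"] * 5
            res = phi_st_pairwise(aln, labels, n_perms=0)
            d = pairwise_distance_matrix(aln)
            _, _, phi_ref = two_level_amova_reference(
                d, [[0, 1, 2], [3, 4, 5, 6, 7]]
            )
            assert res.phi_st == pytest.approx(phi_ref, abs=1e-12)

    def test_small_population_rejected(self):
        aln = Alignment(list("abc"), ["AAA", "AAT", "ATT"])
        with pytest.raises(DegenerateInputError):
            phi_st_pairwise(aln, ["p1", "p1", "p2"], n_perms=0)

    def test_permutation_p_uniform_under_null(self, rng):
        """Label-shuffled data gives uniform permutation p-values."""
        pvals = []
        for _ in range(120):
            aln = iid_alignment(rng, 16, 30)
            labels = rng.permutation(["p1"] * 8 + ["p2"] * 8)
            res = phi_st_pairwise(aln, labels, n_perms=80, seed=rng)
            pvals.append(res.p_value)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestGeneFlow:
    def test_island_model_value(self):
        assert gene_flow_from_fst(1 / 3) == pytest.approx(1.0)

    def test_nonpositive_f_infinite_flow(self):
        assert math.isinf(gene_flow_from_fst(0.0))
        assert math.isinf(gene_flow_from_fst(-0.0384))

    def test_f_at_least_one_rejected(self):
        with pytest.raises(ValueError):
            gene_flow_from_fst(1.0)


class TestAmova:
    def nested_fixture(self, rng, sizes=(2, 3, 3, 4)):
        n = sum(sizes)
        aln = random_alignment(rng, n, 40)
        bounds = np.cumsum((0,) + sizes)
        pops = [list(range(bounds[i], bounds[i + 1])) for i in range(4)]
        return aln, pops

    def test_components_match_brute_force(self, rng):
        for _ in range(5):
            aln, pops = self.nested_fixture(rng)
            zones = np.empty(aln.n, dtype=object)
            for z, pop in zip(("Z1", "Z2", "Z3", "Z4"), pops):
                zones[pop] = z
            meta = meta_for(aln, zones.tolist())
            res = amova3(
                aln, meta, [["Z1", "Z2"], ["Z3", "Z4"]], n_perms=0
            )
            d = pairwise_distance_matrix(aln)
            ref = three_level_amova_reference(
                d, [[pops[0], pops[1]], [pops[2], pops[3]]]
            )
            for key in ref:
                assert res.sigma[key] == pytest.approx(ref[key], abs=1e-9)
            assert sum(res.percent.values()) == pytest.approx(100.0, abs=0.01)

    def test_all_identical_degenerate_flag(self):
        aln = Alignment([f"s{i}" for i in range(8)], ["ACGT"] * 8)
        meta = meta_for(aln, ["Z1"] * 2 + ["Z2"] * 2 + ["Z3"] * 2 + ["Z4"] * 2)
        res = amova3(aln, meta, [["Z1", "Z2"], ["Z3", "Z4"]], n_perms=10)
        assert res.degenerate
        assert res.phi_st == 0.0 and res.phi_ct == 0.0

    def test_limiting_strong_group_structure(self):
        # within-population variance zero, groups far apart
        seq_g1 = "AAAAAAAAAA"
        seq_g2 = "TTTTTTTTTT"
        aln = Alignment(
            [f"s{i}" for i in range(8)], [seq_g1] * 4 + [seq_g2] * 4
        )
        meta = meta_for(aln, ["Z1"] * 2 + ["Z2"] * 2 + ["Z3"] * 2 + ["Z4"] * 2)
        res = amova3(aln, meta, [["Z1", "Z2"], ["Z3", "Z4"]], n_perms=0)
        assert res.phi_ct > 0.9
        assert res.percent["within_pops"] == pytest.approx(0.0, abs=1e-9)

    def test_negative_components_retained(self, rng):
        """Panmictic data can give negative among-group components; they are
        reported as-is and the percentages still sum to 100."""
        saw_negative = False
        for _ in range(20):
            aln, pops = self.nested_fixture(rng, sizes=(3, 3, 3, 3))
            zones = np.empty(aln.n, dtype=object)
            for z, pop in zip(("Z1", "Z2", "Z3", "Z4"), pops):
                zones[pop] = z
            meta = meta_for(aln, zones.tolist())
            res = amova3(aln, meta, [["Z1", "Z3"], ["Z2", "Z4"]], n_perms=0)
            assert sum(res.percent.values()) == pytest.approx(100.0, abs=0.01)
            if res.percent["among_groups"] < 0:
                saw_negative = True
        assert saw_negative

    def test_two_pops_one_group_reproduces_pairwise(self, rng):
        aln = random_alignment(rng, 10, 30)
        zones = ["Z1"] * 4 + ["Z2"] * 6
        meta = meta_for(aln, zones, zoneset=("Z1", "Z2"))
        with pytest.warns(UserWarning, match="single-group"):
            res = amova3(aln, meta, [["Z1", "Z2"]], n_perms=0)
        pair = phi_st_pairwise(aln, zones, n_perms=0)
        assert res.phi_st == pytest.approx(pair.phi_st, abs=1e-12)

    def test_phi_values_recover_components(self, rng):
        aln, pops = self.nested_fixture(rng)
        zones = np.empty(aln.n, dtype=object)
        for z, pop in zip(("Z1", "Z2", "Z3", "Z4"), pops):
            zones[pop] = z
        meta = meta_for(aln, zones.tolist())
        res = amova3(aln, meta, [["Z1"], ["Z2", "Z3", "Z4"]], n_perms=0)
        sa, sb, sc = (
            res.sigma["among_groups"],
            res.sigma["among_pops"],
            res.sigma["within_pops"],
        )
        tot = sa + sb + sc
        assert res.phi_ct == pytest.approx(sa / tot)
        assert res.phi_sc == pytest.approx(sb / (sb + sc))
        assert res.phi_st == pytest.approx((sa + sb) / tot)


def test_pairwise_structure_table_layout(rng):
    aln = random_alignment(rng, 16, 40)
    zones = ["Z1"] * 4 + ["Z2"] * 4 + ["Z3"] * 4 + ["Z4"] * 4
    meta = meta_for(aln, zones)
    tab = pairwise_structure_table(aln, meta, n_perms=50, seed=3)
    assert list(tab.index) == ["Z1", "Z2", "Z3", "Z4"]
    # below-diagonal cells hold Phi, above-diagonal the matching Nm
    phi_21 = float(tab.loc["Z2", "Z1"].rstrip("*"))
    nm_12 = tab.loc["Z1", "Z2"]
    expected = gene_flow_from_fst(min(phi_21, 1 - 1e-12))
    if math.isinf(expected):
        assert nm_12 == "inf"
    else:
        assert float(nm_12) == pytest.approx(expected, abs=0.005)
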