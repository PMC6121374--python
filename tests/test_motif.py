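"""FFL classification, enumeration and census bookkeeping."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from crpffl.motif import (
    FFL_TYPES,
    FFLCensus,
    FFLInstance,
    census_summary,
    classify_signs,
    enumerate_ffls,
    is_coherent,
    multi_output_groups,
)
from crpffl.regnet import Effect, RegulatoryInteraction, build_network

from conftest import brute_force_ffls, random_signed_network

sign = st.sampled_from([+1, -1])


def net_from(edges, tfs):
    """edges: {(u, v): +1/-1}"""
    recs = [
        RegulatoryInteraction(u, v, Effect.ACTIVATION if s > 0 else Effect.REPRESSION)
        for (u, v), s in edges.items()
    ]
    return build_network(recs, tfs)


class TestClassifySigns:
    @pytest.mark.parametrize(
        "signs, expected",
        [
            ((+1, +1, +1), "Coh1"),
            ((-1, +1, -1), "Coh2"),  # the gadA/GadX configuration
            ((+1, -1, -1), "Coh3"),
            ((-1, -1, +1), "Coh4"),
            ((+1, -1, +1), "InCoh1"),
            ((-1, -1, -1), "InCoh2"),
            ((+1, +1, -1), "InCoh3"),
            ((-1, +1, +1), "InCoh4"),
        ],
    )
    def test_sign_table(self, signs, expected):
        assert classify_signs(*signs) == expected

    @given(sign, sign, sign)
    def test_coherence_iff_sign_product(self, sxy, syz, sxz):
        label = classify_signs(sxy, syz, sxz)
        assert is_coherent(label) == (sxz == sxy * syz)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            classify_signs(0, 1, 1)


class TestEnumerate:
    def test_minimal_triangle(self):
        net = net_from({("A", "B"): +1, ("B", "C"): +1, ("A", "C"): +1}, {"A", "B"})
        census = enumerate_ffls(net, "A", {"B"})
        assert len(census.instances) == 1
        inst = census.instances[0]
        assert inst.ffl_type == "Coh1" and census.sffl == [inst] and not census.mffl

    def test_two_tf_target_is_multi_y(self):
        # gadA-like: master represses both TFs and the target; both TFs act on it
        net = net_from(
            {("crp", "gadX"): -1, ("crp", "fis"): +1, ("crp", "gadA"): -1,
             ("gadX", "gadA"): +1, ("fis", "gadA"): +1},
            {"crp", "gadX", "fis"},
        )
        census = enumerate_ffls(net, "crp", {"gadX", "fis"})
        assert len(census.instances) == 2
        assert census.arity["gadA"] == 2
        assert len(census.mffl) == 2 and not census.sffl
        assert {i.ffl_type for i in census.instances} == {"Coh2", "InCoh3"}

    def test_removing_one_y_edge_demotes_to_single(self):
        edges = {("crp", "y1"): +1, ("crp", "y2"): +1, ("crp", "z"): +1,
                 ("y1", "z"): +1, ("y2", "z"): +1}
        tfs = {"crp", "y1", "y2"}
        census = enumerate_ffls(net_from(edges, tfs), "crp", {"y1", "y2"})
        assert len(census.mffl) == 2
        del edges[("y2", "z")]
        census2 = enumerate_ffls(net_from(edges, tfs), "crp", {"y1", "y2"})
        assert len(census2.sffl) == 1 and not census2.mffl

    def test_master_not_in_network(self):
        net = net_from({("A", "B"): +1}, {"A"})
        with pytest.raises(ValueError, match="master"):
            enumerate_ffls(net, "zzz", {"A"})

    def test_self_loops_ignored(self):
        net = net_from(
            {("A", "A"): +1, ("B", "B"): -1, ("A", "B"): +1,
             ("B", "C"): +1, ("A", "C"): +1},
            {"A", "B"},
        )
        census = enumerate_ffls(net, "A", {"A", "B"})
        assert [(i.y, i.z) for i in census.instances] == [("B", "C")]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        interactions, master, tf_set = random_signed_network(seed, n_nodes=25)
        net = build_network(interactions, tf_set)
        census = enumerate_ffls(net, master, tf_set)
        got = sorted(
            (i.y, i.z, i.sign_xy, i.sign_yz, i.sign_xz, i.ffl_type)
            for i in census.instances
        )
        assert got == brute_force_ffls(net, master, tf_set)

    def test_partition_is_exhaustive_and_disjoint(self):
        interactions, master, tf_set = random_signed_network(99, n_nodes=30)
        census = enumerate_ffls(build_network(interactions, tf_set), master, tf_set)
        s, m = census.sffl, census.mffl
        assert len(s) + len(m) == len(census.instances)
        assert not (set(s) & set(m))
        assert sum(census.per_type_counts.values()) == len(census.instances)


class TestCensusTables:
    def test_multi_output_groups(self):
        insts = [
            FFLInstance("A", "B", "C1", +1, +1, +1, "Coh1"),
            FFLInstance("A", "B", "C2", +1, +1, +1, "Coh1"),
            FFLInstance("A", "D", "C1", +1, -1, +1, "InCoh1"),
        ]
        groups = multi_output_groups(FFLCensus("A", insts))
        assert groups == {("A", "B"): ["C1", "C2"]}

    def test_multi_output_single_instance_empty(self):
        census = FFLCensus("A", [FFLInstance("A", "B", "C", +1, +1, +1, "Coh1")])
        assert multi_output_groups(census) == {}

    def test_summary_counts(self):
        insts = [
            FFLInstance("A", "B", "C", +1, +1, +1, "Coh1"),
            FFLInstance("A", "D", "C", +1, +1, +1, "Coh1"),
            FFLInstance("A", "B", "E", +1, -1, +1, "InCoh1"),
        ]
        df = census_summary(FFLCensus("A", insts))
        assert df.loc["Coh1", "n_ffls"] == 2
        assert df.loc["Coh1", "n_genes"] == 1
        assert df.loc["Coh1", "n_tfs"] == 2
        assert df.loc["Total", "n_ffls"] == 3 and df.loc["Total", "n_genes"] == 2
        assert df.attrs["n_sffl"] == 1 and df.attrs["n_mffl"] == 2

    def test_empty_census_all_zero(self):
        df = census_summary(FFLCensus("A", []))
        assert (df["n_ffls"] == 0).all()
        assert set(df.index) == set(FFL_TYPES) | {"Total"}
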