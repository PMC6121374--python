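"""Correlation distance, hierarchical grouping, shape rules and FG merging."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from crpffl.clustering import (
    SHAPES,
    FunctionalGroup,
    ProfileGroup,
    build_profile_groups,
    correlation_distance,
    group_cohesion,
    hierarchical_groups,
    label_shape,
    merge_functional_groups,
)
from crpffl.doseresponse import DOSE_GRID, DoseResponseProfile, compute_profiles
from crpffl.synthetic import SyntheticExpressionSpec, base_shape, generate_expression

POS = tuple(d for d in DOSE_GRID if d > 0)


def prof(gene, values):
    return DoseResponseProfile(gene, POS[: len(values)], np.asarray(values, float))


class TestCorrelationDistance:
    def test_identity_zero(self):
        p = [0.1, 0.5, 1.0, 1.2, 1.3, 1.3, 1.3]
        assert correlation_distance(p, p) == pytest.approx(0.0)

    def test_anticorrelation_two(self):
        p = np.array([0.1, 0.5, 1.0, 1.2, 1.3, 1.3, 1.35])
        assert correlation_distance(p, -p) == pytest.approx(2.0)

    def test_scale_invariance(self):
        p = [1, 2, 3, 4, 5, 6, 7]
        q = [2, 4, 6, 8, 10, 12, 14]
        assert correlation_distance(p, q) == pytest.approx(0.0)

    def test_zero_variance_gives_one(self):
        assert correlation_distance([1, 1, 1], [0, 2, 5]) == 1.0
        assert correlation_distance([1, 1, 1], [1, 1, 1]) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            correlation_distance([1, 2], [1, 2, 3])

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p, q = rng.normal(size=7), rng.normal(size=7)
            d1, d2 = correlation_distance(p, q), correlation_distance(q, p)
            assert d1 == pytest.approx(d2)
            assert 0.0 <= d1 <= 2.0


class TestHierarchicalGroups:
    def two_shape_profiles(self):
        up = base_shape("saturating_up", np.array(POS), 2.0)
        down = base_shape("monotone_down", np.array(POS), 2.0)
        rng = np.random.default_rng(1)
        return [
            prof("u1", up + rng.normal(0, 0.05, 7)),
            prof("u2", up + rng.normal(0, 0.05, 7)),
            prof("d1", down + rng.normal(0, 0.05, 7)),
            prof("d2", down + rng.normal(0, 0.05, 7)),
        ]

    def test_two_shapes_separate_and_match_brute_force(self):
        profiles = self.two_shape_profiles()
        assign, _, genes = hierarchical_groups(profiles, 2)
        got = frozenset(
            frozenset(g for g in genes if assign[g] == c) for c in (1, 2)
        )
        # oracle: of the 7 bipartitions of 4 items, pick the one with the
        # smallest total within-group distance
        dist = {
            (p.gene, q.gene): correlation_distance(p.log2fc, q.log2fc)
            for p, q in itertools.combinations(profiles, 2)
        }

        def within(partition):
            return sum(
                dist.get((a, b), dist.get((b, a), 0.0))
                for part in partition
                for a, b in itertools.combinations(sorted(part), 2)
            )

        names = [p.gene for p in profiles]
        best = min(
            (
                frozenset([frozenset(c), frozenset(set(names) - set(c))])
                for r in (1, 2)
                for c in itertools.combinations(names, r)
            ),
            key=within,
        )
        assert got == best == frozenset([frozenset({"u1", "u2"}), frozenset({"d1", "d2"})])

    def test_k_equals_n_gives_singletons(self):
        profiles = self.two_shape_profiles()
        assign, _, _ = hierarchical_groups(profiles, 4)
        assert sorted(assign.values()) == [1, 2, 3, 4]

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_groups(self.two_shape_profiles(), 5)

    def test_permutation_invariance_and_relabeling(self):
        profiles = self.two_shape_profiles() + [
            prof("x1", base_shape("bell", np.array(POS), 2.0))
        ]
        a1, _, _ = hierarchical_groups(profiles, 2)
        a2, _, _ = hierarchical_groups(profiles[::-1], 2)
        assert a1 == a2
        sizes = {c: sum(1 for v in a1.values() if v == c) for c in set(a1.values())}
        assert sizes[1] == max(sizes.values())  # group 1 is the largest

    def test_planted_five_shapes_recovered(self):
        for seed in range(5):
            spec = SyntheticExpressionSpec(
                shape_counts={s: 8 for s in SHAPES}, amplitude=2.0,
                noise_sd=0.1, seed=seed,
            )
            matrix, truth = generate_expression(spec)
            profiles = compute_profiles(matrix)
            assign, _, genes = hierarchical_groups(profiles, 5)
            ari = adjusted_rand_score(
                [truth[g] for g in genes], [assign[g] for g in genes]
            )
            assert ari >= 0.9


class TestLabelShape:
    def test_saturating_example(self):
        assert label_shape([0.1, 0.4, 1.2, 1.6, 1.8, 1.8, 1.8], POS) == "saturating_up"

    def test_bell_example(self):
        assert label_shape([0.0, 0.3, 1.5, 2.0, 0.6, 0.1, 0.0], POS) == "bell"

    def test_all_zero_unclassified(self):
        assert label_shape([0.0] * 7, POS) == "unclassified"

    @pytest.mark.parametrize("shape", SHAPES)
    def test_canonical_generators_are_labeled_as_themselves(self, shape):
        p = base_shape(shape, np.array(POS), 2.0)
        assert label_shape(p, POS) == shape

    @pytest.mark.parametrize("shape", SHAPES)
    def test_shift_invariance(self, shape):
        p = base_shape(shape, np.array(POS), 2.0)
        assert label_shape(p + 0.7, POS) == shape

    def test_too_short_profile_rejected(self):
        with pytest.raises(ValueError):
            label_shape([0, 1, 2], POS[:3])


def make_group(gid, shape, amplitude=2.0):
    p = base_shape(shape, np.array(POS), amplitude)
    return ProfileGroup(
        group_id=gid, members=[], genes=[f"{gid}_gene"], mean_profile=p,
        shape=shape, type_composition=frozenset(),
    )


class TestFunctionalGroups:
    def test_pairing_by_shape(self):
        sg = [make_group(f"SG{i+1}", s) for i, s in enumerate(SHAPES)]
        mg = [make_group(f"MG{i+1}", s, amplitude=1.5) for i, s in enumerate(SHAPES)]
        fgs = merge_functional_groups(sg, mg)
        assert len(fgs) == 5
        for fg, shape in zip(fgs, SHAPES):
            assert fg.member_groups == [f"SG{SHAPES.index(shape)+1}", f"MG{SHAPES.index(shape)+1}"]

    def test_anticorrelated_mg_forms_own_fg(self):
        sg = [make_group("SG1", "saturating_up")]
        mg = [make_group("MG1", "monotone_down")]
        fgs = merge_functional_groups(sg, mg)
        assert len(fgs) == 2
        assert fgs[1].member_groups == ["MG1"]

    def test_single_sg_no_mg(self):
        fgs = merge_functional_groups([make_group("SG1", "bell")], [])
        assert len(fgs) == 1 and fgs[0].member_groups == ["SG1"]

    def test_group_cohesion_high_for_identical_shapes(self):
        profiles = [
            prof(f"g{i}", base_shape("sigmoid_threshold", np.array(POS), 2.0)
                 + np.random.default_rng(i).normal(0, 0.05, 7))
            for i in range(6)
        ]
        grp = ProfileGroup("SG1", [], [p.gene for p in profiles],
                           np.vstack([p.log2fc for p in profiles]).mean(axis=0),
                           "sigmoid_threshold")
        assert group_cohesion(grp, profiles) > 0.95
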