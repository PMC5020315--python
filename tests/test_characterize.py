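"""Intrusion tests, topic hierarchy, community profiles and exposure."""

import math

import numpy as np
import pytest

from commalign import (
    ContingencyTable,
    ThemeMap,
    build_hierarchy,
    classical_mds,
    community_profiles,
    exposure_analysis,
    generate_intrusion_cases,
    hierarchy_to_newick,
    majority_theme,
    percentages_from_counts,
    score_intrusion,
    topic_distance_matrix,
)
from commalign.characterize import CommunityProfile, IntrusionCase


def assignment_with(topics, posts_per_topic=10):
    return {
        f"t{t}p{i}": t for t in topics for i in range(posts_per_topic)
    }


def simple_theme_map():
    return ThemeMap(
        topic_to_group={0: "clinical evidence", 1: "side effects and harms", 2: "experiences"},
        group_to_theme={
            "clinical evidence": "evidence/advocacy",
            "side effects and harms": "harms/conspiracies",
            "experiences": "experiential",
        },
    )


class TestIntrusionCases:
    @pytest.mark.parametrize(
        "n_topics,k,expected",
        [(31, 5, 4650), (2, 5, 10), (3, 1, 6)],
    )
    def test_case_count_is_ordered_pairs_times_k(self, n_topics, k, expected):
        assignment = assignment_with(range(n_topics))
        cases = generate_intrusion_cases(
            assignment, topics=list(range(n_topics)), k_per_pair=k, seed=0
        )
        assert len(cases) == expected

    def test_case_structure(self):
        assignment = assignment_with(range(3))
        cases = generate_intrusion_cases(assignment, topics=[0, 1, 2], seed=1)
        for c in cases:
            assert len(c.post_ids) == 6
            assert len(set(c.post_ids)) == 6  # without replacement
            intruder = c.post_ids[c.intruder_position]
            assert assignment[intruder] == c.intruder_topic
            others = [p for i, p in enumerate(c.post_ids) if i != c.intruder_position]
            assert all(assignment[p] == c.base_topic for p in others)

    def test_small_topic_pairs_skipped(self):
        assignment = {**assignment_with([0, 1]), "t2p0": 2}  # topic 2 has 1 post
        with pytest.warns(UserWarning, match="skipping"):
            cases = generate_intrusion_cases(assignment, topics=[0, 1, 2], seed=0)
        assert len(cases) == 10  # only the 0<->1 pairs survive

    def test_intruder_position_varies(self):
        assignment = assignment_with([0, 1], posts_per_topic=30)
        cases = generate_intrusion_cases(
            assignment, topics=[0, 1], k_per_pair=50, seed=2
        )
        assert len({c.intruder_position for c in cases}) == 6

    def test_seed_determinism(self):
        assignment = assignment_with([0, 1])
        a = generate_intrusion_cases(assignment, topics=[0, 1], seed=3)
        b = generate_intrusion_cases(assignment, topics=[0, 1], seed=3)
        assert a == b


class TestScoring:
    def make_cases(self):
        assignment = assignment_with(range(3))
        return generate_intrusion_cases(
            assignment, topics=[0, 1, 2], k_per_pair=2, seed=4
        )

    def test_all_correct(self):
        cases = self.make_cases()
        responses = {c.case_id: c.intruder_position for c in cases}
        report = score_intrusion(cases, responses)
        assert report["overall_accuracy"] == 1.0
        assert report["chance_level"] == pytest.approx(1 / 6)

    def test_uniform_responder_hits_chance_in_expectation(self):
        # averaging the indicator over all six positions equals 1/6 exactly
        cases = self.make_cases()
        acc = np.mean(
            [
                score_intrusion(cases, {c.case_id: pos for c in cases})[
                    "overall_accuracy"
                ]
                for pos in range(6)
            ]
        )
        assert acc == pytest.approx(1 / 6)

    def test_partial_accuracy(self):
        cases = self.make_cases()[:5]
        responses = {}
        for i, c in enumerate(cases):
            responses[c.case_id] = (
                c.intruder_position if i < 3 else (c.intruder_position + 1) % 6
            )
        report = score_intrusion(cases, responses)
        assert report["overall_accuracy"] == pytest.approx(0.6)

    def test_group_split(self):
        cases = self.make_cases()
        grouping = {0: "g1", 1: "g1", 2: "g2"}
        responses = {c.case_id: c.intruder_position for c in cases}
        report = score_intrusion(cases, responses, grouping=grouping)
        # ordered pairs within g1: (0,1),(1,0) -> 2 pairs x 2 cases
        assert report["n_intragroup"] == 4
        assert report["n_intergroup"] == 8
        assert report["intergroup_accuracy"] == 1.0

    def test_unknown_case_rejected(self):
        cases = self.make_cases()
        with pytest.raises(ValueError, match="unknown"):
            score_intrusion(cases, {"nope": 0})


class TestTopicDistances:
    def test_identical_distributions_zero_distance(self):
        counts = np.array([[5, 5, 0], [5, 5, 0]])
        d = topic_distance_matrix(topic_word_counts=counts, beta=0.01)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_ln2(self):
        counts = np.array([[1000, 0], [0, 1000]])
        d = topic_distance_matrix(topic_word_counts=counts, beta=1e-9)
        assert d[0, 1] == pytest.approx(math.log(2), rel=1e-4)

    def test_matches_hand_js_computation(self):
        p = np.array([0.5, 0.3, 0.2])
        q = np.array([0.2, 0.2, 0.6])
        m = 0.5 * (p + q)
        kl = lambda a, b: float(np.sum(a * np.log(a / b)))
        expected = 0.5 * kl(p, m) + 0.5 * kl(q, m)
        d = topic_distance_matrix(topic_word_counts=np.array([p, q]) * 1e9, beta=1e-9)
        assert d[0, 1] == pytest.approx(expected, rel=1e-5)

    def test_symmetry_zero_diagonal(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, size=(5, 20))
        d = topic_distance_matrix(topic_word_counts=counts)
        np.testing.assert_allclose(d, d.T)
        assert (np.diag(d) == 0).all() and (d >= 0).all()

    def test_intrusion_backend_confusion_lowers_distance(self):
        assignment = assignment_with(range(3))
        cases = generate_intrusion_cases(
            assignment, topics=[0, 1, 2], k_per_pair=4, seed=5
        )
        responses = {}
        for c in cases:
            pair = {c.base_topic, c.intruder_topic}
            # topics 0 and 1 always confused, pairs with topic 2 always spotted
            if pair == {0, 1}:
                responses[c.case_id] = (c.intruder_position + 1) % 6
            else:
                responses[c.case_id] = c.intruder_position
        d = topic_distance_matrix(
            intrusion_cases=cases, intrusion_responses=responses, topics=[0, 1, 2]
        )
        assert d[0, 1] == 0.0
        assert d[0, 2] == 1.0 and d[1, 2] == 1.0
        np.testing.assert_allclose(d, d.T)

    def test_missing_pair_imputed_with_warning(self):
        assignment = assignment_with(range(3))
        cases = generate_intrusion_cases(
            assignment, topics=[0, 1, 2], k_per_pair=1, seed=6
        )
        answered = {
            c.case_id: c.intruder_position
            for c in cases
            if {c.base_topic, c.intruder_topic} == {0, 1}
        }
        with pytest.warns(UserWarning, match="imputed"):
            d = topic_distance_matrix(
                intrusion_cases=cases, intrusion_responses=answered, topics=[0, 1, 2]
            )
        assert d[0, 2] == 1.0


class TestHierarchy:
    def test_two_topics_single_merge_at_distance(self):
        d = np.array([[0.0, 0.8], [0.8, 0.0]])
        z = build_hierarchy(d)
        assert z.shape == (1, 4)
        assert z[0, 2] == pytest.approx(0.8, rel=1e-6)

    def test_planted_pairs_merge_first(self):
        d = np.full((4, 4), 1.0)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 0.1
        d[2, 3] = d[3, 2] = 0.1
        z = build_hierarchy(d)
        first_two = {frozenset(z[0, :2].astype(int)), frozenset(z[1, :2].astype(int))}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        z = build_hierarchy(d)
        heights = z[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_asymmetric_input_rejected(self):
        d = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            build_hierarchy(d)

    def test_classical_mds_recovers_line(self):
        # three collinear points embed with pairwise distances preserved
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        x = classical_mds(d, n_components=2)
        got = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        np.testing.assert_allclose(got, d, atol=1e-8)

    def test_newick_output_parses(self):
        d = np.array([[0.0, 0.4, 1.0], [0.4, 0.0, 1.0], [1.0, 1.0, 0.0]])
        z = build_hierarchy(d)
        nwk = hierarchy_to_newick(z, labels=[0, 1, 2])
        assert nwk.endswith(");") and nwk.count(",") == 2
        import io

        from Bio import Phylo

        tree = Phylo.read(io.StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["0", "1", "2"]


def profile_table():
    # communities x topics (topics 0=evidence, 1=harms, 2=experiential)
    counts = np.array([[10, 0, 0], [2, 8, 2], [1, 1, 4]])
    return ContingencyTable(counts, [0, 1, 2], [0, 1, 2])


class TestProfiles:
    def test_single_theme_community(self):
        profiles = community_profiles(
            profile_table(), simple_theme_map(), {0: 5, 1: 6, 2: 3}
        )
        assert profiles[0].theme_proportions == {"evidence/advocacy": 1.0}

    def test_mean_posts_per_user(self):
        profiles = community_profiles(
            profile_table(), simple_theme_map(), {0: 5, 1: 6, 2: 3}
        )
        assert profiles[1].mean_posts_per_user == pytest.approx(12 / 6)
        assert profiles[2].mean_posts_per_user == pytest.approx(2.0)

    def test_proportions_sum_to_one(self):
        profiles = community_profiles(
            profile_table(), simple_theme_map(), {0: 5, 1: 6, 2: 3}
        )
        for p in profiles:
            assert sum(p.theme_proportions.values()) == pytest.approx(1.0)

    def test_unmapped_topic_policy(self):
        counts = np.array([[3, 2]])
        t = ContingencyTable(counts, [0], [0, 99])
        with pytest.raises(ValueError, match="theme map"):
            community_profiles(t, simple_theme_map(), {0: 2})
        profiles = community_profiles(t, simple_theme_map(), {0: 2}, unmapped="other")
        assert profiles[0].theme_proportions["other"] == pytest.approx(0.4)

    def test_majority_theme(self):
        p = CommunityProfile(0, {}, {"evidence/advocacy": 0.5, "harms/conspiracies": 0.3,
                                     "experiential": 0.2}, 1, 1.0)
        assert majority_theme(p) == "evidence/advocacy"
        single = CommunityProfile(1, {}, {"experiential": 1.0}, 1, 1.0)
        assert majority_theme(single) == "experiential"

    def test_majority_tie_rule(self):
        p = CommunityProfile(
            0, {}, {"experiential": 0.5, "harms/conspiracies": 0.5}, 1, 1.0
        )
        with pytest.warns(UserWarning, match="tie"):
            assert majority_theme(p) == "harms/conspiracies"


class TestExposure:
    def test_percentages_recompute_exactly_from_counts(self):
        counts = {"a": 3449, "b": 674, "c": 196, "d": 229}
        pct = percentages_from_counts(counts)
        assert pct == {"a": 75.84, "b": 14.82, "c": 4.31, "d": 5.04}
        assert sum(pct.values()) == pytest.approx(100, abs=0.05)

    def test_all_in_one_category(self):
        theme_map = simple_theme_map()
        # one community whose majority is experiential; all posters inside
        counts = np.array([[1, 1, 8]])
        table = ContingencyTable(counts, [0], [0, 1, 2])
        assignment = {"p0": 2, "p1": 2}
        authors = {"p0": "u0", "p1": "u1"}
        report = exposure_analysis(
            assignment, authors, {"u0": 0, "u1": 0}, theme_map, table, {0: 2}
        )
        assert report.counts == {"experiential": 2}
        assert report.percentages == {"experiential": 100.0}

    def test_categories_partition_users(self):
        theme_map = simple_theme_map()
        table = profile_table()
        membership = {"u0": 0, "u1": 1, "u2": 2}
        assignment = {"p0": 2, "p1": 2, "p2": 2, "p3": 0}
        authors = {"p0": "u0", "p1": "u2", "p2": "outsider", "p3": "u1"}
        report = exposure_analysis(
            assignment, authors, membership, theme_map, table,
            {0: 1, 1: 1, 2: 1}, non_core_users={"outsider"},
        )
        assert sum(report.counts.values()) == report.n_users == 3
        assert report.counts["not connected"] == 1

    def test_inconsistent_user_rejected(self):
        theme_map = simple_theme_map()
        table = profile_table()
        report_args = (
            {"p0": 2}, {"p0": "ghost"}, {"u0": 0}, theme_map, table, {0: 1, 1: 1, 2: 1},
        )
        with pytest.raises(ValueError, match="neither"):
            exposure_analysis(*report_args, non_core_users=set())

    def test_theme_map_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "themes.yaml"
        path.write_text(
            "groups:\n  clinical evidence: evidence/advocacy\n"
            "  experiences: experiential\n"
            "topics:\n  0: clinical evidence\n  1: experiences\n"
        )
        tm = ThemeMap.from_yaml(path)
        assert tm.theme(0) == "evidence/advocacy"
        assert tm.group(1) == "experiences"
        assert set(tm.themes) == {"evidence/advocacy", "experiential"}
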