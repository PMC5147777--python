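"""Path counting, classification, statistics and coverage on single landscapes."""

import numpy as np
import pytest

from flaccess.landscape import (
    FitnessLandscape,
    LandscapeShape,
    encode,
    generate_hoc,
    set_initial_fitness,
    uniformize_ranks,
)
from flaccess.paths import (
    MODES,
    PathQuery,
    admissible_successors,
    classify_step,
    count_paths,
    coverage,
    is_accessible,
    path_stats,
    step_class_totals,
)

from conftest import enumerate_paths, oracle_stats, random_landscapes


class TestClassifyStep:
    def test_single_site_examples(self):
        shape = LandscapeShape(4, 1)
        assert classify_step(0, 3, 3, shape) == "forward"
        assert classify_step(0, 1, 3, shape) == "distance_neutral"
        assert classify_step(3, 1, 3, shape) == "backward"

    def test_binary_never_neutral(self):
        shape = LandscapeShape(2, 4)
        rng = np.random.default_rng(0)
        for _ in range(40):
            g = int(rng.integers(shape.N))
            p = int(rng.integers(shape.L))
            h = g ^ (1 << p)
            assert classify_step(g, h, shape.N - 1, shape) in ("forward", "backward")

    def test_rejects_non_adjacent(self):
        shape = LandscapeShape(2, 3)
        with pytest.raises(ValueError):
            classify_step(0, 3, 7, shape)


class TestAdmissibleSuccessors:
    def test_all_mode_single_site(self):
        fl = FitnessLandscape(LandscapeShape(4, 1), np.array([0.1, 0.2, 0.3, 0.9]))
        assert admissible_successors(0, fl).tolist() == [1, 2, 3]
        assert admissible_successors(0, fl, PathQuery("shortest_only")).tolist() == [3]
        # target has maximal fitness: no successors
        assert admissible_successors(3, fl).tolist() == []

    def test_binary_shortest_equals_no_backward(self):
        fl = generate_hoc(LandscapeShape(2, 5), 3)
        for g in range(fl.shape.N):
            a = admissible_successors(g, fl, PathQuery("no_backward")).tolist()
            b = admissible_successors(g, fl, PathQuery("shortest_only")).tolist()
            assert a == b


class TestIsAccessible:
    def test_single_locus_always_accessible(self):
        for K in (2, 3, 4, 7):
            fl = generate_hoc(LandscapeShape(K, 1), K)
            assert is_accessible(fl)

    def test_handworked_binary_examples(self):
        shape = LandscapeShape(2, 2)
        assert not is_accessible(FitnessLandscape(shape, np.array([0.5, 0.1, 0.3, 0.9])))
        assert is_accessible(FitnessLandscape(shape, np.array([0.1, 0.5, 0.3, 0.9])))

    def test_agrees_with_count_positivity(self):
        for fl in random_landscapes(55):
            for mode in MODES:
                q = PathQuery(mode)
                assert is_accessible(fl, q) == (count_paths(fl, q) > 0)
            break  # one shape's worth is plenty here


class TestCountPaths:
    def test_handworked_examples(self):
        assert count_paths(FitnessLandscape(LandscapeShape(2, 2), np.array([0.1, 0.5, 0.3, 0.9]))) == 2
        assert count_paths(FitnessLandscape(LandscapeShape(4, 1), np.array([0.1, 0.2, 0.3, 0.9]))) == 4
        # both intermediates below the start: only the direct edge remains
        assert count_paths(FitnessLandscape(LandscapeShape(4, 1), np.array([0.5, 0.1, 0.2, 0.9]))) == 1

    def test_mode_nesting(self):
        for fl in random_landscapes(77):
            n_all = count_paths(fl, PathQuery("all"))
            n_nb = count_paths(fl, PathQuery("no_backward"))
            n_sh = count_paths(fl, PathQuery("shortest_only"))
            assert n_sh <= n_nb <= n_all

    def test_monotone_in_initial_fitness(self):
        fl = generate_hoc(LandscapeShape(3, 4), 13)
        counts = [
            count_paths(set_initial_fitness(fl, f0))
            for f0 in (0.0, 0.2, 0.4, 0.6, 0.8, 0.95)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_position_permutation_symmetry(self):
        shape = LandscapeShape(3, 4)
        fl = generate_hoc(shape, 17)
        perm = [2, 0, 3, 1]
        permuted = np.empty(shape.N)
        for g in range(shape.N):
            digits = (g // shape.powers) % shape.K
            new_g = int(sum(int(digits[i]) * int(shape.powers[p]) for p, i in enumerate(perm)))
            permuted[new_g] = fl.fitness[g]
        fl2 = FitnessLandscape(shape, permuted)
        for mode in MODES:
            s1 = path_stats(fl, PathQuery(mode))
            s2 = path_stats(fl2, PathQuery(mode))
            assert s1.class_histogram == s2.class_histogram
            assert s1.length_distribution == s2.length_distribution


class TestPathStats:
    def test_single_site_step_classes(self):
        fl = FitnessLandscape(LandscapeShape(4, 1), np.array([0.1, 0.2, 0.3, 0.9]))
        st = path_stats(fl)
        # 0->1->2->3 contributes two neutral steps and one forward step
        assert st.class_histogram == {(0, 0): 1, (0, 1): 2, (0, 2): 1}
        assert st.n_paths == 4
        assert st.total_forward == 4 and st.total_neutral == 4 and st.total_backward == 0

    def test_totals_match_path_stats(self):
        for fl in random_landscapes(88):
            for mode in MODES:
                st = path_stats(fl, PathQuery(mode))
                tot = step_class_totals(fl, PathQuery(mode), exact=True)
                assert tot.n_paths == st.n_paths
                assert tot.total_forward == st.total_forward
                assert tot.total_backward == st.total_backward
                assert tot.total_neutral == st.total_neutral

    def test_float_totals_agree_with_exact(self):
        fl = generate_hoc(LandscapeShape(4, 3), 91)
        ex = step_class_totals(fl, exact=True)
        fl_ = step_class_totals(fl, exact=False)
        assert fl_.n_paths == ex.n_paths
        assert fl_.total_forward == ex.total_forward
        assert fl_.total_backward == ex.total_backward
        assert fl_.total_neutral == ex.total_neutral


class TestCoverage:
    def test_handworked_examples(self):
        assert coverage(FitnessLandscape(LandscapeShape(2, 1), np.array([0.1, 0.9]))).fraction == 1.0
        res = coverage(FitnessLandscape(LandscapeShape(2, 2), np.array([0.1, 0.5, 0.3, 0.9])))
        assert res.fraction == 1.0
        bad = coverage(FitnessLandscape(LandscapeShape(2, 2), np.array([0.5, 0.1, 0.3, 0.9])))
        assert not bad.accessible and bad.fraction == 0.0

    def test_matches_enumerated_path_membership(self):
        for fl in random_landscapes(99):
            for mode in MODES:
                on_paths: set[int] = set()
                for p in enumerate_paths(fl, mode):
                    on_paths.update(p)
                res = coverage(fl, PathQuery(mode))
                assert res.covered == len(on_paths)
                assert res.fraction == len(on_paths) / fl.shape.N

    def test_distance_resolved_counts_sum(self, small_landscape):
        res = coverage(small_landscape)
        assert res.counts_by_distance.sum() == res.covered
        assert res.total_by_distance.sum() == small_landscape.shape.N
        assert np.all(res.counts_by_distance <= res.total_by_distance)


class TestMonotoneTransformInvariance:
    def test_uniformize_leaves_path_structure_unchanged(self):
        for fl in random_landscapes(123):
            uni = uniformize_ranks(fl)
            for mode in MODES:
                q = PathQuery(mode)
                assert count_paths(fl, q) == count_paths(uni, q)
            s1, s2 = path_stats(fl), path_stats(uni)
            assert s1.class_histogram == s2.class_histogram
            c1, c2 = coverage(fl), coverage(uni)
            assert c1.fraction == c2.fraction
            assert np.array_equal(c1.counts_by_distance, c2.counts_by_distance)


class TestPathStatsSerialization:
    def test_json_and_histogram_tsv_roundtrip(self, tmp_path):
        import json

        fl = generate_hoc(LandscapeShape(3, 3), 19)
        st = path_stats(fl)
        payload = json.loads(st.to_json())
        assert int(payload["n_paths"]) == st.n_paths
        assert {int(k): int(v) for k, v in payload["length_distribution"].items()} == (
            st.length_distribution
        )
        out = tmp_path / "hist.tsv"
        st.write_histogram_tsv(out)
        lines = out.read_text().splitlines()
        assert lines[0] == "n_backward\tn_neutral\tpath_count"
        parsed = {
            (int(b), int(n)): int(c)
            for b, n, c in (line.split("\t") for line in lines[1:])
        }
        assert parsed == st.class_histogram

    def test_histogram_memory_guard(self):
        from flaccess.paths import HistogramTooLarge

        fl = generate_hoc(LandscapeShape(4, 4), 23)
        with pytest.raises(HistogramTooLarge, match="pooled totals"):
            path_stats(fl, max_cells=10)
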