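"""Empirical tables, sub-landscape extraction, re-indexing, profiles."""

import itertools

import numpy as np
import pytest

from flaccess.empirical import (
    SubLandscapeSpec,
    TableFormatError,
    apply_reindex,
    build_reindex_map,
    complete_and_normalize,
    count_specs,
    enumerate_or_sample_specs,
    extract_sublandscape,
    fitness_distance_profile,
    read_table,
    sublandscape_ensemble_report,
)
from flaccess.landscape import (
    FitnessLandscape,
    LandscapeShape,
    decode,
    encode,
    generate_hoc,
    neighbors,
    shuffle_fitness,
)
from flaccess.paths import PathQuery, count_paths

from conftest import enumerate_paths


def write(tmp_path, text, name="t.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadTable:
    def test_reads_with_and_without_header(self, tmp_path):
        body = "AA\t1.0\nAC\t2.0\nCA\t0.5\n"
        t1 = read_table(write(tmp_path, "sequence\tfitness\n" + body), "AC")
        t2 = read_table(write(tmp_path, body, "u.tsv"), "AC")
        assert t1.records == t2.records == {"AA": 1.0, "AC": 2.0, "CA": 0.5}
        assert t1.L_full == 2 and t1.K_full == 2
        assert t1.missing_count == 1

    @pytest.mark.parametrize(
        "body,fragment",
        [
            ("AA\t1.0\nACA\t2.0\n", "length"),
            ("AA\t1.0\nAU\t2.0\n", "alphabet"),
            ("AA\t1.0\nAA\t2.0\n", "duplicate"),
            ("AA\t1.0\nAC\tx\n", "non-numeric"),
            ("AA\t1.0\nAC\n", "fields"),
        ],
    )
    def test_rejects_malformed_with_line_number(self, tmp_path, body, fragment):
        with pytest.raises(TableFormatError, match="line 2") as exc:
            read_table(write(tmp_path, body), "AC")
        assert fragment in str(exc.value)

    def test_gzip_transparent(self, tmp_path):
        import gzip

        p = tmp_path / "t.tsv.gz"
        with gzip.open(p, "wt") as fh:
            fh.write("AA\t1.0\nAC\t2.0\n")
        assert read_table(p, "AC").records == {"AA": 1.0, "AC": 2.0}


class TestCompleteAndNormalize:
    def test_affine_map_and_fill(self, tmp_path):
        p = write(tmp_path, "AA\t2.0\nAC\t6.0\nCC\t10.0\n")
        fl = complete_and_normalize(read_table(p, "AC"))
        # min->0, max->1, interior value 6.0 -> 0.5; missing CA -> minimum
        # (string index 0 is sequence position 0, the least-significant digit)
        assert fl.fitness[encode([0, 0], fl.shape)] == 0.0  # AA
        assert fl.fitness[encode([0, 1], fl.shape)] == 0.5  # AC
        assert fl.fitness[encode([1, 0], fl.shape)] == 0.0  # CA missing, filled
        assert fl.fitness[encode([1, 1], fl.shape)] == 1.0  # CC

    def test_degenerate_table_rejected(self, tmp_path):
        p = write(tmp_path, "AA\t3.0\nAC\t3.0\n")
        with pytest.raises(ValueError, match="degenerate"):
            complete_and_normalize(read_table(p, "AC"))


class TestSpecCounting:
    def test_closed_forms_match_combinatorics(self):
        # 10-mer, K=4: C(10,5)*4^5 backgrounds; C(4,2)^10 binary pairs
        shape = LandscapeShape(4, 10)
        assert count_specs(shape, "fixed_background", 5) == 258_048
        assert count_specs(shape, "binary_pair") == 60_466_176

    def test_sampling_without_replacement(self):
        shape = LandscapeShape(4, 4)
        specs = enumerate_or_sample_specs(shape, "fixed_background", 50, seed=1, n_fixed=2)
        assert len(specs) == len(set(specs)) == 50
        # determinism
        again = enumerate_or_sample_specs(shape, "fixed_background", 50, seed=1, n_fixed=2)
        assert specs == again

    def test_cap_at_total(self):
        shape = LandscapeShape(2, 3)
        specs = enumerate_or_sample_specs(shape, "binary_pair", 99, seed=2)
        assert len(specs) == count_specs(shape, "binary_pair") == 1

    def test_binary_pair_yields_hypercube(self):
        shape = LandscapeShape(4, 10)
        full = generate_hoc(shape, 3)
        spec = enumerate_or_sample_specs(shape, "binary_pair", 1, seed=4)[0]
        sub = extract_sublandscape(full, spec, seed=5)
        assert sub.shape.K == 2 and sub.shape.N == 1024


class TestReindexing:
    def _random_noncanonical(self, shape, seed):
        rng = np.random.default_rng(seed)
        return FitnessLandscape(shape, rng.random(shape.N))

    def test_identity_when_already_canonical(self):
        fl = generate_hoc(LandscapeShape(2, 4), 6)
        m = build_reindex_map(fl, 0)
        assert np.array_equal(apply_reindex(fl, m).fitness, fl.fitness)

    def test_binary_map_is_the_flip(self):
        shape = LandscapeShape(2, 3)
        fl = self._random_noncanonical(shape, 8)
        fittest = int(np.argmax(fl.fitness))
        m = build_reindex_map(fl, 0)
        for p, bit in enumerate(decode(fittest, shape)):
            expected = [1, 0] if bit == 0 else [0, 1]
            assert m.perms[p].tolist() == expected

    def test_isomorphism_on_random_landscapes(self):
        # neighbour fitness multisets preserved; path counts carried over
        cases = itertools.product((2, 3, 4), (2, 3, 4))
        seeds = np.random.SeedSequence(42).spawn(9 * 12)
        i = 0
        for K, L in cases:
            shape = LandscapeShape(K, L)
            for _ in range(12):
                fl = self._random_noncanonical(shape, seeds[i])
                i += 1
                m = build_reindex_map(fl, seeds[i - 1])
                ri = apply_reindex(fl, m)
                assert ri.is_canonical
                # inverse map locates each genotype's image
                for g in np.random.default_rng(i).integers(0, shape.N, 5):
                    img = m.apply_index(int(g))
                    a = sorted(fl.fitness[h] for h in neighbors(int(g), shape))
                    b = sorted(ri.fitness[h] for h in neighbors(img, shape))
                    assert a == b
                # path count from the antipodal preimage equals the
                # canonical count on the re-indexed landscape
                inv = np.argsort(m.perms, axis=1)
                a_digits = inv[:, 0]
                a_idx = encode(a_digits, shape)
                fittest = int(np.argmax(fl.fitness))
                assert count_paths(
                    fl, PathQuery(start=a_idx, target=fittest)
                ) == count_paths(ri)


class TestExtraction:
    def test_fixed_background_restriction_oracle(self):
        # counting on the extracted sub-landscape == enumerating within
        # the restricted genotype set of the full landscape
        shape = LandscapeShape(3, 4)
        full = generate_hoc(shape, 31)
        spec = SubLandscapeSpec("fixed_background", (1, 3), (2, 0))
        sub = extract_sublandscape(full, spec, seed=7, renormalize=False)
        assert sub.shape.N == 9
        allowed = {
            g
            for g in range(shape.N)
            if decode(g, shape)[1] == 2 and decode(g, shape)[3] == 0
        }
        t_full = max(allowed, key=lambda g: full.fitness[g])
        # start = full-space genotype carrying the sub-landscape's f[0]
        s_full = next(g for g in allowed if full.fitness[g] == sub.fitness[0])
        oracle = len(
            enumerate_paths(full, "all", start=s_full, target=t_full, allowed=allowed)
        )
        assert count_paths(sub) == oracle

    def test_neighbors_are_free_position_changes(self):
        shape = LandscapeShape(4, 6)
        full = generate_hoc(shape, 33)
        spec = SubLandscapeSpec("fixed_background", (0, 2, 5), (1, 3, 0))
        sub = extract_sublandscape(full, spec, seed=3)
        assert sub.shape == LandscapeShape(4, 3)
        sub.validate()


class TestFitnessDistanceProfile:
    def test_target_bin_is_maximum(self):
        fl = generate_hoc(LandscapeShape(3, 4), 41)
        prof = fitness_distance_profile(fl)
        assert prof[0] == fl.fitness.max()
        assert prof.shape == (5,)

    def test_hoc_profile_flat_at_half(self):
        # ensemble mean over HoC landscapes: E f = 1/2 at every d >= 1
        shape = LandscapeShape(2, 6)
        profs = [
            fitness_distance_profile(generate_hoc(shape, s))
            for s in np.random.SeedSequence(43).spawn(300)
        ]
        mean = np.mean(profs, axis=0)[1:]
        se = 1.0 / np.sqrt(12 * 300 * np.array([6, 15, 20, 15, 6, 1]))
        assert np.all(np.abs(mean - 0.5) < 4 * se)

    def test_shuffling_flattens_profiles(self):
        from flaccess.synthetic import SyntheticSpec, generate_correlated

        tab = generate_correlated(SyntheticSpec(LandscapeShape(2, 7), w=0.8, missing=0.0, seed=5))
        fl = complete_and_normalize(tab)
        orig = fitness_distance_profile(fl)
        assert orig[1] > orig[-1] + 0.2  # strong negative correlation
        shuf = [
            fitness_distance_profile(shuffle_fitness(fl, s))
            for s in np.random.SeedSequence(44).spawn(200)
        ]
        mean = np.mean(shuf, axis=0)[1:]
        assert np.all(np.abs(mean - np.mean(fl.fitness)) < 0.05)


class TestSubEnsembleReport:
    def test_report_structure_and_consistency(self):
        from flaccess.synthetic import SyntheticSpec, generate_correlated

        tab = generate_correlated(SyntheticSpec(LandscapeShape(4, 4), w=0.5, missing=0.02, seed=9))
        full = complete_and_normalize(tab)
        rep = sublandscape_ensemble_report(full, "binary_pair", 80, seed=10)
        assert rep.n_samples == 80
        assert 0 <= rep.accessibility <= 1
        assert rep.curves.n_per_bin.sum() == 80
        assert rep.shuffled is not None
        assert rep.shuffled.n_samples == 80
        # accessible samples have at least one path, so mean count positive
        if rep.n_accessible:
            assert rep.mean_n_paths > 0
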