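"""Motif scanning, windowed density, null models and circular KDE."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dnaakit.boxdensity import (DEFAULT_MOTIFS, BoxDensityModel, CircularGenome,
                                DegenerateProfileError, IUPAC_CODES,
                                expand_motif, find_extrema, permuted_motif_null,
                                reverse_complement, scan_motifs, shuffle_motif,
                                significant_regions, strand_bias, uniform_null,
                                vonmises_zscore, window_counts)
from conftest import brute_force_scan, random_genome


class TestExpandMotif:
    @pytest.mark.parametrize("motif, n", [
        ("ACGT", 1),
        ("TTWTNCACA", 8),  # W x N = 2 x 4
        ("HHMTHCWVH", 972),  # 3*3*2*1*3*1*2*3*3
    ])
    def test_expansion_counts(self, motif, n):
        exp = expand_motif(motif)
        assert len(exp) == n
        assert all(len(s) == len(motif) for s in exp)
        assert all(set(s) <= set("ACGT") for s in exp)

    def test_trivial_identity(self):
        assert expand_motif("ACGT") == {"ACGT"}

    def test_unknown_code_named_in_error(self):
        with pytest.raises(ValueError, match="'X'"):
            expand_motif("ACXGT")

    @given(st.text(alphabet=sorted(IUPAC_CODES), min_size=1, max_size=6))
    def test_size_is_product_of_cardinalities(self, motif):
        expected = int(np.prod([len(IUPAC_CODES[c]) for c in motif]))
        assert len(expand_motif(motif)) == expected


class TestScanMotifs:
    def test_no_match_on_homopolymer(self):
        g = CircularGenome("g", "G" * 30, ori_position=0)
        assert scan_motifs(g, DEFAULT_MOTIFS) == []

    def test_planted_forward_hits_both_motifs(self):
        # TTATACACA satisfies both TTWTNCACA and HHMTHCWVH
        g = CircularGenome("g", "AAAA" + "TTATACACA" + "A" * 17, ori_position=0)
        matches = scan_motifs(g, DEFAULT_MOTIFS)
        assert len(matches) == 1
        m = matches[0]
        assert (m.position, m.strand) == (4, "+")
        assert set(m.motifs_hit) == set(DEFAULT_MOTIFS)

    def test_reverse_strand_plant(self):
        rc = reverse_complement("TTATACACA")  # TGTGTATAA
        g = CircularGenome("g", "G" * 10 + rc + "G" * 11, ori_position=0)
        matches = scan_motifs(g, ("TTWTNCACA",))
        assert len(matches) == 1
        assert (matches[0].position, matches[0].strand) == (10, "-")

    def test_wrap_around_origin_of_coordinates(self):
        # plant the 9-mer so it spans the L-1 -> 0 junction
        inst = "TTATACACA"
        g = CircularGenome("g", inst[4:] + "G" * 21 + inst[:4], ori_position=0)
        matches = scan_motifs(g, ("TTWTNCACA",))
        assert [(m.position, m.strand) for m in matches] == [(26, "+")]

    def test_n_in_genome_never_matches(self):
        g = CircularGenome("g", "AAAA" + "TTATNCACA" + "A" * 17, ori_position=0)
        assert scan_motifs(g, ("TTWTNCACA",)) == []

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            CircularGenome("g", "", ori_position=0)

    def test_matches_brute_force_oracle_on_random_genomes(self, rng):
        for _ in range(5):
            g = random_genome(rng, int(rng.integers(200, 3000)),
                              gc=float(rng.uniform(0.3, 0.7)))
            got = {(m.position, m.strand): set(m.motifs_hit)
                   for m in scan_motifs(g, DEFAULT_MOTIFS)}
            assert got == brute_force_scan(g, DEFAULT_MOTIFS)


class TestCentisomes:
    def test_ori_and_antipode(self):
        g = random_genome(np.random.default_rng(0), 1000, ori=300)
        assert g.to_centisomes(300) == 0.0
        assert g.to_centisomes(800) == 50.0

    def test_modular_arithmetic(self):
        # E. coli MG1655 scale: L = 4,641,652, ori at 3,925,744
        g = CircularGenome("mg", "A" * 100, ori_position=0)
        L, ori, pos = 4_641_652, 3_925_744, 0
        expected = ((pos - ori) % L) / L * 100
        assert expected == pytest.approx(15.4236, abs=1e-3)

    def test_out_of_range_rejected(self):
        g = random_genome(np.random.default_rng(0), 1000)
        with pytest.raises(ValueError):
            g.to_centisomes(1000)


class TestWindowCounts:
    def test_empty_matches_all_zero(self):
        p = window_counts(np.array([]), 10)
        assert p.counts.sum() == 0 and p.n_matches == 0

    def test_single_match_coverage(self):
        p = window_counts(np.array([0.0]), 10)
        assert p.counts.sum() == 10
        covered = set(np.flatnonzero(p.counts))
        assert covered == ({96, 97, 98, 99} | set(range(6)))

    @given(st.lists(st.floats(0, 99.999), max_size=60),
           st.sampled_from([2, 6, 10]))
    def test_coverage_identity(self, cs, w):
        p = window_counts(np.array(cs), w)
        assert p.counts.sum() == len(cs) * w

    def test_mask_removes_interval(self):
        p = window_counts(np.array([1.0, 50.0]), 10, mask_cs=(99.0, 2.0))
        assert p.n_matches == 1  # the match at 1.0 is masked out


class TestUniformNull:
    def test_zero_observed_gives_p_one(self):
        profile = window_counts(np.array([]), 10)
        profile.n_matches = 0
        env = uniform_null(profile, n_sims=100, seed=1, n_boxes=50)
        assert np.all(env.pseudo_p == 1.0)

    def test_extreme_observed_gives_min_p(self):
        profile = window_counts(np.full(50, 0.0), 10)  # 50 boxes stacked at 0
        env = uniform_null(profile, n_sims=200, seed=2)
        assert env.pseudo_p[0] == pytest.approx(1 / 201)

    def test_envelope_brackets_binomial_mean(self):
        rng = np.random.default_rng(3)
        cs = rng.uniform(0, 100, 900)
        profile = window_counts(cs, 10)
        env = uniform_null(profile, n_sims=400, seed=3)
        # binomial mean n*w/100 = 90 lies inside the 5-95% band everywhere
        assert np.all(env.lo <= 90) and np.all(env.hi >= 90)

    def test_too_few_sims_rejected(self):
        profile = window_counts(np.array([1.0]), 10)
        with pytest.raises(ValueError):
            uniform_null(profile, n_sims=1)


class TestPermutedNull:
    def test_homopolymer_permutations_reproduce_observed(self, rng):
        g = random_genome(rng, 2000)
        motif = "AAAAAAAAA"
        profile = window_counts(scan_motifs(g, (motif,)), 10)
        env = permuted_motif_null(g, (motif,), profile, n_perm=10, seed=4)
        # every permutation is the original motif: all null counts tie the
        # observed, so the rank pseudo-p is exactly 1 everywhere
        assert np.all(env.lo == profile.counts)
        assert np.all(env.hi == profile.counts)
        assert np.all(env.pseudo_p == 1.0)

    @given(st.integers(0, 10_000))
    def test_shuffle_preserves_letter_multiset(self, seed):
        rng = np.random.default_rng(seed)
        s = shuffle_motif("TTWTNCACA", rng)
        assert sorted(s) == sorted("TTWTNCACA")

    def test_background_match_rate_near_analytic(self, rng):
        # i.i.d. uniform genome: E[matches] ~= 2 * L * sum over deduplicated
        # expansions of 4^-9, per strand symmetry
        g = random_genome(rng, 100_000, gc=0.5)
        exp = expand_motif("TTWTNCACA") | expand_motif("HHMTHCWVH")
        expect = 2 * len(g) * len(exp) / 4**9
        observed = len(scan_motifs(g, DEFAULT_MOTIFS))
        assert observed == pytest.approx(expect, rel=0.25)


class TestSignificantRegions:
    def _env(self, pseudo_p):
        return type("E", (), {"pseudo_p": np.asarray(pseudo_p)})()

    def test_no_significance(self):
        assert significant_regions(self._env(np.ones(100))) == []

    def test_wrap_merged_interval(self):
        p = np.ones(100)
        p[98:] = 0.01
        p[:6] = 0.01
        assert significant_regions(self._env(p)) == [(98, 5)]

    def test_alternating_centers(self):
        p = np.ones(100)
        p[10] = p[12] = p[14] = 0.01
        assert significant_regions(self._env(p)) == [(10, 10), (12, 12), (14, 14)]

    def test_all_significant_single_interval(self):
        assert significant_regions(self._env(np.zeros(100))) == [(0, 99)]


class TestVonMisesKDE:
    def test_density_integrates_to_one(self, rng):
        cs = rng.uniform(0, 100, 40)
        kde = vonmises_zscore(cs, kappa=200, n_grid=1000)
        theta = kde.grid_cs * 2 * np.pi / 100
        closed = np.append(kde.density, kde.density[0])
        integral = np.trapezoid(closed, np.append(theta, 2 * np.pi))
        assert integral == pytest.approx(1.0, abs=1e-6)
        assert kde.zscore.mean() == pytest.approx(0.0, abs=1e-9)
        assert kde.zscore.std() == pytest.approx(1.0, abs=1e-9)

    def test_uniform_matches_flat(self):
        cs = np.arange(400) * 0.25  # dense regular grid: flat density
        kde = vonmises_zscore(cs, kappa=200)
        assert np.all(np.abs(kde.zscore) < 1e-9)

    def test_point_mass_peaks_at_zero(self):
        kde = vonmises_zscore(np.zeros(10), kappa=200)
        maxima = find_extrema(kde)
        gm = next(m for m in maxima if m.is_global)
        assert min(gm.position_cs, 100 - gm.position_cs) < 0.2

    def test_two_cluster_symmetry(self):
        cs = np.concatenate([np.zeros(20), np.full(20, 50.0)])
        kde = vonmises_zscore(cs, kappa=200, n_grid=1000)
        # standardised curve symmetric under a 50-cs rotation
        assert np.allclose(kde.zscore, np.roll(kde.zscore, 500), atol=1e-9)
        maxima = find_extrema(kde)
        peaks = sorted(round(m.position_cs) % 100 for m in maxima)
        assert peaks == [0, 50]

    def test_invalid_kappa(self):
        with pytest.raises(ValueError):
            vonmises_zscore(np.zeros(3), kappa=0)


class TestFindExtrema:
    def test_single_peak_is_global(self):
        kde = vonmises_zscore(np.full(5, 30.0), kappa=100)
        maxima = find_extrema(kde)
        assert len([m for m in maxima if m.is_global]) == 1

    def test_peak_on_wrap_boundary_found_once(self):
        cs = np.concatenate([np.full(10, 99.5), np.full(10, 0.5)])
        kde = vonmises_zscore(cs, kappa=100)
        maxima = find_extrema(kde, neighborhood_cs=5)
        assert len(maxima) == 1
        assert maxima[0].dist_from_ori_cs < 1.0

    def test_constant_profile_is_degenerate(self):
        kde = vonmises_zscore(np.arange(400) * 0.25, kappa=200)
        with pytest.raises(DegenerateProfileError):
            find_extrema(kde)


class TestStrandBias:
    def _matches(self, specs, genome):
        from dnaakit.boxdensity import BoxMatch

        return [BoxMatch(position=p, strand=s, motifs_hit=("TTWTNCACA",),
                         centisome=genome.to_centisomes(p)) for p, s in specs]

    def test_all_forward_on_right_replichore(self, rng):
        g = random_genome(rng, 1000, ori=0, ter=500)
        res = strand_bias(self._matches([(10, "+"), (100, "+")], g), g)
        assert res["overall"]["fraction"] == 1.0

    def test_strand_symmetric_set(self, rng):
        g = random_genome(rng, 1000, ori=0, ter=500)
        res = strand_bias(
            self._matches([(10, "+"), (10, "-"), (700, "+"), (700, "-")], g), g)
        assert res["overall"]["fraction"] == 0.5

    def test_requires_terminus(self, rng):
        g = random_genome(rng, 1000, ori=0)
        with pytest.raises(ValueError):
            strand_bias([], g)


class TestModelSurface:
    def test_fit_summary_and_tables(self, rng):
        g = random_genome(rng, 20_000, ori=100, ter=10_100)
        model = BoxDensityModel(g, window_cs=10)
        res = model.fit(nulls=("uniform",), n_sims=50, seed=5)
        assert res.n_matches == len(res.matches)
        df = res.profile_dataframe()
        assert {"center_cs", "count", "uniform_pseudo_p"} <= set(df.columns)
        assert "uniform null" in res.summary()
        bed = res.matches_bed()
        if res.matches:
            first = bed.splitlines()[0].split("\t")
            assert int(first[2]) - int(first[1]) == 9
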