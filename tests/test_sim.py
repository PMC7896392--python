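"""Simulation: error maps, site counts, read synthesis, FASTQ output."""

import numpy as np
import pytest

from readsmith.covmodel import Dispersion
from readsmith.fixtures import make_genome
from readsmith.genome import AlleleSet, VariantEdit, revcomp
from readsmith.sim import (
    DegenerateSampler, Fragments, SimProfile, TemplateErrorMap,
    draw_site_counts, draw_template_errors, simulate, synthesize_reads,
    write_fastq,
)


class TestDrawSiteCounts:
    def test_poisson_total_concentrates(self):
        rng = np.random.default_rng(0)
        n, target = 50_000, 20_000
        mu = np.full(n, target / n)
        k = draw_site_counts(mu, Dispersion(0, 0), rng)
        assert abs(k.sum() - target) < 4 * np.sqrt(target)

    def test_single_site_takes_all(self):
        rng = np.random.default_rng(1)
        mu = np.zeros(100)
        mu[42] = 500.0
        k = draw_site_counts(mu, Dispersion(0.5, 0.1), rng)
        assert k[np.arange(100) != 42].sum() == 0
        assert k[42] > 0

    def test_variance_mean_relationship(self):
        rng = np.random.default_rng(2)
        alpha, beta, mu0 = 0.5, 0.1, 4.0
        k = draw_site_counts(np.full(100_000, mu0), Dispersion(alpha, beta),
                             rng)
        expected_var = mu0 + alpha * mu0 + beta * mu0**2
        assert abs(k.var() / expected_var - 1) < 0.1
        assert abs(k.mean() / mu0 - 1) < 0.05


class TestTemplateErrorMap:
    def test_tendency_alphabet_has_five_values(self, trained_profile):
        assert trained_profile.tendency_alphabet == 5
        # codes 0..3 are nucleotides, 4 is none
        g = make_genome(21, [2_000])
        em = draw_template_errors(g, trained_profile,
                                  np.random.default_rng(0))
        assert set(np.unique(em.tendency["chr1"])) <= {0, 1, 2, 3, 4}

    def test_degenerate_always_none_model(self, trained_profile):
        profile = SimProfile(
            combined=trained_profile.combined,
            samplers={**trained_profile.samplers,
                      "tendency": DegenerateSampler(4)},
            fragment_length_distribution=trained_profile
            .fragment_length_distribution,
            adapter_set=trained_profile.adapter_set,
            read_length=trained_profile.read_length,
        )
        g = make_genome(22, [3_000])
        em = draw_template_errors(g, profile, np.random.default_rng(0))
        assert (em.tendency["chr1"] == 4).all()

    def test_save_load_round_trip(self, trained_profile, tmp_path):
        g = make_genome(23, [5_000])
        em = draw_template_errors(g, trained_profile,
                                  np.random.default_rng(3))
        p = tmp_path / "em.tsv"
        em.save(p)
        em2 = TemplateErrorMap.load(p)
        assert em.equal(em2)
        for n in em.seq_names:
            np.testing.assert_array_equal(em.region_pos[n], em2.region_pos[n])
            np.testing.assert_array_equal(em.region_rate[n],
                                          em2.region_rate[n])

    def test_reproducible_given_seed(self, trained_profile):
        g = make_genome(24, [3_000])
        a = draw_template_errors(g, trained_profile, np.random.default_rng(7))
        b = draw_template_errors(g, trained_profile, np.random.default_rng(7))
        assert a.equal(b)


def degenerate_profile(read_length=50, q=35):
    """All-deterministic samplers: identity calls, fixed quality."""
    samplers = {
        "tendency": DegenerateSampler(4),
        "rate": DegenerateSampler(0),
        "seq_quality": DegenerateSampler(q),
        "base_quality": {(s, 0, r): DegenerateSampler(q)
                         for s in (0, 1) for r in range(4)},
        "base_call": {(s, 0, r): DegenerateSampler(r)
                      for s in (0, 1) for r in range(4)},
        "indel": DegenerateSampler(0),
        "indel_active": False,
    }
    from readsmith.covmodel import CombinedBias, FlankParams

    return SimProfile(
        combined=CombinedBias(FlankParams(), np.ones(101), Dispersion()),
        samplers=samplers,
        fragment_length_distribution={40: 1.0},
        adapter_set=None,
        read_length=read_length,
    )


class TestSynthesizeReads:
    def test_degenerate_models_give_exact_template_copies(self):
        g = make_genome(31, [1_000])
        profile = degenerate_profile()
        frags = Fragments(np.zeros(4, int), np.array([10, 100, 200, 300]),
                          np.full(4, 60), np.array([0, 0, 1, 1]),
                          np.zeros(4, int))
        em = TemplateErrorMap(
            ["chr1"], 50,
            {"chr1": np.full((2, 1000), 4, np.uint8)},
            {"chr1": np.zeros((2, 1000))},
            {"chr1": np.zeros((2, 1000), np.int32)},
            {"chr1": np.zeros((2, 1000))},
        )
        (b1, q1, e1), (b2, q2, e2) = synthesize_reads(
            frags, [g], [em], profile, np.random.default_rng(0))
        assert (q1 == 35).all() and (q2 == 35).all()
        assert not e1.any() and not e2.any()
        seq = g.sequences["chr1"]
        from readsmith.genome import decode

        # forward fragment: read1 is the template prefix, read2 the
        # reverse complement of the fragment suffix
        assert decode(b1[0]) == seq[10:60]
        assert decode(b2[0]) == revcomp(seq[10 + 60 - 50 : 10 + 60])
        # reverse fragment: roles swap
        assert decode(b1[2]) == revcomp(seq[200 + 60 - 50 : 200 + 60])
        assert decode(b2[2]) == seq[200:250]

    def test_adapter_appended_at_fragment_end(self, trained_profile):
        g = make_genome(32, [1_000])
        profile = degenerate_profile(read_length=100)
        profile.adapter_set = trained_profile.adapter_set
        frags = Fragments(np.zeros(1, int), np.array([100]),
                          np.array([37]), np.array([0]), np.zeros(1, int))
        em = TemplateErrorMap(
            ["chr1"], 100,
            {"chr1": np.full((2, 1000), 4, np.uint8)},
            {"chr1": np.zeros((2, 1000))},
            {"chr1": np.zeros((2, 1000), np.int32)},
            {"chr1": np.zeros((2, 1000))},
        )
        (b1, _, _), (b2, _, _) = synthesize_reads(
            frags, [g], [em], profile, np.random.default_rng(0))
        from readsmith.genome import decode

        a1 = profile.adapter_set.adapters(0)[0]
        a2 = profile.adapter_set.adapters(1)[0]
        assert decode(b1[0][37 : 37 + len(a1)]) == a1
        assert decode(b2[0][37 : 37 + len(a2)]) == a2


class TestWriteFastq:
    def test_round_trip_and_phred_encoding(self, tmp_path):
        rng = np.random.default_rng(0)
        b = rng.integers(0, 4, size=(2, 30)).astype(np.uint8)
        q = np.array([[0] * 30, [41] * 30])
        p1, p2 = tmp_path / "a_1.fastq", tmp_path / "a_2.fastq"
        write_fastq(p1, p2, ["x", "y"], (b, q, None), (b, q, None))
        lines = p1.read_text().splitlines()
        assert len(lines) == 8
        assert lines[3] == "!" * 30 and lines[7] == "J" * 30
        from readsmith.genome import decode

        assert lines[1] == decode(b[0])
        # mates ordered consistently
        lines2 = p2.read_text().splitlines()
        assert lines2[0] == "@x" and lines[0] == "@x"


class TestSimulate:
    def test_target_depth_arithmetic(self, trained_profile, tmp_path):
        g = make_genome(41, [10_000])
        res = simulate(g, trained_profile, str(tmp_path / "d"), seed=5,
                       depth=20.0)
        # depth 20 at read length 100 over 10 kb -> about 1000 pairs
        assert abs(res.n_pairs - 1000) < 150

    def test_same_seed_byte_identical(self, trained_profile, tmp_path):
        g = make_genome(42, [8_000])
        simulate(g, trained_profile, str(tmp_path / "a"), seed=9, n_pairs=500)
        simulate(g, trained_profile, str(tmp_path / "b"), seed=9, n_pairs=500)
        assert (tmp_path / "a_1.fastq").read_bytes() == \
            (tmp_path / "b_1.fastq").read_bytes()
        assert (tmp_path / "a_2.fastq").read_bytes() == \
            (tmp_path / "b_2.fastq").read_bytes()

    def test_diploid_snp_sees_both_alleles(self, trained_profile, tmp_path):
        g = make_genome(43, [8_000])
        ref = g.sequences["chr1"][4000]
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        alleles = AlleleSet(2, [[], [VariantEdit("chr1", 4000, ref, alt)]])
        res = simulate(g, trained_profile, str(tmp_path / "dip"), seed=11,
                       n_pairs=3000, alleles=alleles)
        counts = np.zeros(2)
        with open(res.truth_path) as fh:
            next(fh)
            for line in fh:
                counts[int(line.split("\t")[4])] += 1
        n = counts.sum()
        p = counts[0] / n
        assert abs(p - 0.5) <= 3 * np.sqrt(0.25 / n)

    def test_abundance_zero_silences_sequence(self, trained_profile, tmp_path):
        g = make_genome(44, [6_000, 6_000])
        res = simulate(g, trained_profile, str(tmp_path / "ab"), seed=13,
                       n_pairs=800, abundance={"chr2": 0.0})
        with open(res.truth_path) as fh:
            next(fh)
            assert all(line.split("\t")[0] == "chr1" for line in fh)

    def test_shared_error_map_reproduces_positions(self, trained_profile,
                                                   tmp_path):
        g = make_genome(45, [6_000])
        em = draw_template_errors(g, trained_profile,
                                  np.random.default_rng(1))
        r1 = simulate(g, trained_profile, str(tmp_path / "m1"), seed=21,
                      n_pairs=300, error_maps=[em], save_error_map=True)
        r2 = simulate(g, trained_profile, str(tmp_path / "m2"), seed=22,
                      n_pairs=300, error_maps=[em], save_error_map=True)
        m1 = TemplateErrorMap.load(r1.error_map_paths[0])
        m2 = TemplateErrorMap.load(r2.error_map_paths[0])
        assert m1.equal(m2)

    def test_both_pairs_and_depth_rejected(self, trained_profile, tmp_path):
        g = make_genome(46, [5_000])
        with pytest.raises(ValueError):
            simulate(g, trained_profile, str(tmp_path / "x"), seed=1)
        with pytest.raises(ValueError):
            simulate(g, trained_profile, str(tmp_path / "x"), seed=1,
                     n_pairs=10, depth=1.0)
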