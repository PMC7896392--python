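"""Training-statistics extraction: pileups, the systematic-error caller,
site exclusion and enumeration, corrected counts and margin filling."""

import numpy as np
import pytest
from scipy import stats as sps

from readsmith.covmodel import SiteData
from readsmith.genome import Genome
from readsmith.stats import (
    CountSummaries, Exclusions, Pileup, build_pileup, classify_systematic,
    corrected_counts, dominant_window, enumerate_sites,
    exclude_low_quality_sites, fill_margins, load_read_batch, poisson_tail,
    region_pos_bin, region_rate_bin,
)


def genome50():
    seq = ("ACGTG" * 10)
    return Genome.from_sequences([("s", seq)])


class TestBuildPileup:
    def test_error_free_reads(self, tmp_path, sam_writer):
        g = genome50()
        seq = g.sequences["s"]
        recs = [{"seq": "s", "pos": i, "bases": seq[i : i + 20],
                 "cigar": [(0, 20)], "name": f"r{i}", "tlen": 20}
                for i in range(0, 30, 3)]
        sam = sam_writer(tmp_path / "a.sam", g, recs)
        batch, _, _ = load_read_batch(sam, g)
        pu = build_pileup(batch, g)
        assert pu.coverage["s"][0].sum() == 10 * 20
        assert pu.coverage["s"][1].sum() == 0
        assert pu.subs["s"].sum() == 0
        assert pu.r_e["s"][0] == 0.0

    def test_soft_clip_expansion_finds_substitution(self, tmp_path, sam_writer):
        g = genome50()
        seq = g.sequences["s"]
        clipped = seq[10:25]
        tail = seq[25:30]
        bad_tail = "T" + tail[1:] if tail[0] != "T" else "A" + tail[1:]
        rec = {"seq": "s", "pos": 10, "bases": clipped + bad_tail,
               "cigar": [(0, 15), (4, 5)], "tlen": 40}
        sam = sam_writer(tmp_path / "b.sam", g, [rec])
        batch, _, _ = load_read_batch(sam, g)
        pu = build_pileup(batch, g)
        assert pu.subs["s"][0].sum() == 1
        assert pu.subs["s"][0, 25].sum() == 1

    def test_adapter_read_through_clip_not_expanded(self, tmp_path, sam_writer):
        g = genome50()
        seq = g.sequences["s"]
        # fragment of length 15: the trailing clip is adapter, not template
        rec = {"seq": "s", "pos": 10, "bases": seq[10:25] + "GGGGG",
               "cigar": [(0, 15), (4, 5)], "tlen": 15}
        sam = sam_writer(tmp_path / "c.sam", g, [rec])
        batch, _, _ = load_read_batch(sam, g)
        pu = build_pileup(batch, g)
        assert pu.subs["s"].sum() == 0
        assert pu.coverage["s"][0].sum() == 15

    def test_variant_positions_excluded(self, tmp_path, sam_writer):
        g = genome50()
        seq = g.sequences["s"]
        rec = {"seq": "s", "pos": 0, "bases": "T" + seq[1:20],
               "cigar": [(0, 20)], "tlen": 20}
        sam = sam_writer(tmp_path / "d.sam", g, [rec])
        batch, _, _ = load_read_batch(sam, g)
        pu = build_pileup(batch, g, variant_positions={"s": [0]})
        assert pu.excluded["s"][0]
        prof = classify_systematic(pu, 20)
        assert prof.tendency["s"][0, 0] == 4  # excluded, never called

    def test_unknown_sequence_raises(self, tmp_path, sam_writer):
        g = genome50()
        other = Genome.from_sequences([("t", "ACGT" * 20)])
        sam = sam_writer(tmp_path / "e.sam", other,
                         [{"seq": "t", "pos": 0, "bases": "ACGT" * 5,
                           "cigar": [(0, 20)]}])
        with pytest.raises(ValueError, match="unknown sequence"):
            load_read_batch(sam, g)


class TestClassifySystematic:
    def test_poisson_tail_closed_form(self):
        # coverage 100, median error rate 0.03 -> mu = 1; top count 5
        p = poisson_tail(np.array([5]), np.array([1.0]))[0]
        assert np.isclose(p, 1 - np.exp(-1) * (65 / 24), atol=1e-6)
        assert np.isclose(p, 0.00366, atol=5e-6)

    def test_bh_adjustment_arithmetic(self):
        adj = sps.false_discovery_control(
            np.array([0.001, 0.02, 0.04]), method="bh")
        np.testing.assert_allclose(adj, [0.003, 0.03, 0.04])
        assert (adj < 0.05).all()

    def _pileup(self, L=200, cov=100, subs=None, r_e=0.01):
        coverage = {"s": np.full((2, L), cov)}
        s = np.zeros((2, L, 4), dtype=np.int64)
        if subs is not None:
            for strand, pos, code, count in subs:
                s[strand, pos, code] = count
        pu = Pileup(["s"], coverage, {"s": s}, {"s": np.zeros(L, bool)})
        pu.r_e["s"] = np.array([r_e])
        return pu

    def test_no_errors_no_calls(self):
        prof = classify_systematic(self._pileup(), 50)
        assert prof.n_systematic == 0
        assert (prof.tendency["s"] == 4).all()

    def test_strong_error_called_with_rate_and_region(self):
        pu = self._pileup(subs=[(0, 50, 2, 30)])
        prof = classify_systematic(pu, read_length=20)
        assert prof.tendency["s"][0, 50] == 2
        assert np.isclose(prof.rate["s"][0, 50], 0.30)
        # region of one read length opens at the call
        assert prof.region_pos["s"][0, 50] == 0
        assert prof.region_pos["s"][0, 55] == 5
        assert prof.region_pos["s"][0, 69] == 19
        assert prof.region_pos["s"][0, 70] == 0
        assert np.isclose(prof.region_rate["s"][0, 55], 0.30)

    def test_higher_rate_call_restarts_region(self):
        pu = self._pileup(subs=[(0, 50, 2, 20), (0, 55, 1, 40)])
        prof = classify_systematic(pu, read_length=20)
        assert prof.region_pos["s"][0, 55] == 0
        assert np.isclose(prof.region_rate["s"][0, 60], 0.40)

    def test_variant_like_position_ignored(self):
        # complementary top errors on the two strands (read orientation):
        # forward G (code 2) vs reverse C (code 1) -> same reference change
        pu = self._pileup(subs=[(0, 80, 2, 30), (1, 80, 1, 30)])
        prof = classify_systematic(pu, read_length=20)
        assert prof.variant_like["s"][80]
        assert prof.tendency["s"][0, 80] == 4
        assert prof.tendency["s"][1, 80] == 4

    def test_reverse_strand_region_extends_downstream(self):
        pu = self._pileup(subs=[(1, 100, 3, 30)])
        prof = classify_systematic(pu, read_length=10)
        assert prof.region_pos["s"][1, 100] == 0
        assert prof.region_pos["s"][1, 95] == 5
        assert prof.region_pos["s"][1, 105] == 0


class TestExcludeLowQuality:
    def _batch(self, tmp_path, sam_writer, lowq_starts, highq_starts):
        g = Genome.from_sequences([("s", "ACGT" * 500)])
        recs = []
        for i, p in enumerate(lowq_starts):
            recs.append({"seq": "s", "pos": p, "bases": "ACGT" * 5,
                         "cigar": [(0, 20)], "mapq": 0, "name": f"l{i}"})
        for i, p in enumerate(highq_starts):
            recs.append({"seq": "s", "pos": p, "bases": "ACGT" * 5,
                         "cigar": [(0, 20)], "mapq": 60, "name": f"h{i}"})
        sam = sam_writer(tmp_path / "x.sam", g, recs)
        batch, _, _ = load_read_batch(sam, g)
        return batch

    def test_nine_between_connects(self, tmp_path, sam_writer):
        batch = self._batch(tmp_path, sam_writer, [100, 200],
                            list(range(105, 150, 5)))  # 9 starts between
        exc = exclude_low_quality_sites(batch)
        assert exc.start_intervals["s"] == [(100, 200)]
        assert exc.site_excluded("s", np.array([150]), 20)[0]

    def test_ten_between_does_not_connect(self, tmp_path, sam_writer):
        batch = self._batch(tmp_path, sam_writer, [100, 200],
                            list(range(105, 155, 5)))  # 10 starts between
        exc = exclude_low_quality_sites(batch)
        assert "s" not in exc.start_intervals

    def test_no_low_quality_reads(self, tmp_path, sam_writer):
        batch = self._batch(tmp_path, sam_writer, [], [10, 50, 90])
        exc = exclude_low_quality_sites(batch)
        assert not exc.start_intervals and not exc.end_intervals


class TestEnumerateAndCounts:
    def test_site_count_per_strand(self):
        g = Genome.from_sequences([("s", "A" * 100)])
        sites = enumerate_sites(g, {}, Exclusions(), [("s", 20)])[0]
        per_strand = (sites.strand == 0).sum()
        assert per_strand == 81 and sites.n_sites == 162

    def test_pair_lands_on_exact_site(self):
        g = Genome.from_sequences([("s", "ACGT" * 50)])
        counts = {("s", 10, 20, 0): 1}
        sites = enumerate_sites(g, counts, Exclusions(), [("s", 20)])[0]
        hit = (sites.starts == 10) & (sites.strand == 0)
        assert sites.k[hit].sum() == 1
        assert sites.k.sum() == 1

    def test_k_sum_equals_accepted_pairs(self):
        rng = np.random.default_rng(0)
        g = Genome.from_sequences([("s", "ACGT" * 250)])
        counts = {}
        for _ in range(50):
            counts[("s", int(rng.integers(0, 900)), 50,
                    int(rng.integers(0, 2)))] = int(rng.integers(1, 5))
        sites = enumerate_sites(g, counts, Exclusions(), [("s", 50)])[0]
        assert sites.k.sum() == sum(counts.values())

    def test_excluded_site_flagged_but_counted(self):
        g = Genome.from_sequences([("s", "ACGT" * 50)])
        exc = Exclusions(start_intervals={"s": [(5, 15)]})
        counts = {("s", 10, 20, 0): 2}
        sites = enumerate_sites(g, counts, exc, [("s", 20)])[0]
        hit = (sites.starts == 10) & (sites.strand == 0)
        assert sites.excluded[hit].all() and sites.k[hit].sum() == 2

    def test_corrected_counts_no_exclusion(self):
        g = Genome.from_sequences([("s", "A" * 1000)])
        counts = {("s", i, 100, 0): 1 for i in range(0, 900)}
        extra = {("s", i, 100, 1): 1 for i in range(0, 100)}
        counts.update(extra)
        cs = corrected_counts(g, counts, Exclusions())
        assert cs.c_ref["s"] == 1000
        assert cs.c_len[100] == 1000

    def test_corrected_counts_scaling(self):
        g = Genome.from_sequences([("s", "A" * 1000)])
        # 10% of the sequence excluded as site starts; 900 pairs remain
        exc = Exclusions(start_intervals={"s": [(900, 999)]})
        counts = {("s", i, 50, 0): 1 for i in range(0, 900)}
        cs = corrected_counts(g, counts, exc)
        assert np.isclose(cs.c_ref["s"], 900 * (1000 / 900))

    def test_adapter_implied_fragment_length(self):
        from readsmith.adapters import AdapterSet
        from readsmith.stats import UnalignedPair

        g = Genome.from_sequences([("s", "A" * 200)])
        adapter = "AGATCGGAAGAGCACACGTC"
        aset = AdapterSet([adapter], ["C" * 20], np.ones((1, 1), bool))
        bases = "GCTT" * 9 + "T" + adapter[:15]  # adapter starts at 37
        rejected = [UnalignedPair(bases, 0)]
        cs = corrected_counts(g, {}, Exclusions(), aset, rejected)
        assert cs.c_len.get(37) == 1


class TestMarginHelpers:
    def test_fragment_length_bin(self):
        assert 57 // 10 == 5

    def test_region_position_bins(self):
        rp = np.array([0, 1, 5, 10, 11, 20, 21])
        np.testing.assert_array_equal(region_pos_bin(rp, 100),
                                      [0, 1, 1, 1, 2, 2, 3])

    def test_region_rate_bins(self):
        rates = np.array([0.0, 0.05, 0.35, 0.99])
        pos = np.array([0, 3, 3, 3])
        np.testing.assert_array_equal(region_rate_bin(rates, pos),
                                      [0, 1, 4, 10])

    def test_dominant_window_majority(self):
        # previous five bases ACCGT before the current base: C dominates
        from readsmith.genome import encode

        row = encode("ACCGTT")[None, :]
        dom = dominant_window(row)
        assert dom[0, 5] == 1  # C

    def test_dominant_window_tie_breaks_to_closest(self):
        from readsmith.genome import encode

        # window AACCG: A and C tied; C occurred closer to the current base
        row = encode("AACCGG")[None, :]
        assert dominant_window(row)[0, 5] == 1


class TestFillMargins:
    def test_margin_totals_conserved_and_strata_present(self, fixture_bundle):
        from readsmith.adapters import AdapterSet

        g = fixture_bundle["genome"]
        truth = fixture_bundle["truth"]
        aset = AdapterSet([truth.adapter1], [truth.adapter2],
                          np.ones((1, 1), bool))
        batch, _, _ = load_read_batch(fixture_bundle["sam"], g,
                                      adapter_set=aset)
        pu = build_pileup(batch, g)
        prof = classify_systematic(pu, batch.read_length)
        ms = fill_margins(batch, g, prof, pu)
        for mset in [ms.tendency, ms.seq_quality, ms.indel,
                     *ms.base_quality.values(), *ms.base_call.values()]:
            totals = {t.sum() for t in mset.tables.values()}
            assert len({round(x, 6) for x in totals}) == 1
            assert mset.consistent()
        # 5-dim base-quality statistic: 10 pairwise margins per stratum
        any_bq = next(iter(ms.base_quality.values()))
        assert len(any_bq.tables) == 10
        assert ms.tendency.dims[0].cardinality == 5
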