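"""Training-statistics extraction from mapped reads.

Everything the simulator learns comes from here: per-position error pileups,
the Poisson/Benjamini-Hochberg caller that separates systematic from random
errors, fragment-site enumeration with low-quality-site exclusion, corrected
reference/length counts, and the six margin statistics for qualities, base
calls and InDels.

All read-level data is held in a :class:`ReadBatch` of dense matrices in
*read order* (cycle 0 = first sequenced base); for reverse-strand reads both
the read and the reference context are complemented back into sequencing
orientation, so strand-specific error tendencies keep a consistent meaning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pysam
from scipy import stats as sps

from .adapters import AdapterSet, match_adapter
from .genome import Genome, encode
from .margins import Dimension, MarginSet

logger = logging.getLogger(__name__)

_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

#: mapping-quality threshold for accepted pairs in site counting
DEFAULT_MQ_THRESHOLD = 10
#: mapping quality below which a read is "low quality" for site exclusion
LOWQ_MQ = 2
#: reference-bin width for the median error rate
ERROR_RATE_BIN = 10_000

NO_TENDENCY = 4  # tendency code for "none"


def tile_from_name(name: str) -> str:
    """Illumina read-name field 5 is the tile; otherwise a single bucket."""
    parts = name.split(":")
    if len(parts) >= 5 and parts[4].isdigit():
        return parts[4]
    return "default"


# ---------------------------------------------------------------------------
# read batch


@dataclass
class ReadBatch:
    """Dense read-order matrices for a set of mapped reads."""

    bases: np.ndarray     # (n, rl) uint8 codes in read order
    quals: np.ndarray     # (n, rl) uint8
    ref: np.ndarray       # (n, rl) uint8, complemented for reverse reads
    valid: np.ndarray     # (n, rl) bool — cycle enters substitution statistics
    refpos: np.ndarray    # (n, rl) int32, -1 where invalid
    segment: np.ndarray   # (n,) 0/1
    strand: np.ndarray    # (n,) 0 = forward, 1 = reverse
    seq_idx: np.ndarray   # (n,) index into seq_names
    tile_idx: np.ndarray  # (n,)
    mapq: np.ndarray      # (n,)
    flen: np.ndarray      # (n,) template length (0 if unknown)
    start: np.ndarray     # (n,) alignment start
    seq_names: list[str] = field(default_factory=list)
    tiles: list[str] = field(default_factory=list)
    indels: list[list] = field(default_factory=list)  # per read: (cycle, kind, code, length)

    @property
    def n_reads(self) -> int:
        return self.bases.shape[0]

    @property
    def read_length(self) -> int:
        return self.bases.shape[1]


@dataclass
class UnalignedPair:
    """First read of a pair excluded by mapping filters (adapter recovery)."""

    bases: str
    segment: int


def load_read_batch(
    sam_path,
    genome: Genome,
    adapter_set: AdapterSet | None = None,
    mq_threshold: int = DEFAULT_MQ_THRESHOLD,
):
    """Parse a coordinate-sorted SAM/BAM into a :class:`ReadBatch`.

    Soft-clipped read ends are re-expanded against the reference (the read is
    compared at its full length) unless an adapter is detected at the clip.
    Returns the batch, accepted pair counts keyed (seq, start, length,
    strand), and the reads rejected by mapping filters (for adapter-implied
    fragment-length recovery).
    """
    af = pysam.AlignmentFile(str(sam_path), check_sq=False)
    seq_names = list(genome.names)
    seq_lookup = {n: i for i, n in enumerate(seq_names)}
    codes_by_seq = {n: genome.codes(n) for n in seq_names}

    rows = []
    rejected: list[UnalignedPair] = []
    pair_counts: dict[tuple, int] = {}
    tiles: list[str] = []
    tile_lookup: dict[str, int] = {}

    for rec in af.fetch(until_eof=True):
        if rec.is_secondary or rec.is_supplementary:
            continue
        segment = 1 if rec.is_read2 else 0
        if rec.is_unmapped:
            rejected.append(UnalignedPair(rec.query_sequence or "", segment))
            continue
        if rec.reference_name not in seq_lookup:
            raise ValueError(
                f"read references unknown sequence {rec.reference_name!r}"
            )
        tile = tile_from_name(rec.query_name)
        if tile not in tile_lookup:
            tile_lookup[tile] = len(tiles)
            tiles.append(tile)
        rows.append((rec, segment, tile_lookup[tile]))
        # pair counting on the first-in-pair forward read of a proper FR pair
        if (
            segment == 0
            and rec.is_paired
            and not rec.mate_is_unmapped
            and rec.template_length != 0
        ):
            if rec.mapping_quality < mq_threshold:
                rejected.append(UnalignedPair(rec.query_sequence or "", segment))
            else:
                tlen = rec.template_length
                if tlen > 0 and not rec.is_reverse and rec.mate_is_reverse:
                    key = (rec.reference_name, rec.reference_start, tlen, 0)
                    pair_counts[key] = pair_counts.get(key, 0) + 1
                elif tlen < 0 and rec.is_reverse and not rec.mate_is_reverse:
                    start = rec.reference_end + tlen  # tlen negative
                    key = (rec.reference_name, start, -tlen, 1)
                    pair_counts[key] = pair_counts.get(key, 0) + 1

    if not rows:
        raise ValueError(f"no mapped reads in {sam_path}")
    rl = max(len(r.query_sequence or "") for r, _, _ in rows)
    n = len(rows)
    bases = np.full((n, rl), 4, dtype=np.uint8)
    quals = np.zeros((n, rl), dtype=np.uint8)
    ref = np.full((n, rl), 4, dtype=np.uint8)
    valid = np.zeros((n, rl), dtype=bool)
    refpos = np.full((n, rl), -1, dtype=np.int64)
    meta = {k: np.zeros(n, dtype=np.int64)
            for k in ("segment", "strand", "seq_idx", "tile_idx", "mapq",
                      "flen", "start")}
    indels: list[list] = [[] for _ in range(n)]

    for i, (rec, segment, tile_i) in enumerate(rows):
        seq = rec.query_sequence or ""
        q = np.array(rec.query_qualities or [0] * len(seq), dtype=np.uint8)
        b = encode(seq)
        rev = rec.is_reverse
        if rev:
            b = _COMP[b[::-1]]
            q = q[::-1]
        L = len(b)
        bases[i, :L] = b
        quals[i, :L] = q
        meta["segment"][i] = segment
        meta["strand"][i] = 1 if rev else 0
        meta["seq_idx"][i] = seq_lookup[rec.reference_name]
        meta["tile_idx"][i] = tile_i
        meta["mapq"][i] = rec.mapping_quality
        meta["flen"][i] = abs(rec.template_length)
        meta["start"][i] = rec.reference_start
        ref_codes = codes_by_seq[rec.reference_name]
        Lref = len(ref_codes)

        cig = rec.cigartuples or [(0, L)]
        if rev:
            cig = cig[::-1]
            cursor = rec.reference_end - 1
            step = -1
        else:
            cursor = rec.reference_start
            step = 1
        cycle = 0
        for op_i, (op, ln) in enumerate(cig):
            if op in (0, 7, 8):  # M/=/X
                pos = cursor + step * np.arange(ln)
                ok = (pos >= 0) & (pos < Lref)
                refpos[i, cycle : cycle + ln] = np.where(ok, pos, -1)
                rc = np.where(ok, ref_codes[np.clip(pos, 0, Lref - 1)], 4)
                if rev:
                    rc = _COMP[rc.astype(np.uint8)]
                ref[i, cycle : cycle + ln] = rc
                valid[i, cycle : cycle + ln] = ok
                cursor += step * ln
                cycle += ln
            elif op == 4:  # soft clip: re-expand unless adapter read-through
                is_tail = op_i == len(cig) - 1
                expand = True
                flen_i = abs(rec.template_length)
                if is_tail and 0 < flen_i <= cycle:
                    expand = False  # clip starts at/after the fragment end
                elif is_tail and adapter_set is not None:
                    cut, _aid = match_adapter(
                        "".join("ACGTN"[c] for c in b[cycle:]),
                        adapter_set, segment,
                    )
                    if cut == 0:
                        expand = False
                if cycle == 0:
                    pos = cursor + step * (np.arange(ln) - ln)
                else:
                    pos = cursor + step * np.arange(ln)
                if expand:
                    ok = (pos >= 0) & (pos < Lref)
                    refpos[i, cycle : cycle + ln] = np.where(ok, pos, -1)
                    rc = np.where(ok, ref_codes[np.clip(pos, 0, Lref - 1)], 4)
                    if rev:
                        rc = _COMP[rc.astype(np.uint8)]
                    ref[i, cycle : cycle + ln] = rc
                    valid[i, cycle : cycle + ln] = ok
                cycle += ln
            elif op == 1:  # insertion
                indels[i].append((cycle, "I", [int(x) for x in b[cycle : cycle + ln]], ln))
                cycle += ln
            elif op == 2 or op == 3:  # deletion / skip
                indels[i].append((cycle, "D", None, ln))
                cursor += step * ln
            elif op == 5:  # hard clip
                continue

    batch = ReadBatch(
        bases, quals, ref, valid, refpos,
        meta["segment"], meta["strand"], meta["seq_idx"], meta["tile_idx"],
        meta["mapq"], meta["flen"], meta["start"],
        seq_names, tiles, indels,
    )
    return batch, pair_counts, rejected


# ---------------------------------------------------------------------------
# pileup


@dataclass
class Pileup:
    """Per (sequence, strand, position) coverage and substitution counts.

    Substituted nucleotides are recorded in read orientation, so a variant
    appears as complementary top errors on the two strands.  ``r_e`` holds
    the median per-position error rate in bins of 10^4 reference bases
    (both strands of a bin share one estimate).
    """

    seq_names: list[str]
    coverage: dict            # name -> (2, L) int64
    subs: dict                # name -> (2, L, 4) int64
    excluded: dict            # name -> (L,) bool (variant-file positions)
    r_e: dict = field(default_factory=dict)  # name -> (n_bins,)

    def error_rate_at(self, name: str, pos: np.ndarray) -> np.ndarray:
        return self.r_e[name][np.asarray(pos) // ERROR_RATE_BIN]


def build_pileup(
    batch: ReadBatch,
    genome: Genome,
    variant_positions: dict | None = None,
) -> Pileup:
    """Accumulate strand-specific coverage and substitution counts.

    ``variant_positions`` maps sequence name to an array of 0-based positions
    to exclude from every statistic.
    """
    cov = {n: np.zeros((2, genome.length(n)), dtype=np.int64)
           for n in genome.names}
    subs = {n: np.zeros((2, genome.length(n), 4), dtype=np.int64)
            for n in genome.names}
    excl = {n: np.zeros(genome.length(n), dtype=bool) for n in genome.names}
    if variant_positions:
        for n, pos in variant_positions.items():
            excl[n][np.asarray(pos, dtype=int)] = True

    for si, name in enumerate(batch.seq_names):
        sel = np.flatnonzero(batch.seq_idx == si)
        if len(sel) == 0:
            continue
        v = batch.valid[sel]
        rp = batch.refpos[sel]
        strands = np.broadcast_to(batch.strand[sel][:, None], v.shape)
        b = batch.bases[sel]
        r = batch.ref[sel]
        use = v & (rp >= 0)
        np.add.at(cov[name], (strands[use], rp[use]), 1)
        mism = use & (b != r) & (b < 4) & (r < 4)
        np.add.at(subs[name], (strands[mism], rp[mism], b[mism]), 1)

    pu = Pileup(batch.seq_names, cov, subs, excl)
    for name in genome.names:
        L = genome.length(name)
        n_bins = (L + ERROR_RATE_BIN - 1) // ERROR_RATE_BIN
        re_arr = np.zeros(n_bins)
        c = cov[name]
        e = subs[name].sum(axis=2)
        keep = ~excl[name]
        for bi in range(n_bins):
            s = slice(bi * ERROR_RATE_BIN, min((bi + 1) * ERROR_RATE_BIN, L))
            m = keep[s]
            covered = c[:, s][:, m]
            errs = e[:, s][:, m]
            ok = covered > 0
            if ok.any():
                re_arr[bi] = float(np.median(errs[ok] / covered[ok]))
                if re_arr[bi] == 0.0:
                    # at low coverage most positions carry no error and the
                    # median collapses; the mean keeps the null test honest
                    re_arr[bi] = float(errs[ok].sum() / covered[ok].sum())
        pu.r_e[name] = re_arr
    return pu


# ---------------------------------------------------------------------------
# systematic-error caller


@dataclass
class SystematicErrorProfile:
    """Per (sequence, strand, position): error tendency, rate and regions.

    tendency codes 0..3 are nucleotides (read orientation), 4 is "none".
    ``region_pos`` is 0 at a region start or outside regions, else the
    1-based offset into the one-read-length region; ``region_rate`` is the
    defining rate of the active region (0 outside).
    """

    seq_names: list[str]
    read_length: int
    tendency: dict   # name -> (2, L) uint8
    rate: dict       # name -> (2, L) float
    region_pos: dict  # name -> (2, L) int32
    region_rate: dict  # name -> (2, L) float
    variant_like: dict  # name -> (L,) bool
    n_tested: int = 0
    n_systematic: int = 0


def poisson_tail(c: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """P(X >= c) for X ~ Poisson(mu)."""
    return sps.poisson.sf(np.asarray(c) - 1, np.asarray(mu))


def classify_systematic(
    pileup: Pileup, read_length: int, fdr: float = 0.05
) -> SystematicErrorProfile:
    """Call systematic errors with a Poisson tail test under BH FDR control.

    For every covered (position, strand) the top substitution count c is
    tested against Poisson(mu = coverage * median_error_rate / 3); the
    Benjamini-Hochberg procedure runs once over all tests genome-wide.
    Positions whose forward top error is the complement of the reverse top
    error (both called) are variant-like and dropped from all statistics.
    Each call opens a one-read-length error region carrying the call's rate;
    a later call with a higher rate inside a region starts a new region.
    """
    names = pileup.seq_names
    pvals = []
    keys = []  # (name, strand, pos, top_code, top_count, coverage)
    for name in names:
        cov = pileup.coverage[name]
        subs = pileup.subs[name]
        keep = ~pileup.excluded[name]
        for strand in (0, 1):
            covered = np.flatnonzero((cov[strand] > 0) & keep)
            if len(covered) == 0:
                continue
            s = subs[strand][covered]
            top_code = np.argmax(s, axis=1)
            top_count = s[np.arange(len(covered)), top_code]
            has_err = top_count > 0
            pos = covered[has_err]
            tc = top_code[has_err]
            cnt = top_count[has_err]
            mu = cov[strand][pos] * pileup.error_rate_at(name, pos) / 3.0
            p = poisson_tail(cnt, np.maximum(mu, 1e-300))
            pvals.append(p)
            keys.append((name, strand, pos, tc, cnt, cov[strand][pos]))

    profile = SystematicErrorProfile(
        names, read_length,
        {n: np.full((2, pileup.coverage[n].shape[1]), NO_TENDENCY, np.uint8)
         for n in names},
        {n: np.zeros((2, pileup.coverage[n].shape[1])) for n in names},
        {n: np.zeros((2, pileup.coverage[n].shape[1]), np.int32) for n in names},
        {n: np.zeros((2, pileup.coverage[n].shape[1])) for n in names},
        {n: np.zeros(pileup.coverage[n].shape[1], bool) for n in names},
    )
    if not pvals:
        return profile
    allp = np.concatenate(pvals)
    profile.n_tested = len(allp)
    adj = sps.false_discovery_control(allp, method="bh")
    offset = 0
    called: dict[tuple, dict] = {}
    for (name, strand, pos, tc, cnt, covc), p in zip(keys, pvals):
        a = adj[offset : offset + len(p)]
        offset += len(p)
        sig = a < fdr
        called.setdefault(name, {})[strand] = (
            pos[sig], tc[sig], cnt[sig] / covc[sig]
        )
    # variant-like: both strands systematic with complementary top errors
    comp = np.array([3, 2, 1, 0])
    for name, by_strand in called.items():
        if 0 in by_strand and 1 in by_strand:
            p0, t0, _ = by_strand[0]
            p1, t1, _ = by_strand[1]
            t1_at = {int(p): int(t) for p, t in zip(p1, t1)}
            for p, t in zip(p0, t0):
                tr = t1_at.get(int(p))
                # reverse-strand errors are stored in read orientation, so a
                # variant shows as forward == complement(reverse) after
                # mapping back to reference orientation, i.e. equal codes in
                # reference orientation: comp[t_rev_readorient] == t_fwd
                if tr is not None and comp[tr] == t:
                    profile.variant_like[name][int(p)] = True
    # assign tendencies/rates and region bookkeeping
    n_sys = 0
    for name, by_strand in called.items():
        vl = profile.variant_like[name]
        L = len(vl)
        for strand, (pos, tc, rate) in by_strand.items():
            ok = ~vl[pos]
            pos, tc, rate = pos[ok], tc[ok], rate[ok]
            n_sys += len(pos)
            profile.tendency[name][strand, pos] = tc
            profile.rate[name][strand, pos] = rate
            # sweep in sequencing direction of this strand, filling regions
            direction = 1 if strand == 0 else -1
            sys_sorted = pos[np.argsort(pos if strand == 0 else -pos)]
            rate_sorted = rate[np.argsort(pos if strand == 0 else -pos)]
            reg_start, reg_rate = None, 0.0
            rp = profile.region_pos[name][strand]
            rr = profile.region_rate[name][strand]
            for p, r in zip(sys_sorted, rate_sorted):
                p = int(p)
                inside = (
                    reg_start is not None
                    and 0 < (p - reg_start) * direction < read_length
                )
                if not inside or r > reg_rate:
                    reg_start, reg_rate = p, float(r)
                    span_end = p + direction * read_length
                    span = np.arange(p, np.clip(span_end, -1, L), direction)
                    rp[span] = np.abs(span - p)
                    rr[span] = reg_rate
    profile.n_systematic = n_sys
    return profile


# ---------------------------------------------------------------------------
# low-quality-site exclusion


@dataclass
class Exclusions:
    """Excluded fragment start/end intervals per sequence."""

    start_intervals: dict = field(default_factory=dict)  # name -> [(lo, hi)]
    end_intervals: dict = field(default_factory=dict)

    @staticmethod
    def _in_intervals(intervals, pos: np.ndarray) -> np.ndarray:
        out = np.zeros(len(pos), dtype=bool)
        for lo, hi in intervals:
            out |= (pos >= lo) & (pos <= hi)
        return out

    def site_excluded(self, name: str, starts: np.ndarray, length: int) -> np.ndarray:
        starts = np.asarray(starts)
        ends = starts + length - 1
        out = self._in_intervals(self.start_intervals.get(name, []), starts)
        out |= self._in_intervals(self.end_intervals.get(name, []), ends)
        return out

    def excluded_start_length(self, name: str) -> int:
        return sum(hi - lo + 1 for lo, hi in self.start_intervals.get(name, []))


def _connect_lowq(low_pos: np.ndarray, all_pos: np.ndarray,
                  max_between: int = 10) -> list[tuple[int, int]]:
    """Maximal runs of low-quality positions connected by < max_between others."""
    low_pos = np.sort(low_pos)
    all_sorted = np.sort(all_pos)
    intervals = []
    run_start = None
    for a, b in zip(low_pos[:-1], low_pos[1:]):
        between = np.searchsorted(all_sorted, b, side="left") - \
            np.searchsorted(all_sorted, a, side="right")
        if between < max_between:
            if run_start is None:
                run_start = a
            run_end = b
        else:
            if run_start is not None:
                intervals.append((int(run_start), int(run_end)))
            run_start = None
    if run_start is not None:
        intervals.append((int(run_start), int(run_end)))
    return intervals


def exclude_low_quality_sites(batch: ReadBatch) -> Exclusions:
    """Exclude site starts/ends inside clusters of low-mapping-quality reads.

    Forward-strand starts (reverse-strand ends) of reads with MQ < 2 are
    connected when fewer than 10 other reads start (end) strictly between
    them; connected runs and everything between are excluded.  Unconnected
    singletons are kept.
    """
    exc = Exclusions()
    for si, name in enumerate(batch.seq_names):
        sel = batch.seq_idx == si
        fwd = sel & (batch.strand == 0)
        rev = sel & (batch.strand == 1)
        starts = batch.start[fwd]
        lowq_starts = batch.start[fwd & (batch.mapq < LOWQ_MQ)]
        if len(lowq_starts) >= 2:
            others = batch.start[fwd & (batch.mapq >= LOWQ_MQ)]
            iv = _connect_lowq(lowq_starts, others)
            if iv:
                exc.start_intervals[name] = iv
        # reverse reads: their reference end = start + aligned length
        if rev.any():
            rl = (batch.refpos[rev].max(axis=1)).astype(np.int64)
            low = batch.mapq[rev] < LOWQ_MQ
            if low.sum() >= 2:
                iv = _connect_lowq(rl[low], rl[~low])
                if iv:
                    exc.end_intervals[name] = iv
    return exc


# ---------------------------------------------------------------------------
# site enumeration and corrected counts


def enumerate_sites(
    genome: Genome,
    pair_counts: dict,
    exclusions: Exclusions,
    lengths: list[tuple[str, int]],
):
    """Build :class:`covmodel.SiteData` for selected (sequence, length) pairs.

    Every possible site of the requested length is enumerated on both
    strands; k_n counts the accepted pairs mapping exactly to the site.
    """
    from .covmodel import all_sites

    out = []
    for seq, length in lengths:
        codes = genome.codes(seq)
        n = max(len(codes) - length + 1, 0)
        k = np.zeros(2 * n)
        for (s, st, ln, strand), c in pair_counts.items():
            if s == seq and ln == length and 0 <= st < n:
                k[strand * n + st] += c
        sd = all_sites(codes, length, seq_id=seq, both_strands=True)
        sd.k = k
        if n:
            starts = np.arange(n)
            ex = exclusions.site_excluded(seq, starts, length)
            sd.excluded = np.concatenate([ex, ex])
        out.append(sd)
    return out


@dataclass
class CountSummaries:
    """Corrected reference-sequence and fragment-length pair counts."""

    c_ref: dict = field(default_factory=dict)
    c_len: dict = field(default_factory=dict)
    total_pairs: int = 0

    def fragment_length_distribution(self) -> dict:
        tot = sum(self.c_len.values())
        return {l: c / tot for l, c in self.c_len.items()} if tot else {}


def corrected_counts(
    genome: Genome,
    pair_counts: dict,
    exclusions: Exclusions,
    adapter_set: AdapterSet | None = None,
    rejected: list | None = None,
    max_fragment_length: int | None = None,
) -> CountSummaries:
    """Count accepted pairs per sequence and length with exclusion correction.

    Pairs on excluded sites are dropped; the per-sequence counts are then
    scaled from the non-excluded part to the full sequence length.  When
    adapters are known, unmapped/low-quality first reads whose adapter
    position implies a fragment length add that length to the distribution.
    """
    cs = CountSummaries()
    raw_ref: dict[str, int] = {}
    for (seq, start, length, _strand), c in pair_counts.items():
        if max_fragment_length is not None and length > max_fragment_length:
            continue
        if exclusions.site_excluded(seq, np.array([start]), length)[0]:
            continue
        raw_ref[seq] = raw_ref.get(seq, 0) + c
        cs.c_len[length] = cs.c_len.get(length, 0) + c
        cs.total_pairs += c
    if adapter_set is not None and rejected:
        for up in rejected:
            if up.segment != 0 or not up.bases:
                continue
            cut, _aid = match_adapter(up.bases, adapter_set, up.segment)
            if cut is not None and cut > 0:
                cs.c_len[cut] = cs.c_len.get(cut, 0) + 1
                cs.total_pairs += 1
    for seq in genome.names:
        L = genome.length(seq)
        non_exc = L - exclusions.excluded_start_length(seq)
        raw = raw_ref.get(seq, 0)
        if non_exc <= 0:
            logger.warning("sequence %s fully excluded; C_ref set to 0", seq)
            cs.c_ref[seq] = 0.0
        else:
            cs.c_ref[seq] = raw * (L / non_exc)
    return cs


# ---------------------------------------------------------------------------
# margin filling


N_RATE_PCT = 101          # systematic error rate as integer percent
N_REGION_RATE_BINS = 11   # 0 = outside, 1..10 equal-width rate bins
MAX_ERRORS_SO_FAR = 20


def region_rate_bin(rate: np.ndarray, region_pos: np.ndarray) -> np.ndarray:
    """Region-start rate in 10 equal-width bins; 0 outside error regions."""
    inside = np.asarray(region_pos) > 0
    b = 1 + np.clip((np.asarray(rate) * 10).astype(int), 0, 9)
    return np.where(inside | (np.asarray(rate) > 0), b, 0)


def region_pos_bin(region_pos: np.ndarray, read_length: int) -> np.ndarray:
    """Bins of ten bases; the first bin covers positions 1-10; 0 = start/outside."""
    rp = np.asarray(region_pos)
    return np.where(rp > 0, (rp - 1) // 10 + 1, 0)


def dominant_window(codes_2d: np.ndarray, none_code: int = 4,
                    window: int = 5) -> np.ndarray:
    """Most frequent code among the previous ``window`` entries per row.

    Ties pick the code whose latest occurrence is closest to the current
    position; rows/positions with an empty window yield ``none_code``.
    """
    x = np.asarray(codes_2d)
    n, L = x.shape
    ncodes = none_code  # codes 0..none_code-1 are real
    counts = np.zeros((n, L, ncodes), dtype=np.int16)
    last = np.full((n, L, ncodes), -1, dtype=np.int32)
    onehots = [(x == c).astype(np.int16) for c in range(ncodes)]
    for c in range(ncodes):
        oh = onehots[c]
        cum = np.cumsum(oh, axis=1)
        prev = np.concatenate([np.zeros((n, 1), np.int16), cum[:, :-1]], axis=1)
        back = np.concatenate(
            [np.zeros((n, window), np.int16), cum[:, :-window]], axis=1
        )[:, :L]
        counts[:, :, c] = prev - back
        idx = np.where(oh > 0, np.arange(L)[None, :], -1)
        lastseen = np.maximum.accumulate(idx, axis=1)
        last[:, :, c] = np.concatenate(
            [np.full((n, 1), -1, np.int32), lastseen[:, :-1]], axis=1
        )
        # forget occurrences older than the window
        too_old = last[:, :, c] < (np.arange(L)[None, :] - window)
        last[:, :, c] = np.where(too_old, -1, last[:, :, c])
        counts[:, :, c] = np.where(last[:, :, c] < 0, 0, counts[:, :, c])
    maxc = counts.max(axis=2)
    score = counts.astype(np.int64) * (L + 1) + (last + 1)
    score[counts < maxc[:, :, None]] = -1
    dom = np.argmax(score, axis=2)
    return np.where(maxc > 0, dom, none_code).astype(np.uint8)


def gc_window_before(
    genome_codes: np.ndarray, strand: int, half_read: int
) -> np.ndarray:
    """Integer-percent GC in the window of ``half_read`` bases ending at each
    base (in sequencing direction of ``strand``), truncated at the contig
    start."""
    codes = genome_codes if strand == 0 else genome_codes[::-1]
    isgc = ((codes == 1) | (codes == 2)).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(isgc)))
    L = len(codes)
    idx = np.arange(L)
    lo = np.maximum(idx + 1 - half_read, 0)
    width = np.maximum(idx + 1 - lo, 1)
    gc = np.floor(100.0 * (cum[idx + 1] - cum[lo]) / width + 0.5).astype(int)
    return gc if strand == 0 else gc[::-1]


@dataclass
class MarginStatistics:
    """The six accumulated margin statistics of a training run."""

    tendency: MarginSet
    rate: MarginSet
    seq_quality: MarginSet
    base_quality: dict   # (segment, tile, ref_base) -> MarginSet
    base_call: dict      # (segment, tile, ref_base) -> MarginSet
    indel: MarginSet
    read_length: int = 0
    tiles: list[str] = field(default_factory=list)
    max_qual: int = 42


def _make_margin_stats(read_length: int, tiles: list[str],
                       max_qual: int = 42) -> MarginStatistics:
    nq = max_qual + 1
    n_rpb = read_length // 10 + 2
    dim = Dimension
    tendency = MarginSet([
        dim("tendency", 5), dim("region_pos_bin", n_rpb), dim("gc_before", 101),
        dim("region_rate_bin", N_REGION_RATE_BINS), dim("ref_base", 4),
        dim("prev_ref_base", 5), dim("dominant_ref", 5),
    ])
    rate = MarginSet([
        dim("rate_pct", N_RATE_PCT), dim("region_pos_bin", n_rpb),
        dim("gc_before", 101), dim("region_rate_bin", N_REGION_RATE_BINS),
        dim("ref_base", 4), dim("dominant_error", 5),
    ])
    seq_quality = MarginSet([
        dim("seq_quality", nq), dim("read_gc", 101), dim("mean_rate_pct", 101),
        dim("flen_bin", 1001), dim("tile", max(len(tiles), 1)),
        dim("segment", 2),
    ])
    base_quality = {}
    base_call = {}
    for seg in (0, 1):
        for ti in range(max(len(tiles), 1)):
            for rb in range(4):
                base_quality[(seg, ti, rb)] = MarginSet([
                    dim("base_quality", nq), dim("seq_quality", nq),
                    dim("prev_quality", nq), dim("cycle", read_length),
                    dim("rate_pct", N_RATE_PCT),
                ])
                base_call[(seg, ti, rb)] = MarginSet([
                    dim("call", 5), dim("base_quality", nq),
                    dim("cycle", read_length),
                    dim("errors_so_far", MAX_ERRORS_SO_FAR + 1),
                    dim("rate_pct", N_RATE_PCT), dim("dominant_error", 5),
                ])
    indel = MarginSet([
        dim("event", 6), dim("indel_pos", read_length),
        dim("cycle", read_length), dim("read_gc", 101),
        dim("last_call", 4), dim("indel_before", 2),
    ])
    return MarginStatistics(tendency, rate, seq_quality, base_quality,
                            base_call, indel, read_length, list(tiles),
                            max_qual)


def fill_margins(
    batch: ReadBatch,
    genome: Genome,
    profile: SystematicErrorProfile,
    pileup: Pileup,
    mq_threshold: int = DEFAULT_MQ_THRESHOLD,
    max_qual: int = 42,
) -> MarginStatistics:
    """Accumulate the six margin statistics from a read batch.

    Template-level statistics (error tendency and rate) are collected per
    covered (position, strand); read-level statistics per accepted read.
    Variant and variant-like positions contribute nothing.
    """
    rl = batch.read_length
    half_read = max(rl // 2, 1)
    ms = _make_margin_stats(rl, batch.tiles, max_qual)

    # ---- template-level statistics: tendency and rate
    for si, name in enumerate(batch.seq_names):
        codes = genome.codes(name)
        L = len(codes)
        keep = ~pileup.excluded[name] & ~profile.variant_like[name]
        for strand in (0, 1):
            covered = np.flatnonzero((pileup.coverage[name][strand] > 0) & keep)
            if len(covered) == 0:
                continue
            # per-position features in sequencing orientation of the strand
            seq_codes = codes if strand == 0 else _COMP[codes[::-1]]
            posmap = covered if strand == 0 else L - 1 - covered
            gcb = gc_window_before(codes, strand, half_read)[covered]
            tend = profile.tendency[name][strand, covered]
            ratev = profile.rate[name][strand, covered]
            rpos = profile.region_pos[name][strand, covered]
            rrate = profile.region_rate[name][strand, covered]
            rb = seq_codes[posmap]
            prev_idx = posmap - 1
            prev_rb = np.where(prev_idx >= 0, seq_codes[np.clip(prev_idx, 0, None)], 4)
            dom_ref_full = dominant_window(seq_codes[None, :], none_code=4)[0]
            dom_ref = dom_ref_full[posmap]
            # dominant error over previous 5 template positions (strand order)
            tend_full = profile.tendency[name][strand]
            tend_seq = tend_full if strand == 0 else tend_full[::-1]
            dom_err_full = dominant_window(tend_seq[None, :], none_code=4)[0]
            dom_err = dom_err_full[posmap]
            rpb = region_pos_bin(rpos, rl)
            rrb = region_rate_bin(rrate, rpos)
            ok = rb < 4
            ms.tendency.accumulate(np.column_stack([
                tend[ok], rpb[ok], gcb[ok], rrb[ok], rb[ok], prev_rb[ok],
                np.where(dom_ref[ok] > 4, 4, dom_ref[ok]),
            ]))
            # the rate conditional is trained at systematic positions only;
            # "none" positions carry no rate of their own
            sysm = ok & (tend < 4)
            rate_pct = np.clip(np.floor(ratev * 100 + 0.5), 0, 100).astype(int)
            ms.rate.accumulate(np.column_stack([
                rate_pct[sysm], rpb[sysm], gcb[sysm], rrb[sysm], rb[sysm],
                dom_err[sysm],
            ]))

    # ---- read-level statistics
    accepted = batch.mapq >= mq_threshold
    idx = np.flatnonzero(accepted)
    if len(idx) == 0:
        return ms
    b = batch.bases[idx]
    q = np.clip(batch.quals[idx], 0, max_qual)
    r = batch.ref[idx]
    v = batch.valid[idx]
    rp = batch.refpos[idx]
    seg = batch.segment[idx]
    strand = batch.strand[idx]
    tile = batch.tile_idx[idx]
    n = len(idx)

    # per-cycle systematic rate / excluded flags gathered per sequence
    rate_pct = np.zeros((n, rl), dtype=np.int64)
    pos_keep = v.copy()
    for si, name in enumerate(batch.seq_names):
        rsel = np.flatnonzero(batch.seq_idx[idx] == si)
        if len(rsel) == 0:
            continue
        rr = rp[rsel]
        ok = rr >= 0
        st = strand[rsel][:, None] * np.ones(rl, dtype=np.int64)[None, :]
        rates = np.zeros(rr.shape)
        rates[ok] = profile.rate[name][st[ok].astype(int), rr[ok]]
        rate_pct[rsel] = np.clip(np.floor(rates * 100 + 0.5), 0, 100).astype(int)
        bad = pileup.excluded[name] | profile.variant_like[name]
        drop = np.zeros(rr.shape, bool)
        drop[ok] = bad[rr[ok]]
        pos_keep[rsel] &= ~drop

    pos_keep &= (r < 4) & (b < 4)
    err = (b != r) & pos_keep
    errors_so_far = np.concatenate(
        [np.zeros((n, 1), int), np.cumsum(err, axis=1)[:, :-1]], axis=1
    ).clip(0, MAX_ERRORS_SO_FAR)
    err_codes = np.where(err, b, 4).astype(np.uint8)
    dom_err = dominant_window(err_codes, none_code=4)

    # sequence quality
    nvalid = np.maximum(pos_keep.sum(axis=1), 1)
    sq = np.floor(q.sum(axis=1, where=pos_keep) / nvalid + 0.5).astype(int)
    read_gc = np.floor(
        100.0 * (((b == 1) | (b == 2)) & (b < 4)).sum(axis=1) / rl + 0.5
    ).astype(int)
    mean_rate = np.floor(
        rate_pct.sum(axis=1, where=pos_keep) / nvalid + 0.5
    ).astype(int)
    flb = np.clip(batch.flen[idx] // 10, 0, 1000).astype(int)
    ms.seq_quality.accumulate(np.column_stack([
        sq, read_gc, mean_rate, flb, tile, seg,
    ]))

    # base quality and base call, stratified by (segment, tile, ref base)
    prev_q = np.concatenate([sq[:, None], q[:, :-1]], axis=1)
    cyc = np.broadcast_to(np.arange(rl)[None, :], (n, rl))
    sq_b = np.broadcast_to(sq[:, None], (n, rl))
    for s in (0, 1):
        for ti in range(max(len(batch.tiles), 1)):
            stratum = (seg == s) & (tile == ti)
            if not stratum.any():
                continue
            rsel = np.flatnonzero(stratum)
            for rb in range(4):
                m = pos_keep[rsel] & (r[rsel] == rb)
                if not m.any():
                    continue
                ms.base_quality[(s, ti, rb)].accumulate(np.column_stack([
                    q[rsel][m], sq_b[rsel][m], prev_q[rsel][m],
                    cyc[rsel][m], rate_pct[rsel][m],
                ]))
                ms.base_call[(s, ti, rb)].accumulate(np.column_stack([
                    b[rsel][m], q[rsel][m], cyc[rsel][m],
                    errors_so_far[rsel][m], rate_pct[rsel][m],
                    dom_err[rsel][m],
                ]))

    # InDel statistic: none-events at every regular cycle, real events rare
    ref_gc = np.floor(
        100.0 * (((r == 1) | (r == 2)) & (r < 4)).sum(axis=1)
        / np.maximum((r < 4).sum(axis=1), 1) + 0.5
    ).astype(int)
    last_call = np.concatenate([r[:, :1], b[:, :-1]], axis=1)
    has_indel = np.zeros((n, rl), bool)
    indel_rows = []
    for bi, gi in enumerate(idx):
        for (cycle, kind, codes_ins, ln) in batch.indels[gi]:
            if kind == "I":
                for j in range(ln):
                    c = min(cycle + j, rl - 1)
                    has_indel[bi, c] = True
                    indel_rows.append((
                        1 + codes_ins[j], min(j, rl - 1), c, ref_gc[bi],
                        int(last_call[bi, c]) % 4,
                        1 if (j > 0 or (c > 0 and has_indel[bi, c - 1])) else 0,
                    ))
            else:
                c = min(cycle, rl - 1)
                for j in range(ln):
                    indel_rows.append((
                        5, min(j, rl - 1), c, ref_gc[bi],
                        int(last_call[bi, c]) % 4,
                        1 if j > 0 else 0,
                    ))
    none_mask = pos_keep & ~has_indel
    rows_none = np.column_stack([
        np.zeros(none_mask.sum(), int),
        np.zeros(none_mask.sum(), int),
        cyc[none_mask],
        np.broadcast_to(ref_gc[:, None], (n, rl))[none_mask],
        np.where(last_call[none_mask] < 4, last_call[none_mask], 0),
        np.concatenate([np.zeros((n, 1), bool), has_indel[:, :-1]],
                       axis=1)[none_mask].astype(int),
    ])
    ms.indel.accumulate(rows_none)
    if indel_rows:
        ms.indel.accumulate(np.array(indel_rows, dtype=int))
    return ms
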