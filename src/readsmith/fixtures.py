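"""Synthetic training inputs with known ground truth.

Everything the trainers consume — reference FASTA, coordinate-sorted SAM,
FASTQ — can be generated here from a :class:`TruthProfile` holding planted
coverage biases, dispersion, quality chains, systematic-error positions and
adapters.  Because positions, errors and qualities are known by
construction, every estimator in the package can be checked for parameter
recovery without downloading data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

from .covmodel import (
    Dispersion, FlankParams, GCSpline, SiteData, all_sites, flank_bias,
    site_mu,
)
from .genome import Genome, decode, revcomp, write_genome

_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def make_genome(
    seed: int,
    lengths: list[int],
    gc: float = 0.5,
    n_runs: list[tuple[int, int, int]] | None = None,
    names: list[str] | None = None,
) -> Genome:
    """Random genome with a target GC fraction and optional planted N runs.

    ``n_runs`` entries are (sequence index, start, length).
    """
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    items = []
    for i, L in enumerate(lengths):
        codes = rng.choice(4, size=L, p=p).astype(np.uint8)
        if n_runs:
            for si, start, ln in n_runs:
                if si == i:
                    codes[start : start + ln] = 4
        name = names[i] if names else f"chr{i + 1}"
        items.append((name, decode(codes)))
    return Genome.from_sequences(items)


@dataclass
class TruthProfile:
    """Planted generative parameters for synthetic data."""

    seed: int = 0
    flank: FlankParams = field(default_factory=FlankParams)
    gc_log_bias: np.ndarray = field(default_factory=lambda: np.zeros(101))
    alpha: float = 0.0
    beta: float = 0.0
    norm: float = 1.0
    read_length: int = 100
    frag_mean: float = 150.0
    frag_sd: float = 15.0
    min_frag: int = 40
    qual_start: float = 25.0   # older-HiSeq-like effective error level
    qual_slope: float = -6.0   # total decline over the read
    qual_sd: float = 2.0
    max_qual: int = 42
    adapter1: str | None = None
    adapter2: str | None = None
    sys_density: float = 0.0   # fraction of (position, strand) with planted errors
    sys_rate_lo: float = 0.2
    sys_rate_hi: float = 0.5
    mapq: int = 60
    lowq_cluster: tuple[str, int, int] | None = None  # (seq, start, end): MQ 0 reads

    def gc_bias(self) -> np.ndarray:
        return np.exp(self.gc_log_bias)

    @classmethod
    def smooth(cls, seed: int, alpha: float = 0.5, beta: float = 0.1,
               flank_scale: float = 0.3, **kw) -> "TruthProfile":
        """A randomly drawn smooth GC curve and small flank parameters."""
        rng = np.random.default_rng(seed)
        knots = np.array([0, 20, 40, 60, 80, 100], float)
        vals = rng.normal(0, 0.8, size=6)
        spl = GCSpline(knots, vals)
        flank = FlankParams(rng.normal(0, flank_scale, size=(4, 30)))
        flank = flank.centered()
        return cls(seed=seed, flank=flank, gc_log_bias=spl.log_bias(),
                   alpha=alpha, beta=beta, **kw)


@dataclass
class PlantedErrors:
    """Planted systematic-error positions per (sequence, strand)."""

    positions: dict = field(default_factory=dict)  # (name, strand) -> array
    rates: dict = field(default_factory=dict)
    tendencies: dict = field(default_factory=dict)  # in read orientation


def plant_systematic_errors(
    genome: Genome, truth: TruthProfile, rng: np.random.Generator
) -> PlantedErrors:
    pe = PlantedErrors()
    for name in genome.names:
        L = genome.length(name)
        codes = genome.codes(name)
        for strand in (0, 1):
            n = rng.binomial(L, truth.sys_density)
            pos = np.sort(rng.choice(L, size=n, replace=False)) if n else np.empty(0, int)
            rates = rng.uniform(truth.sys_rate_lo, truth.sys_rate_hi, size=n)
            # tendency: an erroneous nucleotide differing from the reference
            ref = codes[pos] if n else np.empty(0, np.uint8)
            if strand == 1:
                ref = _COMP[ref]
            shift = rng.integers(1, 4, size=n)
            tend = (ref.astype(int) + shift) % 4
            pe.positions[(name, strand)] = pos
            pe.rates[(name, strand)] = rates
            pe.tendencies[(name, strand)] = tend.astype(np.uint8)
    return pe


def simulate_site_counts(
    genome: Genome,
    truth: TruthProfile,
    length: int,
    rng: np.random.Generator,
    seq_id: str | None = None,
    both_strands: bool = True,
) -> SiteData:
    """Enumerate sites of one length and draw NB counts from planted biases."""
    name = seq_id or genome.names[0]
    sd = all_sites(genome.codes(name), length, seq_id=name,
                   both_strands=both_strands)
    mu = site_mu(sd, truth.flank, truth.gc_bias(), truth.norm)
    disp = Dispersion(truth.alpha, truth.beta)
    if truth.alpha == 0 and truth.beta == 0:
        k = rng.poisson(mu)
    else:
        r = disp.r(mu)
        p = r / (r + np.maximum(mu, 1e-300))
        k = np.where(mu > 0, rng.negative_binomial(np.maximum(r, 1e-9),
                                                   np.clip(p, 1e-12, 1)), 0)
    sd.k = k.astype(float)
    return sd


def _draw_quality_chains(n: int, rl: int, truth: TruthProfile,
                         rng: np.random.Generator) -> np.ndarray:
    """AR(1) quality chains around a linearly declining mean."""
    mean = truth.qual_start + truth.qual_slope * np.arange(rl) / rl
    q = np.empty((n, rl))
    noise = rng.normal(0, truth.qual_sd, size=(n, rl))
    q[:, 0] = mean[0] + noise[:, 0]
    rho = 0.6
    for c in range(1, rl):
        q[:, c] = mean[c] + rho * (q[:, c - 1] - mean[c - 1]) + \
            np.sqrt(1 - rho**2) * noise[:, c]
    return np.clip(np.round(q), 2, truth.max_qual).astype(np.uint8)


def make_mapped_reads(
    genome: Genome,
    truth: TruthProfile,
    n_pairs: int,
    seed: int,
    sam_path,
    fastq_prefix=None,
    planted: PlantedErrors | None = None,
):
    """Write truth-perfect coordinate-sorted SAM (+ optional FASTQ).

    Fragments are placed uniformly with planted coverage biases ignored (the
    coverage model is exercised through :func:`simulate_site_counts`); reads
    carry the planted quality chains, random quality-driven errors, planted
    strand-specific systematic errors, and adapters whenever the fragment is
    shorter than the read length (represented as soft clips in the SAM).
    Returns the planted error set for recovery comparisons.
    """
    rng = np.random.default_rng(seed)
    rl = truth.read_length
    if planted is None:
        planted = plant_systematic_errors(genome, truth, rng)

    seq_lens = np.array([genome.length(n) for n in genome.names], float)
    seq_p = seq_lens / seq_lens.sum()
    seq_choice = rng.choice(len(genome.names), size=n_pairs, p=seq_p)

    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": genome.length(n)} for n in genome.names],
        "CO": [f"readsmith fixture seed={seed}"],
    })
    records = []
    fq1, fq2 = [], []

    for si, name in enumerate(genome.names):
        idx = np.flatnonzero(seq_choice == si)
        if len(idx) == 0:
            continue
        n = len(idx)
        L = genome.length(name)
        codes = genome.codes(name)
        flen = np.clip(
            np.round(rng.normal(truth.frag_mean, truth.frag_sd, size=n)),
            truth.min_frag, L,
        ).astype(int)
        starts = rng.integers(0, L - flen + 1)
        strands = rng.integers(0, 2, size=n)

        sys_rate = np.zeros((2, L))
        sys_tend = np.full((2, L), 4, np.uint8)
        for strand in (0, 1):
            p = planted.positions[(name, strand)]
            sys_rate[strand, p] = planted.rates[(name, strand)]
            sys_tend[strand, p] = planted.tendencies[(name, strand)]

        for seg in (0, 1):
            q = _draw_quality_chains(n, rl, truth, rng)
            # sequencing orientation: seg 0 starts at the fragment 5' end of
            # the fragment strand; seg 1 at the other end, opposite strand
            read_strand = strands if seg == 0 else 1 - strands
            m = np.minimum(flen, rl)  # template-aligned cycles
            # template positions per cycle (read order)
            cyc = np.arange(rl)[None, :]
            fwd_pos = starts[:, None] + cyc
            rev_pos = (starts + flen - 1)[:, None] - cyc
            pos = np.where(read_strand[:, None] == 0, fwd_pos, rev_pos)
            in_frag = cyc < m[:, None]
            posc = np.clip(pos, 0, L - 1)
            tmpl = codes[posc]
            tmpl = np.where(read_strand[:, None] == 1, _COMP[tmpl], tmpl)
            # errors: systematic first, then random from quality
            srate = sys_rate[read_strand[:, None], posc]
            stend = sys_tend[read_strand[:, None], posc]
            u = rng.random((n, rl))
            sys_hit = in_frag & (u < srate) & (stend < 4)
            p_rand = 10.0 ** (-q.astype(float) / 10.0)
            u2 = rng.random((n, rl))
            rand_hit = in_frag & ~sys_hit & (u2 < p_rand)
            bases = tmpl.copy()
            bases[sys_hit] = stend[sys_hit]
            shift = rng.integers(1, 4, size=int(rand_hit.sum()))
            bases[rand_hit] = (bases[rand_hit].astype(int) + shift) % 4
            # adapter tail when the fragment is shorter than the read
            adapter = truth.adapter1 if seg == 0 else truth.adapter2
            if adapter:
                from .genome import encode
                acodes = encode(adapter)
                # adapter then poly-A, as on a real short-fragment read-through
                for ri in np.flatnonzero(m < rl):
                    tail = rl - m[ri]
                    fill = np.zeros(tail, dtype=np.uint8)  # 0 == A
                    fill[: len(acodes)] = acodes[:tail]
                    bases[ri, m[ri]:] = fill
                    q[ri, m[ri]:] = np.minimum(q[ri, m[ri]:], 25)
            else:
                for ri in np.flatnonzero(m < rl):
                    tail = rl - m[ri]
                    bases[ri, m[ri]:] = rng.integers(0, 4, size=tail)
                    q[ri, m[ri]:] = 2

            for j in range(n):
                ri = idx[j]
                a = pysam.AlignedSegment(header)
                a.query_name = f"pair:{ri}"
                a.is_paired = True
                a.is_proper_pair = True
                a.is_read1 = seg == 0
                a.is_read2 = seg == 1
                rev = read_strand[j] == 1
                a.is_reverse = bool(rev)
                a.mate_is_reverse = not rev
                a.reference_id = si
                mq = truth.mapq
                if truth.lowq_cluster is not None:
                    cn, clo, chi = truth.lowq_cluster
                    if cn == name and clo <= starts[j] < chi:
                        mq = 0
                a.mapping_quality = mq
                mlen = int(m[j])
                read_bases = bases[j]
                read_quals = q[j]
                if rev:
                    samq = read_quals[::-1]
                    sam_bases = decode(_COMP[read_bases[::-1]])
                    cigar = ([(4, rl - mlen)] if rl > mlen else []) + [(0, mlen)]
                    a.reference_start = int(starts[j] + flen[j] - mlen)
                else:
                    samq = read_quals
                    sam_bases = decode(read_bases)
                    cigar = [(0, mlen)] + ([(4, rl - mlen)] if rl > mlen else [])
                    a.reference_start = int(starts[j])
                a.cigartuples = cigar
                a.query_sequence = sam_bases
                a.query_qualities = [int(x) for x in samq]
                tl = int(flen[j])
                a.template_length = tl if not rev else -tl
                mate_rev_start = int(starts[j]) if rev else \
                    int(starts[j] + flen[j] - min(flen[j], rl))
                a.next_reference_id = si
                a.next_reference_start = mate_rev_start
                records.append(a)
                fq_bases = decode(read_bases)
                fq_quals = "".join(chr(int(x) + 33) for x in read_quals)
                (fq1 if seg == 0 else fq2).append(
                    f"@pair:{ri}\n{fq_bases}\n+\n{fq_quals}\n"
                )

    records.sort(key=lambda a: (a.reference_id, a.reference_start))
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for a in records:
            out.write(a)
    if fastq_prefix is not None:
        with open(f"{fastq_prefix}_1.fastq", "w") as fh:
            fh.writelines(fq1)
        with open(f"{fastq_prefix}_2.fastq", "w") as fh:
            fh.writelines(fq2)
    return planted


def write_fixture_genome(genome: Genome, path) -> None:
    write_genome(genome, path)


def truth_to_sam(
    genome: Genome, fastq1, fastq2, truth_tsv, sam_path, mapq: int = 60
) -> int:
    """Convert a simulation's FASTQ pair + truth sidecar into perfect SAM.

    Placement comes from the truth table, so no aligner is involved: matched
    cycles get an M run and any read-through beyond the fragment a soft clip.
    Returns the number of pairs written.
    """
    from .genome import encode

    truth = {}
    with open(truth_tsv) as fh:
        next(fh)
        for line in fh:
            seq, start, end, strand, allele, pid = line.rstrip("\n").split("\t")
            truth[int(pid)] = (seq, int(start), int(end), strand, int(allele))

    def read_fastq(path):
        out = []
        with open(path) as fh:
            while True:
                h = fh.readline()
                if not h:
                    break
                bases = fh.readline().strip()
                fh.readline()
                quals = fh.readline().strip()
                pid = int(h.strip().split(":")[-1])
                out.append((pid, bases, quals))
        return out

    reads1 = read_fastq(fastq1)
    reads2 = read_fastq(fastq2)
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": genome.length(n)} for n in genome.names],
    })
    seq_ids = {n: i for i, n in enumerate(genome.names)}
    records = []
    for seg, reads in ((0, reads1), (1, reads2)):
        for pid, bases, quals in reads:
            seq, start, end, strand, _allele = truth[pid]
            flen = end - start
            rl = len(bases)
            mlen = min(flen, rl)
            frag_rev = strand == "-"
            rev = frag_rev if seg == 0 else not frag_rev
            a = pysam.AlignedSegment(header)
            a.query_name = f"pair:{pid}"
            a.is_paired = True
            a.is_proper_pair = True
            a.is_read1 = seg == 0
            a.is_read2 = seg == 1
            a.is_reverse = rev
            a.mate_is_reverse = not rev
            a.reference_id = seq_ids[seq]
            a.mapping_quality = mapq
            b = encode(bases)
            q = np.array([ord(c) - 33 for c in quals], dtype=np.uint8)
            if rev:
                a.reference_start = start + flen - mlen if (seg == 1) != frag_rev \
                    else start + flen - mlen
                a.cigartuples = ([(4, rl - mlen)] if rl > mlen else []) + [(0, mlen)]
                a.query_sequence = decode(_COMP[b[::-1]])
                a.query_qualities = [int(x) for x in q[::-1]]
                a.template_length = -flen
            else:
                a.reference_start = start
                a.cigartuples = [(0, mlen)] + ([(4, rl - mlen)] if rl > mlen else [])
                a.query_sequence = bases
                a.query_qualities = [int(x) for x in q]
                a.template_length = flen
            a.next_reference_id = seq_ids[seq]
            a.next_reference_start = start
            records.append(a)
    records.sort(key=lambda a: (a.reference_id, a.reference_start))
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for a in records:
            out.write(a)
    return len(reads1)
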