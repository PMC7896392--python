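"""Adapter inference from 10-mer statistics of unmapped read parts.

Sequencing adapters show up at the 3' end of reads whose fragment is shorter
than the read length.  Rather than aligning against a catalogue, the trainer
collects all 10-mers of the unmapped parts of the reads (whole read when the
read is unmapped, otherwise the suffix beyond the fragment length), seeds on
the most abundant *starting* 10-mer and greedily extends it while the base
choice stays unambiguous.  Known adapter sets (TruSeq, Nextera) ship as
package data and bypass inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

logger = logging.getLogger(__name__)

K = 10


def _is_homopolymer(kmer: str) -> bool:
    return len(set(kmer)) == 1


@dataclass
class KmerTable:
    """Per-segment 10-mer counts over unmapped read parts.

    For every 10-mer two counts are kept: how often it was the *starting*
    10-mer of an unmapped part, and its total occurrences in unmapped parts.
    Reads whose starting 10-mer recurs within their own unmapped part are
    rejected wholesale (low-complexity filter).
    """

    counts: tuple[dict, dict] = field(default_factory=lambda: ({}, {}))
    rejected: list[int] = field(default_factory=lambda: [0, 0])
    considered: list[int] = field(default_factory=lambda: [0, 0])

    def add_part(self, segment: int, part: str) -> None:
        if len(part) < K:
            return
        start_kmer = part[:K]
        if part.find(start_kmer, 1) != -1:
            self.rejected[segment] += 1
            return
        self.considered[segment] += 1
        table = self.counts[segment]
        for i in range(len(part) - K + 1):
            kmer = part[i : i + K]
            if _is_homopolymer(kmer):
                continue
            entry = table.get(kmer)
            if entry is None:
                entry = [0, 0]
                table[kmer] = entry
            if i == 0:
                entry[0] += 1
            entry[1] += 1

    def total(self, segment: int, kmer: str) -> int:
        entry = self.counts[segment].get(kmer)
        return entry[1] if entry else 0


@dataclass
class AdapterSet:
    """Adapter sequences for first/second reads plus the valid-pairing matrix."""

    first: list[str]
    second: list[str]
    pairing: np.ndarray  # bool, shape (len(first), len(second))

    def __post_init__(self) -> None:
        self.pairing = np.asarray(self.pairing, dtype=bool)
        if self.pairing.shape != (len(self.first), len(self.second)):
            raise ValueError("pairing matrix dimensions do not match adapter lists")
        if self.first and self.second and not self.pairing.any():
            raise ValueError("pairing matrix has no valid pairing")

    def adapters(self, segment: int) -> list[str]:
        return self.first if segment == 0 else self.second

    def mate_adapter(self, segment: int, adapter_id: int) -> str:
        """An adapter valid to pair with ``adapter_id`` on the other segment."""
        if segment == 0:
            js = np.flatnonzero(self.pairing[adapter_id])
            return self.second[int(js[0])]
        js = np.flatnonzero(self.pairing[:, adapter_id])
        return self.first[int(js[0])]


def collect_unmapped_kmers(reads, fragment_lengths=None) -> KmerTable:
    """Accumulate the 10-mer table from a stream of :class:`ReadRecord`.

    ``fragment_lengths`` optionally overrides the per-read fragment length
    (mapping from read name); otherwise ``record.fragment_length`` is used.
    """
    table = KmerTable()
    for rec in reads:
        if not rec.mapped:
            part = rec.bases
        else:
            flen = rec.fragment_length
            if fragment_lengths is not None:
                flen = fragment_lengths.get(rec.name, flen)
            if flen is None or flen >= len(rec.bases):
                continue
            part = rec.bases[max(flen, 0) :]
        table.add_part(rec.segment, part)
    return table


def infer_adapter(
    table: KmerTable,
    segment: int,
    min_seed_count: int | None = None,
    ratio: float = 5.0,
    min_extend_frac: float = 0.01,
) -> str | None:
    """Infer one adapter for a segment by seed-and-extend over 10-mers.

    The most abundant starting 10-mer seeds the adapter.  Each direction is
    extended one base at a time with the candidate 10-mer of highest total
    abundance, stopping when that abundance is not more than ``ratio`` times
    the runner-up's (a positive best against a zero runner-up passes, but
    only above an evidence floor of ``min_extend_frac`` of the seed count —
    one stray k-mer must not extend the adapter) or the candidate 10-mer
    already occurs in the adapter built so far.  A trailing poly-A run of
    length >= 3 is trimmed.  Returns None when no starting 10-mer reaches
    the seed evidence floor.
    """
    counts = table.counts[segment]
    if not counts:
        logger.info("no adapter signal for segment %d", segment + 1)
        return None
    if min_seed_count is None:
        min_seed_count = max(50, int(0.0001 * table.considered[segment]))
    seed, best_start = None, 0
    for kmer, (start_count, _tot) in counts.items():
        if start_count > best_start:
            seed, best_start = kmer, start_count
    if seed is None or best_start < min_seed_count:
        logger.info("no adapter signal for segment %d", segment + 1)
        return None

    adapter = seed
    extend_floor = max(2.0, min_extend_frac * best_start)

    def extend(adapter: str, right: bool) -> str:
        while True:
            context = adapter[-(K - 1) :] if right else adapter[: K - 1]
            cands = []
            for base in "ACGT":
                kmer = context + base if right else base + context
                tot = 0 if _is_homopolymer(kmer) else table.total(segment, kmer)
                cands.append((tot, base, kmer))
            cands.sort(reverse=True)
            best, runner = cands[0], cands[1]
            if best[0] < extend_floor:
                return adapter
            if runner[0] > 0 and best[0] <= ratio * runner[0]:
                return adapter
            if best[2] in adapter:
                return adapter
            adapter = adapter + best[1] if right else best[1] + adapter

    adapter = extend(adapter, right=True)
    adapter = extend(adapter, right=False)

    # poly-A tail trim (DD: maximal trailing run of A, length >= 3)
    n_a = len(adapter) - len(adapter.rstrip("A"))
    if n_a >= 3:
        adapter = adapter[: len(adapter) - n_a]
    return adapter or None


def infer_adapter_set(table: KmerTable, **kwargs) -> AdapterSet | None:
    """Infer one adapter per segment; None unless both segments succeed."""
    a1 = infer_adapter(table, 0, **kwargs)
    a2 = infer_adapter(table, 1, **kwargs)
    if a1 is None or a2 is None:
        return None
    return AdapterSet([a1], [a2], np.ones((1, 1), dtype=bool))


def match_adapter(
    bases: str,
    adapter_set: AdapterSet,
    segment: int,
    max_error_rate: float = 0.10,
    min_overlap: int = 6,
) -> tuple[int | None, int | None]:
    """Locate an adapter in a read by suffix-prefix overlap alignment.

    Returns the leftmost cut position where some adapter prefix aligns to the
    read suffix with at most ``max_error_rate`` mismatches over an overlap of
    at least ``min_overlap`` bases (mismatch-only, no gaps), together with the
    adapter's index; ``(None, None)`` if no position qualifies.
    """
    adapters = adapter_set.adapters(segment)
    n = len(bases)
    for cut in range(0, n - min_overlap + 1):
        suffix = bases[cut:]
        for aid, adapter in enumerate(adapters):
            overlap = min(len(suffix), len(adapter))
            if overlap < min_overlap:
                continue
            mism = sum(
                1 for a, b in zip(suffix[:overlap], adapter[:overlap]) if a != b
            )
            if mism <= max_error_rate * overlap:
                return cut, aid
    return None, None


def load_adapter_files(fasta_first, fasta_second, matrix_path) -> AdapterSet:
    """Load adapter FASTA files and a plain-text 0/1 pairing matrix."""
    from Bio import SeqIO

    first = [str(r.seq).upper() for r in SeqIO.parse(str(fasta_first), "fasta")]
    second = [str(r.seq).upper() for r in SeqIO.parse(str(fasta_second), "fasta")]
    rows = []
    with open(matrix_path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append([int(x) for x in line.split()])
    return AdapterSet(first, second, np.array(rows, dtype=bool))


def builtin_adapters(name: str) -> AdapterSet:
    """Shipped adapter sets: ``truseq`` or ``nextera``."""
    pkg = resources.files("readsmith.data")
    fa1 = pkg / f"{name}_1.fa"
    fa2 = pkg / f"{name}_2.fa"
    mat = pkg / f"{name}.mat"
    from Bio import SeqIO
    import io

    first = [str(r.seq).upper() for r in SeqIO.parse(io.StringIO(fa1.read_text()), "fasta")]
    second = [str(r.seq).upper() for r in SeqIO.parse(io.StringIO(fa2.read_text()), "fasta")]
    rows = [
        [int(x) for x in line.split()]
        for line in mat.read_text().splitlines()
        if line.strip()
    ]
    return AdapterSet(first, second, np.array(rows, dtype=bool))
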