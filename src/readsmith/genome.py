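"""Reference/template genome handling.

Sequences are held as upper-case A/C/G/T/N strings together with an index of
maximal N runs.  Internally all coordinates are 0-based half-open; the 1-based
conventions of VCF and SAM are converted at the parsing boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ALPHABET = "ACGTN"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string as uint8 codes A=0 C=1 G=2 T=3 N=4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _n_runs(name: str, seq: str) -> list[tuple[str, int, int]]:
    codes = encode(seq)
    isn = codes == 4
    if not isn.any():
        return []
    d = np.diff(np.concatenate(([0], isn.view(np.int8), [0])))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(name, int(s), int(e - s)) for s, e in zip(starts, ends)]


@dataclass
class Genome:
    """An ordered collection of named A/C/G/T/N sequences with an N-run index."""

    names: list[str]
    sequences: dict[str, str]
    n_runs: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence identifiers")
        for name in self.names:
            if not self.sequences[name]:
                raise ValueError(f"empty sequence: {name}")

    @classmethod
    def from_sequences(cls, items: list[tuple[str, str]]) -> "Genome":
        names = [n for n, _ in items]
        seqs = {n: s.upper() for n, s in items}
        runs: list[tuple[str, int, int]] = []
        for n in names:
            runs.extend(_n_runs(n, seqs[n]))
        return cls(names, seqs, runs)

    def __len__(self) -> int:
        return len(self.names)

    def length(self, name: str) -> int:
        return len(self.sequences[name])

    @property
    def total_length(self) -> int:
        return sum(len(self.sequences[n]) for n in self.names)

    def codes(self, name: str) -> np.ndarray:
        return encode(self.sequences[name])

    def has_n(self) -> bool:
        return bool(self.n_runs)


def load_genome(path) -> Genome:
    """Read a (possibly wrapped) multi-record FASTA into a :class:`Genome`.

    Lowercase soft-masking is uppercased; IUPAC ambiguity codes other than
    A/C/G/T/N are mapped to N with a logged warning.  ``.gz`` files are
    read transparently.
    """
    if str(path).endswith(".gz"):
        import gzip

        with gzip.open(str(path), "rt") as fh:
            records = list(SeqIO.parse(fh, "fasta"))
    else:
        records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    items: list[tuple[str, str]] = []
    n_mapped = 0
    for rec in records:
        seq = str(rec.seq).upper()
        cleaned = []
        for ch in seq:
            if ch in "ACGTN":
                cleaned.append(ch)
            else:
                cleaned.append("N")
                n_mapped += 1
        items.append((rec.id, "".join(cleaned)))
    if n_mapped:
        logger.warning("mapped %d non-ACGTN characters to N", n_mapped)
    return Genome.from_sequences(items)


def write_genome(genome: Genome, path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(genome.sequences[n]), id=n, description="") for n in genome.names
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def replace_n(genome: Genome, seed: int) -> Genome:
    """Replace every N in the genome deterministically.

    Runs of 1-99 Ns become uniform random A/C/G/T draws; runs of >=100 Ns
    become the repeat of the 4-mer built from the two bases following then the
    two bases preceding the run, truncated to the run length.  Runs touching a
    sequence boundary (fewer than two flanking bases on either side) fall back
    to random fill.  The result can be written as FASTA and reloaded to share
    replacements between simulation runs.
    """
    if not genome.has_n():
        return genome
    rng = np.random.default_rng(seed)
    items: list[tuple[str, str]] = []
    for name in genome.names:
        seq = genome.sequences[name]
        runs = [(s, l) for (n, s, l) in genome.n_runs if n == name]
        if not runs:
            items.append((name, seq))
            continue
        parts = list(seq)
        for start, length in runs:
            end = start + length
            has_flanks = start >= 2 and end + 2 <= len(seq)
            if length >= 100 and has_flanks:
                fourmer = seq[end : end + 2] + seq[start - 2 : start]
                fill = (fourmer * (length // 4 + 1))[:length]
            else:
                if length >= 100:
                    logger.warning(
                        "N run of length %d at %s:%d touches a boundary; random fill",
                        length, name, start,
                    )
                fill = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
            parts[start:end] = fill
        items.append((name, "".join(parts)))
    return Genome.from_sequences(items)


@dataclass
class VariantEdit:
    """One edit: replace ``ref`` starting at 0-based ``pos`` by ``alt``."""

    seq_id: str
    pos: int
    ref: str
    alt: str
    line: int = -1


@dataclass
class AlleleSet:
    """Per-allele edit lists for a haploid or diploid sample."""

    ploidy: int
    edits: list[list[VariantEdit]]  # one list per allele, sorted by position

    def __post_init__(self) -> None:
        if self.ploidy not in (1, 2):
            raise ValueError("only haploid and diploid samples are supported")
        for allele in self.edits:
            prev_end = {}
            for e in allele:
                if e.pos < prev_end.get(e.seq_id, 0):
                    raise ValueError(
                        f"overlapping edits on {e.seq_id} at position {e.pos}"
                    )
                prev_end[e.seq_id] = e.pos + len(e.ref)

    @classmethod
    def empty(cls, ploidy: int = 1) -> "AlleleSet":
        return cls(ploidy, [[] for _ in range(ploidy)])


def load_alleles(vcf_path, genome: Genome, sample: int = 0) -> AlleleSet:
    """Parse SNVs and simple InDels from a VCF into per-allele edit lists.

    The genotype of one sample selects which allele receives each edit.
    Structural and multi-sample records beyond ``sample`` are ignored.
    """
    import pysam

    vf = pysam.VariantFile(str(vcf_path))
    n_samples = len(vf.header.samples)
    edits: list[list[VariantEdit]] = [[], []]
    ploidy = 1
    for i, rec in enumerate(vf.fetch() if vf.index else vf):
        if rec.chrom not in genome.sequences:
            raise ValueError(f"VCF sequence {rec.chrom!r} absent from the genome")
        alts = rec.alts or ()
        if not alts:
            continue
        if n_samples > 0:
            gt = rec.samples[sample].get("GT", (1,))
            gt = tuple(0 if g is None else g for g in gt)
        else:
            gt = (1,)
        ploidy = max(ploidy, min(len(gt), 2))
        pos = rec.pos - 1  # VCF is 1-based
        ref_here = genome.sequences[rec.chrom][pos : pos + len(rec.ref)]
        if ref_here != rec.ref.upper():
            raise ValueError(
                f"VCF REF mismatch at {rec.chrom}:{rec.pos}: "
                f"expected {rec.ref!r}, genome has {ref_here!r}"
            )
        for allele_idx, g in enumerate(gt[:2]):
            if g and g <= len(alts):
                alt = alts[g - 1]
                if any(c not in "ACGTN" for c in alt.upper()):
                    continue  # symbolic / structural allele
                edits[allele_idx].append(
                    VariantEdit(rec.chrom, pos, rec.ref.upper(), alt.upper(), i)
                )
    for lst in edits:
        lst.sort(key=lambda e: (e.seq_id, e.pos))
    return AlleleSet(ploidy, edits[:ploidy])


class CoordinateMap:
    """Maps positions on the original genome to an edited allele template."""

    def __init__(self) -> None:
        self._breaks: dict[str, list[tuple[int, int]]] = {}
        self._deleted: dict[str, list[tuple[int, int]]] = {}

    def _add_break(self, seq_id: str, old_pos: int, shift: int) -> None:
        self._breaks.setdefault(seq_id, []).append((old_pos, shift))

    def _add_deleted(self, seq_id: str, start: int, end: int) -> None:
        self._deleted.setdefault(seq_id, []).append((start, end))

    def map(self, seq_id: str, old_pos: int) -> int | None:
        """New position for ``old_pos``; None if the base was deleted."""
        for s, e in self._deleted.get(seq_id, []):
            if s <= old_pos < e:
                return None
        shift = 0
        for bp, sh in self._breaks.get(seq_id, []):
            if old_pos >= bp:
                shift = sh
        return old_pos + shift


def apply_variants(
    genome: Genome, alleles: AlleleSet, which_allele: int
) -> tuple[Genome, CoordinateMap]:
    """Build the template of one allele, applying edits left to right.

    Returns the edited genome and a coordinate map from original to edited
    positions for downstream truth tracking.
    """
    if which_allele >= alleles.ploidy:
        raise IndexError("allele index out of range")
    edit_list = alleles.edits[which_allele]
    cmap = CoordinateMap()
    if not edit_list:
        return genome, cmap
    by_seq: dict[str, list[VariantEdit]] = {}
    for e in edit_list:
        by_seq.setdefault(e.seq_id, []).append(e)
    items: list[tuple[str, str]] = []
    for name in genome.names:
        seq = genome.sequences[name]
        edits = by_seq.get(name, [])
        if not edits:
            items.append((name, seq))
            continue
        parts: list[str] = []
        cursor = 0
        shift = 0
        for e in edits:
            if seq[e.pos : e.pos + len(e.ref)] != e.ref:
                raise ValueError(
                    f"edit REF mismatch at {name}:{e.pos}: {e.ref!r}"
                )
            parts.append(seq[cursor : e.pos])
            parts.append(e.alt)
            if len(e.ref) > len(e.alt):  # deletion of the tail of ref
                cmap._add_deleted(name, e.pos + len(e.alt), e.pos + len(e.ref))
            shift += len(e.alt) - len(e.ref)
            cmap._add_break(name, e.pos + len(e.ref), shift)
            cursor = e.pos + len(e.ref)
        parts.append(seq[cursor:])
        items.append((name, "".join(parts)))
    return Genome.from_sequences(items), cmap
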