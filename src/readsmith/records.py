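"""Lightweight read-pair record used between the I/O layer and the trainers."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class ReadRecord:
    """One sequenced read with its (optional) mapping.

    ``cigar`` uses the standard operation letters (M/I/D/S); ``start`` is
    0-based on ``seq_id``.  ``strand`` is '+' when the read maps forward.
    ``fragment_length`` is the outer distance of the pair when known.
    """

    segment: int  # 0 = first in pair, 1 = second
    name: str
    bases: str
    qualities: list[int]
    tile: str = "default"
    mapped: bool = False
    seq_id: str | None = None
    start: int = -1
    strand: str = "+"
    mapq: int = 0
    cigar: list[tuple[str, int]] | None = None
    fragment_length: int | None = None

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.bases):
            raise ValueError("qualities length must equal bases length")
        if self.cigar is not None:
            consumed = sum(n for op, n in self.cigar if op in "MIS=X")
            if consumed != len(self.bases):
                raise ValueError("CIGAR inconsistent with read length")
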