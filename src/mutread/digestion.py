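"""In-silico double restriction digestion and fragment size selection.

A genome is scanned for the recognition sites of two enzymes; every pair of
adjacent top-strand cut points defines a candidate fragment, and size
selection retains fragments inside a length window (inclusive on both ends),
by default only those with one end from each enzyme ("mixed ends") because
enzyme-specific adapters cannot amplify same-end fragments.

Coordinates are 0-based half-open throughout; fragment length is the
distance between adjacent top-strand cut points.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping

from .enzymes import Enzyme, iupac_pattern

__all__ = [
    "CutSite",
    "Fragment",
    "find_sites",
    "digest",
    "size_select",
    "covered_bp",
    "write_fragments_bed",
    "read_bed",
]

DEFAULT_SIZE_WINDOW = (350, 450)


@dataclass(frozen=True, order=True)
class CutSite:
    """A top-strand cut point left by one enzyme."""

    contig: str
    position: int
    enzyme: str


@dataclass(frozen=True, order=True)
class Fragment:
    """A genomic interval between two adjacent cut points (half-open)."""

    contig: str
    start: int
    end: int
    left_enzyme: str
    right_enzyme: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"fragment start {self.start} >= end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def mixed_ends(self) -> bool:
        return self.left_enzyme != self.right_enzyme


def find_sites(sequence: str, enzyme: Enzyme, contig: str = "seq") -> list[CutSite]:
    """All IUPAC-compatible matches of the enzyme on the top strand.

    Overlapping matches are all reported (lookahead scan); matches spanning
    an N are not.  Each site is returned as the cut point
    ``match_start + cut_offset``, sorted by position.
    """
    seq = sequence.upper()
    pat = re.compile("(?=" + iupac_pattern(enzyme.recognition).pattern + ")")
    return [
        CutSite(contig, m.start() + enzyme.cut_offset, enzyme.name)
        for m in pat.finditer(seq)
    ]


def digest(
    genome: Mapping[str, str], enzyme_a: Enzyme, enzyme_b: Enzyme
) -> list[Fragment]:
    """Double-digest a genome: fragments between adjacent pooled cut sites.

    Contig ends do not generate fragments (no terminal half-fragments), and
    coincident cut points of the two enzymes yield no zero-length fragment.
    """
    if enzyme_a.recognition.upper() == enzyme_b.recognition.upper():
        raise ValueError(
            f"enzymes {enzyme_a.name} and {enzyme_b.name} have identical recognition"
        )
    fragments: list[Fragment] = []
    for contig in genome:
        seq = genome[contig]
        sites = find_sites(seq, enzyme_a, contig) + find_sites(seq, enzyme_b, contig)
        sites.sort(key=lambda s: (s.position, s.enzyme))
        for left, right in zip(sites, sites[1:]):
            if left.position == right.position:
                continue
            fragments.append(
                Fragment(contig, left.position, right.position, left.enzyme, right.enzyme)
            )
    return fragments


def size_select(
    fragments: Iterable[Fragment],
    min_len: int = DEFAULT_SIZE_WINDOW[0],
    max_len: int = DEFAULT_SIZE_WINDOW[1],
    require_mixed_ends: bool = True,
) -> list[Fragment]:
    """Retain fragments with ``min_len <= length <= max_len`` (inclusive).

    With ``require_mixed_ends`` (the default) fragments flanked by the same
    enzyme on both ends are dropped: with enzyme-specific adapters they are
    never amplified into the library.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [
        f
        for f in fragments
        if min_len <= f.length <= max_len and (f.mixed_ends or not require_mixed_ends)
    ]


def covered_bp(fragments: Iterable[Fragment]) -> int:
    """Total base pairs spanned by a fragment set."""
    return sum(f.length for f in fragments)


def write_fragments_bed(fragments: Iterable[Fragment], sink: str | Path | IO[str]) -> None:
    """Write fragments as 6-column BED (0-based half-open), sorted."""
    rows = sorted(fragments, key=lambda f: (f.contig, f.start, f.end))
    own = isinstance(sink, (str, Path))
    handle = open(sink, "w") if own else sink
    try:
        for f in rows:
            handle.write(
                f"{f.contig}\t{f.start}\t{f.end}\t{f.left_enzyme}-{f.right_enzyme}\t0\t+\n"
            )
    finally:
        if own:
            handle.close()


def read_bed(source: str | Path | IO[str]) -> list[tuple[str, int, int]]:
    """Read a BED file into (contig, start, end) intervals (>= 3 columns)."""
    own = isinstance(source, (str, Path))
    handle = open(source) if own else source
    intervals: list[tuple[str, int, int]] = []
    try:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            intervals.append((fields[0], int(fields[1]), int(fields[2])))
    finally:
        if own:
            handle.close()
    return intervals
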