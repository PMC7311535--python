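"""Read preprocessing for UMI/inner-barcode reduced-representation libraries.

The library construct places, on each mate, a random unique molecular
identifier (UMI, default 4 bp), a sample-specific inner barcode (default
6 bp) and the residual restriction-site tag left by the cut, ahead of the
genomic insert:

    [UMI][inner barcode][RAD-tag][insert ...]

Processing order mirrors the library's own: PCR-duplicate (clone) removal
keyed on both UMIs plus the remaining sequence, inner-barcode
demultiplexing, residual-tag verification, then sliding-window quality
filtering.  Everything operates pre-alignment on raw read pairs.

Clone removal is exact-match on the (UMI1, UMI2, seq1, seq2) key -- UMIs are
not error-corrected or network-collapsed; users wanting Hamming-distance
UMI clustering should do so downstream.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .enzymes import iupac_match

__all__ = [
    "ReadLayout",
    "ReadPair",
    "BarcodeConfigError",
    "clone_filter",
    "demultiplex",
    "radtag_check",
    "quality_filter",
    "read_paired_fastq",
    "write_paired_fastq",
    "hamming",
]

PHRED_OFFSET = 33


@dataclass(frozen=True)
class ReadLayout:
    """Per-mate layout constants of the library construct.

    The default residual tags follow from the cut geometry of the default
    enzyme pair: PstI (CTGCA^G) leaves fragments that read TGCAG after
    adapter ligation, ApoI (R^AATTY) leaves AATT plus a pyrimidine.
    """

    umi_length: int = 4
    barcode_length: int = 6
    expected_tag_r1: str = "TGCAG"
    expected_tag_r2: str = "AATTY"

    def __post_init__(self) -> None:
        if self.umi_length < 0 or self.barcode_length < 0:
            raise ValueError("layout lengths must be >= 0")


@dataclass
class ReadPair:
    """One paired-end read; UMIs/barcodes are filled in as steps trim them."""

    id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str
    umi1: str | None = None
    umi2: str | None = None
    barcode1: str | None = None
    barcode2: str | None = None

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"sequence/quality length mismatch in read {self.id}")


class BarcodeConfigError(ValueError):
    """Barcode map incompatible with the requested mismatch tolerance."""


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("Hamming distance needs equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def clone_filter(
    pairs: Iterable[ReadPair], layout: ReadLayout | None = None
) -> tuple[list[ReadPair], dict[str, int]]:
    """Remove PCR duplicates keyed on (UMI1, UMI2, remaining seq1, remaining seq2).

    The first occurrence of each clone key is kept with its UMIs trimmed
    (and recorded on the pair); later occurrences count as duplicates.
    Reads shorter than the UMI are discarded and logged.
    """
    if layout is None:
        layout = ReadLayout()
    u = layout.umi_length
    seen: set[tuple[str, str, str, str]] = set()
    retained: list[ReadPair] = []
    stats = {"input": 0, "retained": 0, "duplicates": 0, "too_short": 0}
    for pair in pairs:
        stats["input"] += 1
        if len(pair.seq1) < u or len(pair.seq2) < u:
            stats["too_short"] += 1
            continue
        key = (pair.seq1[:u], pair.seq2[:u], pair.seq1[u:], pair.seq2[u:])
        if key in seen:
            stats["duplicates"] += 1
            continue
        seen.add(key)
        retained.append(
            replace(
                pair,
                umi1=pair.seq1[:u],
                umi2=pair.seq2[:u],
                seq1=pair.seq1[u:],
                seq2=pair.seq2[u:],
                qual1=pair.qual1[u:],
                qual2=pair.qual2[u:],
            )
        )
        stats["retained"] += 1
    return retained, stats


def _validate_barcodes(codes: Sequence[str], max_mismatch: int, side: str) -> None:
    for i, a in enumerate(codes):
        for b in codes[i + 1 :]:
            if a != b and hamming(a, b) < 2 * max_mismatch + 1:
                raise BarcodeConfigError(
                    f"{side} barcodes {a}/{b} are closer than "
                    f"2*max_mismatch+1 = {2 * max_mismatch + 1}"
                )


def demultiplex(
    pairs: Iterable[ReadPair],
    barcode_map: Mapping[tuple[str, str], str],
    max_mismatch: int = 1,
    layout: ReadLayout | None = None,
) -> tuple[dict[str, list[ReadPair]], list[ReadPair], dict[str, int]]:
    """Assign read pairs to samples by their inner-barcode pair.

    A pair is assigned iff both mates' leading barcodes match exactly one
    map entry within ``max_mismatch`` Hamming distance; barcodes are then
    trimmed.  Ambiguous or unmatched pairs go to the unassigned pool.
    """
    if layout is None:
        layout = ReadLayout()
    b = layout.barcode_length
    entries = [(bc1.upper(), bc2.upper(), sample) for (bc1, bc2), sample in barcode_map.items()]
    _validate_barcodes(sorted({e[0] for e in entries}), max_mismatch, "mate-1")
    _validate_barcodes(sorted({e[1] for e in entries}), max_mismatch, "mate-2")

    by_sample: dict[str, list[ReadPair]] = {e[2]: [] for e in entries}
    unassigned: list[ReadPair] = []
    stats = Counter({"input": 0, "assigned": 0, "unassigned": 0})
    for pair in pairs:
        stats["input"] += 1
        if len(pair.seq1) < b or len(pair.seq2) < b:
            unassigned.append(pair)
            stats["unassigned"] += 1
            continue
        bc1, bc2 = pair.seq1[:b].upper(), pair.seq2[:b].upper()
        hits = [
            sample
            for e1, e2, sample in entries
            if hamming(bc1, e1) <= max_mismatch and hamming(bc2, e2) <= max_mismatch
        ]
        if len(hits) == 1:
            by_sample[hits[0]].append(
                replace(
                    pair,
                    barcode1=bc1,
                    barcode2=bc2,
                    seq1=pair.seq1[b:],
                    seq2=pair.seq2[b:],
                    qual1=pair.qual1[b:],
                    qual2=pair.qual2[b:],
                )
            )
            stats["assigned"] += 1
        else:
            unassigned.append(pair)
            stats["unassigned"] += 1
    return by_sample, unassigned, dict(stats)


def radtag_check(
    pairs: Iterable[ReadPair],
    layout: ReadLayout | None = None,
    allow_mirror: bool = True,
) -> tuple[list[ReadPair], dict[str, int]]:
    """Keep pairs whose mates start with the expected residual restriction tags.

    Mate 1 must begin with the first enzyme's tag and mate 2 with the
    second's (IUPAC-aware); with ``allow_mirror`` the swapped assignment is
    also accepted, since a fragment can ligate into the adapters in either
    orientation.  Tags are genomic sequence and are retained on the reads.
    """
    if layout is None:
        layout = ReadLayout()
    t1, t2 = layout.expected_tag_r1, layout.expected_tag_r2

    def starts(seq: str, tag: str) -> bool:
        return len(seq) >= len(tag) and iupac_match(tag, seq[: len(tag)])

    passing: list[ReadPair] = []
    stats = {"input": 0, "passed": 0, "tag_failed": 0}
    for pair in pairs:
        stats["input"] += 1
        ok = (starts(pair.seq1, t1) and starts(pair.seq2, t2)) or (
            allow_mirror and starts(pair.seq1, t2) and starts(pair.seq2, t1)
        )
        if ok:
            passing.append(pair)
            stats["passed"] += 1
        else:
            stats["tag_failed"] += 1
    return passing, stats


def _phred(qual: str) -> np.ndarray:
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(float) - PHRED_OFFSET


def _fails_quality(qual: str, window_fraction: float, threshold: float) -> bool:
    scores = _phred(qual)
    n = len(scores)
    if n == 0:
        return False
    w = max(1, int(round(window_fraction * n)))
    if w > n:
        w = n
    means = np.convolve(scores, np.ones(w) / w, mode="valid")
    return bool((means < threshold).any())


def quality_filter(
    pairs: Iterable[ReadPair],
    window_fraction: float = 0.15,
    phred_threshold: float = 10.0,
) -> tuple[list[ReadPair], dict[str, int]]:
    """Discard pairs with a low-quality sliding window in either mate.

    A window spans ``window_fraction`` of the read length; a pair fails if
    the mean Phred score of any window drops below ``phred_threshold``
    (defaults match Stacks' process_radtags: 15% window, Q10).
    """
    passing: list[ReadPair] = []
    stats = {"input": 0, "passed": 0, "quality_failed": 0}
    for pair in pairs:
        stats["input"] += 1
        if _fails_quality(pair.qual1, window_fraction, phred_threshold) or _fails_quality(
            pair.qual2, window_fraction, phred_threshold
        ):
            stats["quality_failed"] += 1
        else:
            passing.append(pair)
            stats["passed"] += 1
    return passing, stats


def _open_text(path: str | Path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_paired_fastq(r1: str | Path, r2: str | Path) -> list[ReadPair]:
    """Load paired FASTQ files (optionally gzipped, Phred+33) into ReadPairs."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    pairs: list[ReadPair] = []
    with _open_text(r1, "r") as h1, _open_text(r2, "r") as h2:
        for (id1, seq1, q1), (id2, seq2, q2) in zip(
            FastqGeneralIterator(h1), FastqGeneralIterator(h2), strict=True
        ):
            name = id1.split()[0].removesuffix("/1")
            pairs.append(ReadPair(id=name, seq1=seq1, seq2=seq2, qual1=q1, qual2=q2))
    return pairs


def write_paired_fastq(pairs: Iterable[ReadPair], r1: str | Path, r2: str | Path) -> None:
    with _open_text(r1, "w") as h1, _open_text(r2, "w") as h2:
        for pair in pairs:
            h1.write(f"@{pair.id}/1\n{pair.seq1}\n+\n{pair.qual1}\n")
            h2.write(f"@{pair.id}/2\n{pair.seq2}\n+\n{pair.qual2}\n")
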