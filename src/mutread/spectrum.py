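"""96-channel trinucleotide mutational spectra.

Single-base substitutions are classified on the pyrimidine strand: a
substitution with a purine reference is reverse-complemented (together with
its flanking bases) before lookup.  The canonical channel order is
substitution-major (C>A, C>G, C>T, T>A, T>C, T>G), then the 5' flanking
base, then the 3' flanking base, both alphabetical -- the order shared by
COSMIC signature tables, so spectra and signature matrices align by label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "CHANNELS",
    "SUBSTITUTIONS",
    "Snv",
    "MutationalSpectrum",
    "RegionIndex",
    "SkippedSnv",
    "trinucleotide_channel",
    "build_spectrum",
    "subsample_snvs",
    "read_vcf_snvs",
    "read_fasta",
]

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Canonical channel labels, e.g. "A[C>A]A", in the fixed 96-entry order.
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)

_CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNELS)}


def channel_index(label: str) -> int:
    """Index of a channel label like ``A[C>T]G`` in the canonical order."""
    try:
        return _CHANNEL_INDEX[label]
    except KeyError:
        raise ValueError(f"unknown channel label {label!r}") from None


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Snv:
    """A single-nucleotide somatic variant (0-based position)."""

    contig: str
    pos: int
    ref: str
    alt: str
    sample: str | None = None

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"not a single-base substitution: {self.ref}>{self.alt}")
        if self.ref.upper() == self.alt.upper():
            raise ValueError(f"ref equals alt ({self.ref}) at {self.contig}:{self.pos}")


class SkippedSnv(ValueError):
    """An SNV that cannot be assigned a channel (N context, edge, ref mismatch)."""

    def __init__(self, snv: Snv, reason: str):
        super().__init__(f"{snv.contig}:{snv.pos} {snv.ref}>{snv.alt}: {reason}")
        self.snv = snv
        self.reason = reason


def trinucleotide_channel(snv: Snv, genome: Mapping[str, str]) -> int:
    """Map an SNV to its canonical 96-channel index using the genome context.

    Raises :class:`SkippedSnv` for positions without two flanking bases, an
    N in the trinucleotide, or a reference-allele mismatch.
    """
    try:
        seq = genome[snv.contig]
    except KeyError:
        raise SkippedSnv(snv, "contig not in genome") from None
    if not 1 <= snv.pos <= len(seq) - 2:
        raise SkippedSnv(snv, "no flanking base on contig")
    tri = seq[snv.pos - 1 : snv.pos + 2].upper()
    ref = snv.ref.upper()
    alt = snv.alt.upper()
    if tri[1] != ref:
        raise SkippedSnv(snv, f"reference mismatch: genome {tri[1]}, record {ref}")
    if any(b not in _BASES for b in tri) or alt not in _BASES:
        raise SkippedSnv(snv, "ambiguous base in context")
    if ref in "AG":  # purine: flip to the pyrimidine strand
        tri = _revcomp(tri)
        ref = tri[1]
        alt = _revcomp(alt)
    return _CHANNEL_INDEX[f"{tri[0]}[{ref}>{alt}]{tri[2]}"]


class RegionIndex:
    """Half-open interval membership over per-contig sorted, disjoint regions."""

    def __init__(self, regions: Iterable[tuple[str, int, int]]):
        per_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end in regions:
            per_contig.setdefault(contig, []).append((int(start), int(end)))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for contig, ivals in per_contig.items():
            ivals.sort()
            self._starts[contig] = np.array([s for s, _ in ivals])
            self._ends[contig] = np.array([e for _, e in ivals])

    @classmethod
    def from_fragments(cls, fragments) -> "RegionIndex":
        return cls((f.contig, f.start, f.end) for f in fragments)

    def __contains__(self, locus: tuple[str, int]) -> bool:
        contig, pos = locus
        starts = self._starts.get(contig)
        if starts is None or len(starts) == 0:
            return False
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos < self._ends[contig][i]


@dataclass
class MutationalSpectrum:
    """Counts over the 96 canonical substitution channels."""

    counts: np.ndarray
    skipped: list[SkippedSnv] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError(f"spectrum needs 96 channels, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("spectrum counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("zero spectrum has no frequency representation")
        return self.counts / self.total

    def to_tsv(self, sink: str | Path | IO[str]) -> None:
        own = isinstance(sink, (str, Path))
        handle = open(sink, "w") if own else sink
        try:
            handle.write("channel\tcount\n")
            for label, count in zip(CHANNELS, self.counts):
                handle.write(f"{label}\t{count:g}\n")
        finally:
            if own:
                handle.close()

    @classmethod
    def from_tsv(cls, source: str | Path | IO[str]) -> "MutationalSpectrum":
        own = isinstance(source, (str, Path))
        handle = open(source) if own else source
        counts = np.zeros(96)
        seen = set()
        try:
            for line in handle:
                line = line.strip()
                if not line or line.startswith("channel"):
                    continue
                label, value = line.split("\t")
                counts[channel_index(label)] = float(value)
                seen.add(label)
        finally:
            if own:
                handle.close()
        if len(seen) not in (0, 96):
            missing = sorted(set(CHANNELS) - seen)
            raise ValueError(f"spectrum TSV missing channels, e.g. {missing[:3]}")
        return cls(counts)


def build_spectrum(
    snvs: Iterable[Snv],
    genome: Mapping[str, str],
    regions: RegionIndex | Iterable[tuple[str, int, int]] | None = None,
) -> MutationalSpectrum:
    """Count SNVs into the 96 channels, optionally restricted to regions.

    Unclassifiable SNVs are excluded and recorded in ``spectrum.skipped``;
    the spectrum total equals the number of contributing SNVs exactly.
    """
    if regions is not None and not isinstance(regions, RegionIndex):
        regions = RegionIndex(regions)
    counts = np.zeros(96)
    skipped: list[SkippedSnv] = []
    for snv in snvs:
        if regions is not None and (snv.contig, snv.pos) not in regions:
            continue
        try:
            counts[trinucleotide_channel(snv, genome)] += 1
        except SkippedSnv as exc:
            skipped.append(exc)
    return MutationalSpectrum(counts, skipped=skipped)


def subsample_snvs(
    snvs: Sequence[Snv], n: int, seed: int | np.random.Generator | None = None
) -> list[Snv]:
    """Uniform sample of ``n`` SNVs without replacement, seed-reproducible.

    Returns all SNVs when ``n >= len(snvs)``; callers decide whether such a
    sample should contribute to a summary.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n >= len(snvs):
        return list(snvs)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(len(snvs), size=n, replace=False)
    return [snvs[i] for i in idx]


def read_vcf_snvs(
    path: str | Path,
    sample: str | None = None,
    apply_filter_column: bool = False,
) -> list[Snv]:
    """Read single-base SNVs from a VCF.

    Multi-allelic records are split; non-SNV alleles are dropped.  The VCF
    FILTER column is ignored by default because filtering is a separate,
    explicit step in this pipeline.
    """
    from cyvcf2 import VCF

    snvs: list[Snv] = []
    vcf = VCF(str(path))
    for record in vcf:
        if apply_filter_column and record.FILTER is not None:
            continue
        if len(record.REF) != 1:
            continue
        for alt in record.ALT:
            if len(alt) != 1 or alt.upper() == record.REF.upper():
                continue
            snvs.append(Snv(record.CHROM, record.start, record.REF, alt, sample=sample))
    vcf.close()
    return snvs


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an in-memory contig -> sequence mapping."""
    from pyfaidx import Fasta

    with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fasta:
        return {name: str(fasta[name][:]) for name in fasta.keys()}
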