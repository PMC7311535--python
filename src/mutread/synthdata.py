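"""Synthetic genomes, signature-mixture mutation sets and library reads.

Everything here is generated with explicit truth tables so the digestion,
spectrum, refitting and read-preprocessing modules can be exercised
end-to-end without any external download:

* genomes with restriction sites planted at known positions and a
  background rejection-sampled to be free of accidental sites, so the
  expected fragment set is exact rather than probabilistic;
* somatic SNV sets drawn from a known signature-exposure mixture by
  multinomial sampling over the 96 channels, placed at genome positions
  with the matching trinucleotide context;
* paired reads in the reduced-representation library layout
  [UMI][inner barcode][residual restriction tag][insert] with a controlled
  PCR-duplication rate and known sample of origin.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np

from .digestion import Fragment, digest, find_sites
from .enzymes import Enzyme, IUPAC_CODES
from .readprep import ReadLayout, ReadPair
from .signatures import SignatureMatrix
from .spectrum import CHANNELS, SUBSTITUTIONS, Snv

__all__ = [
    "SynthesisConfig",
    "GenomeTruth",
    "synthetic_signature_matrix",
    "make_genome",
    "sample_mutations",
    "write_vcf",
    "simulate_reads",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SynthesisConfig:
    """Plan for one synthetic genome: length, composition and planted sites."""

    length: int = 100_000
    gc_fraction: float = 0.41
    site_plan: Sequence[tuple[str, int]] = ()  # (enzyme name, site start)
    purge_enzymes: Sequence[str] = ()  # kept site-free even if not planted
    contig: str = "chrS"
    seed: int = 0


@dataclass
class GenomeTruth:
    """Truth table for a planted genome."""

    sites: list[tuple[str, int, int]]  # (enzyme, site start, cut position)
    fragments: list[Fragment] = field(default_factory=list)


def synthetic_signature_matrix(k: int = 6, seed: int = 7, spread: float = 0.15) -> SignatureMatrix:
    """A set of k mutually dissimilar synthetic signatures (pairwise cosine < 0.3).

    Each signature concentrates ``1 - spread`` of its mass on one of the six
    substitution classes, with random context weights, and spreads the rest
    uniformly over all 96 channels.  These are stand-ins with the same
    mathematical shape as real signature compendia, not estimates of any
    published signature set.
    """
    if not 1 <= k <= 6:
        raise ValueError("k must be between 1 and 6 (one class per signature)")
    rng = np.random.default_rng(seed)
    matrix = np.full((k, 96), spread / 96)
    for i in range(k):
        ctx = rng.dirichlet(np.ones(16) * 2.0)
        matrix[i, i * 16 : (i + 1) * 16] += (1 - spread) * ctx
    names = [f"SynthSig{i + 1}" for i in range(k)]
    return SignatureMatrix(names=names, matrix=matrix)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=probs)


def _realize_site(rng: np.random.Generator, recognition: str) -> str:
    """Pick a concrete A/C/G/T realisation of an IUPAC recognition."""
    return "".join(
        code if code in "ACGT" else rng.choice(sorted(IUPAC_CODES[code]))
        for code in recognition.upper()
    )


def make_genome(
    config: SynthesisConfig, enzymes: Mapping[str, Enzyme]
) -> tuple[dict[str, str], GenomeTruth]:
    """Generate a genome with sites planted exactly at the planned positions.

    The background is rejection-sampled until it contains no accidental
    recognition match for any planted enzyme (at most 1000 repair passes),
    so digestion of the result recovers exactly the planted cut sites.
    """
    rng = np.random.default_rng(config.seed)
    plan = sorted(config.site_plan, key=lambda p: p[1])
    occupied: list[tuple[int, int]] = []
    for name, start in plan:
        enz = enzymes[name]
        if start < 0 or start + enz.site_length > config.length:
            raise ValueError(f"planted site {name}@{start} outside genome")
        for s, e in occupied:
            if start < e and s < start + enz.site_length:
                raise ValueError(f"planted sites overlap near position {start}")
        occupied.append((start, start + enz.site_length))

    seq = _random_sequence(rng, config.length, config.gc_fraction)
    for name, start in plan:
        site = _realize_site(rng, enzymes[name].recognition)
        seq[start : start + len(site)] = list(site)

    planted = {(name, start) for name, start in plan}
    used = {name for name, _ in plan} | set(config.purge_enzymes)
    for attempt in range(1000):
        text = "".join(seq)
        accidental: list[tuple[int, int]] = []
        for name in used:
            enz = enzymes[name]
            for site in find_sites(text, enz, config.contig):
                start = site.position - enz.cut_offset
                if (name, start) not in planted:
                    accidental.append((start, start + enz.site_length))
        if not accidental:
            break
        for start, end in accidental:
            # redraw only bases not belonging to a planted site
            for i in range(start, end):
                if not any(s <= i < e for s, e in occupied):
                    seq[i] = rng.choice(_BASES)
    else:
        raise RuntimeError("could not purge accidental recognition sites in 1000 passes")

    genome = {config.contig: "".join(seq)}
    sites = [
        (name, start, start + enzymes[name].cut_offset) for name, start in plan
    ]
    truth = GenomeTruth(sites=sites)
    planted_enzymes = {name for name, _ in plan}
    if len(planted_enzymes) == 2:
        enz_a, enz_b = (enzymes[n] for n in sorted(planted_enzymes))
        truth.fragments = digest(genome, enz_a, enz_b)
    return genome, truth


def _context_positions(sequence: str) -> dict[str, np.ndarray]:
    """Index interior positions by pyrimidine-strand trinucleotide context."""
    index: dict[str, list[int]] = {}
    seq = sequence.upper()
    for i in range(1, len(seq) - 1):
        tri = seq[i - 1 : i + 2]
        if any(b not in "ACGT" for b in tri):
            continue
        if tri[1] in "AG":
            tri = _revcomp(tri)
        index.setdefault(tri, []).append(i)
    return {k: np.array(v) for k, v in index.items()}


def sample_mutations(
    genome: Mapping[str, str],
    sigs: SignatureMatrix,
    exposures: Sequence[float],
    n: int,
    seed: int | np.random.Generator | None = None,
    sample: str | None = None,
) -> list[Snv]:
    """Draw n SNVs from the signature mixture S^T e by multinomial sampling.

    Channel counts are multinomial over the 96-channel mixture
    distribution; each mutation is placed uniformly at a genome position
    whose pyrimidine-strand trinucleotide matches the channel context,
    without replacement across all draws.  When the genome base is a purine
    the emitted ref/alt are the complement of the channel's pyrimidine
    substitution.
    """
    exposures = np.asarray(exposures, dtype=float)
    if exposures.shape != (sigs.k,) or (exposures < 0).any():
        raise ValueError("exposures must be a non-negative vector of length k")
    if abs(exposures.sum() - 1.0) > 1e-6:
        raise ValueError("exposures must sum to one")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mixture = exposures @ sigs.matrix
    mixture = mixture / mixture.sum()
    channel_counts = rng.multinomial(n, mixture)

    snvs: list[Snv] = []
    contigs = list(genome)
    if len(contigs) != 1:
        raise ValueError("sample_mutations expects a single-contig genome")
    contig = contigs[0]
    seq = genome[contig].upper()
    index = {k: rng.permutation(v) for k, v in _context_positions(seq).items()}
    cursor = {k: 0 for k in index}

    missing: list[str] = []
    for channel, count in zip(CHANNELS, channel_counts):
        if count == 0:
            continue
        ctx = channel[0] + channel[2] + channel[6]  # e.g. A[C>T]G -> ACG
        alt_pyr = channel[4]
        available = index.get(ctx)
        if available is None or cursor[ctx] + count > len(available):
            missing.append(channel)
            continue
        chosen = available[cursor[ctx] : cursor[ctx] + count]
        cursor[ctx] += int(count)
        for pos in chosen:
            base = seq[pos]
            if base in "CT":
                snvs.append(Snv(contig, int(pos), base, alt_pyr, sample=sample))
            else:
                snvs.append(Snv(contig, int(pos), base, _revcomp(alt_pyr), sample=sample))
    if missing:
        raise ValueError(
            f"genome lacks positions for {len(missing)} required contexts, "
            f"e.g. {missing[:3]}; use a longer genome"
        )
    snvs.sort(key=lambda s: (s.contig, s.pos))
    return snvs


def write_vcf(
    snvs: Sequence[Snv], genome: Mapping[str, str], sink: str | Path | IO[str]
) -> None:
    """Write SNVs as a minimal VCF 4.2 file (positions converted to 1-based)."""
    own = isinstance(sink, (str, Path))
    handle = open(sink, "w") if own else sink
    try:
        handle.write("##fileformat=VCFv4.2\n")
        for contig in genome:
            handle.write(f"##contig=<ID={contig},length={len(genome[contig])}>\n")
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for snv in sorted(snvs, key=lambda s: (s.contig, s.pos)):
            handle.write(
                f"{snv.contig}\t{snv.pos + 1}\t.\t{snv.ref}\t{snv.alt}\t.\t.\t.\n"
            )
    finally:
        if own:
            handle.close()


@dataclass
class ReadTruth:
    """Truth for one emitted read pair."""

    read_id: str
    sample: str
    fragment: Fragment
    is_duplicate: bool


def simulate_reads(
    fragments: Sequence[Fragment],
    genome: Mapping[str, str],
    barcode_map: Mapping[tuple[str, str], str],
    layout: ReadLayout | None = None,
    duplication_rate: float = 0.0,
    read_length: int = 150,
    seed: int | np.random.Generator | None = None,
) -> tuple[list[ReadPair], list[ReadTruth]]:
    """Emit one library read pair per fragment, plus controlled PCR duplicates.

    Each mate is UMI + inner barcode + residual restriction tag + insert,
    truncated to ``read_length``; mate 2 reads the reverse complement of the
    fragment.  Duplicates are exact re-emissions (same UMIs and sequence) of
    pairs chosen at the configured rate; the truth table records sample of
    origin, source fragment and duplicate flag per read id.
    """
    if layout is None:
        layout = ReadLayout()
    if not 0 <= duplication_rate < 1:
        raise ValueError("duplication_rate must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    samples = list(barcode_map.items())
    pairs: list[ReadPair] = []
    truth: list[ReadTruth] = []

    originals: list[tuple[ReadPair, ReadTruth]] = []
    seen: set[tuple[str, str]] = set()
    for i, frag in enumerate(fragments):
        (bc1, bc2), sample = samples[rng.integers(len(samples))]
        insert = genome[frag.contig][frag.start : frag.end].upper()
        tag1 = _realize_site(rng, layout.expected_tag_r1)
        tag2 = _realize_site(rng, layout.expected_tag_r2)
        for _ in range(1000):
            umi1 = "".join(rng.choice(_BASES, size=layout.umi_length))
            umi2 = "".join(rng.choice(_BASES, size=layout.umi_length))
            seq1 = (umi1 + bc1 + tag1 + insert)[:read_length]
            seq2 = (umi2 + bc2 + tag2 + _revcomp(insert))[:read_length]
            # distinct molecules must never alias as clones, or the truth
            # duplicate count would under-state the library's
            if (seq1, seq2) not in seen:
                break
        else:
            raise RuntimeError("UMI space exhausted; raise umi_length or lower depth")
        seen.add((seq1, seq2))
        pair = ReadPair(
            id=f"read{i}",
            seq1=seq1,
            seq2=seq2,
            qual1="I" * len(seq1),
            qual2="I" * len(seq2),
        )
        originals.append((pair, ReadTruth(pair.id, sample, frag, False)))

    n_dup = int(round(duplication_rate * len(originals)))
    dup_sources = (
        rng.choice(len(originals), size=n_dup, replace=False) if n_dup else np.array([], int)
    )
    for pair, t in originals:
        pairs.append(pair)
        truth.append(t)
    for j, src in enumerate(sorted(int(s) for s in dup_sources)):
        pair, t = originals[src]
        dup = ReadPair(
            id=f"read{len(originals) + j}",
            seq1=pair.seq1,
            seq2=pair.seq2,
            qual1=pair.qual1,
            qual2=pair.qual2,
        )
        pairs.append(dup)
        truth.append(ReadTruth(dup.id, t.sample, t.fragment, True))
    return pairs, truth
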