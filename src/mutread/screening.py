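"""Simulation experiments: profile stability and enzyme-pair screening.

Two experiments drive method design.  The *stability* experiment asks how
many somatic mutations are needed before a refitted signature profile
stabilises: random subsets of increasing size are drawn from each sample's
full SNV set, refitted, and compared to the full-set profile by cosine
similarity.  The *screen* experiment ranks candidate enzyme pairs: each
pair's in-silico digest (with size selection) defines the sequenced
territory, each sample's SNVs are restricted to it, and the restricted
profile is compared to the full profile.  A generic target-region variant
covers exome-style panels supplied as BED intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .digestion import covered_bp, digest, size_select, DEFAULT_SIZE_WINDOW
from .enzymes import Enzyme
from .signatures import (
    DegenerateFitError,
    ExposureProfile,
    SignatureMatrix,
    ZeroSpectrumError,
    cosine_similarity,
    fit_exposures,
)
from .spectrum import RegionIndex, Snv, build_spectrum, subsample_snvs

__all__ = [
    "StabilityCurve",
    "stability_experiment",
    "screen_combinations",
    "region_restrict_experiment",
]


@dataclass
class StabilityCurve:
    """Replicate-level cosine similarities per subset size.

    ``data`` holds one row per (sample, size, replicate) with the cosine
    similarity of the subset-derived profile to the sample's full-set
    profile; ``contributing`` records, per size, which samples had enough
    mutations to be subsampled at that size.
    """

    data: pd.DataFrame
    contributing: dict[int, list[str]]

    def summary(self) -> pd.DataFrame:
        """Mean/sd cosine per subset size over contributing samples and replicates."""
        grouped = self.data.groupby("size")["cosine"]
        out = grouped.agg(["mean", "std", "count"]).reset_index()
        out["n_samples"] = [len(self.contributing[s]) for s in out["size"]]
        return out


def _reference_profiles(
    snv_sets: Mapping[str, Sequence[Snv]],
    genome: Mapping[str, str],
    sigs: SignatureMatrix,
) -> dict[str, ExposureProfile]:
    return {
        sample: fit_exposures(build_spectrum(snvs, genome), sigs)
        for sample, snvs in snv_sets.items()
    }


def stability_experiment(
    snv_sets: Mapping[str, Sequence[Snv]],
    genome: Mapping[str, str],
    sigs: SignatureMatrix,
    sizes: Sequence[int],
    replicates: int = 10,
    seed: int | None = None,
    reference: Mapping[str, ExposureProfile] | None = None,
) -> StabilityCurve:
    """Profile stability under random mutation subsets of increasing size.

    For every subset size and replicate, each contributing sample's SNVs
    are subsampled without replacement, the spectrum refitted, and the
    cosine similarity to the sample's full-set profile recorded.  A sample
    contributes at size n only if it carries at least n mutations.
    Deterministic under ``seed``.  ``reference`` profiles may be supplied
    to compare against an external truth instead of the full-set fit.
    """
    rng = np.random.default_rng(seed)
    refs = dict(reference) if reference is not None else _reference_profiles(
        snv_sets, genome, sigs
    )
    rows = []
    contributing: dict[int, list[str]] = {}
    for size in sizes:
        contributing[int(size)] = [
            s for s in snv_sets if len(snv_sets[s]) >= size
        ]
        for sample in contributing[int(size)]:
            snvs = snv_sets[sample]
            for rep in range(replicates):
                subset = subsample_snvs(snvs, int(size), rng)
                profile = fit_exposures(build_spectrum(subset, genome), sigs)
                rows.append(
                    {
                        "sample": sample,
                        "size": int(size),
                        "replicate": rep,
                        "cosine": cosine_similarity(profile, refs[sample]),
                    }
                )
    return StabilityCurve(pd.DataFrame(rows), contributing)


def screen_combinations(
    genome: Mapping[str, str],
    snv_sets: Mapping[str, Sequence[Snv]],
    sigs: SignatureMatrix,
    enzyme_pairs: Sequence[tuple[Enzyme, Enzyme]],
    window: tuple[int, int] = DEFAULT_SIZE_WINDOW,
) -> pd.DataFrame:
    """Rank enzyme pairs by similarity of reduced-representation profiles.

    For each pair: digest + size-select, restrict every sample's SNVs to
    the retained fragments, refit, and compare to the sample's full-set
    profile.  Returns one row per pair with mean/sd cosine over samples
    with a non-empty restricted spectrum, the mean recovered mutation
    count, covered genome size, and how many samples were flagged
    (zero-spectrum restriction, excluded from the mean).
    """
    refs = _reference_profiles(snv_sets, genome, sigs)
    rows = []
    for enz_a, enz_b in enzyme_pairs:
        fragments = size_select(digest(genome, enz_a, enz_b), *window)
        regions = RegionIndex.from_fragments(fragments)
        cosines, yields, flagged = [], [], 0
        for sample, snvs in snv_sets.items():
            spectrum = build_spectrum(snvs, genome, regions=regions)
            yields.append(spectrum.total)
            try:
                profile = fit_exposures(spectrum, sigs)
            except (ZeroSpectrumError, DegenerateFitError):
                flagged += 1
                continue
            cosines.append(cosine_similarity(profile, refs[sample]))
        rows.append(
            {
                "enzyme_a": enz_a.name,
                "enzyme_b": enz_b.name,
                "n_fragments": len(fragments),
                "covered_bp": covered_bp(fragments),
                "mean_cosine": float(np.mean(cosines)) if cosines else float("nan"),
                "sd_cosine": float(np.std(cosines, ddof=1)) if len(cosines) > 1 else float("nan"),
                "mean_mutations": float(np.mean(yields)) if yields else 0.0,
                "n_samples": len(cosines),
                "n_flagged": flagged,
            }
        )
    return pd.DataFrame(rows)


def region_restrict_experiment(
    snv_sets: Mapping[str, Sequence[Snv]],
    regions: RegionIndex | Sequence[tuple[str, int, int]],
    genome: Mapping[str, str],
    sigs: SignatureMatrix,
) -> pd.DataFrame:
    """Per-sample cosine to the full profile under a fixed target-region set.

    Generic panel simulation (exome-style BED targets).  Samples whose
    restricted spectrum is empty are flagged rather than scored.
    """
    if not isinstance(regions, RegionIndex):
        regions = RegionIndex(regions)
    refs = _reference_profiles(snv_sets, genome, sigs)
    rows = []
    for sample, snvs in snv_sets.items():
        spectrum = build_spectrum(snvs, genome, regions=regions)
        row = {
            "sample": sample,
            "n_mutations": spectrum.total,
            "cosine": float("nan"),
            "flagged": False,
        }
        try:
            profile = fit_exposures(spectrum, sigs)
            row["cosine"] = cosine_similarity(profile, refs[sample])
        except (ZeroSpectrumError, DegenerateFitError):
            row["flagged"] = True
        rows.append(row)
    return pd.DataFrame(rows)
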