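"""Mutational-signature refitting and profile comparison.

A signature matrix S holds k signatures as rows over the 96 canonical
channels, each row a probability distribution.  Exposures are obtained by
non-negative least squares: minimise ||S^T x - p||_2 subject to x >= 0,
where p is the observed spectrum normalised to sum one, and the fitted
coefficients are rescaled to sum one.  Fitting on frequencies rather than
raw counts changes only the overall scale of x, which the final
normalisation removes, so the two conventions give identical profiles.

Profiles are compared by cosine similarity,

    cossim(P, Q) = sum_i P_i Q_i / (||P||_2 ||Q||_2),

which is 1 for identical and 0 for disjoint-support (independent) profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .spectrum import CHANNELS, MutationalSpectrum, channel_index

__all__ = [
    "SignatureMatrix",
    "ExposureProfile",
    "ZeroSpectrumError",
    "DegenerateFitError",
    "fit_exposures",
    "cosine_similarity",
    "load_signatures",
]


class ZeroSpectrumError(ValueError):
    """Refitting requested on an all-zero spectrum."""


class DegenerateFitError(ValueError):
    """NNLS returned the all-zero solution; the exposure profile is undefined."""


@dataclass
class SignatureMatrix:
    """k signatures as rows over the 96 canonical channels (rows sum to 1)."""

    names: list[str]
    matrix: np.ndarray  # shape (k, 96)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 96:
            raise ValueError(f"signature matrix must be k x 96, got {self.matrix.shape}")
        if len(self.names) != self.matrix.shape[0]:
            raise ValueError("number of names does not match number of rows")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate signature names")
        if (self.matrix < 0).any():
            raise ValueError("signature matrix has negative entries")
        sums = self.matrix.sum(axis=1)
        if (sums <= 0).any():
            bad = [n for n, s in zip(self.names, sums) if s <= 0]
            raise ValueError(f"signature rows sum to zero: {bad}")
        self.matrix = self.matrix / sums[:, None]

    @property
    def k(self) -> int:
        return self.matrix.shape[0]

    def row(self, name: str) -> np.ndarray:
        return self.matrix[self.names.index(name)]

    def to_tsv(self, sink: str | Path | IO[str]) -> None:
        frame = pd.DataFrame(self.matrix.T, index=list(CHANNELS), columns=self.names)
        frame.to_csv(sink, sep="\t", index_label="Channel")


@dataclass
class ExposureProfile:
    """Fitted, sum-to-one signature contributions for one sample."""

    names: list[str]
    weights: np.ndarray
    residual_norm: float
    n_mutations: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any():
            raise ValueError("exposure weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("exposure weights must sum to one")

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.names, name="weight")

    def to_tsv(self, sink: str | Path | IO[str]) -> None:
        own = isinstance(sink, (str, Path))
        handle = open(sink, "w") if own else sink
        try:
            handle.write("signature\tweight\n")
            for name, weight in zip(self.names, self.weights):
                handle.write(f"{name}\t{weight:.10g}\n")
        finally:
            if own:
                handle.close()

    @classmethod
    def from_tsv(cls, source: str | Path | IO[str]) -> "ExposureProfile":
        frame = pd.read_csv(source, sep="\t")
        weights = frame["weight"].to_numpy(dtype=float)
        return cls(
            names=list(frame["signature"]),
            weights=weights / weights.sum(),
            residual_norm=float("nan"),
            n_mutations=float("nan"),
        )


def fit_exposures(
    spectrum: MutationalSpectrum | np.ndarray, sigs: SignatureMatrix
) -> ExposureProfile:
    """Refit signature exposures to a spectrum by non-negative least squares.

    The spectrum is normalised to frequencies, ``min ||S^T x - p||`` is
    solved with x >= 0, and the solution is rescaled to sum one.  An
    all-zero spectrum or an all-zero NNLS solution is an error: downstream
    cosine comparison is undefined on zero vectors.
    """
    counts = spectrum.counts if isinstance(spectrum, MutationalSpectrum) else np.asarray(
        spectrum, dtype=float
    )
    total = counts.sum()
    if total <= 0:
        raise ZeroSpectrumError("cannot fit exposures to an all-zero spectrum")
    p = counts / total
    x, residual = scipy.optimize.nnls(sigs.matrix.T, p)
    if x.sum() == 0:
        raise DegenerateFitError("NNLS fit is identically zero; profile undefined")
    return ExposureProfile(
        names=list(sigs.names),
        weights=x / x.sum(),
        residual_norm=float(residual),
        n_mutations=float(total),
    )


def cosine_similarity(
    p: ExposureProfile | Sequence[float] | np.ndarray,
    q: ExposureProfile | Sequence[float] | np.ndarray,
) -> float:
    """Cosine similarity sum(P_i Q_i) / (||P|| ||Q||) of two profiles."""
    pv = np.asarray(p.weights if isinstance(p, ExposureProfile) else p, dtype=float)
    qv = np.asarray(q.weights if isinstance(q, ExposureProfile) else q, dtype=float)
    if pv.shape != qv.shape:
        raise ValueError(f"profile lengths differ: {pv.shape} vs {qv.shape}")
    np_, nq = np.linalg.norm(pv), np.linalg.norm(qv)
    if np_ == 0 or nq == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(pv @ qv / (np_ * nq))


def _labels_from_cosmic(frame: pd.DataFrame) -> pd.DataFrame:
    """Normalise a signature table to index = canonical channel labels."""
    cols = {c.lower(): c for c in frame.columns}
    if "type" in cols and "subtype" in cols:
        sub = frame[cols["type"]].astype(str)
        ctx = frame[cols["subtype"]].astype(str)
        labels = [f"{c[0]}[{s}]{c[2]}" for s, c in zip(sub, ctx)]
        frame = frame.drop(columns=[cols["type"], cols["subtype"]])
        frame.index = labels
        return frame
    first = frame.columns[0]
    if frame[first].astype(str).str.contains(r"\[").all():
        frame = frame.set_index(first)
        return frame
    raise ValueError(
        "cannot locate channel labels: need Type/Subtype columns or a "
        "label column like A[C>T]G"
    )


def load_signatures(source: str | Path | IO[str]) -> SignatureMatrix:
    """Load a signature matrix from a COSMIC-style TSV.

    Accepts both the split Type/Subtype layout and a combined label column
    (``A[C>T]G``); channels are harmonised to the canonical order by label,
    so row order in the file is irrelevant.  Rows are renormalised to sum 1.
    """
    frame = pd.read_csv(source, sep="\t")
    frame = _labels_from_cosmic(frame)
    missing = set(CHANNELS) - set(frame.index)
    extra = set(frame.index) - set(CHANNELS)
    if missing or extra:
        raise ValueError(
            f"channel labels do not match the 96 canonical channels "
            f"(missing {len(missing)}, unknown {len(extra)})"
        )
    frame = frame.loc[list(CHANNELS)]
    matrix = frame.to_numpy(dtype=float).T
    return SignatureMatrix(names=[str(c) for c in frame.columns], matrix=matrix)
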