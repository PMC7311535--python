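"""Restriction enzyme definitions and the built-in enzyme catalog.

An enzyme is a named IUPAC recognition sequence plus the position of the
top-strand cut within that site (``cut_offset``).  The catalog shipped with
the package holds type II enzymes suitable for reduced-representation
library design: recognition sites of at most six base pairs, insensitive to
CpG methylation, with unambiguous A/C/G/T sites -- plus ApoI (R^AATTY),
whose degenerate site motivates full IUPAC support in the matcher.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

__all__ = [
    "Enzyme",
    "EnzymeConfigError",
    "IUPAC_CODES",
    "iupac_pattern",
    "iupac_match",
    "reverse_complement",
    "load_catalog",
    "get_enzyme",
]

# IUPAC nucleotide ambiguity codes -> the set of concrete bases they stand for.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class EnzymeConfigError(ValueError):
    """Raised for an invalid enzyme definition (bad IUPAC code, bad offset)."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly IUPAC-ambiguous) sequence."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def iupac_pattern(recognition: str) -> re.Pattern[str]:
    """Compile a recognition sequence to a regex of concrete-base classes.

    N in the *target* sequence never matches: the classes enumerate A/C/G/T
    only, so recognition matches spanning assembly gaps are rejected.
    """
    parts = []
    for code in recognition.upper():
        bases = IUPAC_CODES.get(code)
        if bases is None:
            raise EnzymeConfigError(f"invalid IUPAC code {code!r} in recognition {recognition!r}")
        parts.append("[" + "".join(sorted(bases)) + "]")
    return re.compile("".join(parts))


def iupac_match(recognition: str, seq: str) -> bool:
    """True if ``seq`` (concrete bases) matches ``recognition`` position-wise."""
    if len(seq) != len(recognition):
        return False
    for code, base in zip(recognition.upper(), seq.upper()):
        bases = IUPAC_CODES.get(code)
        if bases is None:
            raise EnzymeConfigError(f"invalid IUPAC code {code!r} in recognition {recognition!r}")
        if base not in bases:
            return False
    return True


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: recognition site and top-strand cut position.

    ``cut_offset`` is the 0-based position of the cut point within the
    recognition site on the top strand, e.g. PstI CTGCA^G has offset 5 and
    ApoI R^AATTY has offset 1.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition:
            raise EnzymeConfigError("recognition sequence must be non-empty")
        iupac_pattern(self.recognition)  # validates codes
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise EnzymeConfigError(
                f"cut_offset {self.cut_offset} outside recognition of length "
                f"{len(self.recognition)} for {self.name}"
            )

    @property
    def site_length(self) -> int:
        return len(self.recognition)

    def is_palindromic(self) -> bool:
        """True if the recognition equals its own IUPAC reverse complement."""
        return reverse_complement(self.recognition) == self.recognition.upper()


def load_catalog() -> dict[str, Enzyme]:
    """Load the packaged enzyme catalog (name -> Enzyme)."""
    catalog: dict[str, Enzyme] = {}
    text = resources.files("mutread").joinpath("data/enzymes.tsv").read_text()
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        name, recognition, cut_offset = line.split("\t")
        enz = Enzyme(name, recognition, int(cut_offset))
        if enz.site_length > 6:
            raise EnzymeConfigError(
                f"catalog enzyme {name} has recognition longer than 6 bp"
            )
        catalog[name] = enz
    return catalog


_CATALOG: dict[str, Enzyme] | None = None


def get_enzyme(name: str) -> Enzyme:
    """Look up a catalog enzyme by name (case-sensitive)."""
    global _CATALOG
    if _CATALOG is None:
        _CATALOG = load_catalog()
    try:
        return _CATALOG[name]
    except KeyError:
        raise KeyError(
            f"unknown enzyme {name!r}; catalog has {sorted(_CATALOG)}"
        ) from None
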