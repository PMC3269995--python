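"""Restriction enzymes: IUPAC site matching, cut coordinates, digestion.

Cut coordinates are 0-based indices of the first base *after* the
top-strand cut, so a sequence with one internal cut at coordinate ``c``
splits into ``seq[:c]`` and ``seq[c:]``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterator

IUPAC_TO_REGEX = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]",
    "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]",
    "N": "[ACGT]",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction endonuclease with a fixed top-strand cut offset.

    ``cut_offset_top`` counts nucleotides from the start of the
    recognition pattern to the top-strand cut; for type IIS enzymes it
    exceeds the pattern length (the enzyme cuts downstream of its site).
    """

    name: str
    recognition: str
    cut_offset_top: int

    def __post_init__(self) -> None:
        if not self.recognition or any(
            b not in IUPAC_TO_REGEX for b in self.recognition
        ):
            raise ValueError(f"invalid IUPAC recognition pattern: {self.recognition!r}")
        if self.cut_offset_top < 0:
            raise ValueError("cut offset must be >= 0")

    @property
    def palindromic(self) -> bool:
        return self.recognition == reverse_complement(self.recognition)

    @property
    def pattern_regex(self) -> str:
        return "".join(IUPAC_TO_REGEX[b] for b in self.recognition)


@dataclass(frozen=True)
class RecognitionSite:
    """One match of an enzyme site on a duplex sequence.

    ``start`` is the 0-based plus-strand coordinate of the leftmost base
    of the recognition pattern; ``cut`` is the realized top-strand cut
    coordinate (may fall outside the pattern for type IIS enzymes).
    """

    enzyme: str
    start: int
    strand: str  # '+' or '-'
    cut: int


def _load_registry() -> dict[str, RestrictionEnzyme]:
    registry: dict[str, RestrictionEnzyme] = {}
    text = resources.files("radsnp").joinpath("data/enzymes.tsv").read_text()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, recognition, offset = line.split("\t")
        registry[name] = RestrictionEnzyme(name, recognition, int(offset))
    return registry


_REGISTRY: dict[str, RestrictionEnzyme] | None = None


def enzyme_registry() -> dict[str, RestrictionEnzyme]:
    """Packaged enzyme table (name -> RestrictionEnzyme), loaded once."""
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = _load_registry()
    return dict(_REGISTRY)


def get_enzyme(name: str | RestrictionEnzyme) -> RestrictionEnzyme:
    if isinstance(name, RestrictionEnzyme):
        return name
    try:
        return enzyme_registry()[name]
    except KeyError:
        raise KeyError(f"unknown enzyme: {name!r}") from None


def find_recognition_sites(
    sequence: str, enzyme: str | RestrictionEnzyme
) -> list[RecognitionSite]:
    """IUPAC-degenerate site search on both strands, sorted by cut coordinate.

    Minus-strand matches of non-palindromic patterns are reported with the
    top-strand coordinate of the duplex cut implied by the enzyme's offset
    read along the bottom strand. Palindromic enzymes are searched on the
    plus strand only (both strands give the same site).
    """
    enz = get_enzyme(enzyme)
    sequence = sequence.upper()
    m = len(enz.recognition)
    sites: list[RecognitionSite] = []
    for match in re.finditer(f"(?=({enz.pattern_regex}))", sequence):
        p = match.start()
        sites.append(RecognitionSite(enz.name, p, "+", p + enz.cut_offset_top))
    if not enz.palindromic:
        rc_regex = "".join(
            IUPAC_TO_REGEX[b] for b in reverse_complement(enz.recognition)
        )
        for match in re.finditer(f"(?=({rc_regex}))", sequence):
            p = match.start()
            sites.append(RecognitionSite(enz.name, p, "-", p + m - enz.cut_offset_top))
    sites.sort(key=lambda s: (s.cut, s.start, s.strand))
    return sites


@dataclass(frozen=True)
class Fragment:
    start: int
    end: int  # half-open
    sequence: str

    def __len__(self) -> int:
        return self.end - self.start


def digest(sequence: str, enzyme: str | RestrictionEnzyme = "PstI") -> list[Fragment]:
    """Cut ``sequence`` at every internal recognition site.

    Returns fragments in genomic order; their lengths always sum to the
    input length, and a sequence with s internal cut coordinates yields
    s + 1 fragments.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    cuts = sorted(
        {s.cut for s in find_recognition_sites(sequence, enzyme) if 0 < s.cut < len(sequence)}
    )
    bounds = [0, *cuts, len(sequence)]
    return [
        Fragment(a, b, sequence[a:b]) for a, b in zip(bounds, bounds[1:])
    ]


def internal_cut_sites(sequence: str, enzyme: str | RestrictionEnzyme = "PstI") -> list[int]:
    """Strictly increasing cut coordinates that fall inside the sequence."""
    return sorted(
        {s.cut for s in find_recognition_sites(sequence, enzyme) if 0 < s.cut < len(sequence)}
    )


def iter_fragments_lengths(fragments: list[Fragment]) -> Iterator[int]:
    for f in fragments:
        yield len(f)
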