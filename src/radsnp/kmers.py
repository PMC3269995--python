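"""K-mer occurrence spectra partitioned by dinucleotide (CpG) content, and
the Karlin-Mrazek dinucleotide rate statistic."""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

DINUCLEOTIDES = [a + b for a in "ACGT" for b in "ACGT"]


@dataclass
class KmerSpectrum:
    k: int
    counts: Counter  # k-mer -> occurrence count
    source: str = ""

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def histogram(self) -> Counter:
        """occurrence count -> number of distinct k-mers seen that often."""
        return Counter(self.counts.values())


@dataclass
class SpectrumClassSplit:
    dinucleotide: str
    # class key ('0', '1', '2+') -> (occurrence count -> n distinct k-mers)
    histograms: dict[str, Counter]

    def classes(self) -> tuple[str, ...]:
        return ("0", "1", "2+")


@dataclass
class CpGStats:
    f_dinuc: float
    p_first: float
    p_second: float
    rho: float
    dinucleotide: str = "CG"


def _canonical(kmer: str) -> str:
    rc = kmer.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    return min(kmer, rc)


def count_kmers(
    sequences: Iterable[str], k: int = 10, canonical: bool = False,
    source: str = "",
) -> KmerSpectrum:
    """Forward-strand k-mer counting; windows containing N (or any other
    non-ACGT character) are skipped.

    Total counts always equal the number of clean windows:
    sum over sequences of max(L - k + 1, 0) minus N-containing windows.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter = Counter()
    longest = 0
    valid = frozenset("ACGT")
    for seq in sequences:
        seq = seq.upper()
        longest = max(longest, len(seq))
        if set(seq) <= valid:
            counts.update(seq[i:i + k] for i in range(len(seq) - k + 1))
        else:
            for i in range(len(seq) - k + 1):
                window = seq[i:i + k]
                if set(window) <= valid:
                    counts[window] += 1
    if longest and k > longest:
        warnings.warn(f"k={k} exceeds the longest sequence ({longest} nt); "
                      "spectrum is empty", stacklevel=2)
    if canonical:
        folded: Counter = Counter()
        for kmer, n in counts.items():
            folded[_canonical(kmer)] += n
        counts = folded
    return KmerSpectrum(k=k, counts=counts, source=source)


def count_overlapping(seq: str, pattern: str) -> int:
    """Occurrences of ``pattern`` counted with overlap (CGCG has 2 CG)."""
    n = 0
    start = 0
    while True:
        idx = seq.find(pattern, start)
        if idx < 0:
            return n
        n += 1
        start = idx + 1


def split_by_dinucleotide(
    spectrum: KmerSpectrum, dinucleotide: str = "CG"
) -> SpectrumClassSplit:
    """Partition the spectrum's distinct k-mers by how many times they
    contain the focal dinucleotide (0, 1, 2-or-more), returning one
    occurrence histogram per class. The class histograms sum cell-wise to
    the unsplit histogram."""
    dinucleotide = dinucleotide.upper()
    if len(dinucleotide) != 2 or set(dinucleotide) - set("ACGT"):
        raise ValueError(f"invalid dinucleotide: {dinucleotide!r}")
    hists: dict[str, Counter] = {"0": Counter(), "1": Counter(), "2+": Counter()}
    for kmer, occ in spectrum.counts.items():
        n = count_overlapping(kmer, dinucleotide)
        key = "0" if n == 0 else ("1" if n == 1 else "2+")
        hists[key][occ] += 1
    return SpectrumClassSplit(dinucleotide=dinucleotide, histograms=hists)


def random_dinucleotide_control(
    spectrum: KmerSpectrum,
    n_controls: int,
    seed: int | np.random.Generator = 0,
    exclude: str = "CG",
) -> list[SpectrumClassSplit]:
    """Class splits for dinucleotides sampled uniformly from the 15
    non-focal possibilities; deterministic for a fixed seed."""
    if n_controls < 1:
        raise ValueError("n_controls must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = [d for d in DINUCLEOTIDES if d != exclude.upper()]
    chosen = rng.choice(pool, size=n_controls, replace=n_controls > len(pool))
    return [split_by_dinucleotide(spectrum, d) for d in chosen]


def cpg_rate(sequences: Iterable[str], dinucleotide: str = "CG") -> CpGStats:
    """Karlin-Mrazek dinucleotide rate rho = f(XY) / (p(X) p(Y)).

    f(XY) is the overlap-counted dinucleotide frequency per dinucleotide
    window (denominator sum of L-1 over sequences); p(X), p(Y) are
    mononucleotide frequencies over all bases.
    """
    dinucleotide = dinucleotide.upper()
    if len(dinucleotide) != 2 or set(dinucleotide) - set("ACGT"):
        raise ValueError(f"invalid dinucleotide: {dinucleotide!r}")
    base_counts: Counter = Counter()
    dinuc_count = 0
    windows = 0
    n_seqs = 0
    for seq in sequences:
        seq = seq.upper()
        n_seqs += 1
        base_counts.update(seq)
        dinuc_count += count_overlapping(seq, dinucleotide)
        windows += max(len(seq) - 1, 0)
    if n_seqs == 0 or windows == 0:
        raise ValueError("no sequence content")
    total_bases = sum(base_counts[b] for b in "ACGT")
    p1 = base_counts[dinucleotide[0]] / total_bases
    p2 = base_counts[dinucleotide[1]] / total_bases
    if p1 * p2 == 0:
        raise ZeroDivisionError(
            f"rate undefined: p({dinucleotide[0]}) * p({dinucleotide[1]}) = 0")
    f = dinuc_count / windows
    return CpGStats(f_dinuc=f, p_first=p1, p_second=p2, rho=f / (p1 * p2),
                    dinucleotide=dinucleotide)


def split_to_frame(split: SpectrumClassSplit) -> "pd.DataFrame":
    import pandas as pd

    rows = [
        {"class": cls, "occurrence_count": occ, "n_kmers": n}
        for cls, hist in split.histograms.items()
        for occ, n in sorted(hist.items())
    ]
    return pd.DataFrame(rows, columns=["class", "occurrence_count", "n_kmers"])
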