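"""Segregation chi-square tests, two-point linkage, Kosambi distances and
LOD-threshold linkage grouping."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass
class SegregationResult:
    marker_id: str
    observed: tuple[int, ...]
    ratio: tuple[float, ...]
    chi2: float
    df: int
    p_value: float
    included: bool   # fit for mapping: chi2 <= critical(df, alpha=0.01)
    distorted: bool  # chi2 > critical(df, alpha=0.1)


@dataclass
class TwoPointResult:
    marker_a: str
    marker_b: str
    n_informative: int
    n_recombinant: int
    r_hat: float
    lod: float
    cm: float


@dataclass
class LinkageGrouping:
    groups: list[list[str]]
    threshold: float
    singletons: list[str]


def chi_square_gof(
    observed: Sequence[int],
    ratio: Sequence[float],
    marker_id: str = "",
    alpha_include: float = 0.01,
    alpha_distort: float = 0.1,
) -> SegregationResult:
    """Goodness of fit of observed class counts to an expected ratio
    (1:1 for testcross, 1:2:1 for intercross markers).

    ``included`` follows the mapping criterion (chi2 within the alpha=0.01
    critical value); ``distorted`` flags chi2 beyond the alpha=0.1 value.
    """
    observed = tuple(int(o) for o in observed)
    if len(observed) != len(ratio):
        raise ValueError("observed and ratio must have the same class count")
    if any(o < 0 for o in observed):
        raise ValueError("counts must be non-negative")
    n = sum(observed)
    if n == 0:
        raise ValueError("no observations")
    if any(r <= 0 for r in ratio):
        raise ValueError("expected class proportions must be positive")
    total_ratio = sum(ratio)
    expected = [n * r / total_ratio for r in ratio]
    chi2 = float(sum((o - e) ** 2 / e for o, e in zip(observed, expected)))
    df = len(observed) - 1
    p_value = float(stats.chi2.sf(chi2, df))
    crit_include = float(stats.chi2.ppf(1 - alpha_include, df))
    crit_distort = float(stats.chi2.ppf(1 - alpha_distort, df))
    return SegregationResult(
        marker_id=marker_id, observed=observed, ratio=tuple(ratio),
        chi2=chi2, df=df, p_value=p_value,
        included=chi2 <= crit_include, distorted=chi2 > crit_distort,
    )


def kosambi_cm(r: float) -> float:
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) cM."""
    if not 0.0 <= r < 0.5:
        raise ValueError("recombination fraction must be in [0, 0.5)")
    return 25.0 * math.log((1 + 2 * r) / (1 - 2 * r))


def kosambi_inverse(d_cm: float) -> float:
    """Recombination fraction for a Kosambi distance: r = tanh(2d/100)/2."""
    if d_cm < 0:
        raise ValueError("map distance must be >= 0")
    return 0.5 * math.tanh(2.0 * d_cm / 100.0)


def two_point_testcross(
    g1: Sequence[str],
    g2: Sequence[str],
    marker_a: str = "m1",
    marker_b: str = "m2",
    missing: str = "-",
) -> TwoPointResult:
    """Two-point analysis of two testcross-coded marker vectors.

    Genotypes are two-class codes (e.g. 'a'/'h'); progeny missing either
    marker are excluded pairwise. Phase is chosen to minimize the
    recombinant count. The LOD is evaluated at r̂ clamped to
    [1/(2n), 0.5] so fully cosegregating pairs score finitely.
    """
    if len(g1) != len(g2):
        raise ValueError("genotype vectors must have equal length")
    keep = [i for i in range(len(g1)) if g1[i] != missing and g2[i] != missing]
    n = len(keep)
    if n < 2:
        raise ValueError("fewer than 2 shared informative progeny")
    mismatches = sum(1 for i in keep if g1[i] != g2[i])
    rec = min(mismatches, n - mismatches)  # phase minimizing r
    r_hat = rec / n
    r = min(max(r_hat, 1.0 / (2 * n)), 0.5)
    lod = (n - rec) * math.log10(2 * (1 - r)) + rec * math.log10(2 * r)
    lod = max(lod, 0.0)
    cm = kosambi_cm(r_hat) if r_hat < 0.5 else math.inf
    return TwoPointResult(marker_a, marker_b, n, rec, r_hat, lod, cm)


def group_markers(
    results: Sequence[TwoPointResult],
    threshold: float = 6.0,
    max_rec: float = 0.40,
    markers: Sequence[str] | None = None,
) -> LinkageGrouping:
    """Single-linkage grouping: markers joined through chains of pairs with
    LOD >= threshold and r̂ <= max_rec; groups labelled deterministically by
    their smallest member id."""
    names = set(markers or [])
    for res in results:
        names.add(res.marker_a)
        names.add(res.marker_b)
    parent: dict[str, str] = {m: m for m in names}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for res in results:
        if res.lod >= threshold and res.r_hat <= max_rec:
            ra, rb = find(res.marker_a), find(res.marker_b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    clusters: dict[str, list[str]] = {}
    for m in names:
        clusters.setdefault(find(m), []).append(m)
    groups = sorted(
        (sorted(members) for members in clusters.values()),
        key=lambda g: g[0],
    )
    singletons = [g[0] for g in groups if len(g) == 1]
    groups = [g for g in groups if len(g) > 1]
    return LinkageGrouping(groups=groups, threshold=threshold, singletons=singletons)


def pairwise_two_point(
    genotypes: Mapping[str, Sequence[str]], missing: str = "-"
) -> list[TwoPointResult]:
    """All-pairs two-point results for a marker -> genotype-vector mapping."""
    names = list(genotypes)
    out = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            out.append(two_point_testcross(
                genotypes[a], genotypes[b], a, b, missing=missing))
    return out


def segregation_report(
    genotypes: Mapping[str, Sequence[str]], missing: str = "-"
) -> list[SegregationResult]:
    """Auto-ratio segregation tests: two observed classes -> 1:1,
    three -> 1:2:1 (classes ordered a, h, b)."""
    out = []
    for marker, vec in genotypes.items():
        counts: dict[str, int] = {}
        for g in vec:
            if g != missing:
                counts[g] = counts.get(g, 0) + 1
        classes = sorted(counts)
        if len(classes) == 2:
            observed = [counts[c] for c in classes]
            ratio = (1.0, 1.0)
        elif len(classes) == 3:
            order = [c for c in ("a", "h", "b") if c in counts] or classes
            observed = [counts[c] for c in order]
            ratio = (1.0, 2.0, 1.0)
        else:
            continue
        out.append(chi_square_gof(observed, ratio, marker_id=marker))
    return out
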