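"""CAPS assay design: allele-differential restriction sites, fragment-size
prediction, gel-detectability filtering and digestion-pattern scoring."""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

from .enzymes import (
    RestrictionEnzyme,
    digest,
    find_recognition_sites,
    get_enzyme,
    internal_cut_sites,
)

PAPER_ENZYME_PANEL = (
    "BamHI", "EcoRI", "EcoRV", "NdeI", "XbaI",
    "BccI", "FokI", "XmnI", "DraI", "TaqI", "MseI",
)


@dataclass(frozen=True)
class SimpleVariant:
    """A biallelic substitution or short indel on a contig; ``ref`` and
    ``alt`` are plain allele strings anchored at ``position``."""

    contig_id: str
    position: int
    ref: str
    alt: str

    @property
    def snp_id(self) -> str:
        return f"{self.contig_id}-{self.position}"

    @property
    def length_shift(self) -> int:
        return len(self.alt) - len(self.ref)


@dataclass(frozen=True)
class DifferentialSite:
    enzyme: str
    cut_position: int  # within the allele sequence that carries the site
    cutting_allele: str  # 'ref' or 'alt'
    strand: str


@dataclass
class CapsAssay:
    snp_id: str
    enzyme: str
    amplicon: tuple[int, int]  # [start, end) on the contig (ref coordinates)
    product_size: int  # uncut-allele product
    cut_positions: dict[str, list[int]]  # per allele, relative to amplicon
    fragments: dict[str, list[int]]  # 'hom_uncut' | 'hom_cut' | 'het'
    fragment_size_difference: int
    uncut_allele: str  # 'ref' or 'alt'


def apply_variant(sequence: str, variant: SimpleVariant) -> str:
    if sequence[variant.position:variant.position + len(variant.ref)] != variant.ref:
        raise ValueError(
            f"variant {variant.snp_id} inconsistent with contig sequence")
    return (sequence[:variant.position] + variant.alt
            + sequence[variant.position + len(variant.ref):])


def differential_digestion(
    sequence: str,
    variant: SimpleVariant,
    enzymes: Sequence[str | RestrictionEnzyme] = PAPER_ENZYME_PANEL,
) -> list[DifferentialSite]:
    """Recognition sites present under exactly one allele.

    Cut coordinates on the alt sequence downstream of an indel are mapped
    back to ref coordinates before comparison, so shared sites never appear
    differential merely because of the length shift.
    """
    ref_seq = sequence
    alt_seq = apply_variant(sequence, variant)
    shift = variant.length_shift
    out: list[DifferentialSite] = []
    for enzyme in enzymes:
        enz = get_enzyme(enzyme)
        ref_sites = {
            (s.cut, s.strand): s
            for s in find_recognition_sites(ref_seq, enz)
            if 0 < s.cut < len(ref_seq)
        }
        alt_sites = {}
        for s in find_recognition_sites(alt_seq, enz):
            if not 0 < s.cut < len(alt_seq):
                continue
            mapped = s.cut - shift if s.cut > variant.position else s.cut
            alt_sites[(mapped, s.strand)] = s
        for key, s in ref_sites.items():
            if key not in alt_sites:
                out.append(DifferentialSite(enz.name, s.cut, "ref", s.strand))
        for key, s in alt_sites.items():
            if key not in ref_sites:
                out.append(DifferentialSite(enz.name, s.cut, "alt", s.strand))
    out.sort(key=lambda d: (d.enzyme, d.cut_position, d.cutting_allele))
    return out


def predict_fragments(product_size: int, cut_positions: Sequence[int]) -> list[int]:
    """Fragment lengths from ordered internal cut positions; lengths always
    sum to the product size."""
    cuts = list(cut_positions)
    if any(not 0 < c < product_size for c in cuts):
        raise ValueError("cut positions must lie strictly inside the product")
    if sorted(cuts) != cuts or len(set(cuts)) != len(cuts):
        raise ValueError("cut positions must be strictly increasing")
    bounds = [0, *cuts, product_size]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def _min_pairwise_difference(lengths: Sequence[int]) -> int:
    distinct = sorted(set(lengths))
    if len(distinct) < 2:
        return 0
    return min(b - a for a, b in zip(distinct, distinct[1:]))


def design_caps_assays(
    sequence: str,
    variant: SimpleVariant,
    enzymes: Sequence[str | RestrictionEnzyme] = PAPER_ENZYME_PANEL,
    product_range: tuple[int, int] = (100, 400),
    primer_window: int = 50,
    min_fragment_difference: int = 20,
    enforce_product_bounds: bool = True,
) -> list[CapsAssay]:
    """Accepted CAPS assays for one variant.

    The amplicon spans the whole contig by default; when the contig exceeds
    the maximum product size its ends are trimmed (within the primer
    landing windows) while keeping the variant inside. An assay is accepted
    only if every pair of distinct fragment lengths across the two
    homozygote patterns differs by at least ``min_fragment_difference`` bp
    (the agarose-gel detectability rule).
    """
    min_prod, max_prod = product_range
    L = len(sequence)
    if L < min_prod:
        raise ValueError(
            f"contig ({L} bp) shorter than the minimum product size {min_prod}")
    start, end = 0, L
    if enforce_product_bounds and L > max_prod:
        excess = L - max_prod
        trim_start = min(excess, primer_window - 1)
        trim_end = min(excess - trim_start, primer_window - 1)
        start, end = trim_start, L - trim_end
        if end - start > max_prod or not start <= variant.position < end:
            return []
    amplicon_seq = sequence[start:end]
    amp_variant = SimpleVariant(
        variant.contig_id, variant.position - start, variant.ref, variant.alt)
    if not 0 <= amp_variant.position < len(amplicon_seq):
        return []
    ref_amp = amplicon_seq
    alt_amp = apply_variant(amplicon_seq, amp_variant)
    assays: list[CapsAssay] = []
    diff_by_enzyme: dict[str, list[DifferentialSite]] = {}
    for d in differential_digestion(amplicon_seq, amp_variant, enzymes):
        diff_by_enzyme.setdefault(d.enzyme, []).append(d)
    for enzyme_name in diff_by_enzyme:
        ref_cuts = internal_cut_sites(ref_amp, enzyme_name)
        alt_cuts = internal_cut_sites(alt_amp, enzyme_name)
        frags_ref = predict_fragments(len(ref_amp), ref_cuts)
        frags_alt = predict_fragments(len(alt_amp), alt_cuts)
        if len(ref_cuts) < len(alt_cuts):
            uncut_allele, frag_uncut, frag_cut = "ref", frags_ref, frags_alt
        elif len(alt_cuts) < len(ref_cuts):
            uncut_allele, frag_uncut, frag_cut = "alt", frags_alt, frags_ref
        else:
            continue  # equal cut counts: no clean presence/absence pattern
        union = sorted(set(frag_uncut) | set(frag_cut), reverse=True)
        min_diff = _min_pairwise_difference(union)
        if min_diff < min_fragment_difference:
            continue
        assays.append(CapsAssay(
            snp_id=variant.snp_id,
            enzyme=enzyme_name,
            amplicon=(start, end),
            product_size=max(frag_uncut),
            cut_positions={"ref": ref_cuts, "alt": alt_cuts},
            fragments={
                "hom_uncut": sorted(frag_uncut, reverse=True),
                "hom_cut": sorted(frag_cut, reverse=True),
                "het": union,
            },
            fragment_size_difference=min_diff,
            uncut_allele=uncut_allele,
        ))
    return assays


def score_caps_pattern(
    observed: Sequence[int],
    assay: CapsAssay,
    tolerance: float = 0.05,
) -> str | None:
    """Match an observed gel fragment pattern to the assay's predicted
    hom-uncut / hom-cut / het patterns within a relative size tolerance.
    Returns the pattern name or None when nothing matches (unscored)."""
    observed = sorted(set(int(x) for x in observed), reverse=True)
    if not observed:
        raise ValueError("empty observation")

    def matches(predicted: Sequence[int]) -> bool:
        predicted = sorted(set(predicted), reverse=True)
        if len(predicted) != len(observed):
            return False
        return all(
            abs(o - p) <= tolerance * p for o, p in zip(observed, predicted)
        )

    for name in ("hom_uncut", "hom_cut", "het"):
        if matches(assay.fragments[name]):
            return name
    return None


def digest_fragment_lengths(sequence: str, enzyme: str | RestrictionEnzyme) -> list[int]:
    """Lengths of the restriction fragments of one amplicon allele."""
    return [len(f) for f in digest(sequence, enzyme)]


def score_diploid_digest(
    allele_seqs: tuple[str, str], assay: CapsAssay, enzyme: str,
    tolerance: float = 0.05,
) -> str | None:
    """Digest both allele sequences of a diploid amplicon and score the
    pooled fragment pattern."""
    observed = sorted({
        l for seq in allele_seqs for l in digest_fragment_lengths(seq, enzyme)
    })
    return score_caps_pattern(observed, assay, tolerance)


# ---------------------------------------------------------------------------
# Published validation panel (packaged fixture)
# ---------------------------------------------------------------------------

def load_validation_table() -> pd.DataFrame:
    """Machine-readable CAPS validation panel: 24 assays with enzyme,
    product size, realized cut position, per-parent restriction products,
    segregation outcome and linkage-group assignment."""
    with resources.files("radsnp").joinpath("data/table2.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    df["product_size"] = df["product_size"].astype(int)
    df["cut_site"] = df["cut_site"].astype(int)
    for col in ("parent_uncut_products", "parent_het_products"):
        df[col] = df[col].map(
            lambda s: [int(x) for x in s.split(",")])
    return df


def validation_panel_summary(df: pd.DataFrame | None = None) -> dict[str, int]:
    """Bookkeeping over the validation panel: clean testcross assays,
    loci on pre-existing linkage groups, distinct pre-existing groups."""
    if df is None:
        df = load_validation_table()
    testcross = df[df["segregation"] == "Test cross"]
    on_existing = df[df["linkage_group"].str.startswith("LG Alt_")]
    return {
        "n_assays": len(df),
        "n_testcross": len(testcross),
        "n_on_existing_groups": len(on_existing),
        "n_distinct_existing_groups": on_existing["linkage_group"].nunique(),
    }
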