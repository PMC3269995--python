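"""Truth-table comparison helpers for simulated pipelines: map assembled
contigs back to reference RAD loci and score genotype recovery."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .assembly import RadContig
from .enzymes import reverse_complement
from .simulate import ReferenceGenome, TruthTable, VariantRecord
from .variants import GenotypeCall, VariantSite

_COMP = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class LocusAnchor:
    chrom: str
    cut: int
    side: str  # 'left' or 'right'

    def ref_position(self, offset: int) -> int:
        """Reference coordinate of contig offset ``offset``."""
        return self.cut + offset if self.side == "right" else self.cut - 1 - offset


def reference_flanks(
    reference: ReferenceGenome, length: int
) -> dict[str, LocusAnchor]:
    """Flank prefix sequence -> locus anchor, for both sides of every
    planted cut site."""
    out: dict[str, LocusAnchor] = {}
    for chrom, cut in reference.cut_sites:
        seq = reference.chromosomes[chrom]
        right = seq[cut:cut + length]
        left = reverse_complement(seq[cut - length:cut])
        out.setdefault(right, LocusAnchor(chrom, cut, "right"))
        out.setdefault(left, LocusAnchor(chrom, cut, "left"))
    return out


def map_contigs_to_loci(
    contigs: Sequence[RadContig],
    reference: ReferenceGenome,
    anchor_length: int = 54,
    max_mismatches: int = 3,
) -> dict[str, LocusAnchor]:
    """Assign each contig to the reference locus whose flank its prefix
    matches (exact, then Hamming <= max_mismatches)."""
    flanks = reference_flanks(reference, anchor_length)
    keys = list(flanks)
    mat = np.zeros((len(keys), anchor_length), dtype=np.uint8)
    for i, s in enumerate(keys):
        mat[i] = np.frombuffer(s.encode(), dtype=np.uint8)
    out: dict[str, LocusAnchor] = {}
    for c in contigs:
        prefix = c.sequence[:anchor_length]
        if len(prefix) < anchor_length:
            continue
        hit = flanks.get(prefix)
        if hit is None:
            q = np.frombuffer(prefix.encode(), dtype=np.uint8)
            mism = np.count_nonzero(mat != q, axis=1)
            best = int(np.argmin(mism))
            if mism[best] <= max_mismatches:
                hit = flanks[keys[best]]
        if hit is not None:
            out[c.contig_id] = hit
    return out


def truth_variant_index(truth: TruthTable) -> dict[tuple[str, int], VariantRecord]:
    return {(v.chrom, v.pos): v for v in truth.variants}


def _truth_zygosity(v: VariantRecord, accession_index: int, strand: str) -> tuple[str, str | None]:
    """(zygosity, hom allele on the contig strand) for one accession."""
    h0, h1 = v.genotypes[accession_index]
    if h0 != h1:
        return "het", None
    allele = v.alt if h0 else v.ref
    if strand == "left":
        allele = allele.translate(_COMP)
    return "hom", allele


def genotype_recovery(
    sites: Sequence[VariantSite],
    genotypes: Mapping[str, Mapping[str, GenotypeCall]],
    contig_anchors: Mapping[str, LocusAnchor],
    truth: TruthTable,
    sample_ids: Sequence[str],
) -> tuple[float, int]:
    """Fraction of mappable called sites at which every sample's imputed
    zygosity (and homozygous allele) matches the simulator truth.

    SNP-only comparison: reference coordinates are read straight off the
    locus anchor, so it is exact when the simulation plants no indels.
    Returns (fraction matching, number of sites compared).
    """
    tindex = truth_variant_index(truth)
    matched = compared = 0
    for site in sites:
        anchor = contig_anchors.get(site.contig_id)
        if anchor is None:
            continue
        ref_pos = anchor.ref_position(site.position)
        tv = tindex.get((anchor.chrom, ref_pos))
        compared += 1
        ok = True
        for ai, sample in enumerate(sample_ids):
            call = genotypes[site.site_id][sample]
            if tv is None:
                # no planted variant here: truth is homozygous reference
                if call.zygosity != "hom":
                    ok = False
                continue
            zyg, allele = _truth_zygosity(tv, ai, anchor.side)
            if call.zygosity != zyg:
                ok = False
            elif zyg == "hom" and call.alleles and call.alleles[0] != allele:
                ok = False
        matched += ok
    return (matched / compared if compared else 0.0), compared


def locus_recovery(
    contigs: Sequence[RadContig],
    reference: ReferenceGenome,
    anchor_length: int = 54,
) -> tuple[float, int]:
    """Fraction of reference RAD loci recovered by a contig that matches
    the reference flank exactly over its whole length (divergence-0
    oracle). Returns (fraction, number of truth loci)."""
    anchors = map_contigs_to_loci(contigs, reference, anchor_length, max_mismatches=0)
    exact_loci = set()
    for c in contigs:
        anchor = anchors.get(c.contig_id)
        if anchor is None:
            continue
        seq = reference.chromosomes[anchor.chrom]
        if anchor.side == "right":
            flank = seq[anchor.cut:anchor.cut + c.length]
        else:
            flank = reverse_complement(seq[anchor.cut - c.length:anchor.cut])
        if c.sequence == flank:
            exact_loci.add((anchor.chrom, anchor.cut, anchor.side))
    n_truth = 2 * len(reference.cut_sites)
    return len(exact_loci) / n_truth if n_truth else 0.0, n_truth
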