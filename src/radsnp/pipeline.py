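"""End-to-end orchestration: reads -> clusters -> reference contigs ->
pileup -> variant sets -> marker classification."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import assembly, variants
from .assembly import AssemblyStats, RadContig, ReadPair, SECluster


def _codes_matrix(seqs: Sequence[str], length: int) -> np.ndarray:
    mat = np.zeros((len(seqs), length), dtype=np.uint8)
    for i, s in enumerate(seqs):
        mat[i] = np.frombuffer(s[:length].encode(), dtype=np.uint8)
    return mat


def select_template_sample(pairs: Sequence[ReadPair]) -> str:
    """Default reference template: the sample with the most retained reads."""
    counts: dict[str, int] = {}
    for p in pairs:
        counts[p.sample_id] = counts.get(p.sample_id, 0) + 1
    return max(sorted(counts), key=lambda s: counts[s])


def deduplicate_clusters(
    clusters: Sequence[SECluster],
    template_sample: str,
    max_mismatches: int = variants.MAX_MISMATCHES,
) -> list[SECluster]:
    """Collapse clusters whose SE representatives differ by no more than the
    alignment mismatch cap: they are the same locus seen through different
    haplotypes. The representative cluster is the one with the most
    template-sample reads (then highest coverage); dropped clusters' reads
    re-enter downstream through mismatch-tolerant alignment."""
    if not clusters:
        return []
    length = min(len(c.se_representative) for c in clusters)

    def weight(c: SECluster) -> tuple:
        n_template = sum(1 for m in c.members if m.sample_id == template_sample)
        return (-n_template, -c.coverage, c.se_representative)

    ordered = sorted(clusters, key=weight)
    kept: list[SECluster] = []
    kept_mat = np.zeros((0, length), dtype=np.uint8)
    for c in ordered:
        query = np.frombuffer(c.se_representative[:length].encode(), dtype=np.uint8)
        if len(kept) > 0:
            mism = np.count_nonzero(kept_mat != query, axis=1)
            if int(mism.min()) <= max_mismatches:
                continue
        kept.append(c)
        kept_mat = np.vstack([kept_mat, query[None, :]])
    kept.sort(key=lambda c: c.cluster_id)
    return kept


def anchor_unique_single_ends(
    se_seqs: Sequence[str],
    contigs: Sequence[RadContig],
    max_mismatches: int = variants.MAX_MISMATCHES,
) -> dict[str, str]:
    """Map each distinct SE sequence to the contig whose prefix it matches
    best (exact first, then <= max_mismatches), mirroring short-read
    alignment against the reference contig set."""
    if not contigs:
        return {}
    length = len(min(se_seqs, key=len)) if se_seqs else 0
    primary = [c for c in contigs if c.node == 1 and c.length >= length]
    by_prefix: dict[str, str] = {}
    for c in sorted(contigs, key=lambda c: (c.node, -c.length, c.contig_id)):
        if c.length >= length:
            by_prefix.setdefault(c.sequence[:length], c.contig_id)
    out: dict[str, str] = {}
    unresolved = []
    for se in se_seqs:
        hit = by_prefix.get(se[:length])
        if hit is not None:
            out[se] = hit
        else:
            unresolved.append(se)
    if unresolved and primary:
        prefix_mat = _codes_matrix([c.sequence for c in primary], length)
        for block_start in range(0, len(unresolved), 256):
            block = unresolved[block_start:block_start + 256]
            qmat = _codes_matrix(block, length)
            # (queries, contigs) mismatch counts
            mism = (qmat[:, None, :] != prefix_mat[None, :, :]).sum(axis=2)
            best = np.argmin(mism, axis=1)
            for qi, se in enumerate(block):
                if mism[qi, best[qi]] <= max_mismatches:
                    out[se] = primary[best[qi]].contig_id
    return out


@dataclass
class CallingResult:
    pileup: variants.Pileup
    ccrad1: list[variants.VariantSite]
    ccrad2: list[variants.VariantSite]
    genotypes: dict[str, dict[str, variants.GenotypeCall]]
    markers: list[variants.MarkerRecord]
    n_pairs_aligned: int = 0
    n_pairs_rejected: int = 0


def run_variant_calling(
    pairs: Sequence[ReadPair],
    contigs: Sequence[RadContig],
    sample_ids: Sequence[str],
    min_coverage_ccrad1: int = 6,
    per_sample_coverage: bool = False,
    **genotype_thresholds,
) -> CallingResult:
    """Align all pairs to their anchored contigs, build the pileup, call the
    comprehensive and fully-informative variant sets and classify markers."""
    by_id = {c.contig_id: c for c in contigs}
    anchors = anchor_unique_single_ends(
        sorted({p.se_seq for p in pairs}), contigs)
    codes_cache = {
        cid: variants._codes(c.sequence) for cid, c in by_id.items()
    }
    pileup = variants.Pileup(
        {c.contig_id: c.sequence for c in contigs}, sample_ids)
    n_aligned = n_rejected = 0
    for pair in pairs:
        contig_id = anchors.get(pair.se_seq)
        if contig_id is None:
            n_rejected += 1
            continue
        pa = variants.align_read_pair(
            pair, by_id[contig_id], contig_codes=codes_cache[contig_id])
        if pa is None:
            n_rejected += 1
            continue
        pileup.add_pair(pa)
        n_aligned += 1
    ccrad1 = variants.call_ccrad1(
        pileup, min_coverage=min_coverage_ccrad1, per_sample=per_sample_coverage)
    genotypes = variants.genotype_sites(ccrad1, pileup, **genotype_thresholds)
    ccrad2 = variants.select_ccrad2(ccrad1, pileup)
    markers = variants.classify_markers(ccrad2, genotypes, sample_ids)
    return CallingResult(
        pileup=pileup, ccrad1=ccrad1, ccrad2=ccrad2, genotypes=genotypes,
        markers=markers, n_pairs_aligned=n_aligned, n_pairs_rejected=n_rejected,
    )


@dataclass
class PipelineResult:
    contigs: list[RadContig]
    stats: AssemblyStats | None
    calling: CallingResult
    template_sample: str
    n_pairs_retained: int
    n_pairs_discarded: int


def run_read_pipeline(
    pairs_by_sample: Mapping[str, Sequence[ReadPair]],
    k_values: Sequence[int] = assembly.DEFAULT_K_VALUES,
    min_cluster_coverage: int = 25,
    max_cluster_coverage: int = 400,
    min_contig_length: int = 100,
    min_pe_coverage: float = 4.0,
    min_coverage_ccrad1: int = 6,
    template_sample: str | None = None,
    **genotype_thresholds,
) -> PipelineResult:
    """Quality filter -> SE clustering -> per-locus assembly -> contig
    filters -> alignment -> variant calling -> marker classification."""
    all_pairs: list[ReadPair] = []
    for sample in sorted(pairs_by_sample):
        all_pairs.extend(pairs_by_sample[sample])
    retained, discarded = assembly.quality_filter(all_pairs)
    template = template_sample or select_template_sample(retained)
    clusters = assembly.cluster_single_ends(
        retained, min_cluster_coverage, max_cluster_coverage)
    clusters = deduplicate_clusters(clusters, template)
    contigs, _log = assembly.assemble_all(
        clusters, k_values=k_values,
        min_length=min_contig_length, min_pe_coverage=min_pe_coverage,
        template_sample=template)
    stats = assembly.assembly_stats(contigs) if contigs else None
    sample_ids = sorted(pairs_by_sample)
    calling = run_variant_calling(
        retained, contigs, sample_ids,
        min_coverage_ccrad1=min_coverage_ccrad1, **genotype_thresholds)
    return PipelineResult(
        contigs=contigs, stats=stats, calling=calling,
        template_sample=template,
        n_pairs_retained=len(retained), n_pairs_discarded=len(discarded),
    )
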