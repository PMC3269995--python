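"""Multi-sample variant discovery on RAD contigs: read-pair alignment under
mismatch/gap caps, pileups, two-tier variant sets (comprehensive and fully
informative), genotype imputation and testcross/intercross classification.

Allele keys in pileups are ``"A"`` for a plain base, ``"A+CT"`` for a base
followed by a 1-2 nt insertion and ``"A-2"`` for a base followed by a
1-2 nt deletion, all anchored at the leftmost reference position.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

from .assembly import RadContig, ReadPair

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i

MAX_MISMATCHES = 3
MAX_GAP_LENGTH = 2


def _codes(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class ReadAlignment:
    """One accepted read-to-contig alignment.

    ``events`` is only populated for gapped alignments; ungapped reads are
    fully described by (offset, seq).
    """

    offset: int
    mismatches: int
    gap_length: int
    seq: str
    events: list[tuple[int, str]] | None = None  # (ref_pos, allele key)


@dataclass
class PairAlignment:
    contig_id: str
    sample_id: str
    se: ReadAlignment
    pe: ReadAlignment


def _hamming_scan(read_codes: np.ndarray, contig_codes: np.ndarray) -> tuple[int, int]:
    """(best offset, mismatch count) over all ungapped placements."""
    L = len(read_codes)
    if len(contig_codes) < L:
        return -1, L + 1
    windows = np.lib.stride_tricks.sliding_window_view(contig_codes, L)
    mism = np.count_nonzero(windows != read_codes, axis=1)
    best = int(np.argmin(mism))
    return best, int(mism[best])


_ALIGNER = Align.PairwiseAligner()
_ALIGNER.mode = "global"
_ALIGNER.match_score = 1.0
_ALIGNER.mismatch_score = -1.0
_ALIGNER.open_gap_score = -4.0
_ALIGNER.extend_gap_score = -1.0
# read may land anywhere on the contig: unaligned contig flanks are free
try:
    _ALIGNER.end_deletion_score = 0.0
except AttributeError:  # older Biopython naming
    _ALIGNER.query_end_gap_score = 0.0


def _gapped_align(seq: str, contig: str) -> ReadAlignment | None:
    try:
        aln = _ALIGNER.align(contig, seq)[0]
    except (IndexError, OverflowError):
        return None
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return None
    events: list[tuple[int, str]] = []
    mismatches = 0
    gap_length = 0
    # leading/trailing query gaps would leave read bases unaligned: reject
    if q_blocks[0][0] != 0 or q_blocks[-1][1] != len(seq):
        return None
    pending: dict[int, str] = {}
    for bi, ((ts, te), (qs, qe)) in enumerate(zip(t_blocks, q_blocks)):
        for tp, qp in zip(range(ts, te), range(qs, qe)):
            events.append((tp, seq[qp]))
            if contig[tp] != seq[qp]:
                mismatches += 1
        if bi + 1 < len(t_blocks):
            t_next, q_next = t_blocks[bi + 1][0], q_blocks[bi + 1][0]
            t_gap = t_next - te
            q_gap = q_next - qe
            gap_length += t_gap + q_gap
            if te == 0:
                return None  # gap with no anchoring base
            anchor = te - 1
            base = events[-1][1]
            if q_gap:  # insertion in the read
                events[-1] = (anchor, f"{base}+{seq[qe:q_next]}")
            if t_gap:  # deletion in the read
                prev = events[-1][1]
                events[-1] = (anchor, f"{prev}-{t_gap}")
    first = t_blocks[0][0]
    return ReadAlignment(
        offset=int(first), mismatches=mismatches, gap_length=int(gap_length),
        seq=seq, events=events,
    )


def align_read(
    seq: str,
    contig: str,
    max_mismatches: int = MAX_MISMATCHES,
    max_gap_length: int = MAX_GAP_LENGTH,
    contig_codes: np.ndarray | None = None,
) -> ReadAlignment | None:
    """Best placement of one read on a contig, or None if it violates the
    mismatch/gap acceptance thresholds."""
    if len(contig) < len(seq):
        return None
    pos = contig.find(seq)
    if pos >= 0:
        return ReadAlignment(offset=pos, mismatches=0, gap_length=0, seq=seq)
    if contig_codes is None:
        contig_codes = _codes(contig)
    offset, mism = _hamming_scan(_codes(seq), contig_codes)
    if mism <= max_mismatches:
        return ReadAlignment(offset=offset, mismatches=mism, gap_length=0, seq=seq)
    aln = _gapped_align(seq, contig)
    if aln is None or aln.mismatches > max_mismatches or aln.gap_length > max_gap_length:
        return None
    if aln.gap_length == 0:
        return None  # the ungapped scan already found its best placement
    if aln.events and aln.events[-1][0] >= len(contig) - 1:
        # gap squeezed in to make an overhanging read fit the contig end
        return None
    return aln


def align_read_pair(
    pair: ReadPair,
    contig: RadContig,
    max_mismatches: int = MAX_MISMATCHES,
    max_gap_length: int = MAX_GAP_LENGTH,
    contig_codes: np.ndarray | None = None,
) -> PairAlignment | None:
    """Align a read pair to its anchored contig; accepted only when both
    mates pass (<= 3 mismatches, <= 2 nt gap per read)."""
    seq = contig.sequence
    if len(seq) < len(pair.se_seq):
        return None
    if contig_codes is None:
        contig_codes = _codes(seq)
    # SE is restriction-anchored: offset 0 on its locus contig
    se_mism = int(np.count_nonzero(
        contig_codes[:len(pair.se_seq)] != _codes(pair.se_seq)))
    if se_mism > max_mismatches:
        se_aln = align_read(pair.se_seq, seq, max_mismatches, max_gap_length,
                            contig_codes)
        if se_aln is None or se_aln.offset != 0:
            return None
    else:
        se_aln = ReadAlignment(0, se_mism, 0, pair.se_seq)
    pe_target = pair.pe_seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
    pe_aln = align_read(pe_target, seq, max_mismatches, max_gap_length, contig_codes)
    if pe_aln is None:
        return None
    return PairAlignment(contig.contig_id, pair.sample_id, se_aln, pe_aln)


# ---------------------------------------------------------------------------
# Pileups
# ---------------------------------------------------------------------------

class Pileup:
    """Per-contig, per-sample allele counts: dense 4 x L base counts plus a
    sparse map for indel-bearing alleles."""

    def __init__(self, contigs: Mapping[str, str], sample_ids: Sequence[str]):
        self.contigs = dict(contigs)
        self.sample_ids = list(sample_ids)
        self._dense: dict[str, dict[str, np.ndarray]] = {
            cid: {s: np.zeros((4, len(seq)), dtype=np.int32) for s in sample_ids}
            for cid, seq in self.contigs.items()
        }
        self._sparse: dict[tuple[str, int], dict[str, Counter]] = {}

    def add_alignment(self, contig_id: str, sample_id: str, aln: ReadAlignment) -> None:
        dense = self._dense[contig_id][sample_id]
        if aln.events is None:
            codes = _codes(aln.seq)
            valid = codes >= 0
            positions = np.arange(aln.offset, aln.offset + len(codes))[valid]
            np.add.at(dense, (codes[valid], positions), 1)
            return
        for pos, allele in aln.events:
            if len(allele) == 1:
                code = _BASE_CODE[ord(allele)]
                if code >= 0:
                    dense[code, pos] += 1
            else:
                cell = self._sparse.setdefault((contig_id, pos), {})
                cell.setdefault(sample_id, Counter())[allele] += 1

    def add_pair(self, pa: PairAlignment) -> None:
        self.add_alignment(pa.contig_id, pa.sample_id, pa.se)
        self.add_alignment(pa.contig_id, pa.sample_id, pa.pe)

    def sample_counts(self, contig_id: str, pos: int) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for s in self.sample_ids:
            col = self._dense[contig_id][s][:, pos]
            counts = {"ACGT"[i]: int(col[i]) for i in range(4) if col[i] > 0}
            sparse = self._sparse.get((contig_id, pos), {}).get(s)
            if sparse:
                for allele, n in sparse.items():
                    counts[allele] = counts.get(allele, 0) + n
            out[s] = counts
        return out

    def pooled_counts(self, contig_id: str, pos: int) -> dict[str, int]:
        pooled: dict[str, int] = {}
        for counts in self.sample_counts(contig_id, pos).values():
            for allele, n in counts.items():
                pooled[allele] = pooled.get(allele, 0) + n
        return pooled

    def candidate_columns(self, contig_id: str) -> Iterable[int]:
        """Columns with >= 2 distinct observed alleles (pooled)."""
        pooled = sum(self._dense[contig_id].values())
        multi = np.flatnonzero(np.count_nonzero(pooled > 0, axis=0) >= 2)
        sparse_cols = {
            pos for (cid, pos) in self._sparse if cid == contig_id
        }
        yield from sorted(set(multi.tolist()) | sparse_cols)


def build_pileup(
    alignments: Iterable[PairAlignment],
    contigs: Mapping[str, str],
    sample_ids: Sequence[str],
) -> Pileup:
    pileup = Pileup(contigs, sample_ids)
    for pa in alignments:
        pileup.add_pair(pa)
    return pileup


# ---------------------------------------------------------------------------
# Variant sites and genotypes
# ---------------------------------------------------------------------------

_INDEL_RE = re.compile(r"^[ACGT]([+][ACGT]{1,2}|-[12])$")


def allele_is_valid(allele: str) -> bool:
    """Plain base, or base plus a 1-2 nt insertion/deletion."""
    return (len(allele) == 1 and allele in "ACGT") or bool(_INDEL_RE.match(allele))


@dataclass
class VariantSite:
    contig_id: str
    position: int
    ref: str  # allele key of the reference allele (contig base)
    alts: list[str]
    var_class: str  # 'SNP' or 'indel'
    biallelic: bool
    in_ccrad2: bool = False

    @property
    def site_id(self) -> str:
        return f"{self.contig_id}:{self.position}"


@dataclass
class GenotypeCall:
    sample_id: str
    zygosity: str  # 'het' | 'hom' | 'ambiguous' | 'no_call'
    alleles: tuple[str, ...]
    counts: dict[str, int]
    frequency: float  # minor-allele frequency within the sample

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class MarkerRecord:
    site: VariantSite
    genotypes: dict[str, GenotypeCall]
    labels: list[tuple[str, ...]]  # ('testcross', het parent, hom parent) | ('common_intercross',)

    @property
    def marker_class(self) -> str:
        if any(l[0] == "common_intercross" for l in self.labels):
            return "common_intercross"
        if any(l[0] == "testcross" for l in self.labels):
            return "testcross"
        return "uninformative"


def call_ccrad1(
    pileup: Pileup,
    min_coverage: int = 6,
    per_sample: bool = False,
) -> list[VariantSite]:
    """Comprehensive variant list: columns with >= 2 observed alleles and
    a depth threshold (pooled across samples by default)."""
    sites: list[VariantSite] = []
    for contig_id, seq in pileup.contigs.items():
        for pos in pileup.candidate_columns(contig_id):
            pooled = pileup.pooled_counts(contig_id, pos)
            alleles = {a: n for a, n in pooled.items() if allele_is_valid(a)}
            if len(alleles) < 2:
                continue
            if per_sample:
                per = pileup.sample_counts(contig_id, pos)
                if any(sum(c.values()) < min_coverage for c in per.values()):
                    continue
            elif sum(alleles.values()) < min_coverage:
                continue
            ref = seq[pos]
            alts = sorted(a for a in alleles if a != ref)
            if not alts or ref not in alleles and len(alts) < 2:
                continue
            var_class = "SNP" if all(len(a) == 1 for a in alleles) else "indel"
            sites.append(VariantSite(
                contig_id=contig_id, position=pos, ref=ref, alts=alts,
                var_class=var_class, biallelic=(len(alleles) == 2),
            ))
    return sites


def impute_genotype(
    counts: Mapping[str, int],
    sample_id: str,
    het_window: tuple[float, float] = (0.25, 0.75),
    het_min_depth: int = 4,
    het_min_reads: int = 2,
    hom_maf: float = 0.10,
) -> GenotypeCall:
    """Zygosity from within-sample allele counts.

    het: top-two alleles each supported by >= 2 reads, each at a frequency
    inside [0.25, 0.75], total depth >= 4. hom: minor allele frequency
    < 0.10. depth 0: no_call. Everything else: ambiguous.
    """
    counts = {a: n for a, n in counts.items() if n > 0}
    depth = sum(counts.values())
    if depth == 0:
        return GenotypeCall(sample_id, "no_call", (), {}, 0.0)
    ranked = sorted(counts.items(), key=lambda it: (-it[1], it[0]))
    major, major_n = ranked[0]
    maf = (depth - major_n) / depth
    if (depth - major_n) < hom_maf * depth - 1e-9:  # strictly below threshold
        return GenotypeCall(sample_id, "hom", (major,), dict(counts), maf)
    supported = [a for a, n in ranked if n >= het_min_reads]
    if len(supported) > 2:
        return GenotypeCall(sample_id, "ambiguous", (), dict(counts), maf)
    if len(ranked) >= 2:
        (a1, n1), (a2, n2) = ranked[0], ranked[1]
        lo, hi = het_window
        if (depth >= het_min_depth and n2 >= het_min_reads
                and lo <= n1 / depth <= hi and lo <= n2 / depth <= hi):
            return GenotypeCall(
                sample_id, "het", tuple(sorted((a1, a2))), dict(counts), maf)
    return GenotypeCall(sample_id, "ambiguous", (), dict(counts), maf)


def select_ccrad2(
    sites: Sequence[VariantSite], pileup: Pileup
) -> list[VariantSite]:
    """Fully informative subset: every sample has >= 1 read at the site.
    Marks sites in place and returns the retained subset."""
    retained = []
    for site in sites:
        per = pileup.sample_counts(site.contig_id, site.position)
        if all(sum(c.values()) >= 1 for c in per.values()):
            site.in_ccrad2 = True
            retained.append(site)
    return retained


def genotype_sites(
    sites: Sequence[VariantSite], pileup: Pileup, **thresholds
) -> dict[str, dict[str, GenotypeCall]]:
    """site_id -> sample_id -> GenotypeCall for every site."""
    out: dict[str, dict[str, GenotypeCall]] = {}
    for site in sites:
        per = pileup.sample_counts(site.contig_id, site.position)
        out[site.site_id] = {
            s: impute_genotype(counts, s, **thresholds)
            for s, counts in per.items()
        }
    return out


def classify_markers(
    sites: Sequence[VariantSite],
    genotypes: Mapping[str, Mapping[str, GenotypeCall]],
    sample_ids: Sequence[str],
) -> list[MarkerRecord]:
    """Testcross/intercross classification over ordered sample pairs.

    A testcross label (het parent, hom partner) is emitted for every
    ordered pair where exactly that asymmetry holds; a site heterozygous in
    all three samples is a common intercross. Ambiguous or missing
    genotypes make the comparisons they touch uninformative.
    """
    records = []
    for site in sites:
        calls = {s: genotypes[site.site_id][s] for s in sample_ids}
        labels: list[tuple[str, ...]] = []
        if all(c.zygosity == "het" for c in calls.values()):
            labels.append(("common_intercross",))
        else:
            for het_s in sample_ids:
                if calls[het_s].zygosity != "het":
                    continue
                for hom_s in sample_ids:
                    if hom_s != het_s and calls[hom_s].zygosity == "hom":
                        labels.append(("testcross", het_s, hom_s))
        records.append(MarkerRecord(site=site, genotypes=calls, labels=labels))
    return records


def marker_summary(records: Sequence[MarkerRecord]) -> "pd.DataFrame":
    """Mining-summary table: per-category site and contig counts."""
    import pandas as pd

    rows = []

    def add(category: str, recs: list[MarkerRecord]) -> None:
        rows.append({
            "category": category,
            "contigs": len({r.site.contig_id for r in recs}),
            "sites": len(recs),
        })

    add("all_sites", list(records))
    testcross = [r for r in records if r.marker_class == "testcross"]
    add("testcross", testcross)
    pairs = sorted({l[1:] for r in testcross for l in r.labels if l[0] == "testcross"})
    for het_s, hom_s in pairs:
        add(f"{het_s}_testcross_over_{hom_s}",
            [r for r in testcross if ("testcross", het_s, hom_s) in r.labels])
    add("common_intercross",
        [r for r in records if r.marker_class == "common_intercross"])
    add("uninformative",
        [r for r in records if r.marker_class == "uninformative"])
    return pd.DataFrame(rows, columns=["category", "contigs", "sites"])


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

def _expand_alleles(
    contig_seq: str, pos: int, alleles: Sequence[str]
) -> tuple[str, dict[str, str]]:
    """Expand allele keys to VCF REF/ALT strings with a shared anchor."""
    max_del = max(
        (int(a.split("-")[1]) for a in alleles if "-" in a), default=0)
    ref = contig_seq[pos:pos + 1 + max_del]
    expanded = {}
    for a in alleles:
        if len(a) == 1:
            expanded[a] = a + contig_seq[pos + 1:pos + 1 + max_del]
        elif "+" in a:
            base, ins = a.split("+")
            expanded[a] = base + ins + contig_seq[pos + 1:pos + 1 + max_del]
        else:
            base, d = a.split("-")
            expanded[a] = base + contig_seq[pos + 1 + int(d):pos + 1 + max_del]
    return ref, expanded


def write_vcf(
    sites: Sequence[VariantSite],
    genotypes: Mapping[str, Mapping[str, GenotypeCall]],
    contigs: Mapping[str, str],
    sample_ids: Sequence[str],
    path: str | Path,
) -> None:
    """VCF 4.2 with GT and AD per sample; positions are 1-based."""
    lines = ["##fileformat=VCFv4.2", "##source=radsnp"]
    for cid in sorted(contigs):
        lines.append(f"##contig=<ID={cid},length={len(contigs[cid])}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">')
    lines.append('##INFO=<ID=SET,Number=1,Type=String,Description="Variant set membership">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header.extend(sample_ids)
    lines.append("\t".join(header))
    for site in sorted(sites, key=lambda s: (s.contig_id, s.position)):
        seq = contigs[site.contig_id]
        if site.ref != seq[site.position]:
            raise ValueError(
                f"reference allele {site.ref!r} inconsistent with contig "
                f"{site.contig_id} at {site.position}")
        ordered = [site.ref, *site.alts]
        ref_str, expanded = _expand_alleles(seq, site.position, ordered)
        alt_strs = [expanded[a] for a in site.alts]
        index = {a: i for i, a in enumerate(ordered)}
        fields = [
            site.contig_id, str(site.position + 1), site.site_id,
            ref_str, ",".join(alt_strs) or ".", ".", "PASS",
            f"SET={'CcRAD2' if site.in_ccrad2 else 'CcRAD1'}", "GT:AD",
        ]
        for s in sample_ids:
            call = genotypes[site.site_id][s]
            ad = ",".join(str(call.counts.get(a, 0)) for a in ordered)
            if call.zygosity == "hom" and call.alleles[0] in index:
                i = index[call.alleles[0]]
                gt = f"{i}/{i}"
            elif call.zygosity == "het" and all(a in index for a in call.alleles):
                i, j = sorted(index[a] for a in call.alleles)
                gt = f"{i}/{j}"
            else:
                gt = "./."
            fields.append(f"{gt}:{ad}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")
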