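"""RAD locus assembly: exact single-end clustering, per-locus de Bruijn
contig construction, contig filters and assembly statistics."""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

DEFAULT_K_VALUES = (21, 25, 29, 33)


@dataclass(frozen=True)
class ReadPair:
    """One RAD read pair: restriction-anchored single end plus sheared mate."""

    read_id: str
    se_seq: str
    pe_seq: str
    se_qual: str
    pe_qual: str
    sample_id: str

    def __post_init__(self) -> None:
        if not self.se_seq or not self.pe_seq:
            raise ValueError("read sequences must be non-empty")
        if len(self.se_qual) != len(self.se_seq) or len(self.pe_qual) != len(self.pe_seq):
            raise ValueError(f"quality/sequence length mismatch in {self.read_id}")


@dataclass
class SECluster:
    cluster_id: str
    se_representative: str
    members: list[ReadPair]

    @property
    def coverage(self) -> int:
        return len(self.members)


@dataclass
class RadContig:
    contig_id: str
    locus_id: str
    node: int
    sequence: str
    pe_coverage: float

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class AssemblyStats:
    contig_count: int
    total_bp: int
    mean_length: float
    n50: int
    gc_fraction: float
    alternative_fraction: float

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def _phred(qual: str) -> np.ndarray:
    return np.frombuffer(qual.encode(), dtype=np.uint8).astype(int) - 33


def read_fails_quality(qual: str, max_poor: int = 5, poor_phred: int = 10) -> bool:
    """A read fails when more than ``max_poor`` bases are at or below
    ``poor_phred``."""
    return int(np.count_nonzero(_phred(qual) <= poor_phred)) > max_poor


def quality_filter(
    reads: Iterable[ReadPair], max_poor: int = 5, poor_phred: int = 10
) -> tuple[list[ReadPair], list[tuple[str, str]]]:
    """Drop pairs where either mate has more than ``max_poor`` bases at
    Phred <= ``poor_phred``. Returns (retained, discard log)."""
    kept: list[ReadPair] = []
    discarded: list[tuple[str, str]] = []
    for pair in reads:
        se_bad = read_fails_quality(pair.se_qual, max_poor, poor_phred)
        pe_bad = read_fails_quality(pair.pe_qual, max_poor, poor_phred)
        if se_bad or pe_bad:
            discarded.append(
                (pair.read_id, "se_low_quality" if se_bad else "pe_low_quality"))
        else:
            kept.append(pair)
    return kept, discarded


def cluster_single_ends(
    reads: Iterable[ReadPair], min_coverage: int = 25, max_coverage: int = 400
) -> list[SECluster]:
    """Pool reads from every sample and collapse on 100% SE identity,
    then drop clusters outside the [min_coverage, max_coverage] depth
    bounds. Cluster ids are assigned in decreasing-coverage order."""
    by_se: dict[str, list[ReadPair]] = {}
    for pair in reads:
        by_se.setdefault(pair.se_seq, []).append(pair)
    surviving = [
        (se, members) for se, members in by_se.items()
        if min_coverage <= len(members) <= max_coverage
    ]
    surviving.sort(key=lambda it: (-len(it[1]), it[0]))
    return [
        SECluster(cluster_id=f"locus{i + 1:05d}", se_representative=se, members=members)
        for i, (se, members) in enumerate(surviving)
    ]


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _kmer_counts(sequences: Iterable[tuple[str, int]], k: int) -> Counter:
    counts: Counter = Counter()
    for seq, mult in sequences:
        for i in range(len(seq) - k + 1):
            counts[seq[i:i + k]] += mult
    return counts


def _extend_paths(
    seed: str, counts: Counter, k: int, min_count: int,
    max_length: int, max_paths: int,
) -> list[str]:
    """Greedy unitig extension from the seed; forks once per ambiguous
    branch while the path budget allows, otherwise breaks the contig at the
    branch point."""
    finished: list[str] = []
    active = [seed]
    while active:
        path = active.pop()
        while len(path) < max_length:
            suffix = path[-(k - 1):]
            observed = {
                b: counts[suffix + b] for b in "ACGT" if counts.get(suffix + b, 0) > 0
            }
            strong = [b for b, n in observed.items() if n >= min_count]
            if len(observed) == 1:
                # unambiguous: follow even below the count threshold
                path += next(iter(observed))
            elif len(strong) == 1:
                path += strong[0]  # weak alternatives treated as noise
            elif len(strong) > 1 and 1 + len(active) + len(finished) < max_paths:
                ranked = sorted(strong, key=lambda b: (-observed[b], b))
                active.extend(path + b for b in ranked[1:])
                path += ranked[0]
            else:
                break  # dead end or unresolvable branch
        finished.append(path)
    return finished


def _mean_kmer_coverage(seq: str, counts: Counter, k: int) -> float:
    vals = [counts[seq[i:i + k]] for i in range(len(seq) - k + 1)]
    return float(np.mean(vals)) if vals else 0.0


def _pe_coverage(contig: str, pe_targets: Counter, read_length: int) -> float:
    aligned = 0
    for pe, mult in pe_targets.items():
        if pe in contig:
            aligned += len(pe) * mult
    return aligned / len(contig) if contig else 0.0


def assemble_locus(
    cluster: SECluster,
    k_values: Sequence[int] = DEFAULT_K_VALUES,
    min_kmer_count: int = 2,
    max_length: int = 2000,
    max_nodes: int = 4,
    template_sample: str | None = None,
) -> list[RadContig]:
    """Per-locus mini de Bruijn assembly over the SE representative and the
    reverse-complemented paired ends, swept over ``k_values``.

    With a ``template_sample``, only that sample's reads feed the graph
    (single-accession template assembly keeps the graph nearly linear);
    paired-end coverage is still scored over all members. Every contig is
    anchored on the SE representative as its prefix. Distinct surviving
    sequences are ranked by (length, mean k-mer coverage) and labelled
    NODE1, NODE2, ... deterministically.
    """
    if not k_values:
        raise ValueError("k_values must be non-empty")
    se = cluster.se_representative
    pe_targets: Counter = Counter(_revcomp(p.pe_seq) for p in cluster.members)
    graph_members = cluster.members
    if template_sample is not None:
        template_members = [
            m for m in cluster.members if m.sample_id == template_sample]
        if len(template_members) >= 2 * min_kmer_count:
            graph_members = template_members
    graph_pe: Counter = Counter(_revcomp(p.pe_seq) for p in graph_members)
    sequences = [(se, len(graph_members))] + list(graph_pe.items())
    candidates: dict[str, float] = {}
    for k in k_values:
        if k >= len(se):
            continue
        counts = _kmer_counts(sequences, k)
        for path in _extend_paths(se, counts, k, min_kmer_count, max_length, max_nodes):
            cov = _mean_kmer_coverage(path, counts, k)
            if path not in candidates or cov > candidates[path]:
                candidates[path] = cov
    # drop sequences that are prefixes of a longer surviving one
    seqs = sorted(candidates, key=len, reverse=True)
    kept: list[str] = []
    for s in seqs:
        if not any(longer.startswith(s) for longer in kept):
            kept.append(s)
    kept.sort(key=lambda s: (-len(s), -candidates[s], s))
    kept = kept[:max_nodes]
    if not kept:
        return []
    contigs = []
    for j, seq in enumerate(kept, start=1):
        contigs.append(RadContig(
            contig_id=f"{cluster.cluster_id}_NODE{j}",
            locus_id=cluster.cluster_id,
            node=j,
            sequence=seq,
            pe_coverage=_pe_coverage(
                seq, pe_targets, len(cluster.members[0].pe_seq)),
        ))
    return contigs


def filter_contigs(
    contigs: Iterable[RadContig],
    min_length: int = 100,
    min_pe_coverage: float = 4.0,
) -> list[RadContig]:
    """Drop short contigs, low paired-end coverage, and contigs containing
    an N homopolymer (>= 2 consecutive N). Order preserved; idempotent."""
    return [
        c for c in contigs
        if c.length >= min_length
        and c.pe_coverage >= min_pe_coverage
        and "NN" not in c.sequence
    ]


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that contigs of length >= L cover at least half of
    the total assembly."""
    if not lengths:
        raise ValueError("no contigs")
    total = sum(lengths)
    half = total / 2
    covered = 0
    for L in sorted(lengths, reverse=True):
        covered += L
        if covered >= half:
            return L
    return min(lengths)


def assembly_stats(contigs: Sequence[RadContig]) -> AssemblyStats:
    if not contigs:
        raise ValueError("no contigs to summarize")
    lengths = [c.length for c in contigs]
    total = sum(lengths)
    concat_counts = Counter()
    for c in contigs:
        concat_counts.update(c.sequence)
    acgt = sum(concat_counts[b] for b in "ACGT")
    gc = (concat_counts["G"] + concat_counts["C"]) / acgt if acgt else 0.0
    loci: dict[str, int] = {}
    for c in contigs:
        loci[c.locus_id] = loci.get(c.locus_id, 0) + 1
    alt_fraction = sum(1 for n in loci.values() if n > 1) / len(loci)
    return AssemblyStats(
        contig_count=len(contigs),
        total_bp=total,
        mean_length=total / len(contigs),
        n50=n50(lengths),
        gc_fraction=gc,
        alternative_fraction=alt_fraction,
    )


def sequence_gc_fraction(sequences: Iterable[str]) -> float:
    """GC over concatenated sequences, ignoring non-ACGT characters."""
    counts = Counter()
    for seq in sequences:
        counts.update(seq.upper())
    acgt = sum(counts[b] for b in "ACGT")
    if acgt == 0:
        raise ValueError("no ACGT bases")
    return (counts["G"] + counts["C"]) / acgt


def assemble_all(
    clusters: Sequence[SECluster],
    k_values: Sequence[int] = DEFAULT_K_VALUES,
    min_kmer_count: int = 2,
    min_length: int = 100,
    min_pe_coverage: float = 4.0,
    template_sample: str | None = None,
) -> tuple[list[RadContig], list[str]]:
    """Assemble every cluster and apply the contig filters.

    Returns (contigs, log of dropped loci)."""
    contigs: list[RadContig] = []
    log: list[str] = []
    for cluster in clusters:
        nodes = assemble_locus(cluster, k_values, min_kmer_count,
                               template_sample=template_sample)
        if not nodes:
            log.append(f"{cluster.cluster_id}\tno_contig_with_se_anchor")
            continue
        kept = filter_contigs(nodes, min_length, min_pe_coverage)
        if not kept:
            log.append(f"{cluster.cluster_id}\tall_contigs_filtered")
        contigs.extend(kept)
    return contigs, log


def write_contig_fasta(contigs: Sequence[RadContig], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.contig_id} pe_cov={c.pe_coverage:.2f} len={c.length}\n")
            for i in range(0, c.length, 70):
                fh.write(c.sequence[i:i + 70] + "\n")
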