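"""Synthetic RAD-seq data: reference genomes, diverged diploid accessions,
paired-end RAD libraries and F1 progeny genotypes, with full ground truth.

All coordinates are 0-based, half-open. A cut coordinate is the index of
the first base after the top-strand cut, so the right-side RAD locus of a
cut at ``c`` reads ``seq[c:]`` and the left-side locus reads
``revcomp(seq[:c])``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .assembly import ReadPair
from .enzymes import digest, get_enzyme, reverse_complement
from .linkage import kosambi_inverse

BASES = np.array(["A", "C", "G", "T"])
PSTI_SITE = "CTGCAG"

# CpG-free unit used for optionally planted tandem repeat families
DEFAULT_REPEAT_UNIT = "ATTGATTAGGTTAATCCATTAGGATTCAATGGTCAATTAG"


@dataclass
class SimParams:
    """Knobs for the whole synthetic pipeline; one seed drives everything."""

    genome_length: int = 2_000_000
    n_chromosomes: int = 1
    pstI_site_spacing: int = 5_000
    divergence_rate: float = 0.0056
    het_rate_per_accession: tuple[float, float, float] = (0.0002, 0.0005, 0.0008)
    indel_fraction: float = 0.02
    read_length: int = 54
    # hard truncation bounds for the sheared-end position. The default
    # reaches below the nominal 300-800 gel window so that mate coverage
    # is contiguous from the anchored read outward (a strict gel cut
    # would leave the first ~250 nt covered by the anchored read only and
    # no anchored contig could assemble); pass (300, 800) for a hard cut.
    insert_range: tuple[int, int] = (56, 500)
    insert_mean: float = 300.0
    insert_sd: float | None = None  # None: uniform over insert_range
    depth_weights: tuple[float, float, float] = (1.2, 2.6, 5.9)
    error_rate: float = 0.0
    n_progeny: int = 94
    gc_content: float = 0.374
    site_loss_fraction: float = 0.0
    low_quality_read_fraction: float = 0.0
    repeat_copies: int = 0
    repeat_unit: str = DEFAULT_REPEAT_UNIT
    sample_ids: tuple[str, str, str] = ("artichoke", "cardoon", "wild")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be > 0")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        for name in ("divergence_rate", "indel_fraction", "error_rate",
                     "gc_content", "site_loss_fraction", "low_quality_read_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if len(self.het_rate_per_accession) != 3:
            raise ValueError("het_rate_per_accession must have length 3")
        if any(not 0.0 <= h <= 1.0 for h in self.het_rate_per_accession):
            raise ValueError("het rates must be in [0, 1]")
        if self.insert_range[0] < self.read_length + 2:
            raise ValueError("insert minimum must exceed read_length")
        if self.insert_range[0] > self.insert_range[1]:
            raise ValueError("insert_range must be (min, max) with min <= max")
        if self.pstI_site_spacing < 2 * self.insert_range[1]:
            raise ValueError(
                "pstI_site_spacing must be >= 2 x insert max "
                "(loci would overlap ambiguously)"
            )
        if any(w <= 0 for w in self.depth_weights):
            raise ValueError("depth_weights must be positive")
        if self.n_progeny < 1:
            raise ValueError("n_progeny must be >= 1")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


@dataclass
class ReferenceGenome:
    chromosomes: dict[str, str]
    # (chrom, pattern start); cut coordinate = start + 5 for PstI
    planted_sites: list[tuple[str, int]]

    @property
    def cut_sites(self) -> list[tuple[str, int]]:
        return [(c, s + 5) for c, s in self.planted_sites]


@dataclass
class DiploidAccession:
    accession_id: str
    haplotypes: dict[str, tuple[str, str]]
    role: str = "parent"

    def __post_init__(self) -> None:
        for chrom, (h0, h1) in self.haplotypes.items():
            for h in (h0, h1):
                if set(h) - set("ACGT"):
                    raise ValueError(f"non-ACGT characters in {self.accession_id}/{chrom}")


@dataclass
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    # one (hap0, hap1) pair of 0/1 alt indicators per accession
    genotypes: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    var_class: str  # 'SNP' or 'indel'


@dataclass
class LocusRecord:
    chrom: str
    cut_pos: int
    side: str  # 'left' or 'right'
    present: tuple[bool, bool, bool]


@dataclass
class TruthTable:
    variants: list[VariantRecord]
    loci: list[LocusRecord]

    def variants_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.variants:
            row = {"CHROM": v.chrom, "POS": v.pos, "REF": v.ref, "ALT": v.alt,
                   "CLASS": v.var_class}
            for label, gt in zip(("A", "B", "C"), v.genotypes):
                row[f"GT_{label}"] = f"{gt[0]}|{gt[1]}"
            rows.append(row)
        return pd.DataFrame(
            rows, columns=["CHROM", "POS", "REF", "ALT",
                           "GT_A", "GT_B", "GT_C", "CLASS"])

    def loci_frame(self) -> pd.DataFrame:
        rows = [
            {"CHROM": l.chrom, "CUT_POS": l.cut_pos, "SIDE": l.side,
             "PRESENT_A": l.present[0], "PRESENT_B": l.present[1],
             "PRESENT_C": l.present[2]}
            for l in self.loci
        ]
        return pd.DataFrame(
            rows, columns=["CHROM", "CUT_POS", "SIDE",
                           "PRESENT_A", "PRESENT_B", "PRESENT_C"])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.variants_frame().to_csv(outdir / "truth_variants.tsv", sep="\t", index=False)
        self.loci_frame().to_csv(outdir / "truth_loci.tsv", sep="\t", index=False)


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASE_BYTES[codes].tobytes().decode()


def _random_background(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def _scrub_pattern(codes: np.ndarray, pattern: str, gc: float,
                   rng: np.random.Generator,
                   protected: set[int] | None = None) -> None:
    """Resample bases until no occurrence of ``pattern`` remains outside
    protected (planted) windows. Mutates ``codes`` in place."""
    pat = np.array([BASES.tolist().index(b) for b in pattern])
    m = len(pat)
    protected = protected or set()
    for _ in range(100):
        hits = np.flatnonzero(
            np.all(
                np.lib.stride_tricks.sliding_window_view(codes, m) == pat, axis=1
            )
        )
        hits = [h for h in hits if h not in protected]
        if not hits:
            return
        for h in hits:
            # resample one base inside the offending window, avoiding
            # positions that belong to a protected planted site
            for off in rng.permutation(m):
                if not any(p <= h + off < p + m for p in protected):
                    old = codes[h + off]
                    choices = [b for b in range(4) if b != old]
                    codes[h + off] = rng.choice(choices)
                    break
    raise RuntimeError("failed to scrub spurious recognition sites")


def simulate_reference(params: SimParams) -> ReferenceGenome:
    """Haploid reference with CTGCAG sites planted ~every ``pstI_site_spacing``
    nt and no spurious occurrences anywhere else."""
    rng = params.rng(0)
    chrom_len = params.genome_length // params.n_chromosomes
    if chrom_len < params.pstI_site_spacing:
        raise ValueError("chromosomes shorter than the site spacing")
    chromosomes: dict[str, str] = {}
    planted: list[tuple[str, int]] = []
    margin = params.insert_range[1] + params.read_length
    for ci in range(params.n_chromosomes):
        name = f"chr{ci + 1}"
        codes = _random_background(chrom_len, params.gc_content, rng)
        positions = []
        pos = margin + int(rng.integers(0, max(1, params.pstI_site_spacing // 4)))
        while pos + len(PSTI_SITE) + margin < chrom_len:
            positions.append(pos)
            jitter = int(rng.integers(-(params.pstI_site_spacing // 10),
                                      params.pstI_site_spacing // 10 + 1))
            pos += params.pstI_site_spacing + jitter
        site_codes = np.array([BASES.tolist().index(b) for b in PSTI_SITE])
        for p in positions:
            codes[p:p + len(PSTI_SITE)] = site_codes
        if params.repeat_copies > 0 and len(positions) >= 2:
            # tandem repeat family parked between the last two planted
            # sites, centred so it stays clear of both locus windows
            tract = params.repeat_unit * params.repeat_copies
            gap_lo = positions[-2] + len(PSTI_SITE) + margin
            gap_hi = positions[-1] - margin
            start = gap_lo + max(0, (gap_hi - gap_lo - len(tract)) // 2)
            if start + len(tract) <= gap_hi:
                rep_codes = np.array([BASES.tolist().index(b) for b in tract])
                codes[start:start + len(tract)] = rep_codes
            else:
                raise ValueError(
                    "repeat tract does not fit between planted sites; "
                    "reduce repeat_copies or increase spacing")
        _scrub_pattern(codes, PSTI_SITE, params.gc_content, rng,
                       protected=set(positions))
        chromosomes[name] = _codes_to_str(codes)
        planted.extend((name, p) for p in positions)
    return ReferenceGenome(chromosomes, planted)


def _splice_haplotype(ref: str, variants: list[tuple[int, str, str]]) -> str:
    """Apply (pos, ref_allele, alt_allele) edits, sorted, non-overlapping."""
    parts: list[str] = []
    prev = 0
    for pos, ra, aa in sorted(variants):
        parts.append(ref[prev:pos])
        parts.append(aa)
        prev = pos + len(ra)
    parts.append(ref[prev:])
    return "".join(parts)


def derive_accessions(
    reference: ReferenceGenome, params: SimParams
) -> tuple[list[DiploidAccession], TruthTable]:
    """Three diploid accessions diverged from the reference, plus the
    complete variant/locus truth table.

    Divergence sites are planted at rate 2 x ``divergence_rate`` with each
    accession homozygous alt with probability 1/2, so any two accessions
    differ at ~``divergence_rate`` per nt. Heterozygous sites are added per
    accession at its own rate. ``site_loss_fraction`` of the planted cut
    sites are knocked out (both haplotypes) in one random accession.
    """
    rng = params.rng(1)
    variants: list[VariantRecord] = []
    site_intact: dict[tuple[str, int], list[list[bool]]] = {}
    for chrom, start in reference.planted_sites:
        site_intact[(chrom, start)] = [[True, True] for _ in range(3)]

    lost_sites: set[tuple[str, int]] = set()
    n_lost = int(round(params.site_loss_fraction * len(reference.planted_sites)))
    if n_lost:
        idx = rng.choice(len(reference.planted_sites), size=n_lost, replace=False)
        lost_sites = {reference.planted_sites[i] for i in idx}

    for chrom, seq in reference.chromosomes.items():
        L = len(seq)
        forbidden = np.zeros(L, dtype=bool)
        for c, start in reference.planted_sites:
            if c == chrom:
                forbidden[start:start + len(PSTI_SITE)] = True
        taken = forbidden.copy()

        def draw_positions(rate: float) -> np.ndarray:
            mask = rng.random(L) < rate
            mask &= ~taken
            pos = np.flatnonzero(mask)
            taken[pos] = True
            # keep a 3 nt guard band so indel edits never overlap
            for p in pos:
                taken[max(0, p - 3):p + 4] = True
            return pos

        def make_alleles(p: int) -> tuple[str, str, str]:
            ref_base = seq[p]
            if rng.random() < params.indel_fraction and 3 < p < L - 4:
                if rng.random() < 0.5:  # insertion of 1-2 nt
                    ins = "".join(rng.choice(BASES, size=int(rng.integers(1, 3))))
                    return ref_base, ref_base + ins, "indel"
                dlen = int(rng.integers(1, 3))
                return seq[p:p + 1 + dlen], ref_base, "indel"
            alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            return ref_base, alt, "SNP"

        # inter-accession divergence sites
        for p in draw_positions(2.0 * params.divergence_rate):
            ra, aa, cls = make_alleles(int(p))
            gts = tuple(
                (1, 1) if rng.random() < 0.5 else (0, 0) for _ in range(3)
            )
            variants.append(VariantRecord(chrom, int(p), ra, aa, gts, cls))
        # per-accession heterozygous sites
        for ai, het_rate in enumerate(params.het_rate_per_accession):
            if het_rate == 0:
                continue
            for p in draw_positions(het_rate):
                ra, aa, cls = make_alleles(int(p))
                gt = [(0, 0)] * 3
                gt[ai] = (1, 0) if rng.random() < 0.5 else (0, 1)
                variants.append(VariantRecord(chrom, int(p), ra, aa, tuple(gt), cls))
        # deliberate restriction-site knockouts
        for (schrom, start) in sorted(lost_sites):
            if schrom != chrom:
                continue
            p = start + 2  # inside CTGCAG
            ref_base = seq[p]
            alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            ai = int(rng.integers(0, 3))
            gt = [(0, 0)] * 3
            gt[ai] = (1, 1)
            variants.append(VariantRecord(chrom, p, ref_base, alt, tuple(gt), "SNP"))
            site_intact[(chrom, start)][ai] = [False, False]

    variants.sort(key=lambda v: (v.chrom, v.pos))

    accessions = []
    roles = ("parentA", "parentB", "reference_donor")
    for ai, sample_id in enumerate(params.sample_ids):
        haplotypes = {}
        for chrom, seq in reference.chromosomes.items():
            edits0 = [(v.pos, v.ref, v.alt) for v in variants
                      if v.chrom == chrom and v.genotypes[ai][0]]
            edits1 = [(v.pos, v.ref, v.alt) for v in variants
                      if v.chrom == chrom and v.genotypes[ai][1]]
            haplotypes[chrom] = (
                _splice_haplotype(seq, edits0), _splice_haplotype(seq, edits1)
            )
        accessions.append(DiploidAccession(sample_id, haplotypes, roles[ai]))

    loci = []
    for chrom, start in reference.planted_sites:
        cut = start + 5
        present = tuple(any(site_intact[(chrom, start)][ai]) for ai in range(3))
        for side in ("left", "right"):
            loci.append(LocusRecord(chrom, cut, side, present))
    return accessions, TruthTable(variants, loci)


# ---------------------------------------------------------------------------
# RAD library simulation
# ---------------------------------------------------------------------------

@dataclass
class RadLocusTemplate:
    """One haplotype-level template: sequence read 5'->3' away from the cut."""
    chrom: str
    hap_index: int
    cut_pos: int  # reference-free: coordinate on the haplotype
    side: str
    template: str


def enumerate_locus_templates(
    accession: DiploidAccession, min_length: int,
    enzyme: str = "PstI",
) -> list[RadLocusTemplate]:
    """Digest both haplotypes; each internal cut contributes one locus per
    side (flank), oriented so position 0 is the restriction end."""
    out: list[RadLocusTemplate] = []
    for chrom, haps in accession.haplotypes.items():
        for hi, hap in enumerate(haps):
            frags = digest(hap, enzyme)
            for i, frag in enumerate(frags):
                if i > 0 and len(frag) >= min_length:  # starts at a cut
                    out.append(RadLocusTemplate(
                        chrom, hi, frag.start, "right", frag.sequence))
                if i < len(frags) - 1 and len(frag) >= min_length:  # ends at a cut
                    out.append(RadLocusTemplate(
                        chrom, hi, frag.end, "left",
                        reverse_complement(frag.sequence)))
    return out


def allocate_depth(
    total_pairs: int, weights: Sequence[float], rng: np.random.Generator
) -> np.ndarray:
    """Multinomial split of a read budget across samples."""
    w = np.asarray(weights, dtype=float)
    return rng.multinomial(total_pairs, w / w.sum())


def _inject_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for h in hits:
        old = arr[h].decode()
        arr[h] = rng.choice([b for b in "ACGT" if b != old]).encode()
    return arr.tobytes().decode()


def simulate_rad_library(
    accession: DiploidAccession,
    params: SimParams,
    n_pairs: int,
    rng: np.random.Generator | None = None,
) -> list[ReadPair]:
    """Paired 2 x ``read_length`` reads for one sample.

    The single end starts exactly at a cut site; the paired-end mate's far
    coordinate is a truncated-normal insert size in ``insert_range``
    (clipped to the restriction fragment). Substitution errors at
    ``error_rate``; constant Q40 qualities unless
    ``low_quality_read_fraction`` plants 6 bases at Q10 in the single end.
    """
    if rng is None:
        rng = params.rng(2)
    L = params.read_length
    lo, hi = params.insert_range
    templates = enumerate_locus_templates(accession, min_length=lo)
    if not templates:
        raise ValueError(f"accession {accession.accession_id} has no surviving RAD loci")
    if params.insert_sd is None:
        inserts = rng.integers(lo, hi + 1, size=n_pairs)
    else:
        from scipy import stats as _stats

        a = (lo - params.insert_mean) / params.insert_sd
        b = (hi - params.insert_mean) / params.insert_sd
        inserts = np.rint(_stats.truncnorm.rvs(
            a, b, loc=params.insert_mean, scale=params.insert_sd,
            size=n_pairs, random_state=rng)).astype(int)
    pairs: list[ReadPair] = []
    q40 = chr(33 + 40) * L
    for i in range(n_pairs):
        t = templates[int(rng.integers(0, len(templates)))]
        s = int(min(inserts[i], len(t.template)))
        se = _inject_errors(t.template[:L], params.error_rate, rng)
        pe = _inject_errors(
            reverse_complement(t.template[s - L:s]), params.error_rate, rng)
        se_qual = q40
        if params.low_quality_read_fraction > 0 and rng.random() < params.low_quality_read_fraction:
            qual = list(q40)
            for p in rng.choice(L, size=6, replace=False):
                qual[p] = chr(33 + 10)
            se_qual = "".join(qual)
        pairs.append(ReadPair(
            read_id=f"{accession.accession_id}_{i:07d}",
            se_seq=se, pe_seq=pe, se_qual=se_qual, pe_qual=q40,
            sample_id=accession.accession_id,
        ))
    return pairs


def simulate_libraries(
    accessions: Sequence[DiploidAccession],
    params: SimParams,
    total_pairs: int,
) -> dict[str, list[ReadPair]]:
    """All three samples, read counts proportional to ``depth_weights``."""
    rng = params.rng(2)
    counts = allocate_depth(total_pairs, params.depth_weights, rng)
    return {
        acc.accession_id: simulate_rad_library(acc, params, int(n), rng)
        for acc, n in zip(accessions, counts)
    }


# ---------------------------------------------------------------------------
# Progeny simulation
# ---------------------------------------------------------------------------

@dataclass
class ProgenyMarker:
    marker_id: str
    parent_a: tuple[int, int]  # ordered haplotype alleles
    parent_b: tuple[int, int]
    group: str = "ungrouped"
    cm: float = 0.0


def _gametes(
    markers: list[ProgenyMarker],
    which_parent: int,
    n_progeny: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Haplotype-index walk along each linkage group with Kosambi-inverse
    recombination between adjacent markers; groups independent."""
    n_markers = len(markers)
    out = np.zeros((n_markers, n_progeny), dtype=np.int8)
    order = sorted(range(n_markers), key=lambda i: (markers[i].group, markers[i].cm, i))
    for p in range(n_progeny):
        prev_group = None
        state = 0
        prev_cm = 0.0
        for i in order:
            m = markers[i]
            if m.group != prev_group:
                state = int(rng.integers(0, 2))
                prev_group, prev_cm = m.group, m.cm
            else:
                r = kosambi_inverse(m.cm - prev_cm)
                if rng.random() < r:
                    state = 1 - state
                prev_cm = m.cm
            alleles = m.parent_a if which_parent == 0 else m.parent_b
            out[i, p] = alleles[state]
    return out


def simulate_progeny(
    markers: list[ProgenyMarker],
    n_progeny: int,
    rng: np.random.Generator | int | None = None,
    independent: bool = False,
) -> np.ndarray:
    """Mendelian F1 genotypes: array of shape (markers, progeny, 2) holding
    the maternal and paternal transmitted alleles.

    Markers sharing a ``group`` recombine at the Kosambi-inverse of their
    cM gap; with ``independent=True`` (or all-distinct groups) markers
    segregate independently.
    """
    if n_progeny < 1:
        raise ValueError("n_progeny must be >= 1")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    if independent:
        markers = [dataclasses.replace(m, group=f"__indep{i}")
                   for i, m in enumerate(markers)]
    ga = _gametes(markers, 0, n_progeny, rng)
    gb = _gametes(markers, 1, n_progeny, rng)
    return np.stack([ga, gb], axis=-1)


def genotype_codes(progeny: np.ndarray) -> np.ndarray:
    """Collapse (maternal, paternal) allele pairs to 'a' (0/0), 'h' (het),
    'b' (1/1) codes."""
    total = progeny.sum(axis=-1)
    codes = np.full(total.shape, "h", dtype="U1")
    codes[total == 0] = "a"
    codes[total == 2] = "b"
    return codes


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_fastq_pairs(pairs: Sequence[ReadPair], prefix: str | Path) -> None:
    prefix = str(prefix)
    with open(prefix + "_1.fastq", "w") as f1, open(prefix + "_2.fastq", "w") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.se_seq}\n+\n{p.se_qual}\n")
            f2.write(f"@{p.read_id}/2\n{p.pe_seq}\n+\n{p.pe_qual}\n")


def run_simulation(params: SimParams, outdir: str | Path, total_pairs: int) -> None:
    """Full generator: genome FASTA, per-sample paired FASTQ, truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = simulate_reference(params)
    write_fasta(reference.chromosomes, outdir / "reference.fasta")
    accessions, truth = derive_accessions(reference, params)
    truth.write(outdir)
    for sample_id, pairs in simulate_libraries(accessions, params, total_pairs).items():
        write_fastq_pairs(pairs, outdir / sample_id)
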