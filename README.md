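# radsnp

A toolkit for restriction-site associated DNA (RAD) SNP discovery in a
three-accession design, built around six pieces:

- **`radsnp.simulate`** — synthetic data with full ground truth: a haploid
  reference with planted PstI (CTGCAG) sites, three diverged diploid
  accessions (configurable divergence ≈5.6/kb, per-accession heterozygosity,
  1–2 nt indels, optional restriction-site knockouts and tandem repeat
  families), paired 2×54 bp RAD libraries with unequal per-sample depth, and
  Mendelian F1 progeny genotypes with Kosambi-linked transmission.
- **`radsnp.assembly`** — quality filtering (>5 bases at Phred ≤10 discards a
  read), clustering of single ends at 100% identity with 25–400× coverage
  bounds, per-locus de Bruijn contig assembly over a k sweep with NODE1/NODE2
  alternative labelling, contig filters (≥100 bp, ≥4.0× paired-end coverage,
  no N homopolymers) and assembly statistics (N50, GC, alternative fraction).
- **`radsnp.variants`** — read-pair alignment to contigs (≤3 mismatches,
  ≤2 nt gap per read), per-sample pileups, a comprehensive ≥6× variant list
  (CcRAD1) and its fully informative subset with read support in all three
  samples (CcRAD2), genotype imputation (het: allele frequency 0.25–0.75,
  ≥4× depth, ≥2 reads per allele; hom: minor allele frequency <0.10),
  testcross/intercross marker classification and VCF 4.2 output.
- **`radsnp.kmers`** — k-mer spectra (default k=10) split by CpG content
  (0 / 1 / 2+), random-dinucleotide negative controls, and the
  Karlin–Mrázek CpG rate ρ = f(CG)/(p(C)·p(G)).
- **`radsnp.caps`** — CAPS assay design from SNPs: IUPAC restriction-site
  search over an 11-enzyme panel (incl. type IIS FokI/BccI), allele-
  differential digestion, fragment-size prediction, a ≥20 bp
  fragment-difference gel-detectability rule, and digestion-pattern scoring;
  plus a packaged machine-readable copy of the published validation panel.
- **`radsnp.linkage`** — chi-square segregation tests with mapping-inclusion
  (α=0.01) and distortion (α=0.1) flags, two-point testcross linkage (r̂,
  LOD), the Kosambi mapping function and LOD-threshold single-linkage
  grouping (default LOD ≥6.0, r̂ ≤0.40).

`radsnp.pipeline` wires reads → clusters → reference contigs → pileup →
variant sets → classified markers end to end, and `radsnp.evaluation` maps
assembled contigs back to simulated truth for recovery scoring.

## CLI

```bash
radsnp simulate --config sim.cfg --seed 1 --outdir data --pairs 100000
radsnp assemble --sample A:data/a_1.fastq:data/a_2.fastq \
                --sample B:data/b_1.fastq:data/b_2.fastq \
                --sample C:data/c_1.fastq:data/c_2.fastq \
                --k 21,25,29,33 --min-cov 25 --max-cov 400 --outdir asm
radsnp call --contigs asm/contigs.fasta --sample A:... --sample B:... \
            --sample C:... --min-cov-ccrad1 6 --het-window 0.25:0.75 \
            --outdir calls
radsnp kmer --input asm/contigs.fasta --k 10 --dinuc CG --controls 5 \
            --seed 1 --outdir kmer
radsnp caps --contigs asm/contigs.fasta --vcf calls/variants.vcf \
            --min-frag-diff 20 --product 100:400 --out assays.tsv
radsnp segtest --genotypes genotypes.tsv --out seg.tsv
radsnp group --genotypes genotypes.tsv --lod 6.0 --max-rec 0.40 --outdir lg
```

The simulate config file is `key = value` per line (JSON values), e.g.
`genome_length = 2000000`, `insert_range = [56, 500]`.

## Notes on the simulation geometry

RAD paired-end reads only cover a locus contiguously if some sheared mates
land close to the restriction cut; the simulator's default mate-endpoint
distribution is therefore uniform over (56, 500) nt rather than a hard
300–800 gel window (which would leave the first ~250 nt covered by the
anchored read alone). Pass `insert_range=(300, 800)` and a numeric
`insert_sd` to model a strict truncated-normal size selection.
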