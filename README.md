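# tcskit

A clinical-exome toolkit for Treacher Collins syndrome (TCS) cohorts — and,
more generally, for single-gene Mendelian workups built on whole-exome
sequencing. TCS is a mandibulofacial dysostosis caused by defects in
ribosome-biogenesis genes (*TCOF1*, *POLR1D*, *POLR1C*, *POLR1B*), usually
through loss-of-function alleles. The package implements the bespoke
computations such a study needs downstream of alignment and variant
calling:

- **Exon-level read-depth CNV screening** (`tcskit.depth_screen`): per-base
  coverage (samtools-depth style TSV) is reduced to per-exon arithmetic
  means (missing bases excluded), each sample is library-size scaled, and a
  test sample's relative coverage is divided per exon by the control-cohort
  median. A single lost copy sits near a normalized ratio of
  r = c/2 = 0.5; states are assigned by configurable ratio bands
  (het-del band [0.35, 0.65] by default) and consecutive non-diploid exons
  merge into one candidate segment.
- **Transcript coordinate models** (`tcskit.genome_model`): ordered exons
  with paired genomic (0-based half-open) and coding (c.) intervals,
  c.-to-genomic mapping with intronic offsets, BED and exon-table I/O. The
  nine-exon *POLR1C* model (GRCh38, chr6, + strand, CDS 1275 nt) is built
  in.
- **HGVS consequence arithmetic** (`tcskit.hgvs`): parsing of c.
  substitutions, insertions, deletions and splice-boundary variants;
  sequence editing, translation and codon-by-codon comparison; frameshift
  fs\*N nomenclature with stop position = first_affected + N − 1 (e.g.
  p.Arg77Ilefs\*97 → stop at residue 173); canonical ±1/±2 donor/acceptor
  classification.
- **ACMG/AMP classification** (`tcskit.acmg`): the published five-tier
  combining clauses over PVS/PS/PM/PP and BA/BS/BP evidence, triage filters
  (allele frequency > 0.01%, inheritance mode, < 2 matching
  manifestations), LOF double-count warnings, and evidence suggestion from
  computed consequences.
- **Pedigree and cohort analysis** (`tcskit.pedigree`, `tcskit.cohort`):
  autosomal-dominant segregation checking, informative-transmission counts
  for PP1 co-segregation, phenotype-frequency tables and diagnostic yield.
- **Synthetic data** (`tcskit.simulate`): seeded generators for every input
  class — Poisson exome coverage with sample and exon biases and embedded
  copy-number events, random complete CDSs, random AD pedigrees, and the
  fixed eleven-patient TCS cohort fixture.

## Worked example

Simulate a 15-sample cohort (14 diploid controls plus one carrier of a
single-copy deletion over *POLR1C* exons 1–2) at ~100× and screen each
sample against the rest:

```python
from tcskit import CnvScreen, DepthSimConfig, polr1c_transcript, simulate_depth_cohort

t = polr1c_transcript()
cfg = DepthSimConfig(cnv_events=(("T01", (1, 2), 1),), seed=1)
depth, truth = simulate_depth_cohort(t, cfg)
print(CnvScreen(depth, t).fit().summary())
```

```
CNV screen: POLR1C (ENST00000642195.1), 9 exons, 15 samples
het_del band [0.35, 0.65], hom_del <= 0.15, dup >= 1.35
candidate segments: 1
sample chrom exon_span  c_span  mean_ratio   state  n_exons confidence
   T01  chr6       1-2 c.1-162      0.4999 het_del        2         ok
```

The screen recovers exactly the planted segment: sample T01, exons 1–2
(c.1–162), mean normalized ratio 0.4999 ≈ 0.5, the one-copy expectation.

Variant consequences and classification:

```python
from tcskit import CodingSequence, combine, consequence, fs_stop_position, parse_c

cds = CodingSequence("toy", "ATGAAAGTTGACTAA")          # MKVD*
consequence(cds, parse_c("c.6_7insC")).hgvs_p           # 'p.Val3Argfs*2'
fs_stop_position("p.Arg77Ilefs*97")                     # stop_position=173
combine({"PVS1", "PM2", "PP4"}).tier                    # 'pathogenic'
```

The insertion shifts the frame at residue 3 and the new frame terminates
two codons in (stop at protein position 4); the fs\*N arithmetic places
the p.Arg77Ilefs\*97 stop at residue 173; and a very-strong LOF criterion
plus one moderate and one supporting criterion combine to a pathogenic
verdict.

A command-line interface mirrors the library
(`tcskit simulate | cnv-screen | annotate | classify | ped-check |
summarize`); run `tcskit --help`.

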