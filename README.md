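# exrte

Genome/transcriptome survey of **expressed LTR retrotransposons (exRTEs)**.

Most LTR retrotransposons in a plant genome are transcriptionally silent;
a small minority are expressed, and a subset of those still move. This
package implements, as a tested and reusable pipeline, the analysis that
separates the two groups and characterises what distinguishes them:

1. **Candidate catalog** — parse LTRdigest-style GFF3 annotation, keep
   elements > 500 bp with similarity to at least one canonical
   retroelement protein (GAG, AP, INT, RT, RH), and collapse copies with
   > 95% global-alignment identity.
2. **Expression calling** — per-sample RPKM
   (`reads · 10⁹ / (length · library size)`) and breadth of coverage
   (fraction of bases at depth ≥ 1). An element is an exRTE when
   RPKM ≥ 0.25 in ≥ 1 sample, breadth ≥ 60% in ≥ 1 sample, and it carries a
   protein-domain match of ≥ 50 aa; everything else in the catalog is an
   n-exRTE.
3. **Insertion dating** — align the element's 5′ and 3′ LTRs; from the
   transition frequency *p* and transversion frequency *q* compute the
   Kimura two-parameter distance
   `k = −½ ln[(1 − 2p − q)·√(1 − 2q)]` and the insertion time
   `T = k / 2r` with `r = 1.3 × 10⁻⁸` substitutions·site⁻¹·year⁻¹;
   elements with `T < 0.5 Myr` are *recent*.
4. **ORF / motif screen** — six-frame start-to-stop ORFs ≥ 300 nt, domain
   labelling, and a scan for the CCHC zinc-knuckle RNA-binding motif
   `CX₂CX₄HX₄C` in GAG proteins; the screen's FDR is the motif frequency
   among non-GAG ORFs.
5. **Gene proximity** — distance to the nearest annotated gene with four
   categories: insertion (inside a gene), overlapped, close (< 1 kb),
   distant (≥ 1 kb).
6. **Mobilome (ACM)** — per-cultivar genomic depth normalised by
   single-copy reference genes, divided by the element's minimum across
   cultivars (the ACM ratio). Elements above the cutoff in > 1 cultivar
   form the mobile group 1.
7. **Enrichment statistics** — two-sided Fisher exact tests (minimum-
   likelihood convention, log-factorial arithmetic) and Wilcoxon rank-sum
   tests comparing the exRTE and n-exRTE sets.

A first-class **synthetic-data generator** plants all of the above in a toy
genome with full ground truth — LTR pairs diverged at controlled
transition/transversion rates, ORFs with recognisable domain tags and
controlled motif counts, expression evidence realising target RPKM and
breadth, per-cultivar depth realising copy-number multipliers, and genes at
controlled distances — so every stage is testable offline.

## Worked example

```sh
$ exrte simulate --out demo --seed 7
wrote 50 elements to demo

$ exrte run --dataset demo --out demo_out
exRTEs: 15  n-exRTEs: 35
```

`demo_out/summary.json` records the filter funnel — 50 annotated elements,
50 candidates, 32 passing the RPKM screen, 23 also passing the breadth
screen, 15 surviving the domain-length curation and redundancy removal —
exactly the 15 elements the generator planted as expressed (5 detected only
in non-stressed samples, 5 only in stressed, 5 in both). Per-stage tables
(`catalog.tsv`, `expression.tsv`, `age.tsv`, `orfs.tsv`, `proximity.tsv`,
`acm.tsv`, `enrichment.tsv`) hold every intermediate quantity.

The statistics are available stand-alone. The recency contingency table
(21 of 44 exRTEs recent vs 5,932 of 29,037 + 5,932 n-exRTEs):

```sh
$ exrte fisher 21 23 5932 29037
p = 2.38424e-06  OR = 4.46933

$ exrte percent 25 44
57% (56.8182%)
```

i.e. recent insertions are strongly enriched among expressed elements
(odds ratio ≈ 4.5), and 25 of 44 mobile-group elements is reported as 57%.

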