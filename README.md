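# ampliskip

Quantification of exon skipping in long-read cDNA amplicon sequencing, with
allele-specific phasing.

## The problem

Intronic splice-region variants (the motivating case is *PHYH*:c.678+5G>T,
associated with adult Refsum disease) can weaken a splice donor without
abolishing it. RT-PCR of the affected transcript followed by nanopore
long-read sequencing captures every splice isoform of the amplicon in single
reads, so the *fraction of transcripts* affected — and, when a coding SNV
distinguishes the two alleles, the fraction affected *per allele* — can be
measured directly. `ampliskip` implements that analysis as a reusable,
tested pipeline:

1. **Read QC** — keep reads within a closed length window (default
   800–1800 bp) whose mean Phred quality, computed in error-probability
   space, is ≥ Q10.
2. **Isoform classification** — with one known amplicon and an enumerable
   candidate set (full-length, skip exons 5+6, skip exon 6), each read is
   globally aligned (unit-cost edit distance, via edlib) to every candidate
   and assigned to the nearest one subject to a distance ceiling
   (≤ 0.20 × isoform length) and a best-vs-second margin (≥ 20 nt); anything
   else is `other`.
3. **Allele phasing** — each called read is genotyped at a coding SNV by
   reading the base its alignment places at the SNV's isoform-relative
   offset (bases below Q10 at the site are treated as noise). Reads whose
   isoform skips the SNV's exon are *unphasable by structure*.
4. **Estimation** — per-allele skipping fractions, either **direct**
   (SNV in a retained exon: a simple row ratio of the allele × isoform
   contingency table) or **indirect** (SNV inside the skipped exons:
   `S / (S + I)` where `S` = skipped reads, all attributed to the splice
   allele, and `I` = phased splice-allele full-length reads), plus allele
   balance and overall isoform fractions.
5. **Frame annotation** — skipping exons 5+6 removes 264 coding nt
   (264 mod 3 = 0: in-frame, 88 residues); skipping exon 6 alone removes
   182 nt (182 mod 3 = 2: frameshift).

A seeded synthetic-data module generates truth-labeled ONT-like reads
(substitution/insertion/deletion noise with two-level per-base qualities)
from biallelic isoform mixtures, so the whole pipeline is testable without
deposited data.

## Worked example

Simulate a compound-heterozygote sample (splice allele carrying c.823C at
36.4 % read share, skipping exons 5+6 in 85.3 % of its transcripts; trans
allele c.823T, no skipping) and run the pipeline:

```sh
ampliskip simulate --config examples/patient1.json --out scratch/p1 \
    --n-reads 3000 --seed 31
ampliskip run --fastq scratch/p1.fastq --config examples/patient1.json \
    --out-dir scratch/p1_out --sample-id p1
```

The Markdown report printed by `run` (same numbers as
`scratch/p1_out/p1.report.json`):

```
# Sample p1

## Read QC

- input reads: 3000
- kept: 3000 (length failures: 0, quality failures: 0)

## Isoform fractions

- full: 70.7%
- skip56: 29.3%
- skip6: 0.0%
- other: 0.0%

## Allele balance (phased reads)

- splice_allele: 33.9%
- trans_allele: 66.1%

## Per-allele skipping estimates

- splice_allele (direct, n=894): skip56 84.6%, skip6 0.0%, total skipped 84.6%
- trans_allele (direct, n=1745): skip56 0.0%, skip6 0.0%, total skipped 0.0%

## Frame consequences

- skip56: in-frame deletion of 264 nt (88 residues)
- skip6: out-of-frame deletion of 182 nt (frame offset 2)
```

Reading it: 29.3 % of all reads skip exons 5+6, but phasing shows the
skipping is confined to the splice allele (84.6 % of its reads vs 0.0 % on
the trans allele, estimates within binomial noise of the simulated truth),
and the resulting deletion is in-frame — a hypomorphic rather than null
effect. Intermediate tables (per-read calls, the allele × isoform counts,
junction support in TSV/BED12, QC stats) are persisted next to the report.

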