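# Methods

## The measurement model

A single RT-PCR product (cDNA of the canonical *PHYH*-like transcript, exon
1 through the 3′UTR) is sequenced on a long-read platform so that each read
spans the entire amplicon. Because the amplicon and its plausible splice
isoforms are fully enumerable, read interpretation reduces to three closed
sub-problems: (i) is the read good enough to use, (ii) which candidate
isoform does it represent, and (iii) which allele did it come from. All
downstream quantities — overall skipping fractions, allele balance, and the
per-allele skipping estimates — are ratios of cells of the resulting
(allele × isoform) contingency table, which the pipeline persists so every
reported number can be recomputed from it.

## The amplicon model

A transcript model is an ordered list of exons with a CDS anchor.
Coordinates are HGVS-style c.-numbering (1-based inclusive) on the outside
and 0-based half-open amplicon offsets on the inside. The default model has
nine exons of lengths 150, 110, 104, 110, 82, 182, 160, 120, 165 nt
(1183 nt total), a 60 nt 5′UTR in exon 1 and a 1023 nt CDS leaving a 100 nt
3′UTR in exon 9. The two biologically anchored facts are exon 6 = 182 nt
(c.497–678, fixed by the c.678+5 donor) and exon 5 = 82 nt (c.415–496, so
that skipping both removes 264 nt). The flanking exon sizes are a
convention of this package, chosen so that all three isoform lengths
(1183 / 919 / 1001 nt) sit inside the default QC length window and so that
the phasing SNV at c.823 falls in exon 7, which every skipping isoform
retains. Frame arithmetic counts CDS bases only; skipping sets that touch a
UTR-only exon are rejected rather than guessed.

## Synthetic reads

The simulator emulates sequencing of a biallelic isoform mixture. Each read
independently draws its allele (by allele weight), then its isoform (by the
allele's isoform weights), plants the allele's SNV base wherever the
containing exon is retained (a skipped exon simply lacks the site — no
sentinel), and is corrupted by independent per-base events:

| parameter | default | meaning |
|---|---|---|
| `sub_rate` | 0.03 | substitution probability per base |
| `ins_rate` | 0.02 | insertion probability per inter-base slot |
| `del_rate` | 0.02 | deletion probability per base |
| `quality_correct` | Q14 | Phred value of faithful bases |
| `quality_error` | Q7 | Phred value of substituted/inserted bases |

The ~7 % total error with two-level qualities mimics the dominant features
of ONT R9/R10 cDNA reads that matter to this pipeline: edit distances of
~7 % of read length and informative (if coarse) per-base qualities. It does
**not** model homopolymer-conditioned errors, chimeras/template switches,
strand effects (all reads are forward; the amplicon is one PCR product), or
RNA degradation. Passing tests therefore demonstrate correctness of the
classification/phasing logic under realistic error *rates*, not robustness
to every artifact of real libraries. One seeded NumPy generator drives each
simulation; identical configuration and seed give byte-identical FASTQ and
truth tables.

With the default error model the mean read quality in probability space is
≈ Q13, so simulated reads pass the Q10 filter; QC quality rejection is
exercised with explicitly constructed low-quality reads.

## Read QC

Reads are kept iff their length lies in the closed interval
[`min_len`, `max_len`] (defaults 800–1800 nt) **and** their mean quality is
at least `min_mean_q` (default Q10). Mean quality is
−10·log10(mean 10^(−qᵢ/10)) — the error-probability mean used by standard
long-read filters — which by Jensen's inequality never exceeds the
arithmetic Phred mean; the two disagree, and the probability-space form is
deliberately the implemented one. A read failing both checks counts as a
length failure, making the QC stats a deterministic partition. The quality
comparison carries a 1 × 10⁻⁹ slack so a read sitting exactly on the
threshold is kept despite the probability round trip losing the last ulp.

## Isoform classification

Each read is aligned end-to-end (unit-cost Levenshtein, edlib's NW mode)
against every candidate isoform sequence. The best candidate is called iff

* best distance ≤ `max_norm_dist` × isoform length (default 0.20, ~3× the
  simulated error rate), and
* (second best − best) ≥ `min_margin` (default 20 nt; the smallest
  structural difference between candidates is 82 nt, so genuine reads clear
  it easily and ties are never broken arbitrarily).

Everything else is `other`, a first-class category. Overall fractions are
reported with two denominator conventions — all accepted reads including
`other` (default) and known-isoforms-only — because published percentages
rarely state which was used; both appear in every report.

## Allele phasing

The genotyper re-aligns the read to its called isoform, walks the CIGAR to
the SNV's isoform-relative offset, and reads the base there. Outcomes:
allele base → phased; gap or third base → unphased (noise); SNV exon
skipped by the called isoform → unphased (structure). Unphased-by-noise
reads are excluded from allele-level estimates entirely; only
unphased-by-structure reads enter the indirect estimator.

**Site base-quality gate.** Bases below `min_base_quality` (default Q10,
0 disables) at the SNV site are treated as noise. This default is a
deliberate design choice: a substitution error at the site does not merely
drop a read, it silently assigns it to the *wrong* allele, and because the
trans allele typically contributes the majority of full-length reads, the
resulting flips systematically deflate the splice-allele skipping estimate
(measured at ≈ 2.5–3.5 percentage points under the default error model).
Erroneous bases carry low quality, so the gate removes the flips at the
cost of a ~1 % loss of correctly read sites, leaving the direct estimator
unbiased to within ~0.3 pp.

## Estimators

* **Direct** (SNV retained everywhere): fraction = n[allele][isoform] /
  Σ n[allele][·]. An empty row yields an explicitly *undefined* estimate,
  never 0.
* **Indirect** (SNV inside the skipped exons): skipped reads cannot be
  phased, so all of them are attributed to the splice allele and
  fraction = S / (S + I) with S = skipped reads and I = phased
  splice-allele full-length reads. The attribution assumption (trans allele
  shows no skipping, as observed wherever direct phasing is possible) is
  recorded on the estimate object and in reports rather than silently
  applied.
* **Allele balance**: each allele's share among phased reads only.

Known property of the indirect estimator: S is never thinned by phasing
dropout (skipped reads need no phasing) while I is (≈ 10 % of inclusion
reads fail phasing by gaps/third bases under the default error model), so
the indirect estimate runs slightly above the direct one — about
1.9 percentage points at the study's conditions. The masked-phase
consistency check quantifies exactly this. The discrepancy is inherent to
the estimator's definition, shared by the equivalent manual calculation on
real data, and documented rather than corrected, since correcting it would
require an estimate of the phasing dropout rate that real analyses of this
kind do not make.

Binomial sampling noise dominates all simulation-based checks; tolerances
in the test suite are 3 binomial standard deviations at the relevant
support size.

## Problem sizes

Simulation-based tests use 10,000 reads for end-to-end parameter recovery,
20,000 for the indirect-vs-direct consistency check (2 pp tolerance), and
200–3,000 reads for targeted behaviours (oracle equivalence on short reads,
control-level skipping, homozygote junction support). These sizes put
3-SD binomial tolerances at or below ~2 pp, comparable to the per-patient
read counts the measurement design targets.

## Known limitations

* Frame annotation is arithmetic only (deleted nt mod 3); it does not scan
  for the downstream premature stop codon, which requires the real CDS
  sequence.
* One phasing SNV per run is used by the pipeline (the first configured);
  multi-SNV haplotype assembly is out of scope.
* No PCR-duplicate or chimera modeling; uncertainty reporting is limited to
  read-count support (binomial-scale reasoning is left to the caller).
* Novel-isoform discovery is out of scope: a read is either one of the
  configured candidates or `other`.
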