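# Methods

## Study design the package models

The unit of analysis is a *discordant sib pair*: a patient with early-onset
lung cancer and never-smoker status, and an unaffected full sibling used as
an intra-familial control. Full sibs share on average half of their
heterozygous germline variants, so variants observed in the patient's
blood exome but absent from the sibling's are enriched for private
susceptibility alleles. The package adds two tumor-derived readouts for
each patient — a tumor exome (somatic mutations; zygosity at candidate
loci) and tumor/normal RNA-seq (FPKM) — and integrates the three into a
per-patient candidate table with a functional annotation per variant.

The model is deliberately oligogenic: no burden statistic or cross-family
aggregation is computed. Each patient's output is their own list of
candidate variants; the cohort summary only pools and de-duplicates.

## Prioritization cascade

Six stages, applied in order to the affected sib's annotated variant
table; each is a pure filter, so the composition equals the conjunction of
the six predicates (a property the tests verify against a brute-force
single-pass implementation).

| stage | rule | default |
|---|---|---|
| coverage | total read depth ≥ `min_depth` | 10 reads |
| exonic/rare | exonic consequence and (MAF ≤ `max_maf` or MAF unreported) | 0.01 |
| benign/in-house | drop `benign`/`likely_benign` and in-house DB keys | — |
| deleterious | truncating (frameshift indel, nonsense) pass; missense needs CADD ≥ `cadd_min` and MetaSVM = D; synonymous never pass | CADD 20 |
| discordant | key absent in the sibling, or hom-ref there with depth ≥ `min_depth` | — |
| panel | gene in the cancer-predisposition panel (case-insensitive) | — |

Notes on choices that were genuinely open:

* **"Low coverage" quantified at 10 reads.** A common germline exome
  heuristic; configurable, and the packaged example is insensitive to it
  within a wide band.
* **CADD cutoff 20** (top 1% scaled deleteriousness) with MetaSVM
  conjunction for missense. Ensemble missense scores are undefined for
  truncating variants, which therefore pass unconditionally under the
  default `truncating_or_scores` rule; `cadd_or_svm` and `cadd_and_svm`
  apply the score rule to all non-synonymous variants instead.
* **Absent annotations are an explicit state**, never zero: an unreported
  population frequency is treated as rare (configurable), an absent CADD
  fails the missense score rule.
* **Discordance for unobserved sites.** Exome tables rarely carry
  reference blocks, so a key missing from the sibling's table counts as
  absent. When the sibling does carry a hom-ref record, it must meet the
  depth threshold to confirm absence; a shallow hom-ref call removes the
  candidate. This is conservative and is a documented limitation of
  table-level (rather than read-level) discordance.
* **Direction.** `affected_only` is the susceptibility screen;
  `unaffected_only` runs the symmetric protective screen.

Candidate order is deterministic (chromosome, position, alt allele), and a
`FilterTrace` records input/output counts plus removed keys per stage,
including the truncating/missense split at the deleterious stage.

## Somatic extraction and LOH

Somatic calling is table subtraction: tumor records whose key is absent
from blood (or hom-ref there). No probabilistic caller is re-implemented —
the inputs are already-called per-sample tables. Tallies count missense,
frameshift indel and nonsense within coding consequences.

LOH at a germline candidate locus requires blood het and tumor
homozygous-alt, where the tumor side is satisfied by the recorded genotype
state or by an alt-allele fraction ≥ `min_hom_af` (default 0.8). The 0.8
default tolerates moderate normal-cell contamination without estimating
purity; `min_hom_af` must exceed 0.5, since anything at or below it cannot
distinguish LOH from a balanced heterozygote. Tumor purity is never
estimated from data — the simulator exposes a purity parameter that scales
the expected LOH allele fraction (`p·1 + (1−p)·0.5`), and nothing else
consumes it.

## Expression significance and classification

FPKM values are compared on log2 scale with a pseudocount (default 0.1
FPKM) guarding zero values. The control-normal group C (≥ 2 samples,
default 5 in simulation) calibrates the variance; T and N are single
observations, as in the matched-pair design being modelled:

* `p_t_vs_c`, `p_n_vs_c`: prediction-interval t statistic
  `(x − mean_C) / (s_C · sqrt(1 + 1/m))` with `m − 1` degrees of freedom,
  two-sided.
* `p_t_vs_n`: `(x_T − x_N) / (s_C · sqrt(2))`, same df — the difference of
  two single observations whose variance is borrowed from C. Whether the
  tumor-vs-normal p should instead come from a transcript-level model is a
  modelling choice; the `method` parameter records it, and a
  `permutation` alternative (exact rank of the observation among the
  pooled controls; pairwise control differences for the T-vs-N contrast)
  is provided. Rank p-values are exactly super-uniform under
  exchangeability, which the tests verify at 2,000 null genes.

Degenerate inputs: identical controls (zero spread) give p = 1 for a value
equal to the control mean and p = 0 otherwise; this is what makes
noise-free simulations recover planted labels exactly.

Classification of a candidate's gene, with linear fold threshold
`min_fold` (default 2) and `alpha` 0.05, checked in this order:

1. `BOTH_DOWN` — T ≤ C/fold and N ≤ C/fold, both p-vs-C ≤ α
   (transcript instability in the carrier);
2. `TUMOR_DOWN` — T ≤ N/fold, p(T vs N) ≤ α (second hit);
3. `TUMOR_UP` — T ≥ N·fold, p(T vs N) ≤ α (oncogene-like);
4. `NO_CHANGE` otherwise.

`BOTH_DOWN` must pre-empt the tumor-vs-normal contrasts: when the matched
normal is itself depressed, T-vs-N is uninformative. The fold conditions
use raw FPKM (exactly scale-invariant); only the p-values see the
pseudocount, so classification is scale-invariant away from the α decision
boundary. The numeric rule separating the three patterns is this package's
formalization; the genome-wide DE thresholds (|fold| ≥ 2, p ≤ 0.05) are
applied to the per-gene patterns as well.

A `NO_CHANGE` truncating variant in a putative tumor suppressor can be
kept on the RNA-effect panel through an explicit retain-list (the worked
example retains URI1). This is an opt-in judgment call, never an
automatic rule.

## Enrichment and networks

Over-representation is the one-sided hypergeometric upper tail; the EASE
variant decrements the overlap by one (an overlap of 1 is evaluated at 0
and scores p = 1). Benjamini–Hochberg q-values are assigned across the
tested sets. Exact annotation-database statistics of web services are out
of scope — gene sets are user-supplied GMT.

The candidate network is the induced subgraph of a user-supplied edge list
on the candidate genes; components of size ≥ 2 are reported with the set
of owning cases. Expansion adds up to `k` (default 20) outside
interactors ranked by (connections to current nodes, total degree, symbol)
— a deterministic tie-break. Edge provenance labels are carried as opaque
strings; no evidence-score thresholding is applied.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with one seeded `numpy` generator and no global state:

* background het variants shared between sibs per-variant
  Bernoulli(`sib_share_prob` = 0.5) — recombination-aware haplotype blocks
  are deliberately not modelled, because the analysis uses no linkage
  information;
* per-case signature sizes fixed or Poisson(mean 10); planted variants
  are annotated with wide margins past every default threshold, and every
  background variant violates at least one threshold by construction, so
  cascade recovery is exact by design (sensitivity 1, zero false
  positives), which is what the recovery tests assert;
* somatic draws with class proportions 1092 : 374 : 43
  (missense : frameshift indel : nonsense), checked against multinomial
  bands at n = 10,000;
* LOH conversions with expected-count allele depths (exact detection at
  purity 1, deterministic degradation away from it);
* log-normal FPKM (sigma 0.25 natural-log units) around class-specific
  means with planted fold 4 and a 5-sample control group.

What the simulator does **not** emulate — and what passing recovery tests
therefore do not demonstrate about real data: annotation errors and
caller-specific artifacts, mutational spectra and trinucleotide context,
clonal heterogeneity, linkage between nearby variants, batch effects in
FPKM, and any correlation between a variant's deleteriousness annotations
and its gene's expression behaviour. Separability of planted from
background variants is by construction; real cascades lose true positives
at every stage.

## Problem sizes and known limitations

The default test-suite problem sizes (hundreds to a few thousand variants
per table, 2,000 null genes, 10,000 somatic draws) were chosen as the
smallest sizes at which the statistical checks have meaningful resolution;
the whole suite runs in seconds.

* With the minimum control group (m = 5, df = 4) the location test is
  underpowered at fold 4 under default noise: macro-averaged class
  recovery falls slightly below 0.9, recovering comfortably by m = 10.
  The property test documents and exercises the larger group.
* The worked example's genomic coordinates, alleles, depths and FPKM
  values are synthetic placeholders keyed to authentic cDNA notations;
  its transcription choices for the three variants shared between two
  cases (and a companion ESRRA notation) are recorded in
  `WorkedExample.metadata`, including the alternate assignment reading.
* Variant identity is (chrom, pos, ref, alt) with left-normalized indels
  assumed on input; no liftover or normalization is performed internally.
* The pipeline consumes annotations (CADD, MetaSVM, MAF, clinical
  significance); it never computes them, and disagreements between
  annotation sources are out of scope.
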