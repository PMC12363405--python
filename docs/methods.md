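# Methods

This note documents the models, parameter choices and numerical decisions
behind `ctdna_mrd`, in the spirit of a methods supplement: what is being
simulated, how each statistic is computed, and what the validation studies
do and do not demonstrate.

## The assay being modelled

The package models a tumour-informed liquid-biopsy workflow for aggressive
B-cell lymphoma built on a hybrid-capture panel: 42 recurrently mutated
genes (~300 bp targets in the desk-scale design) for somatic variant
discovery, plus a genome-wide backbone of 1040 common SNPs used for
copy-number analysis and sample-identity fingerprinting. Library molecules
carry 10-nt unique molecular identifiers (UMIs); reads sharing a mapping
position, strand and UMI are PCR/sequencing copies of one plasma cfDNA
fragment, and a majority vote across them cancels most sequencing error.
Downstream, everything is counted in *consensus molecules*, each
representing one original cfDNA fragment.

## Synthetic data generator

The generator produces every input the pipeline consumes, with sidecar
truth tables that reconcile exactly with the emitted reads.

**Fragments.** Source molecules are placed uniformly within their capture
target with truncated-normal lengths (mean 167 bp, sd 40, bounds
50–400 bp) — the canonical mononucleosomal cfDNA size distribution. Reads
are emitted pre-aligned with match-only CIGARs; alignment is outside the
model's scope, which isolates the assay computation from aligner
behaviour.

**UMI families.** Family sizes follow a shifted negative binomial
(minimum 1; default mean 4, dispersion 2), the usual overdispersed model
of PCR duplication. With these defaults ~65% of molecules yield a family
of ≥3 reads; `molecules_for_consensus_depth` inverts this survival
fraction when a simulation must hit a prescribed consensus depth.

**Errors.** Each sequenced base flips independently with probability
`per_base_error` (default 0.003) to one of the three other bases. Quality
scores, indel errors, duplex chemistry and GC bias are deliberately out of
scope; consequences are discussed under *Limitations*.

**Somatic content.** A molecule covering a planted variant carries its alt
allele with probability `VAF x tumour_fraction`. Variants declared as a
cis pair co-occur on the same carrier molecule (co-occurrence probability
configurable, default 1.0 — the model describes cis detection, not trans
contamination). Germline backbone genotypes are Hardy–Weinberg draws from
the population allele frequency (default 0.5, as fingerprinting panels
select maximally informative SNPs).

**Dilution series.** Two simulated individuals are mixed at a fraction
`f`; interrogated sites are those where the minor individual contributes
the alt allele (expected VAF `f` at hom-alt sites, `f/2` at het sites).
Every fragment covers its interrogated site, so consensus depth per site
equals the surviving-molecule count. The modelled spike-in depth
(~5000 consensus molecules/site over 101 sites) is a design choice of this
artifact; the corresponding wet-lab input mass is not part of the model.

**Clinical cohorts.** Progression times are exponential with an
EMR-dependent hazard (defaults 0.0037/month with EMR vs 0.034/month
without, i.e. a protective hazard ratio ≈ 0.11), censored administratively
at 50 months; baseline burden is log-normal (median ≈ 530 hGE/mL, IQR
≈ 280–2070). EMR patients drop ≥ 2 log10 in burden by the early
timepoint by construction.

**Determinism.** All randomness flows from one seed through labelled,
hash-stable substreams; regenerating any sample or study with the same
seed is byte-identical.

## Consensus calling

Families key on (contig, 5' start, strand, UMI). By default UMIs must
match exactly; an optional directional merge absorbs a family into a
larger one at the same position when the UMIs are within the configured
Hamming distance and `size_small <= size_large/2 + 1`, the standard model
of UMI sequencing errors producing low-count satellites.

Families below `min_family = 3` reads are discarded. At each covered
position the consensus is the plurality base among covering members when
its fraction reaches 2/3; ties and weaker pluralities are masked to N
(conservative masking rather than fabricating a base; the threshold is a
package choice). Retained molecules count once downstream regardless of
family size.

Two implementations exist and are property-tested for equality: an
explicit per-read path, and a columnar engine that stores reads as sparse
differences against the reference and votes only at positions where some
member differs from it. The engine is exact — everywhere else the vote is
unanimously reference — and is what makes hundreds of millions of
simulated bases tractable on one CPU.

**Background error model.** The post-consensus background is pooled over
designated variant-free positions flanking interrogated sites: rate =
Σ most-frequent-alt molecules / Σ informative molecules, floored at
`0.5/Σ` when no alt molecule is observed so that downstream binomial
tests stay defined. Sites overlapping a germline variant are excluded.
Under the default error and family-size settings the realised
post-consensus background is ~2–7×10⁻⁶, dominated by families of exactly
three reads in which two members share a coincident error (probability
≈ e² per base), several hundred-fold below the raw rate.

## Variant analysis

**Discovery** is a one-sided binomial tail test of the alt consensus count
against the background rate, requiring ≥ 2 alt molecules, Bonferroni
corrected across all tested panel positions. Tumour/normal subtraction
uses matched buccal genotypes: a buccal VAF ≥ 0.20 flags the call
germline; calls without buccal coverage are retained but flagged
unevaluable. Only SNVs are modelled; variant identity is
(contig, position, ref, alt), so no indel normalisation is needed.

**Tracked genotyping** for longitudinal monitoring is threshold-free:
counts are reported for every baseline reporter at every timepoint, with
zero coverage reported as *missing* — distinct from an observed VAF of 0.

**Phased pairs.** All somatic variant pairs within 100 bp (inclusive,
1-based positions) on one contig are evaluated; a pair is reported when at
least one consensus molecule carries both alt bases. Joint observation of
two variants on one molecule is quadratically unlikely under independent
background errors, which is what makes phased variants a
sensitivity-enhancing MRD signal.

## Quantification, EMR and MRD

Burden follows the CAPP-Seq convention:

    hGE/mL = cfDNA (ng/mL) x 1000 / 3.3 (pg per haploid genome) x mean reporter VAF

The 3.3 pg constant and the mean (not median) across reporters are package
choices, configurable; they are the single most consequential convention
in the quantification layer.

**EMR** is a ≥ 2 log10 drop (boundary inclusive) from baseline to the
early cycle-1 draw; draws outside day 7–22 warn. Undetected early samples
are imputed at a fixed floor (default 1 hGE/mL) before the log ratio — a
reproducible absolute floor rather than a depth-dependent limit; a
depth-dependent alternative (`0.5/informative x cfDNA hGE`) is available.
An undetected baseline makes EMR unevaluable.

**MRD** is positive when either (a) the aggregate binomial test of summed
alt vs summed informative molecules across reporters beats the background
at α = 0.05 *and* at least two distinct reporters show signal (guarding
against single-site artifacts), or (b) at least one consensus molecule
carries both members of a known phased pair. Below 1000 informative
molecules the call is unevaluable. Rule (b) is an explicit
operationalisation of phased-variant MRD evidence; the single-molecule
threshold reflects the near-zero joint background rate. Reporters judged
likely CHIP (e.g. variants persisting at high VAF through remission) can
be excluded via an explicit list; no automated CHIP classifier is
attempted.

## Copy number, LOH and identity

Backbone depths are library-size normalised (per-sample median), divided
by a panel-of-normals reference profile (median of ≥ 3 normals) and
log2-transformed. Calls are made per chromosome arm: gain/loss when the
arm median exceeds ±0.3 (CNVkit-customary thresholds) *and* a sign test
across the arm's loci rejects symmetry at 0.05, with ≥ 5 usable loci.
Arm-level calling replaces circular binary segmentation deliberately: the
recurrent lesions in this disease are arm/segment scale. The expected
log2 for a clonal segment, `log2((1-tf) + tf*copies/2)`, is exposed for
test oracles only — tumour fraction is not jointly estimated.

LOH is flagged when the mean |BAF − 0.5| at germline-het loci in a
segment reaches 0.15 with ≥ 5 informative loci (a one-copy loss at
tumour fraction 0.5 gives deviation 1/6).

Identity QC bins VAFs at backbone loci with ≥ 20 molecules into
hom-ref/het/hom-alt (< 0.1 / 0.1–0.9 / > 0.9) and computes call
concordance over co-called loci; < 0.80 raises the mislabel flag. Under
Hardy–Weinberg at allele frequency 0.5, unrelated individuals agree at
only Σ genotype-frequencies² = 0.375, so the flag separates cleanly from
same-individual resampling (> 0.95).

## Outcome statistics

Implemented from first principles over the pooled event-time table, with
`lifelines` and `scipy` used as independent cross-checks in the test
suite only:

- **Fisher exact (2×2),** two-sided by the minimum-likelihood rule: the
  sum of hypergeometric probabilities not exceeding the observed table's.
  This convention reproduces p = 0.0014 for the EMR×CMR table
  [[8,0],[1,7]].
- **Kaplan–Meier** product-limit, ties resolved events-before-censors.
  The median is the first time the curve reaches 0.5; undefined if never.
- **Log-rank**: U = Σ(O−E) over pooled event times with the
  hypergeometric variance, χ² on 1 df.
- **Mantel–Haenszel hazard ratio** (O_A/E_A)/(O_B/E_B) with
  se(log HR) = √(1/E_A + 1/E_B) on the log scale. The Peto-style
  alternative (se = 1/√V) gives near-identical intervals at these sample
  sizes. With zero events in one group the estimate degenerates to 0/∞
  and a one-sided interval is returned with a warning.
- **Reverse-KM follow-up**: the KM median with the censor flag inverted.
- **Pearson r** by the product-moment formula.

Patients with EOT response "NA" are excluded from response contingency
tables (response unassessable), which is why the non-EMR denominator in
the bundled cohort is 8 rather than 9. Progression events are relapse,
progression or death from any cause.

The null-calibration study for the log-rank test uses exponential event
times with administrative censoring at 30 months (n = 100 per group).
With heavy late-tail random censoring the χ² approximation is measurably
anticonservative at this sample size (an implementation-independent
property, confirmed against `scipy.stats.logrank`), so the trial-style
administrative design is used for level checks.

## Validation studies and problem sizes

The `studies` module runs the analytical-validation experiments end to
end; the numbered `analysis/` scripts and `scripts/acceptance.py` are
thin drivers over it. Default sizes: spike-in at 0.2% over 101 discordant
SNPs, ~5000 consensus molecules/site, 10 replicates; error suppression on
10 targets × 2000 molecules with 100 variant-free sites; VAF recovery at
{10%, 1%, 0.2%} over 100 replicates; phasing on ~650 double-covering
molecules per pair; 500 null replicates for test calibration; CNV at
2000× backbone depth. These sizes make every study a few minutes on one
CPU while keeping the binomial machinery in the regime the assay actually
operates in.

## Limitations

- Sequencing error is uniform and context-free; real error is
  quality- and context-dependent and includes indels, so the absolute
  background rates here are optimistic even though the *relative*
  suppression behaviour is faithful.
- Single-strand consensus only; duplex chemistry would suppress errors
  further and is not modelled.
- The simulated cohort's survival structure is exponential with a binary
  EMR effect — adequate for validating the estimators, not a disease
  model. Passing survival checks say nothing about real patient data.
- The hGE/mL formula is a convention; absolute burdens are only
  comparable across samples analysed with the same convention.
- CNV calling is arm-scale; focal events smaller than an arm's backbone
  spacing are invisible by design.
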