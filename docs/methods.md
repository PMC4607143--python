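# Methods

`ampliped` implements the analysis pipeline behind an amplicon-sequencing
SNP genotyping assay for a small, low-diversity captive-breeding population:
variant-call filtering, panel QC, diversity statistics, within-amplicon
haplotype estimation, and likelihood-based parentage assignment with
simulation-calibrated confidence. This note records the models, the defaults
and why they were chosen, and what the synthetic-data generator does and does
not emulate.

## Data model

Genotypes are unordered allele pairs per (sample, locus); there is no phase
and no half-call — a call with one known allele is coerced to missing with a
warning. Loci are grouped into amplicons (long PCR products, kilobases in
length), and SNPs within an amplicon are physically linked: they are
inherited as haplotypes. Coordinates are 1-based inclusive throughout (VCF
convention; PLINK MAP files share the same positions). Multi-allelic markers
(microsatellites) use the same containers with more than one alternate
allele; the text PED/MAP dialect is restricted to biallelic loci.

When the same sample is genotyped on several sequencing runs, two
reconciliation policies are provided: keep the latest run's call, or keep
only concordant calls and blank disagreements (counting them). The source
data do not state which was used; the latest-run policy is the default used
by nothing downstream — merging is always explicit.

## Variant-call filter

A site passes when it is covered by at least `min_depth_q` (default 4) reads
passing base and mapping quality ≥ 20, with alternate support of at least

    max(min_alt_reads, ceil(min_alt_fraction * depth))   # default max(2, 0.2·depth)

reads. The absolute floor governs below 10× (where 20% of depth < 2), the
fractional rule above — one consistent formalisation of a two-branch rule
whose low-coverage bound was stated only qualitatively. Loci with minor
allele frequency strictly below 0.03 are removed (a locus at exactly 0.03 is
kept); MAF is computed over all genotyped samples, pooled — the genotyped
population contains relatives, which violates homogeneity assumptions, but
pooling matches how the assay was actually run; a founders-only option
exists.

Genotyping error is measured from replicate control samples as discordant ÷
shared non-missing calls, pooled call-weighted over all replicate pairs (not
averaged per pair), so pairs sharing more loci weigh more — this matches a
single population-level "error rate of genotype calling".

Excess-heterozygosity flags mark collapsed segmental duplications: a locus
with H_obs > 0.6 and H_obs − H_exp > 0.2 is annotated (never removed). The
thresholds are this package's defaults — the original QC was done by manual
inspection of alignments — and are configurable. Amplicon-level QC flags
call rates below 50% (amplification/ascertainment failure) and amplicons
left with ≤ 2 usable SNPs (too little information to keep).

## Diversity statistics

The Hardy–Weinberg test is the exact two-sided conditional test: given the
observed allele counts, each possible heterozygote count h (same parity as
the minor-allele count) has conditional probability ∝ n! / (n₁! h! n₂!)·2ʰ,
and the p-value sums the probabilities not exceeding the observed table's.
It is computed with log-gamma arithmetic and verified in the tests against
an exact rational enumeration. `in_hwe` uses α = 0.05 per locus with no
multiple-testing correction by default — per-amplicon counts of deviating
loci are reported raw — with a Bonferroni option. Expected heterozygosity
uses the unbiased small-sample estimator 2p(1−p)·n/(n−1).

Per-individual heterozygosity is the heterozygous fraction of typed calls;
individuals typed at fewer than 30 loci are flagged excluded and left out of
the summary histogram (bin width 0.05).

Haplotype frequencies within an amplicon are estimated by
expectation–maximisation over unphased multi-locus genotypes
(gene-counting): the E-step distributes each individual over its compatible
haplotype pairs proportional to f_j·f_k (×2 when j ≠ k), the M-step
re-estimates frequencies, until max |Δf| < 1e-6 or 1000 iterations.
Individuals with any missing call inside the amplicon are dropped from the
estimation and counted — integrating over missing sites would be possible
but missingness handling was unstated in the source analysis, and dropping
is transparent. Individuals with more than 16 heterozygous sites in one
amplicon (2¹⁵+ phasings) are likewise dropped with a warning; in
low-diversity data this is rare. Initialisation is the product of
single-locus allele frequencies, which makes the fit deterministic;
the observed-data log-likelihood is non-decreasing by construction and
checked in tests. Haplotypes below 1e-6 are pruned from the output, and the
per-amplicon report counts haplotypes above 1e-3 so numerical dust does not
inflate counts.

## Parentage likelihood

Genotyping error uses the replacement model: with probability ε the recorded
genotype is a random Hardy–Weinberg draw at the locus' frequencies,

    P(g_obs | g_true) = (1 − ε)·1[g_obs = g_true] + ε·P_HW(g_obs).

This is the simple symmetric form standard in likelihood parentage; an
allele-level mistyping matrix would add parameters the data cannot inform.
The default ε = 0.01 is deliberately conservative against the 0% measured on
retained neutral loci (error reached ~7% only on duplication-affected immune
loci, which QC removes); ε is configurable per analysis.

Single-parent LOD at one locus compares P(offspring, candidate | candidate
is a parent, mate drawn from HW) against P(offspring)·P(candidate), both
integrating the error model over true genotypes; the trio LOD conditions on
a known (or previously assigned) parent. Per-locus terms are precomputed as
small lookup tables over observed-genotype codes (3×3 and 3×3×3 for
biallelic loci, general G for k alleles), making batched evaluation over
thousands of simulated trios cheap. With ε = 0 a Mendelian-impossible
configuration yields −∞ and is counted as an exclusion; when the
offspring/known-parent pair is itself impossible the trio ratio is 0/0 and
the locus is scored 0 for the candidate (it carries no information about
them) while still counted as an exclusion. Loci are treated as independent
in the likelihood even though SNPs within an amplicon are linked — the
convention of the standard tooling in this field; the practical effect is
that the LOD's variance is understated, which the Monte-Carlo calibration
(run on the same independence assumption) absorbs, and which the end-to-end
tests exercise against a generator that simulates full linkage.

Delta is the gap between the two highest positive LODs (a single positive
LOD is its own delta; no positive LOD means no assignment). The critical
delta Δ* at confidence c is calibrated by simulating the candidate pool:
draw parents from HW at the facility's allele frequencies, create the
offspring by Mendelian transmission plus unrelated candidates, apply the
observed missingness (`prop_loci_typed`, estimated from the data when not
set) and ε to everyone, include the true parent with probability
`prop_candidates_sampled` (reduced automatically when registry candidates
were never genotyped), and take the smallest threshold t on the achieved
delta grid such that among trials with delta > t the true parent tops the
ranking with frequency ≥ c. Fewer than 100 positive-delta trials yield
Δ* = +∞ (no confident assignment possible) with a warning. Default
10 000 cycles; confidence levels strict = 0.95 and relaxed = 0.80.

Assignment per offspring: facility-specific allele frequencies (falling back
to the full matrix when fewer than 10 genotyped animals, and floored at
1e-4 so no observed genotype has zero likelihood); trio analysis when one
parent is known; otherwise a single-parent dam analysis followed by a sire
analysis that conditions on the dam only if she was confidently assigned.
Candidates sharing fewer than 20 typed loci with the offspring are removed
from the ranking; if none remain the result is downgraded to
exclusions-only. Exact LOD ties (indistinguishable candidates, e.g. fully
homozygous siblings) never produce an assignment — ambiguity is reported,
not broken arbitrarily.

## Synthetic-data generator

The generator is the test bed: it produces a panel, a two-generation
population and an observation layer with known truth.

* **Panel.** 14 amplicons by default (the study panel ranged 14–17), each
  7.8–10.1 kb with 1–41 SNPs and a founder pool of 2–8 distinct haplotypes
  with Dirichlet(0.8) frequencies. Per-SNP minor-allele targets are drawn
  from 0.5·Beta(0.7, 2.8) (mean ≈ 0.1, mass below 0.2) and realised by
  assigning the alternate base to the haplotype subset whose pool frequency
  best matches the target — the resulting spectrum is skewed low, matching a
  population where most retained SNPs are uncommon.
* **Population.** Founders sample haplotype pairs per amplicon from the
  pool. Facilities follow configurable structures (defaults mirror the
  study's eleven breeding groups: known vs unknown dams, 2–12 candidate
  sires, full-sib/half-sib candidate sets built by giving candidates shared
  hidden parents). Offspring receive one parental haplotype per amplicon —
  no recombination within an amplicon (≤ 10 kb; negligible) and free
  recombination between amplicons.
* **Observation.** Missingness has three components consumed against the
  overall `missing_rate` budget (default 0.44, the study's average):
  marker-level failure (default: 40% of loci missing in 90% of samples),
  whole-amplicon dropout per sample (default 0.05), and a per-call component
  doubled for a low-quality sample subset (default 10% of samples). The
  marker-level component dominates deliberately: the study reports both 44%
  average missingness *and* ~109 shared typed loci per offspring/dam/sire
  trio out of 164–192 — only missingness that is strongly correlated across
  individuals (the same poorly-amplifying markers failing everywhere) is
  consistent with both numbers; independent per-sample missingness would
  leave ~30 shared loci. Genotyping error replaces calls with HW draws at
  rate ε_sim (default 0.01), the same form the likelihood assumes, so
  calibration tests are internally consistent.

What the generator does **not** emulate: sequence reads or depth (the filter
is tested on synthetic pileup counts, not simulated reads), founder
relatedness or inbreeding (real founders' kinship was unknown;
all founders are drawn independent), multi-generation drift, mutation, sex
chromosomes, and genuine segmental duplication (duplication QC is tested by
collapsing two simulated paralogs). Passing tests therefore demonstrate
correctness of the statistics and the assignment machinery under the study's
stated data structure, not robustness to artefacts the generator omits.

## Problem sizes and numerics

Test and acceptance runs use Monte-Carlo sizes chosen to keep the whole
suite fast while leaving comfortable statistical margins: 3 000–10 000
calibration cycles (the statistic of interest is a 95% proportion, so 10⁴
trials give a ±0.4% standard error), 200 simulated offspring for the
facility-recovery check (as 100 replicate two-offspring groups of the
known-dam/two-sires shape, so allele frequencies come from a broad
population rather than one giant sibship), 1 000 loci × 500 individuals for
the HWE type-I check, and 20 random two-locus datasets against a
multi-resolution grid-search oracle (final resolution 8e-4, hill-climbed to
convergence at each scale). Exact tests (filter rule, HWE enumeration, trio
LOD vs the 27-term sum) are compared at 1e-9 relative or 1e-10 absolute.
All randomness flows from explicit seeds; there is no global RNG state.

## Known limitations

* The likelihood's locus-independence assumption overstates the information
  in linked SNPs; the optional remedy (collapsing amplicons to multi-allelic
  haplotype super-loci via the EM output) is supported by the data model —
  `ParentageModel` accepts k-allelic frequency vectors — but not wired into
  `assign_parentage` as a mode.
* Parent-pair search is sequential (dam first, then sire given dam), not a
  joint search over pairs.
* The exact-test p-value and the EM fit reproduce the standard methods, not
  the byte-level output of any particular external program; numerical
  agreement with other tools is expected only to the precision of the
  methods themselves.
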