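# Methods

`hlapocket` implements an amino-acid-level fine-mapping workflow for HLA
Class II case-control data, centred on the DP heterodimer. The analysis
unit is the two-field allele (the protein-level resolution of HLA
nomenclature); everything downstream — residues, binding-pocket
combinations, the rs9277534 expression class, TCE groups — is a
deterministic function of the allele call, except cis pairing of the DPA1
and DPB1 chains, which is inferred by EM.

## Statistical model

**Frequencies.** Allele and residue frequencies are chromosome-based: a
subject typed at a locus contributes two chromosomes. 95% CIs are Wald
(`p ± 1.96·sqrt(p(1−p)/n)`, clipped to [0, 1]). The Wald choice is a
documented, swappable default; at the cohort sizes involved (hundreds of
chromosomes) it is indistinguishable from score intervals away from the
boundary.

**Association.** Case status is regressed on per-subject dosage (0/1/2
copies, or an expected dosage in [0, 2] for phase-ambiguous combinations)
by unadjusted logistic regression under an additive genetic model; OR =
exp(slope), Wald CI and two-sided p. Stratum-specific results are re-fits
on the subset, not interaction models. Newton/IRLS with a 1e-10 tolerance
on the log-likelihood, at most 100 iterations (statsmodels `Logit`
underneath; the test suite checks the slope against an independently
written Newton oracle to 1e-6). Complete or quasi-complete separation is
detected on the scalar dosage (disjoint or boundary-touching case/control
ranges, or a blown-up fit) and reported as a flagged result with an
infinite/zero OR and no CI — never an exception, mirroring how such cells
are reported in practice.

**Multiple testing.** Bonferroni within natural families: one family per
gene for allele tests (threshold α/m with m the number of common alleles),
the number of haplotypes tested for haplotype families, and the number of
pocket combinations (10) for the combination analysis. The screen stage
deliberately uses *uncorrected* p < 0.05: it is a candidate generator, and
correcting there would discard legitimate candidates (the susceptible
DPA1*03:01-type signal sits near p ≈ 0.02).

**Haplotype EM.** DPA1~DPB1 and DQA1~DQB1 cis haplotype frequencies are
estimated from unphased genotypes by the standard two-locus EM under HWE:
a double heterozygote is compatible with two phase configurations; the
E-step weighs each by the product of current haplotype frequencies, the
M-step re-estimates frequencies from expected chromosome counts.
Initialization is the deterministic product of marginal allele frequencies
(no random restarts by default — the two-locus likelihood is well behaved
at these allele counts, and the suite cross-checks against a brute-force
simplex maximizer to 1e-4). Convergence: |Δloglik| < 1e-8, max 1,000
iterations; the log-likelihood is asserted non-decreasing at every step.
After convergence one extra E+M pass makes the stored posteriors and
frequencies mutually consistent, so expected combination dosages sum
exactly to 2n times the qualifying haplotype mass. Haplotype tests are 1-df
Pearson chi-squared on the 2×2 of EM-expected chromosome counts
(haplotype vs rest × case vs control) with Woolf CIs; haplotypes with an
expected count below 5 in either group are binned before testing. An
EM-free sensitivity coding (direct counting with double heterozygotes
split half/half) is provided and agrees with EM to <0.005 when phase
ambiguity is rare.

**Pocket combinations.** A combination such as `a31:M + b84:G|V` is a
conjunction over chain positions with a disjunctive residue set per term.
Beta-only combinations are counted directly on the two DPB1 calls. For
alpha+beta combinations the dosage is the posterior-expected number of cis
DPA1~DPB1 haplotypes satisfying both chains, using the subject's EM phase
posterior. Whether the original tabulations enforced cis pairing is not
stated; cis is the default here because the heterodimer is the functional
unit, and an `independent` mode (random pairing of the two loci, each
pairing weight 1/2) is available as a sensitivity analysis. Positions
belonging to several pockets are reported in all of them (β69 sits in P4,
P5 and P7 per the pocket table; it is never collapsed to a single pocket).

**Opposing-directionality screen.** Among common alleles (frequency ≥0.05
in the full cohort *or* either stratum — a disjunctive rule), significant
alleles are split by OR direction. Candidate residues are the tracked
positions where the protective and susceptible groups carry *different
residue sets* (set inequality, not disjointness: a position counts when at
least one group carries a residue the other lacks — this is what makes 14
β1 positions separate DPB1*04:01 from the 06:01/18:01/104:01 group even
though 18:01 shares β11 G and β69 K with 04:01), intersected with pocket
membership.

**LD.** For two chromosome-level binary features, D = p_AB − p_A·p_B and
R² = D²/(p_A(1−p_A)·p_B(1−p_B)). The squared-D form is used: the
dimensionally inconsistent unsquared variant that sometimes appears in
print cannot produce values in [0, 1]. Within DPB1 (residue vs rs9277534
class, residue vs residue) no phasing is needed — both features are
functions of the same allele call; DPA1×DPB1 pairs are evaluated on the EM
haplotype frequencies. Perfect correspondence returns exactly 1.0 (guarded
against floating-point cancellation).

**Expression class and TCE.** rs9277534 A (low DP expression) / G (high)
is a deterministic annotation of the DPB1 allele from the packaged map; no
expression quantity is modelled. TCE groups 1/2/3 are looked up per
allele, with an exon-2 sequence fallback for novel alleles that share
exon 2 with a known allele.

## Packaged mapping data

All coordinates are mature-protein numbering (position 1 = first residue
after the signal peptide). The residue, expression and TCE maps ship as
TSVs with `#provenance=` headers and can be replaced by user-supplied
files in the same format.

The packaged fixture covers the 44 DPB1 alleles of the published
residue/rs9277534 classification and the four common DPA1 alleles.
Residues at the printed positions (β11, β36, β55, β69, β76, β84, β96,
β170; α11, α31) are exact transcriptions; β85–87 follow the published
84–87 GGPM/VGPM/DEAV motifs. The remaining tracked positions (β8, β9,
β56, β57, β65, α66) and the monomorphic non-tracked pocket positions are
**synthetic** assignments, tied deterministically to the printed
hypervariable pattern so that every published constraint holds (including
the 14-position screen result). Two filler entries (DPB1\*105:01, copying
03:01, and the generator pseudo-allele 99:99, copying 15:01) keep pipeline
lookups total; both are class-consistent with the β96/β170 ⇔ rs9277534
equivalence, so the exact-LD identities are unaffected. The exon-2
sequences backing the TCE fallback are likewise synthetic (tracked-residue
strings with unique suffixes), and the TCE grouping itself is a fixture
approximating the functional-distance classification (groups 1 =
{09:01, 10:01, 17:01}, 2 = {01:01, 03:01, 14:01, 45:01}, 3 = the rest).
Analyses that depend on real full-protein sequences should load an
IPD-IMGT/HLA-derived map instead.

## The synthetic-cohort generator

The generator is the study-conditions module: every test and calibration
runs on cohorts it draws, so what passes here demonstrates correctness of
the *methods* under the assumed data-generating process, not properties of
any real cohort.

Defaults (`gad_like_config`): 849 subjects; case fraction 0.546; two
self-described-race strata with weights 0.592/0.371 (renormalized);
per-stratum DPA1~DPB1 haplotype frequency tables matched to the published
common-allele control frequency profile (e.g. White DPA1*01:03 ≈ 0.80,
Black ≈ 0.47, DPB1*04:01 0.42/0.205), with remainder mass on the
99:99~99:99 pseudo-haplotype; other genes drawn independently per locus
from stratum-specific tables (linkage equilibrium across genes — the
analyses never use cross-gene LD, and DP is recombinationally separated
from DQ); per-gene missing-completely-at-random rates matched to the
published per-gene Ns (5–9%). Disease status is Bernoulli(logistic(lp))
with lp = baseline + Σ effect×dosage, dosages computed on the *phased*
truth; the default planted effects are the two pocket-1 combinations at
their reported odds ratios (0.57 protective, 1.63 susceptible). The
baseline is solved exactly over the enumerated dosage distribution so the
marginal case fraction lands on target. One integer seed governs all
draws in a documented order; identical config+seed gives byte-identical
cohorts, and the phased truth ledger always unphases to the emitted table.

What the generator does *not* emulate: genotyping error, departures from
HWE, cross-gene LD, within-stratum admixture, covariates (age/sex), and
real haplotype diversity beyond the ~20 common haplotypes per stratum.

The screen-recovery validation scenario plants the protective combination
at OR 0.57 and the susceptible one at OR 2.0 — the upper range of the
susceptibility ORs reported for these loci — chosen by power analysis so
that a single n=849 cohort nominates both opposing arms with high
probability; the effect-recovery calibration uses 0.57 exactly.

## Problem sizes used in the test suite

Calibrations are sized to be decisive yet quick on one CPU: 2,000 null
cohorts for type-I error, 200 replicates (n=1,000) for EM frequency error,
200 replicates (n=849) for combination-OR recovery and CI coverage, 100
replicates for screen recovery, 200 for haplotype-CI coverage. The whole
suite runs in a few minutes.

## Known limitations

- Synthetic residue assignments at unprinted positions are internally
  consistent but not real sequence data; results at those positions are
  method demonstrations only.
- Haplotype ORs come from chromosome-level 2×2s of EM-expected counts;
  subject-level regression on expected haplotype dosage is a defensible
  alternative and can differ slightly at high prevalence.
- Wald CIs everywhere; exact/profile intervals would behave better for
  very rare alleles (those are binned or flagged instead).
- The pipeline's manifest records a content hash, not timestamps, so
  re-runs are byte-identical; run times are only logged to stderr.
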