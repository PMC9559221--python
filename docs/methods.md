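# Methods

## Nomenclature and matching model

Alleles are modeled at one-field (`A*11`, the serology-era "antigen" or
allele-group level) or two-field (`A*11:02`, protein level) resolution.
Serologic split/broad equivalence tables are deliberately not modeled: the
antigen level is defined as first-field equality, which is how one-field
molecular typing is used in practice.  Third/fourth fields, expression
suffixes and G/P groups are out of scope.

Antigen mismatch (MM) counting supports two views:

- **LR3** — donor-versus-recipient first-field groups at A, B, DRB1; each
  locus contributes 0–2, global range 0–6.
- **HR6** — two-field alleles at A, B, C, DRB1, DPB1 plus one combined DQ
  locus unit, global range 0–12.  A donor DQ unit is a (DQB1, DQA1) chain
  pair; it mismatches when its beta *or* its alpha chain is absent from
  the recipient.  Typing is unphased, so donor chains are paired in table
  order (a lone chain pairs with every partner); the convention is
  centralised in `hla.donor_dq_units`.  Counting DQA1+DQB1 as a single
  unit (rather than two loci) is what keeps the six-locus global scale at
  0–12; this is an assumption of the package and is configurable only by
  counting loci separately downstream.

Homozygous typings are stored as a single distinct allele and contribute
each antigen once.  Mismatch counts are donor-against-recipient by
definition (no symmetrisation), monotone under recipient-allele addition,
and LR3 ≤ HR6 whenever the HR genotype refines the same LR genotype.

## Imputation of untyped loci

Untyped loci (typically C and DQ when an antibody against them appears)
are expanded from a population haplotype frequency table: all unordered
haplotype pairs whose union reproduces the observed genotype — matching
at the observed resolution, so a one-field observation matches any
two-field table allele of its group — are enumerated and weighted
`f(h1)·f(h2)`, doubled for heterozygous pairs (Hardy–Weinberg random
union).  The maximum-weight pair supplies a *point estimate*, mirroring
how clinical estimated typing yields a single allele per locus; the
normalized best-pair probability and the full ranked list are returned so
callers can flag low-confidence (< 0.5) expansions.  Ties break
lexicographically on the serialized haplotypes, making results
deterministic.  Scale invariance (frequencies need not be normalized) and
agreement with exhaustive enumeration are enforced by tests.  No specific
frequency table is bundled: registries and frequency tables are versioned
external data, and all tests use synthetic tables.

## Bead positivity and specificities

A bead is positive iff `MFI > 500` and `MFI / MFI_lowest > 5`, where the
lowest bead is taken over the same sample and HLA class (the scope of the
denominator is configurable to panel-wide; the per-class reading is the
default because class I and class II panels are separate runs).  A zero
lowest bead makes the ratio +infinity, so the absolute threshold alone
decides.  Input MFI is assumed vendor-normalized; no background
subtraction is re-implemented.  Positive DQ/DP beads sharing a beta chain
merge into one specificity accumulating the reactive alpha variants;
class I and DRB beads stay one specificity per allele unless an explicit
cross-reactive group is declared.

## Dual-mode DSA assignment

**LR mode** (what a center with one-field A/B/DRB1 typing plus estimated
C/DQ can conclude):

- A/B/DRB1: DSA iff any member allele shares a donor first-field group.
- C/DQB1: DSA iff a member allele equals the estimated two-field donor
  allele exactly; alpha chains are ignored (unknowable in this view).
  Exact equality, not group matching, is used because estimated typing is
  already at two-field resolution.
- DP, DQ-alpha-only and DRB3/4/5 targets: `unclassifiable_typing`.

**HR mode** (complete two-field donor typing, panel-aware):

- Class I and DRB: DSA iff a member allele equals a donor allele.
  Otherwise, donor alleles of the targeted group are checked against the
  panel: if one is unrepresented the verdict is `unassessable_panel`
  (the assay cannot exclude reactivity against it), else `not_DSA`.
- DQ/DP heterodimers: chain-level matching — DSA iff a member beta equals
  a donor beta and (the bead carries no alpha information, or a member
  alpha equals a donor alpha).  Donor cis phasing is *not* required:
  donor typing is unphased, and chain-level matching reproduces every
  verdict in the worked reference cohort.  When the donor's alpha locus
  was never typed, a beta match alone yields DSA with reason code
  `beta_match_alpha_untyped`; the beta identity already establishes
  anti-donor reactivity, so this is recorded rather than raised.
- `unassessable_panel` aggregates with `not_DSA` for patient-level flags:
  an unassessable antibody is not *confirmed* donor-specific.

Patients are classified by the two mode flags into LR+/HR+, LR+/HR−,
LR−/HR+ and negative; HR class I/II flags derive only from HR-confirmed
specificities.  The specificity unit is one bead-group row; a known
one-off counting ambiguity in mixed rows is documented in the acceptance
tests as a ±1 tolerance on row-level tallies, while patient-level counts
are convention-independent.

## Eplet mismatch

The registry is an input table (`allele, eplet, abv`); antibody-verified
flags are global per eplet name.  EpMM of a scope is the union of donor
eplets minus the union of *all* recipient alleles' eplets in scope
(genotype-level, the HLAMatchmaker convention), with interlocus
deduplication by eplet name (toggleable).  `nonshared_eplets` explains
antigen-level calls that dissolve at allele level: eplets of the presumed
target absent from both the actual donor allele and the recipient.  The
bundled `registry_synthetic.csv` is a constructed registry that satisfies
the worked cohort's non-shared annotations; real registry releases are
user-supplied, and any count that depends on registry version is outside
the acceptance surface.

## Outcome statistics

Kaplan–Meier curves with global and pairwise log-rank tests, Cox models
for death-censored graft loss and logistic models for ABMR, over the
four-group classification.  Numerics come from lifelines (Efron handling
of ties — fixed, stated) and statsmodels; the module's own contract is
the comparison plan, the group encodings, the collinearity rule
(overlapping exposure definitions such as "any LR dnDSA" and "confirmed
dnDSA" are fitted in independent models), and NA flagging: zero-event
strata, non-convergence and quasi-complete separation yield flagged rows,
never crashes.  Significance is two-tailed at 0.05.

## Synthetic cohort generator

The generator emulates the structure of a multi-center kidney transplant
cohort so the whole pipeline is testable without external data.  Per donor/recipient
pair: genotypes are two haplotypes from a 17-haplotype European-style
synthetic pool (A/B/C/DRB1/DQB1–DQA1 in cis; frequencies are covered
mass); DPB1 is drawn from an independent 9-allele pool, reflecting its
weak linkage; HLA-identical pairs are redrawn.  The LR donor view keeps
first-field A/B/DRB1 and carries estimated two-field C/DQ that is wrong
with probability ε per locus (the estimate is swapped for the most
frequent alternative allele, with its cis alpha partner for DQ — the
realistic imputation failure mode, which keeps the LR view internally
consistent).  The bead panel contains every pool molecule plus panel-only
alleles (as real SAB panels carry alleles absent from the local gene
pool), each dropped with probability γ.

Immunization is per mismatched donor molecule with probability
`logistic(α + β·EpMM)` of that molecule's class-level eplet mismatch
(no mechanistic form is established for this process; the logistic-in-
EpMM choice encodes only the direction of the association).  With
probability `offtarget_rate` the resulting antibody misses the donor
allele and binds same-group (same-beta, other-alpha for DQ) beads only —
allele-level divergence, the dominant source of antigen-level false
calls.  Donor molecules missing from the panel produce group-reactive
binding on the remaining same-group beads.  Patients additionally develop
third-party antibodies at a small Poisson rate.  Positive beads draw
log-normal MFI (median 5000, σ 0.5), background beads median 100, σ 0.45,
so both sides of each positivity threshold are exercised; the background
σ is chosen so spurious super-threshold beads are rare (≈0.2% per
sample).  ABMR and graft-loss times are exponential with the hazard
multiplied by θ for patients carrying any true donor-binding antibody
(mistargeted antibodies carry no excess hazard); censoring is
N(55, 15.6) months, floored at 1.

Default parameters are the package's study conditions: n = 241 pairs,
θ = 4.0, ε = 0.15, γ = 0.08, `third_party_rate` = 0.10, and
(α, β) = (−6.20, 0.10) with `offtarget_rate` = 0.159 calibrated once by
large-replicate simulation so that the *observed* confirmed-DSA
prevalence is 13% and the expected antigen-level false-call fraction
among LR-positive patients is 20%.  Determinism: identical config and
seed give byte-identical emitted tables; the synthetic eplet registry is
a fixed property of the antigen universe, independent of the sampling
seed.

What the generator does *not* emulate — and hence what passing recovery
tests do not show about real data: realistic population linkage beyond
the 17-haplotype pool, center effects, time-varying antibody titers,
preformed-DSA exclusion dynamics, MFI-based risk strata, competing risks,
and DP alpha-chain typing (synthetic DP beads are beta-only).  eGFR and
other covariates are drawn directly rather than derived.

## Numerical and design choices

- Mismatch/assignment is pure integer and string computation; no
  tolerances are involved and fixture results are platform-independent.
- Imputation tie-break: lexicographic on serialized haplotype pairs.
- Haplotype-frequency sum may be ≤ 1 (covered mass); a sum above 1 + 1e-6
  is rejected.
- Cox ties: Efron approximation (lifelines default), fixed.
- Logistic separation detection: non-finite standard errors or |coef| >
  15 flag the row as NA.
- Problem sizes in the test suite — 200 replicates of 241 pairs for
  parameter recovery, 150–200 pairs for monotonicity sweeps, 50
  registries for the EpMM oracle — were chosen to give stable Monte
  Carlo estimates at interactive runtimes.

## Known limitations

- The LR/HR refinement-consistency guarantee holds only when beads are
  two-field faithful; real assays show cross-reactivity beyond the
  modeled mistargeting.
- DQ chain pairing by table order is a convention; for donors
  heterozygous at both DQ chains the two possible cis arrangements can
  differ, and the package does not attempt phasing.
- The one-off specificity-counting ambiguity for mixed bead-group rows is
  documented, not resolved; patient-level classification is unaffected.
- `unassessable_panel` and "negative" are not distinguishable for donors
  whose molecule is off-panel but whose group is otherwise covered; both
  count against confirmation.
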