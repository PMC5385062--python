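# Methods

This note documents the models, estimators and numerical choices behind
`cladescout`, in the spirit of the methods documentation that simulation
and statistics packages ship alongside their APIs.

## Sequence identity and clustering

Pairwise identity is defined operationally, because "percent similarity"
has no single standard: we compute a global alignment with free end gaps
(match +1, mismatch −1, gap open −2.5, gap extend −2.0, via
`Bio.Align.PairwiseAligner`) and report

* **identity** — matches / aligned columns over the *end-gap-free span*
  (the columns between the first and last position where both sequences
  are present), and
* **overlap** ("coverage") — the column count of that span.

Arguments are ordered canonically before alignment so the function is
exactly symmetric.  The near-linear gap cost is deliberate: on unrelated
sequences the optimal alignment collapses to a short local span whose
overlap then fails the 100-base coverage requirement, while genuinely
homologous pairs (≤ ~35% divergence) align end to end.  Two OTUs are
linked iff identity ≥ 0.80 **and** overlap ≥ 100 bases; clusters are the
connected components of this link graph (single linkage), emitted in a
canonical order (sorted by smallest member id) so results are independent
of input order.

The reference screen uses the same identity: an OTU is *unidentifiable*
when no named reference reaches the threshold over at least `min_overlap`
aligned bases.  The coverage condition is applied to the screen as well as
to clustering — without it, a spurious 30-base near-perfect span against an
unrelated reference would masquerade as a high-identity hit.

Target selection groups OTUs that form a connected component at > 0.95
identity *and* verify pairwise (> 0.95 for every pair); components that
fail the pairwise check are split into individual targets.  When a cluster
offers more targets than wanted (`per_cluster_cap`), targets are ranked by
summed read counts — the most abundant template is the one PCR is most
likely to recover.

## Primer design

Candidates are an exhaustive enumeration: every substring of length 16–21
of the annotated ITS2 window, in both orientations (reverse candidates are
the reverse complement of the template slice).  Slices containing IUPAC
ambiguity codes are skipped — a degenerate 3′ decamer has no well-defined
exact-match count.  The five acceptance criteria, all configurable
(`PrimerConfig`):

| criterion    | bound                 | rationale |
|--------------|-----------------------|-----------|
| melting temperature | 54–58 °C       | one annealing program for all primers |
| GC content   | 33–62%                | stable but not GC-clamped oligos |
| length       | 16–21 nt              | specificity vs. synthesis cost |
| 3′-decamer hits | < 20 OTUs (both strands) | mis-priming proxy: extension needs a perfect 3′ end |
| flank distance | > 20 nt from both conserved-gene boundaries | unspecific products stay size-distinguishable |

"GC 33–62%" is our reading of an AT/GC balance band; a literal AT:GC odds
ratio in [0.33, 0.62] would asymmetrically forbid AT-rich primers and
contradicts how primers are designed in practice.  The bounds are config
fields, so either reading can be enforced.

Melting temperature defaults to unified nearest-neighbor thermodynamics
(SantaLucia 1998 parameter set as shipped in
`Bio.SeqUtils.MeltingTemp.Tm_NN`, entropy salt correction, 250 nM + 250 nM
oligo, 50 mM Na⁺); the Wallace 2/4 rule is available as `method="wallace"`
for quick estimates.  The 54–58 °C window applies to whichever method the
config selects.  The test suite checks `Tm_NN` against an independent
re-implementation of the published parameter table to 0.1 °C, and asserts
duplex symmetry Tm(s) = Tm(revcomp(s)).

Passing candidates are ranked by (fewest 3′-decamer hits, |Tm − 56 °C|,
longer length, 5′-most position) — specificity first, then annealing
centrality; the remaining keys are deterministic tie-breaks.  For grouped
targets a candidate is only reported if its template-strand slice occurs
verbatim in every member's variable window, so a single synthesized oligo
serves the whole group.  With large (8-member) groups this can be
infeasible — the CLI design stage then falls back to designing for
individual members, mirroring how real campaigns mix individual and
grouped targets.

Pairing is fixed by orientation: a specific *reverse* primer extends
leftward across ITS1/5.8S into the 18S gene and therefore pairs with the
18S universals (NS5a, NS7a); a specific *forward* primer pairs with the
28S universals (TW13, LR5).  Universal primer sequences are configuration
data with editable defaults taken from the classic eukaryote rRNA primer
repertoire; the simulator plants whatever sequences the config holds, so
nothing downstream depends on the exact oligos.

`insilico_pcr` scans templates for convergent binding sites: binding is an
exact match, or ≤ `max_mismatch` substitutions never falling in the 3′
decamer (polymerases do not extend a mismatched 3′ end); amplicons longer
than `max_product_length` (default 4000 bp) are discarded.  More than one
amplicon on a template marks the pair as unspecific.

## Construct assembly and chimera control

Reads are chained 18S → ITS → 28S.  Each junction is scored by the best
*gapless dovetail* overlap (suffix of the growing construct vs. prefix of
the incoming read, both orientations of the incoming read), maximizing
matches − mismatches with ties to the longer overlap.  Gapless is adequate
because Sanger/pyrosequencing consensus reads after trimming are
substitution-dominated.  Statuses:

* `ok` — overlap ≥ 30 bases at ≥ 97% identity; merged, with disagreeing
  bases resolved in favour of the Sanger read (higher per-base quality
  than the pyrosequenced fragment);
* `chimera_flag` — a substantial overlap whose identity falls below 97%:
  the two reads sample different organisms;
* `no_overlap` / `conflict` — no usable junction, or two reads claiming
  the same region with different sequences.

The 30-base / 0.97 defaults are package choices (configurable): trimmed
Sanger data should agree near-perfectly, while cross-organism overlaps at
order-level divergence (≥ 20%) sit far below 0.97, which is what makes the
overlap itself an effective first-pass chimera filter.  Reference-based
chimera detection and per-region taxonomy cross-checks are out of scope;
the module reports per-junction identities so external evidence can be
joined downstream.

## Niche statistics

For group *g* and variable *v*, the **group sample** is the multiset of
*v*-values at sites where *g* occurs, each value weighted by the summed
occurrences of the group's member OTUs at that site; the **null sample**
is *v* at all sites with a non-missing value, unweighted.  Sites missing
*v* are dropped from analyses of *v* only.  A group with zero occurrences
raises a "not determined" error rather than fabricating a value.

The narrowness criterion is conjunctive:

1. frequency-weighted population SD of the group sample is more than
   2× smaller than the null SD, and
2. a classic Levene test (mean-centered; weights expanded to repeat
   counts; `center="median"` gives Brown–Forsythe) rejects at α = 0.05,

with star grades `*`/`**`/`***` at p < 0.05/0.01/0.001.  Both the SD ratio
and Levene's W are invariant under affine rescaling of *v*, so verdicts do
not depend on units.  Degenerate inputs have defined answers: identical
samples give W = 0, p = 1; zero within-group deviation in both samples
gives p = 1 by convention.

Categorical (biome/region) bias uses a G-statistic of observed vs.
expected category counts, with expectations proportional to the number of
sites per category, and a permutation null that shuffles the
site-to-category labels.  P-values use the add-one estimator
(1 + #{G_perm ≥ G_obs}) / (n_perm + 1) with n_perm = 999, so p ∈
{0.001, …, 1} and is never zero.  This is a deliberate methodological
substitution for random-forest permutation importance: the G test is
direct, assumption-light and exactly checkable against exhaustive
enumeration on small inputs, at the cost of not modelling interactions
among predictors.

`cv_r2` is a harness, not a model: any object with `fit`/`predict`
(sklearn regressors clone cleanly; anything else is deep-copied) is
evaluated by repeated k-fold cross-validation (k = 10, 100 repeats).  Per
repeat, R² = 1 − SSE/SST is computed on the *pooled* out-of-fold
predictions about the overall mean — pooling, rather than averaging
per-fold R², keeps small folds from dominating.  A mean-only predictor
can therefore never score above zero, which the tests assert.

## The synthetic community

`synthetic_data` generates everything the pipeline consumes.  A root
operon (default 1800 / 200 / 160 / 280 / 900 bp for 18S / ITS1 / 5.8S /
ITS2 / 28S — field-realistic sizes; the ITS2 window leaves ~200
primer-design positions after flank margins) is drawn uniformly at random;
the configured universal-primer sites are written into the conserved genes
at positions approximating their real annealing sites and are excluded
from mutation (their invariance is what "universal" means).  Clade
ancestors mutate from the root, OTUs from their ancestor; spacers and
genes have separate per-branch substitution probabilities.

The mutation model is intentionally minimal: independent per-site
substitutions, uniform over the three alternative bases, no indels.  Two
rounds with probabilities m₁, m₂ compose to q = m₁ + m₂ − (4/3)m₁m₂, and
two lineages at q_A, q_B from a common ancestor differ per site with
probability q_A + q_B − (4/3)q_A q_B (`expected_divergence`).  The default
rates (spacers 0.16 root→ancestor, 0.015 ancestor→OTU; genes 0.02 and
0.005) put between-clade ITS divergence at ≈ 30% and within-clade at ≈ 3%
— comfortably astride the 80% clustering threshold, with conserved genes
diverging a few percent.  Calibration tests compare realized divergences
with these closed forms (re-derived independently via 4×4 Markov matrices
in the test suite).

Site environments are uniform draws (MAT −5–28 °C, MAP 100–4000 mm, pH
3–8.5, soil C 0.3–45%, soil P 20–1200 mg/kg, fire 1–200 yr) spanning
tundra-to-tropics surveys; biome and region labels are uniform over six
categories each.  Occurrence is Bernoulli with the clade's Gaussian
response to its focal variable; `niche_sd=None` yields a flat
no-preference niche.  All outputs are byte-reproducible from
`SimulationConfig` (one `numpy` `SeedSequence` stream per product:
sequences, occurrences, references).

What the simulator does **not** emulate — and what passing tests therefore
do not show about field data: sequencing error and read-depth structure
(occurrences are clean presence draws), indels and alignment ambiguity,
rate heterogeneity along sequences and across lineages, phylogenetic
signal deeper than the two-level clade/OTU hierarchy, spatial and
environmental autocorrelation among sites, and correlated environmental
predictors.  Results on synthetic data certify the *bookkeeping and the
statistics*, not robustness to those real-world complications.

## Problem sizes used in tests and the acceptance script

The default community is 4 clades × 8 OTUs over 200 sites — large enough
that clustering, primer coverage and niche recovery are non-trivial, small
enough that the full pipeline runs in seconds.  Monte-Carlo checks use 100
read-set simulations for chimera rates, 100 seeds for narrow-niche power,
200 for null-niche size, and 200 × 999 permutations for the size of the
bias test; oracle-equivalence suites use 20 random instances of ≤ 50
sequences.  These sizes were chosen so each property estimate has binomial
noise well inside its asserted margin.

## Known limitations

* Identity depends on the chosen alignment scoring; other tools
  (BLAST-style local identity, Sequencher) will disagree near thresholds.
  The scoring is documented and configurable at the threshold level, not
  at the scoring-matrix level.
* Primer thermodynamics ignore hairpins, homo/heterodimers and
  degenerate-base design; the 3′-decamer count is a substring statistic,
  not a hybridization model.
* The niche tests treat sites as independent; spatially clustered
  sampling will inflate significance.  The narrowness criterion compares
  spreads only — a group can shift its niche mean without narrowing and
  stay undetected.
* `cv_r2` reports predictability of occurrence weights, not variable
  importance; no random-forest importance machinery is included.
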