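# Methods

This note records the models implemented in `imprintdiv`, the conventions
chosen where several were defensible, the defaults and why they were
picked, and what the synthetic-data experiments do and do not demonstrate.

## Coding sequences and codon-aware alignment

Inputs are coding DNA sequences (one per gene per species) over
{A, C, G, T, N}. `longest_orf` scans the three forward frames for the
longest ATG-initiated, stop-terminated reading frame (stop trimmed, ties to
the leftmost start); reverse strands are not scanned because inputs are
mRNA-oriented. Translation uses the standard genetic code; any codon
containing N translates to X; internal stops are errors.

Pairwise alignment is protein-level global Needleman–Wunsch with affine
gaps, backed by Biopython's `PairwiseAligner`. Defaults are BLOSUM62 with
gap open 10 and gap extension 0.5 (a gap of length L costs
10 + 0.5·(L − 1)); these are conventional protein-alignment settings, kept
configurable because no single canonical choice exists for this step. Among
co-optimal alignments the first in the aligner's deterministic enumeration
order is returned; ties affect only which optimal alignment is reported,
never the score. Back-translation replaces each residue by its source codon
and each gap by `---`, which guarantees the two codon-alignment invariants
relied on downstream: gap runs are multiples of three, and ungapping
recovers the input sequences exactly.

Quartet alignments are built by star alignment to human: each other
species is pairwise-aligned to the human protein and insertion runs are
merged with the "once a gap, always a gap" rule. This is sufficient for
the fixed four-taxon problem; no progressive multiple alignment is
attempted.

## Pairwise divergence statistics

* **Percent identity** = 100 × identical non-gap columns / *all* alignment
  columns. Counting gap columns in the denominator makes identity and
  indel statistics coherent (a gappy alignment cannot score 100%); the
  alternative denominator (ungapped columns only) is available via an
  argument because database identity conventions vary.
* **Gap count** = number of maximal gap runs over both rows, i.e. indel
  *events*, not gap columns (a 3-residue deletion is one event); a
  column-count mode exists as an option.
* **Nei–Gojobori Ka/Ks** as described in the README. Two conventions are
  worth restating: stop-codon targets are excluded from synonymous site
  numerators while the denominator stays 3 per position (so S + N = 3L
  exactly), and multi-difference codon pairs average over all minimal
  pathways that avoid stop intermediates. Codon columns containing a gap,
  an N, or a stop in either row are skipped. Saturation (pS or pN ≥ 3/4)
  leaves the corrected rate undefined and flags the result rather than
  raising.
* **Silent CpG mutability.** The unit is the dinucleotide spanning the
  third position of codon i and the first position of codon i+1, evaluated
  in both rows (both codons must be gap- and N-free in both rows). A site
  is CpG–CpG when both rows read CG, and CpG–TpG when one row reads CG,
  the other TG, and the C↔T exchange at that third position is synonymous.
  Because the ancestral state of a CG/TG mismatch is unknowable from two
  sequences, the index is direction-agnostic:
  `mutability_index = n_CpG-TpG / (n_CpG-CpG + n_CpG-TpG)`, the mismatch
  fraction of silent third-position CpG contexts. The raw ratio
  `n_CpG-TpG / n_CpG-CpG` is also exposed since "ratio" is the other
  natural reading. (In the standard code a third-position C↔T exchange is
  always synonymous, so the synonymy clause only excludes degenerate
  contexts; it is kept explicit for non-standard codes.)
* **SNP density** = SNP count / (coding length in kb).

## Triangulation to the rodent ancestor

Under additivity of evolutionary distance on the unrooted
(human, (mouse, rat)) star, the human-to-ancestor path is
(d_hs,mm + d_hs,rn − d_mm,rn)/2, applied to divergences (100 − identity) for
identities and to Ka/Ks rates directly. The estimate is only meaningful
when the rodents are mutually closer than either is to human; the
implementation returns an *inapplicable* status (not an exception) when
mouse–rat identity fails to exceed both human–rodent identities, or when
the mouse–rat rate exceeds either human–rodent rate, and the table-level
driver counts these cases so genome-wide exclusion totals are reportable.
On noise-free additive inputs the recovery is exact to machine precision
(property-tested); on estimated distances the output is an estimate and can
fall outside [min, max] of the inputs.

## Codon branch models

The 61-sense-codon rate matrix has Q_ij = π_j · κ^[transition] ·
ω^[nonsynonymous] for single-nucleotide changes and 0 otherwise, scaled to
one expected substitution per codon per unit branch length; each branch's
matrix is scaled at its own ω. Codon frequencies default to uniform over
the 61 sense codons, with F1x4 (products of empirical nucleotide
frequencies) available; the frequency model is a declared choice, not an
estimate. Likelihood is computed by Felsenstein pruning over the two
internal nodes of the fixed quartet, vectorized over compressed site
patterns; transition probabilities come from a symmetrized
eigendecomposition cached per (κ, ω, frequency) triple, which makes the
five per-branch matrix exponentials cheap inside the optimizer.

Fitting maximizes lnL over log-transformed parameters (5 branch lengths,
κ, one or two ω) with L-BFGS-B, ω bounded to [10⁻⁴, 10], κ to [0.05, 100],
branch lengths to [10⁻⁶, 20]. The default start is data-informed (branch
lengths from three-point combinations of pairwise codon p-distances with a
log correction; κ = 2, ω = 0.3) plus two random restarts; bulk simulation
experiments use the single data-informed start, which proved sufficient on
this unimodal 4-taxon problem. The paired driver warm-starts the
two-ratios fit at the one-ratio optimum, which enforces the nesting
inequality lnL₂ ≥ lnL₁ by construction. Per-branch Ka and Ks are derived
by splitting each branch length into synonymous and nonsynonymous flow at
the branch's ω and normalizing by model-based site proportions evaluated
at ω = 1; with this decomposition each branch's Ka/Ks equals its ω exactly.

The LRT statistic 2(lnL₂ − lnL₁) is clipped at zero (tiny negatives are
numerical) and compared with 2.71. That threshold is the 5% critical value
of the one-sided mixture null ½δ₀ + ½χ²₁; equivalently it is the 10% point
of χ²₁. Since the null ω_fg = ω_bg is interior to the parameter space, the
*two-sided* exceedance of 2.71 under the null is ≈ 0.10, and the 5% reading
attaches to the *directional* rejection — statistic ≥ 2.71 with the
foreground ω on the elevated side. The calibration experiment therefore
reports both rates; the directional rate is the one expected to sit at
0.05. The saturation filter (drop Ks = 0 and Ks > 2.5) is applied to
branch-level Ks before gene-level conclusions are drawn.

## Group statistics

Group comparisons use the two-sided Mann–Whitney rank-sum test: exact null
distribution when the smaller group has ≤ 8 observations and no ties are
present, normal approximation with tie correction otherwise. A one-sided
alternative is available by argument. Contingency analyses use the Pearson
chi-square with df = 1 and no continuity correction; on the X-linkage
table the uncorrected test gives p ≈ 0.06 where a Yates-corrected test
stays above 0.1 — the uncorrected form is the declared convention, and the
reported percentages (to two decimals) are unaffected. When several
orthologs exist for a gene/species pair the one with the highest protein
identity is kept (ties to the lexicographically smallest gene id); the
representative paralog is the rank-1 (evolutionarily most recent) entry.
Ks values recorded with the database sentinel −1 are excluded from Ks and
Ka/Ks summaries but the gene's identity columns remain. No
multiple-testing correction is applied; each test is reported raw.

## Synthetic data

The generator evolves root codon sequences along the fixed quartet using
the *same* rate-matrix code as the likelihood, so simulation and inference
agree on the process by construction; an independently written
Gillespie-style event simulator in the test suite cross-checks the
end-state distribution and the substitutions-per-codon scaling. Ortholog
pair tables are produced by running the real alignment and Nei–Gojobori
stages on the simulated sequences; only paralog and SNP tables are drawn
from distributions.

Default conditions (one place, not revisited): maternal n = 26 and
paternal n = 27 genes with a background of 120 genes — a desk-scale
subsample standing in for a genome-wide set four orders larger; 300 codons
per gene; branch lengths (human 0.35, mouse 0.12, rat 0.14, cow 0.40,
ancestor 0.25 substitutions/codon) chosen so pairwise synonymous
divergence lands near Ks ≈ 0.6 for human–rodent and ≈ 0.2 for mouse–rat;
κ = 2; ω 0.13 (background), 0.16 (maternal), 0.136 (paternal); lognormal
per-gene rate dispersion (σ = 0.3) to emulate across-gene rate variation;
root third-position C enrichment (×1.5) so CpG contexts occur at realistic
frequency. Whole-codon deletions are available (default off) to exercise
gap handling; no within-gene rate heterogeneity or sub-codon indels are
simulated.

Two derived configurations exist. The *null* configuration equalizes every
parameter across groups and is used for false-positive calibration. The
*planted-divergence* configuration raises the maternal group to ω = 0.35
with a 1.6× faster clock: deliberately stronger than the few-percent
identity shifts seen in genome-scale data, because with a background of
tens (not thousands) of genes only an effect of this size is detectable —
the experiment demonstrates that the pipeline orders and detects a true
group difference end to end, not that the real effect size would be
significant at desk scale.

Calibration experiments are model-matched (uniform root frequencies, no
rate dispersion) so that deviations measure inference error rather than
model misspecification: ω recovery uses 20 replicates of 500 codons; LRT
null calibration uses 200 replicates of 250 codons (the null law is
length-stable at these divergences); power uses 20 replicates of 500
codons with foreground ω 0.8 against background 0.1.

## What passing tests show — and what they do not

The oracle tests pin the arithmetic: Nei–Gojobori counts match exhaustive
enumeration on all 61×61 codon pairs, the pruning likelihood matches
explicit internal-state summation to 10⁻⁸, alignment scores match
brute-force enumeration for short sequences, and triangulation is exact on
additive inputs. The simulation experiments show statistical soundness
under the generating model: unbiased ω recovery at realistic lengths, a
calibrated null rejection rate, and high power for a large foreground
effect. None of this certifies behaviour on real data, where alignment
error, rate heterogeneity, selection on synonymous sites, biased gene
conversion and annotation noise all violate the generator's assumptions;
the package's claim is that the *methods* are implemented correctly and
behave as theory predicts when their assumptions hold.

## Numerical and degenerate-input choices

Transition probabilities are clipped at 0 and row-renormalized after the
eigendecomposition (guarding tiny negative round-off); site likelihoods
are floored at 10⁻³⁰⁰ before logging. Empty or all-gap alignments,
zero-length coding sequences, duplicate group assignments, duplicate
paralog ranks and out-of-range identities raise typed errors naming the
offending record. The Ks = −1 sentinel is converted to a discarded status
at parse time and asserted never to reach arithmetic. Optimizer
non-convergence is reported via a `converged` flag on the results object
rather than an exception.
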