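# Methods

`retrosel` implements the molecular-evolution workflow used to ask
whether chimeric retrogenes — fusion genes created when a reverse-transcribed
mRNA reinserts into the genome and captures flanking sequence — evolve
under positive selection after their origin, where on the gene tree that
selection acts, which codon sites it touches, and how long ago the
retroposition happened.  All analyses operate on in-frame codon
alignments of the parental and retrocopy sequences sampled across
related species (here, Oryza-scale data: 4–16 sequences, 150–600
codons), with a rooted gene tree.

## The codon substitution model

The engine is the standard reversible 61-state codon model.  Between
sense codons *i* and *j* differing at exactly one nucleotide position,

    q_ij = pi_j * kappa^[transition] * omega^[non-synonymous]

and `q_ij = 0` for codons two or three steps apart; diagonals make rows
sum to zero.  `kappa` is the transition/transversion rate ratio, `omega`
(= dN/dS = Ka/Ks) the ratio of non-synonymous to synonymous rates:
omega < 1 indicates purifying selection, omega ≈ 1 neutrality, omega > 1
positive selection.  Stop codons have no state; codon equilibrium
frequencies `pi` come from the alignment (empirical codon proportions by
default, the analogue of estimating frequencies from the data; `uniform`,
`F1x4` and `F3x4` are also available).  Zero-frequency sense codons are
floored at 1e-10 and renormalised so likelihoods stay finite.

Log likelihoods use Felsenstein pruning over codon-site patterns
(identical columns collapsed with multiplicities), with per-node
rescaling against underflow.  The transition matrices `P(t) = exp(Qt)`
are computed by eigendecomposition of the pi-symmetrised generator,
which is numerically stable because the model is reversible.

**Scaling conventions.** For branch-wise models each branch's generator
is normalised to one expected substitution per codon per unit time *at
that branch's omega*, so branch lengths are expected substitutions per
codon.  Site-class mixtures (M1a, Model A) instead share a single scale
— the class-proportion-weighted background rate — because the point of a
site mixture is that fast classes really accumulate more substitutions
than conserved ones; a per-class normalisation would silently erase that
contrast.  The simulator follows the same two conventions, so fitted and
generating parameters are directly comparable.

Because the model is reversible, the likelihood is invariant to where
the root sits; the two root-adjacent branch lengths are therefore only
jointly identified when they share an omega class.  Trees are kept
rooted (the duplication node must be directional for pattern
classification), and simulated fixtures include an outgroup parental
copy so that the two stems at the duplication node are distinguishable.

## Branch-specific models and the optimal-model search

A *branch partition* assigns every branch to one of R omega classes
(one-ratio: R = 1; free-ratio: R = B).  Fitting maximises the likelihood
over branch lengths, kappa and the free class omegas with bounded
L-BFGS-B on log-transformed parameters (three starts at omega ∈
{0.1, 1, 3} for cold fits, single warm starts inside searches;
convergence tolerance ~1e-8 lnL units).  Parameter counts follow
`np = B + 1 + #free-omega-classes`; fixing a class omega (the
"fix-model" null with omega = 1) removes one free parameter.  Reported
omegas are capped at 999, the conventional rendering of an effectively
infinite dN/dS when no synonymous changes occurred.  Expected per-branch
substitution counts decompose the flux: `nN = L·t·rhoN`, `nS = L·t·rhoS`
with `rhoN + rhoS = 1` the equilibrium non-synonymous/synonymous
fractions of total flow at the branch's omega.

Three search procedures look for the best partition:

* **Method I (greedy splitting).**  From one-ratio, try splitting each
  branch into a fresh class; fully refit the best candidate and accept
  it only if its df = 1 LRT against the incumbent is significant at
  `alpha / m`, where m is the number of candidate moves in the step.
* **Method II (moves and merges).**  Candidates additionally include
  moving a branch into an existing class and merging two classes,
  ranked by AIC.  Complexity-increasing winners face the same guarded
  LRT; complexity-neutral or -decreasing winners are accepted whenever
  they lower AIC.
* **Method III (estimate-guided clustering).**  Fit the free-ratio
  model, sort the branch omega estimates, and cut the sorted sequence
  wherever consecutive values differ by more than a factor
  `(1 + k)/k` (k = 0.5 → 3×, interpreted as a scale-free clustering
  granularity).  The induced partition is refit, validated against
  one-ratio by a guarded LRT, and refined with Method II moves.

The Bonferroni guard (`alpha / m`) exists because accepting the *best*
of m candidate splits at raw alpha is a selected test: measured on
one-ratio simulations it produced false splits in ~45% of replicates,
versus 5–10% with the guard, at no practical cost in power against
omega = 3 on 500 codons (those LRTs have p-values orders of magnitude
below the corrected threshold).  For speed, candidates are *screened* by
re-optimising only the omega of the class that changed (all other
parameters held at the incumbent MLE); the single winning candidate is
always fully refit before the accept/reject decision, so no decision
rests on a screened value.

Across methods the final model is chosen by: equal class counts — higher
lnL; nested partitions — LRT at alpha; otherwise lower AIC; ties break
toward fewer classes, then method III > II > I.

Positive selection on a branch class is then assessed two ways, mirroring
how such evidence is combined in practice: the fix-model LRT (classes
with omega-hat > 1 pinned to 1, df = number of pinned classes), and the
substitution-count heuristic that flags a branch with more than 9
expected non-synonymous substitutions and (numerically) zero synonymous
ones.  A pair's verdict carries the evidence tier — `LRT-significant`,
`count-heuristic`, or `none` — rather than a bare boolean, because the
two criteria can disagree.

## Branch-site models and site identification

On a designated foreground branch set, Model A mixes four site classes:
class 0 (omega0 < 1 everywhere), class 1 (neutral everywhere), and
classes 2a/2b (omega0 / 1 on the background, omega2 ≥ 1 on the
foreground), with proportions tied as `p2a/p2b = p0/p1`.  Test 1
contrasts Model A with the site model M1a (df 2); test 2 contrasts it
with the omega2 = 1 null Model A (df 1).  Model A fits warm-start from
the fitted M1a (omega2 started at 2.5), which both speeds the triple fit and
keeps the nesting inequalities numerically honest.

Sites are identified by Bayes empirical Bayes: the posterior probability
of membership in classes 2a ∪ 2b, integrated over a uniform prior grid —
the 10-division triangle on (p0, p1) (45 midpoints), 10 midpoints on
omega0 ∈ (0, 1), and 10 log-uniform midpoints on omega2 ∈ (1, 999) —
with kappa, branch lengths and the rate scale held at their MLEs.
A log-spaced omega2 grid was chosen because the cap is 999: a linear
grid to the cap would place nearly all prior mass in the saturated
regime.  Sites with posterior above 0.95 are flagged, labelled with
their 1-based position and the first (reference) sequence's residue.

Two properties of this machinery are worth knowing when reading results.
First, with a *single* foreground branch the per-site evidence is
bounded: only the branch's endpoint states are observable, so a site
showing one non-synonymous change rarely exceeds posterior ~0.9
regardless of the true omega2 (the likelihood ratio is capped by the
grid's omega2/omega0 ratio less saturation losses).  Confident calls at
the 95% level need either several changes at the same codon or a
foreground *set* of several branches whose changes are independently
witnessed by descendants.  The site-recovery fixtures therefore place
the foreground on a retrocopy clade (stem plus descendant branches),
which is also the biologically natural unit for a young retrogene under
episodic selection.  Second, in the pipeline each omega > 1 branch of
the final branch model is tested as foreground separately (Model A
assumes one foreground regime), and reports are concatenated.

## Neutrality, dating, enrichment

**Tajima's D** is computed on the nucleotide columns after complete
deletion (every codon column containing a gap, ambiguity code or stop in
any sequence is removed; ambiguity codes count as gaps).  With m
sequences, S segregating sites and mean pairwise difference count k̄:
`ps = S/n_sites`, `a1 = Σ 1/i`, Watterson's `theta = ps/a1` (per site),
`pi = k̄/n_sites`, and D from the standard a1, a2, b1, b2, c1, c2,
e1, e2 construction.  With S = 0 the statistic is undefined and reported
as missing with a reason.  m is the number of *sequences* throughout.

**NG86 Ka/Ks**: synonymous site counts use the ⅓-per-position
convention averaged over the two sequences (changes creating a stop
count as non-synonymous); differences average over all minimal
substitution pathways per codon with equal weight, discarding pathways
through stop codons unless every pathway is; both proportions receive
the Jukes–Cantor correction `d = −¾ ln(1 − 4p/3)`, which is undefined
(saturation error) at p ≥ ¾.  No transition/transversion weighting is
applied — that is the original method; a ts/tv ratio supplied in a
config is recorded but unused.

**Dating**: `T = Ks / (2r)` with the rice synonymous clock
`r = 6.5e-9` substitutions/site/year, reported in million years.  The
95% interval is `1.96 ×` the codon-bootstrap standard error of Ks
(1000 resamples by default, seeded).  In the pipeline the dated pair is
the first parental versus first retrocopy sequence.

**Enrichment**: the cohort's positive fraction is compared with a
genomic baseline by a two-sided Fisher exact test on
`[[hits, total−hits], [round(rate·N), N−round(rate·N)]]`; the baseline
N is an explicit argument because there is no single canonical choice.

## Pattern classification

The duplication node is the MRCA of the designated parental and
retrocopy taxa (the retrocopy clade must be monophyletic, else a
classification error).  Given the branches in omega > 1 classes of the
final branch model:

* **Pattern 1** — a retrocopy-side branch incident to the duplication
  node is selected (episodic change right after retroposition), with or
  without parental-side elevation;
* **Pattern 2** — selection exclusively on the parental-side branch
  incident to the duplication node;
* **Pattern 3** — selection exclusively on parental-side branches *not*
  incident to the duplication node (the parental gene changed only after
  some time had passed);
* otherwise no pattern.

## The simulator

`synthetic_data` generates codon alignments by exact jump-chain
(Gillespie) sampling of the continuous-time codon chain along each
branch, so the truth record contains *realised* per-branch synonymous
and non-synonymous substitution counts, the per-site class assignments
(drawn once at the root — site classes are site properties, the Model A
generative assumption), and the generating parameters.  One integer seed
fixes the output bit for bit.

Default study conditions: kappa = 2; uniform codon frequencies;
background omega 0.2 (typical purifying selection on rice coding genes);
episodic foreground omega 4 on selected branches; genes of 400–500
codons; trees of 6–16 tips with branch lengths drawn uniformly from
0.02–0.10 substitutions/codon (Oryza-like depths).  Retrogene-pair
fixtures build parental and retrocopy clades joined at a duplication
node whose stem branches are drawn from 0.06–0.12 (the stems span the
whole pre-speciation interval), plus an outgroup parental copy
(`out_P`) so the two stems are identifiable.  Gap corruption, when
requested, blanks a random subset of sequences in a chosen fraction of
columns.

Calibration fixtures make specific, documented choices:

* *Branch-site fixtures* use 10-tip trees with a clade foreground
  (4–5 leaves) and strongly conserved background omega0 = 0.02 — the
  regime matching the near-zero omega0 estimates typical of conserved
  parental genes — with p0 = 0.85, p1 = 0.05 and omega2 = 10 for power
  runs, or the selected class removed for null runs.
* *Site-recovery fixtures* plant exactly 5 sites at omega2 = 10 on the
  clade foreground of an otherwise conserved (omega 0.02) 400-codon
  gene.
* *Parameter-recovery fixtures* use branch lengths 0.08–0.2 so the
  per-replicate Fisher information supports meaningful accuracy bands
  (at shallower depths the sampling error of kappa-hat alone reaches
  ~13%).

What the simulator does **not** emulate: indels and alignment error
(gaps are injected as missingness, not evolved), codon-usage bias and
non-uniform equilibrium frequencies, among-site rate variation beyond
the omega classes, recombination/gene conversion between paralogs, and
base-composition drift.  Passing tests therefore demonstrate that the
estimators and searches recover truth under the model's own generative
assumptions at study scale — not that those assumptions hold for any
particular real alignment.

## Numerical choices and degenerate inputs

Bounds: omega ∈ [1e-6, 999], kappa ∈ [1e-3, 100], branch lengths ∈
[1e-7, 20] (all optimised on the log scale); mixture logits bounded at
±30; omega0 kept strictly inside (0, 1).  LRT statistics are clamped at
0; an alternative fit more than 1e-6 below its null raises a nesting
error (and search code falls back to "no improvement").  Ties in
`select_final` break deterministically (fewer classes, then method
order).  Empty alignments after complete deletion, saturated distances,
non-monophyletic retrocopy clades, and overlap between parental and
retrocopy label sets raise typed errors; optimizer non-convergence flags
the fit rather than raising.  Expected counts are reported to one
decimal in tables, as is conventional.

## Problem sizes used in the test suite

The suite's simulation studies run at the study-scale defaults above
with 20 replicates per calibration (search power at 500 codons / 6
taxa; branch-site type-I at 300 codons / 10 taxa; site recovery at 400
codons / 10 taxa; parameter recovery at 500 codons / 6 taxa), and the
acceptance script re-runs smaller versions (3–5 replicates) of the same
studies alongside the instant published-number identities.

## Known limitations

* The two search methods II and III can legitimately disagree with
  method I near the detection threshold; `select_final`'s tie-break is a
  convention, and reports carry the full per-method trail for audit.
* With a single short foreground branch, empirical-Bayes site posteriors
  saturate below the 95% threshold for single-change sites (see above);
  this is a property of endpoint-observable data, not an implementation
  limit.
* The root-adjacent branch pair is only jointly identified when both
  edges share an omega class; estimates of the two lengths individually
  should not be interpreted.
* Ks-based ages inherit the single-rate clock assumption; the bootstrap
  interval reflects sampling error only, not rate uncertainty.
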