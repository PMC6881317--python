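# retrosel

Branch and branch-site codon-model tests of positive selection for
chimeric retrogene / parental gene pairs, with optimal-branch-model
search, empirical-Bayes site identification, neutrality testing,
synonymous-clock dating, and evolutionary-pattern classification.

## The problem

A chimeric retrogene is born when a reverse-transcribed mRNA reinserts
into the genome and captures flanking exon/intron sequence, creating a
new fusion gene next to its intact parental gene.  Given in-frame codon
alignments of the two copies sampled across related species (rice-scale
data: 4–16 sequences, 150–600 codons) and a gene tree, the questions
are:

1. Does any lineage show positive selection (dN/dS = omega > 1), and
   which — the young retrocopy stem, the parental stem, or later
   parental branches (evolutionary patterns 1 / 2 / 3)?
2. Which codon sites carry the signal?
3. How old is the retroposition event?
4. Is the cohort of retrogene pairs enriched for positive selection
   relative to the genomic background?

The machinery is the standard reversible 61-codon substitution model
(rate `pi_j * kappa^[ts] * omega^[nonsyn]` between single-step codons):
branch-specific models grouping branches into omega classes, searched
by three procedures (greedy LRT splitting; AIC moves and merges;
free-ratio-guided clustering) and compared by LRT/AIC; nested
"fix-model" tests pinning suspect classes to omega = 1; the
substitution-count heuristic (nN > 9, nS = 0); branch-site Model A with
tests 1 and 2 and Bayes-empirical-Bayes site posteriors at the 95%
level; Tajima's D with complete deletion; NG86 Ka/Ks with
Jukes–Cantor correction and ages `T = Ks/(2r)` at the rice synonymous
rate `r = 6.5e-9` /site/year; and a Fisher exact enrichment test.
Because the study's sequence data are not deposited, a codon simulator
with exact jump-chain sampling provides study-scale fixtures with known
truth (realised substitution counts, planted selected branches and
sites) against which every stage is calibrated.  `docs/methods.md` has
the full model description and design rationale.

## Worked example

Simulate a retrogene pair with positive selection planted on the
retrocopy stem, then run the full per-pair analysis:

```python
from retrosel.synthetic_data import make_pair_fixture
from retrosel.pattern_pipeline import AnalysisConfig, analyze_pair

aln, tree, truth = make_pair_fixture("pattern1", seed=3, n_codons=300)
verdict = analyze_pair(
    aln, tree, truth["parental_taxa"], truth["retro_taxa"],
    AnalysisConfig(methods=("I",), n_boot=100), pair_id="demo",
)
print(truth["positive_branches"], verdict.foreground_branches)
print(verdict.positive, verdict.evidence, verdict.pattern)
print(round(verdict.age.ks, 3), round(verdict.age.age_my, 1))
```

prints

```
[10] [10]
True LRT-significant 1
0.231 17.7
```

— the search found exactly the planted branch (id 10, the retrocopy
stem), the fix-model LRT called it significant, the pair is classified
as pattern 1 (episodic change right after retroposition), and the
synonymous divergence of the two sequenced copies (Ks ≈ 0.23) dates the
duplication to roughly 18 million years under the rice clock (this
simulated pair is older than the study's young retrogenes: its Ks
accumulates along both stems and both species clades).

The same pipeline is scriptable from the shell:

```
retrosel simulate --scenario pattern1 --seed 3 --out fixture/
retrosel analyze --alignment fixture/alignment.fasta --tree fixture/tree.nwk \
    --parental sp1_P,sp2_P,sp3_P --retro sp1_C,sp2_C,sp3_C --out out/
retrosel cohort out/*.verdict.json --out summary/
```

The numbered scripts under `analysis/` run the cohort-scale study:
simulate 24 pairs (7 with planted selection), analyse each, collect the
branch-site site tables, the neutrality/dating tables, and the cohort
summary with the enrichment test; their outputs land in `results/`.

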