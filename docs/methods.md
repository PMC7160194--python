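# Methods

## Karyotype encoding and the base-number rule

A record stores a male diploid complement: autosome count and
morphology (acrocentric `a` = one-armed, metacentric `m` = two-armed),
the sex-chromosome system, and per-field uncertainty flags (`?` suffix
= uncertain score kept at face value; bare `?` = unknown). Validation
enforces that autosomes come in pairs (even counts), that morphology
counts sum to the total, and that the Y-presence flag agrees with the
sex system. The ambiguous XXXY-or-XYYY system is carried as its own
category: both readings contain a Y and imply two X-autosome fusions,
which is all the downstream analyses use.

The base number maps a karyotype to its ancestral-equivalent diploid
autosome count: XX0 → observed autosomes; XXY → +2; XXXY (or
XXXY-or-XYYY) → +4. The rationale is that each X-autosome fusion
converts one free autosome pair into sex-chromosome material, so the
rule inverts the fusions. Two policy choices:

* **Face value by default.** Uncertain scores (e.g. `26a?`) enter
  summaries and reconstructions at face value, with the flag carried so
  sensitivity runs can drop them. This matches how the study's own
  tallies treat them.
* **All-metacentric X0 complements** (a completed Robertsonian fusion
  series, e.g. `14m + Xm0`) are outside the rule. Default: unknown
  (missing data). Optional `arm_equivalents` mode scores the total
  autosome arm count (14 metacentrics → 28 arms), since Robertsonian
  fusions conserve arm number. The default is deliberately the
  conservative one; both are exposed.

## Parsimony

The engine is a Sankoff dynamic program over a rooted tree (polytomies
allowed): a down-pass computes, for every node and state, the minimum
subtree cost; an up-pass computes the minimum cost of the rest of the
tree. A state belongs to a node's MPR set iff down + up costs equal the
global minimum — i.e. membership is decided by an exact "fix this node
to this state" query, not by heuristic set rules. Branch transitions
are classified from the same quantities: an ordered pair (s → t) is
*possible* on a branch if some minimum-cost reconstruction uses it and
*obligate* if every one does. No single reconstruction is ever sampled;
ambiguity is always reported as the full MPR set.

Fitch parsimony is defined as unit-cost Sankoff. On polytomies this
gives a single unambiguous semantics and agrees with the
Fitch/Hartigan set-operation count, which the test suite implements
independently and checks against.

Directional models use an absorbing `FORBIDDEN` sentinel (IEEE
infinity), not a large finite cost, so forbidden paths can never win by
accumulation. Gains-only (0→1 costs 1, reversal forbidden, root pinned
to 0) counts minimum character origins; losses-only is its mirror. An
infeasible model yields an explicit infeasible result, not an
exception. A brute-force oracle enumerates all ancestral labelings
(guarded to ≤10⁶) and is the ground truth for engine tests.

Numerical notes: costs are floats; minimum-cost membership uses an
absolute 1e-9 tolerance, which is exact for the integer-valued unit and
directional models used in the analyses.

## The study analyses

* **Neo-Y origins.** The binary Y-presence character under gains-only
  parsimony gives the minimum number of independent origins and the
  branches that carry them (each obligate under the directional model);
  losses-only with a Y-constrained root gives the competing polarity's
  cost. On the bundled fixtures these are 4 and 7.
* **Base-number ancestry.** The base-number character, treated as
  unordered states under Fitch (the data contrast 26 vs 28; no step
  cost is imposed), reconstructed at three named ancestors: the tree
  root, the Jollas-Tomis MRCA, and the Attulus MRCA.
* **Sensitivity analysis** reruns the reconstruction with named
  (taxon, field) scores deleted. The state domain is fixed by the
  undeleted data so MPR sets stay comparable across scenarios; a
  scenario that deletes everything reports the full domain.
* **Origin context** is descriptive, not a significance test: for each
  origin branch, whether 28 is in the branch's MPR set or observed in a
  descendant tip, and the topologically nearest tip (minimum node hops;
  the fixture carries no branch lengths) with base number 26, with its
  Y state. On the bundled data all four origins sit in 28-autosome
  lineages; the nearest-26 report also surfaces the one oddity — under
  the literal counting rule *Sittisax ranieri* (24a + XXY) scores 26
  while carrying a Y.
* **Root condition.** Whether the deep ancestors are ambiguous without
  an imposed outgroup state is reported by running with and without a
  zero-length constraint tip observing 26 attached at the root, and not
  asserted a priori: the answer depends on how the uncertain tips are
  scored.

## Locus QC

Occupancy is the number of core taxa with any sequence at a locus (no
length floor); loci with fewer than the threshold (default 7) are
discarded. The long-branch statistic ranks all branches — terminal and
internal — of the gene tree treated as unrooted: the two root-adjacent
branches of a rooted binary representation are one unrooted branch and
are summed before ranking. This makes the ratio invariant to rooting,
which the tests verify across all rootings. The discard rule is
inclusive (ratio ≥ 5 by default, reading "at least five times longer"
literally); a zero second-longest branch with a positive longest is
treated as infinite ratio and discarded; loci without an evaluable tree
are kept and flagged, never silently dropped.

## Synthetic data

The generators exist so that every estimator in the package has a true
value to recover; no claim is made that they model real sitticine
evolution beyond the minimal structure the analyses invert.

* **Yule trees**: with k lineages the next split waits Exp(k·λ) and
  hits a uniform lineage; tips are contemporaneous. The test suite
  checks the scaled inter-speciation waits against Exp(1) by
  Kolmogorov-Smirnov across replicates.
* **Karyotype evolution**: a per-branch Gillespie simulation with four
  event types — pair gain (+2), pair loss (−2, blocked below 20
  autosomes), and the two irreversible fusions XX0→XXY→XXXY (each −2
  autosomes). Defaults put each rate at 0.06 events per unit branch
  length; on an 18-tip unit-rate Yule tree (expected total length 17)
  that is roughly three events per tree — sparse enough that parsimony
  should usually recover the true fusion count, which is the property
  the recovery test measures (≥90% of 200 fixed-seed replicates; the
  threshold is a test budget, not an estimate of anything). A
  fusion-rate multiplier applied when the autosome count is ≥28 lets
  simulations create or break the association between extra autosomes
  and neo-Y origins. Simulated morphology is all-acrocentric; XYYY,
  X0, and Robertsonian metacentric series are not simulated — they are
  outside the counting rule's domain, so passing recovery tests say
  nothing about such complements.
* **Locus sets**: per-taxon Bernoulli presence, Yule gene-tree
  topologies on the present taxa written unrooted (basal trifurcation,
  as single-search ML software emits), branch lengths redrawn iid
  Uniform(0.8, 1.2). Near-unit branches bound the background
  longest/second-longest ratio by 1.5, so a branch planted at scale ≥ 4
  is always the unique exceedance and the planted/clean labels are
  exact ground truth for the filter — by design: the generator
  validates the filter's decision rule, not its false-positive rate on
  realistic branch-length distributions.

## Fixtures

`sitticini_karyotypes.tsv` transcribes the study's male complement
table (18
species; multi-locality rows collapsed, specimen and nucleus tallies
summed; evidence columns are pass-through metadata never used in
computation). `sitticini_tree.nwk` is the 18-taxon karyotyped phylogeny,
topology only. Within subgenus *Sitticus* the resolution adopted is
(finschi,(pubescens,(fasciger,terebratus))) — pubescens nested within
the terebratus group with finschi basal — which is the arrangement
consistent with the published clade statements that also reproduces
the published reconstruction results (4 origins vs 7 losses, 28
uniquely ancestral for *Attulus* at face value, ambiguity after
deleting the two uncertain autosome counts, and a root resolvable only
under the imposed outgroup condition of 26).

## Known limitations

* Parsimony only: no likelihood or Bayesian ancestral reconstruction,
  no branch-length-aware models, no chromEvol-style rate estimation.
* The origin/base-number association is reported descriptively; the
  package deliberately implements no correlation test.
* The QC filters reproduce decision rules, not the study's actual locus
  counts, which would require the raw sequence data and stochastic ML
  gene-tree searches.
* Karyotype records describe males only; chiasma counts and meiotic
  behaviour are carried as free-text notes, not modeled.
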