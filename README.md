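# karyotrace

Karyotype evolution on phylogenies: parsimony reconstruction of neo-Y
sex-chromosome origins and ancestral base chromosome numbers from male
karyotype tables, together with the locus-QC filters used on the
phylogenomic side of such studies and ground-truthed synthetic-data
generators for testing all of it.

## The problem

Most jumping spiders (Salticidae) share a conservative male karyotype:
26 acrocentric autosomes plus X₁X₂0 sex chromosomes. The sitticine
jumping spiders are strikingly more variable — extra autosome pairs,
all-metacentric complements, and repeated, independently derived neo-Y
systems (XXY, XXXY) created by X-autosome fusions. `karyotrace`
implements the comparative machinery needed to analyse such a dataset
on a phylogeny:

* **Karyotype encoding.** Complement strings (`26a`, `14m`, `XaXaYa`,
  `XaXaXaYm|XmYaYaYa`) parse into validated records with uncertainty
  flags. The *base number* of a karyotype is its ancestral-equivalent
  diploid autosome count: the observed autosomes, plus 2 if the male
  system is XXY (one autosome pair bound into the sex chromosomes by a
  fusion) or plus 4 if XXXY (two pairs). An all-metacentric X0
  complement — the footprint of a completed Robertsonian fusion
  series — is outside the rule and scores unknown by default, or as the
  total autosome arm count in `arm_equivalents` mode.
* **Parsimony engine.** Fitch (unordered, symmetric) and Sankoff
  (arbitrary cost matrices, forbidden transitions, hard root
  constraints) ancestral-state reconstruction with exact MPR state sets
  per node and obligate/possible transition classification per branch,
  validated against a brute-force enumeration oracle. Directional
  models count minimum origins (gains-only, Camin-Sokal-like) or
  minimum losses (losses-only, Dollo-like).
* **Study drivers.** Neo-Y origin counting, ancestral base-number
  reconstruction, taxon-deletion sensitivity analysis, and a
  descriptive check of whether each neo-Y origin falls in a
  28-autosome lineage.
* **Locus QC.** Occupancy filtering (discard loci sequenced for fewer
  than *k* core taxa) and long-branch paralog filtering (discard loci
  whose gene tree's longest branch is at least five times the second
  longest, measured on the unrooted tree so the statistic is invariant
  to rooting).
* **Synthetic data.** Yule tree simulation, Gillespie simulation of
  pair gain/loss and irreversible X-autosome fusion events with full
  event logs, and locus sets with planted occupancy patterns and
  paralog branches.

The package bundles the study fixtures it was built around: an
18-species karyotype table and the matching 18-taxon phylogeny.

## Worked example

```python
from karyotrace import chromevo, datasets
from karyotrace.karyotypes import base_number, summarize_complements

tree = datasets.load_study_tree()          # 18-taxon sitticine phylogeny
records = datasets.load_karyotype_table()  # Table of male complements

summary = summarize_complements(records)
print(summary.n_standard, summary.n_neo_y, summary.total)
# 8 6 18   -> 8 species with the usual 26a+XX0, 6 with neo-Y systems

cutleri = next(r for r in records if r.species == "Attulus_cutleri")
print(base_number(cutleri).value)
# 28   -> 26 free autosomes + one pair bound into the XXY system

report = chromevo.y_origin_analysis(tree, records)
print(report.gains_only_cost, report.losses_only_cost)
# 4 7.0  -> neo-Y arose 4 times; a Y-ancestral reading needs 7 losses
print([c.in_28_lineage for c in report.origin_contexts])
# [True, True, True, True]  -> every origin sits in a 28-autosome lineage

attulus = [t for t in tree.tip_labels if t.startswith("Attulus")]
print(sorted(chromevo.base_number_ancestry(tree, records, attulus)))
# ['28']  -> 28 is the unique most-parsimonious Attulus ancestral state
```

The same analyses are exposed on the command line:

```
karyotrace reconstruct --out report.json
karyotrace reconstruct --delete Attinella_dorsata:autosomes \
                       --delete Attulus_burjaticus:autosomes
karyotrace locus-qc --alignments loci/alignments --trees loci/trees \
                    --core core.txt --min-occupancy 7 --ratio 5.0
karyotrace simulate --n-tips 18 --seed 1 --out-prefix sim
karyotrace make-loci --n-loci 200 --core core.txt \
                     --paralog-fraction 0.075 --out-dir loci
```

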