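# modessence

**Essentiality–centrality analysis of protein interaction networks at three
scales of organization: proteins, complexes, and functional modules.**

In *S. cerevisiae*, hub proteins in the physical interaction network are
more likely to be essential than low-degree proteins. A long-standing
question is *why*: is a protein's total degree what matters, or its
participation in essential functional modules? `modessence` implements the
analysis pipeline that dissects this question by categorizing every
interaction relative to a module universe (curated protein complexes, or
specific GO biological-process terms), and asking at each scale whether
essentiality tracks topology:

* **Protein level** — split each protein's annotated degree into
  *intramodular* (partner shares a module) and *intermodular* parts, and
  compare Spearman rank correlations (SRCC) with essentiality, including
  partial SRCCs controlling for one degree component, hub-fraction curves,
  Wilcoxon rank-sum comparisons, and a semantic-similarity-weighted degree
  (Lin similarity over a GO-style DAG):
  `tSS(t1,t2) = 2 log p(a*) / (log p(t1) + log p(t2))`, with `a*` the most
  informative common ancestor.
* **Within-complex level** — a per-complex permutation test: among
  complexes with ≥ 2 essential and ≥ 2 non-essential interacting members,
  count those where essential members have strictly higher mean
  intracomplex degree, and compare against within-complex label shuffles
  (empirical p over 10,000 permutations).
* **Module level** — infer a cross-talk network over modules: a module
  pair is connected when its intermodular interaction count exceeds the
  mean over 100 degree-preserving stub-rewired networks by an odds-score
  `(n_real + 1)/(n_rand + 1) ≥ 5` and is supported by ≥ 2 vertex-disjoint
  interactions; then relate per-module cross-talk degree to module
  essentiality.

Everything runs on synthetic interactomes with planted structure (modular
edge blocks, degree-dependent essentiality, planted cross-talk pairs), so
the full pipeline is testable end to end without downloading BioGRID, GO or
complex catalogs — while the parsers accept the corresponding real file
formats (tab-delimited interaction tables, OBO 1.2, GAF 2.x, TSV module
catalogs) for real-data runs.

The package is for computational/systems biologists studying
centrality–lethality relationships, module-level network organization, or
needing a tested implementation of constrained degree-preserving
randomization and odds-score enrichment for module pairs.

## Worked example

Generate the default synthetic study (2,000 proteins, 40 complexes,
p_in = 0.3, p_out = 0.005, 20 planted cross-talk pairs) and run the full
pipeline:

```sh
modessence simulate --seed 17 --out fixture/
modessence run --fixture fixture/ --seed 17 --out results/
```

or equivalently in Python:

```python
from modessence import GeneratorConfig, RunConfig, generate_study, run_all
from modessence.synthetic import write_fixture

write_fixture(generate_study(GeneratorConfig(seed=17)), "fixture/")
bundle = run_all(RunConfig(fixture_dir="fixture/", seed=17, out_dir="results/"))
print(bundle["correlations"])
```

At seed 17 this prints (rounded):

| quantity | rho |
|---|---|
| SRCC(essential, intramodular degree) | 0.515 |
| SRCC(essential, intermodular degree) | 0.129 |
| SRCC(essential, total annotated degree) | 0.414 |
| partial SRCC(essential, total \| intra) | 0.161 |
| partial SRCC(essential, total \| inter) | 0.491 |

Intramodular degree correlates with essentiality far more than
intermodular degree, and controlling for intramodular degree collapses the
total-degree correlation (0.414 → 0.161) while controlling for
intermodular degree does not — the essentiality signal lives in the
intramodular interactions. The per-complex permutation test reports 27
testable complexes, 25 of which (92.6%) show higher mean essential
intracomplex degree, empirical p = 1e-4 at 10,000 permutations. Cross-talk
inference recovers all 20 planted module pairs (precision 1.0, recall 1.0)
and SRCC between binary module essentiality and cross-talk degree is 0.35.

All outputs are written as TSV (degree tables, hub curves, correlation and
Wilcoxon panels, permutation-test row, cross-talk edge/node tables) plus a
JSON run manifest; one top-level seed makes reruns bit-identical.

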