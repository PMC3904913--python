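# sempar

Semantic **similarity** and semantic **particularity** measures for
ontology-annotated gene sets.

Similarity measures quantify what two genes' annotation sets share; they say
nothing about what each set has *in addition*. `sempar` complements a
symmetric set similarity (Wang's semantic-value similarity, or Lin's
IC similarity) with a non-symmetric particularity value `Par(S1, S2)` in
[0, 1], so a pair of genes is described by the tuple `(Sim, Par12, Par21)`:
high similarity with a high one-sided particularity flags a gene that shares
its main functions with the other but also carries substantial functions of
its own.

Given two direct annotation sets `S1`, `S2` and a term informativeness `I`:

- `S*` is a set expanded with all ancestors of its members;
- `MPT(S1, S2)` — terms of `S1` with no descendant in `S1` and absent from `S2*`;
- `MCT(S1, S2)` — terms of `S1* ∩ S2*` with no descendant in `S1*` or `S2*`;
- `PI(S1, S2) = Σ_{t ∈ MPT} [I(t) − I(MICA(t, S2))]`, where the MICA is the
  most informative common ancestor of `t` and `S2`;
- `Par(S1, S2) = PI / (PI + Σ_{t ∈ MCT} I(t))`.

`I` can be Wang's corpus-free semantic value (sum of maximum edge-factor
products over ancestors; factors 0.8 for `is_a`, 0.6 for `part_of`, 0.7 for
the `regulates` family, all configurable), a corpus information content
`−log p(t)` with annotation-propagated frequencies, or an explicit table.

## Layout

| module | contents |
| --- | --- |
| `sempar.ontology` | OBO 1.2/1.4 reader, typed weighted DAG, ancestor/descendant queries |
| `sempar.annotations` | GAF 2.x / two-column TSV reader, set expansion, propagated frequencies |
| `sempar.informativeness` | semantic value, information content, table backings |
| `sempar.measures` | MPT/MCT/MICA/PI/Par, Wang & Lin term similarity, set similarity (bma/max/avg), `compare` |
| `sempar.pipeline` | pairwise gene matrices, 20-bin particularity statistics, Sim/Par profile classification, TSV I/O |
| `sempar.fixtures` | seeded random ontologies/corpora, OBO/TSV emitters, the three-species worked-example fixture |

## Library quick start

```python
from sempar import (
    load_obo, load_gaf, SemanticValueModel, compare,
)

g = load_obo("go.obo", namespace_filter="molecular_function")
corpus = load_gaf("annotations.gaf", g, namespace="molecular_function")
backing = SemanticValueModel(g)
c = compare(g, backing, corpus.gene_terms["GENE1"], corpus.gene_terms["GENE2"])
print(c.sim, c.par12, c.par21)
```

## CLI

```sh
# one pair -> JSON tuple
sempar compare --obo go.obo --gaf ann.gaf --namespace molecular_function \
    --method sv --genes GENE1,GENE2

# cohort matrix -> TSV, then binned statistics and profile counts
sempar matrix --obo go.obo --gaf ann.gaf --namespace molecular_function \
    --method sv --genes-file genes.txt --out pairs.tsv
sempar bins --in pairs.tsv --out bins.tsv
sempar profiles --in pairs.tsv --theta-sim 0.5 --theta-par 0.5

# seeded synthetic ontology + annotations for experimentation
sempar fixtures make --spec '{"n_terms": 50, "n_genes": 10, "seed": 1}' --out-dir fx/
```

`--method sv` uses Wang semantic values (and Wang similarity); `--method ic`
uses corpus IC (and Lin similarity). Edge factors are overridable with
`--weights is_a=0.8,part_of=0.6,regulates=0.7`.

## Conventions and edge cases

- `Par(S, S) = 0`; `Par(S, ∅) = 1` and `Par(∅, S) = 0` for nonempty `S`;
  `Par(∅, ∅)` raises.
- When both `MPT` and `MCT` are empty (e.g. `S1 = {root}` against a deeper
  set) the ratio is 0/0; `sempar` returns 0 and logs a warning.
- Similarity bins are half-open `[lo, lo + 0.025)` over `[0.5, 0.999]`, the
  last bin closed; `sim = 1.0` pairs are excluded from bins. Both
  particularity directions are pooled by default.
- A comparison is *valid* only when both genes carry at least one annotation;
  invalid pairs are reported with a reason, never silently dropped.
- Evidence codes are retained as metadata and never used as weights.
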