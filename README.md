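# adiposcreen

An in-silico drug-repositioning cascade for **white-fat browning** — the
conversion of energy-storing white adipose tissue (WAT) into thermogenic,
brown-fat-like (beige) tissue, an attractive route to anti-obesity
therapy. Starting from literature evidence, the cascade narrows a genome
of candidates down to a short list of target genes and the existing
drugs that hit them:

1. **Literature mining** — three query phrases ("brown-fat-like
   development", "brown fat", "brown adipose tissue") each retrieve the
   genes linked to matching documents; the intersection of the three
   lists seeds the analysis.
2. **Two-stage enrichment** — the intersection is tested against
   biological-process annotations, and the genes of the passing terms are
   then tested against pathway annotations. Significance is the
   hypergeometric upper tail
   `P(X ≥ k) = Σ_{i=k}^{min(K,n)} C(K,i)·C(N−K,n−i) / C(N,n)`
   for `k` of `n` query genes falling in a size-`K` term within a
   size-`N` universe, corrected across terms (Benjamini–Hochberg by
   default) with cutoffs `1.00e−07` (process) and `1.00e−06` (pathway).
3. **Interaction network** — the surviving genes are joined on a
   STRING-dialect weighted edge list at confidence ≥ 0.900, isolated
   genes are removed, and per-node degree and Freeman betweenness are
   computed. **Key nodes** are the genes whose degree *and* betweenness
   both reach their network-wide means.
4. **Anchor augmentation** — the gene membership of the most browning-
   relevant enriched process ("brown fat cell differentiation") is merged
   into the key-node list to form the final target list.
5. **Drug funnel** — catalog drugs are matched to the final targets,
   then filtered by development status (launched / clinical phases
   I–III / pre-registration / registered), by documented development
   detail, and by a mechanism-of-action blacklist (beta-1 adrenoceptor
   agonists/antagonists, interleukin-6 antagonists, CREB-binding protein
   inhibitors); survivors are tabulated by mechanism class.

Because the original screen ran against live web services, the package
ships two substitutes: a **synthetic-data generator** that emulates all
four inputs with planted ground truth (so every stage is testable
offline), and the **published gene lists** as packaged fixtures (so the
downstream half of the cascade reproduces the published 18-gene target
list exactly).

## Worked example

Generate a synthetic study and run the full cascade on it:

```sh
$ adiposcreen simulate --seed 7 --out-dir demo/data
wrote synthetic bundle to demo/data (core=30, hubs=3, eligible drugs=33)

$ adiposcreen run --input-dir demo/data --out-dir demo/out
final genes: 17; final drugs: 33
  funnel matched: 83
  funnel status: 58
  funnel detail: 43
  funnel mechanism: 33
```

The three planted query lists intersect in a 30-gene core; enrichment
recovers the planted terms; the network stage finds the 3 planted hub
genes (plus one planted isolate, removed); augmentation with the anchor
term's genes yields 17 final targets for this seed; and the drug funnel
narrows 83 matched drugs to the 33 planted eligible ones — 25 fall to
the status whitelist, 15 to the development-detail requirement, 10 to
the mechanism blacklist. `demo/data/manifest.json` records the planted
truth; `demo/out/` holds every stage's table and the funnel report.

Reproducing the published final gene list from the packaged fixtures:

```sh
$ adiposcreen fixtures --out-dir demo/fx
final list (18): ADIPOQ, CREBBP, FABP4, IL6, INS, LEP, LPL, PIK3R1,
PPARG, ADIG, ADRB1, ADRB3, CEBPB, MRAP, PPARGC1A, PRDM16, SLC2A4, UCP1
```

— the 9 key genes from the network analysis plus the 13 "brown fat cell
differentiation" genes, deduplicated to 18.

The same flows are available as a library:

```python
from adiposcreen import (GeneratorConfig, generate, load_published_fixtures,
                         augment_with_anchor)

bundle = generate(GeneratorConfig(seed=7))   # in-memory, with manifest
fx = load_published_fixtures()
final = augment_with_anchor(fx.key_genes, fx.anchor)
len(final)  # 18
```

## Layout

- `src/adiposcreen/corpus.py` — literature queries and intersection
- `src/adiposcreen/enrichment.py` — hypergeometric tail, correction, enrichment
- `src/adiposcreen/network.py` — interaction network, centrality, key nodes
- `src/adiposcreen/prioritize.py` — anchor augmentation
- `src/adiposcreen/drugs.py` — drug funnel and class tally
- `src/adiposcreen/synthetic.py` — generator with planted truth
- `src/adiposcreen/fixtures.py` — packaged published gene lists
- `src/adiposcreen/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — modelling notes, parameter choices, limitations
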