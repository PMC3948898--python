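# consilience

Consensus-evidence pipelines for two recurring problems in computational
drug-target work, built around one shared validation core:

1. **Consensus miRNA-target prediction.** Three algorithmically different
   target-prediction programs each emit scored candidate miRNA-target
   interactions (MTIs). Keeping only predictions that clear each program's
   high-precision threshold (miTG score > 0.7; mirSVR score ≤ −0.1;
   context+ score ≥ −1.67 with ≥ 1 conserved site) and intersecting the
   three reliable sets yields a low-false-positive consensus model, which
   is validated on truth sets built from over-expression proteomics
   (proteins up under miRNA over-expression ⇒ known-false pair) and
   direct-evidence curation (reporter-gene assays ⇒ known-true pair).
2. **Conformer-ensemble virtual screening.** A receptor ensemble (crystal
   structure + MD snapshots) is represented as columns of a compound ×
   conformer score table with a two-phase rank (grid score, then re-rank
   score, lower = better). Each conformer is benchmarked on actives/decoys
   at top-fraction cutoffs (10%…100%); conformers strictly beating the
   reference structure on ACC, PPV **and** FPR are "valid"; candidate hits
   are compounds ranking in the top 10% for at least k valid conformers.

Both frameworks are scored with the same confusion-matrix metrics,

    ACC = 100·(TP+TN)/total,  PPV = 100·TP/(TP+FP),  FPR = 100·FP/(FP+TN),

and ranked screens with the rank AUC (probability a random active outranks
a random decoy, ties at 1/2). Supporting stages: a SAM-style two-class
permutation-FDR differential-expression filter with a 2-fold floor, a
hypergeometric term-enrichment filter (p < 0.05 and fold enrichment ≥ 2),
multi-source interaction-list integration, and fully seeded synthetic-data
generators so every stage runs with no external downloads. See
`docs/methods.md` for the models and design choices.

## Worked example

Generate a synthetic 26-conformer docking benchmark (39 actives, 1448
decoys), evaluate every conformer at the 10% cutoff, select valid
conformers and call consensus hits:

```sh
consilience simulate dock --seed 5 --out demo/
consilience screen evaluate demo/scores.tsv --labels demo/labels.tsv \
    --reference t0000ps --cutoffs 0.1,0.2 --out demo/eval.tsv
consilience screen consensus demo/scores.tsv --labels demo/labels.tsv \
    --reference t0000ps --q 0.1 --k all --out demo/hits.tsv
```

which prints

```
wrote 1487 compounds x 26 conformers to demo (reference t0000ps)
evaluated 26 conformer(s) at 2 cutoff(s)
valid conformers: 3; consensus hits (k=3): 10
```

Here 3 of the 26 conformers (including the reference itself) survive the
strictly-better-on-all-three-metrics rule at the 10% cutoff, and 10
compounds rank in the top 10% for every valid conformer — the all-conformer consensus hit list written to
`demo/hits.tsv`, with the per-k strategy comparison in
`demo/hits.k_of_n.json`. The same library surface is importable directly
(`consilience.screen`, `consilience.mti`, `consilience.expression`,
`consilience.integration`, `consilience.synthetic`); the other subcommands
are `mti predict|validate`, `expr filter`, `enrich`, `integrate union` and
`simulate mti|expr|annot`.

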