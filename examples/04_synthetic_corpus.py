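"""Generate a synthetic corpus, run the pipeline, and score it against gold.

The generator emulates the FHH-section entry structure (coded fields plus
telegraphic comments) and knows exactly which relative/condition/onset
each entry intends, so extraction quality can be measured without any
real data.  On a clean corpus the pipeline recovers the gold relations
perfectly; adding typos to comment terms knocks recall down.
"""

from fhhkit import (
    SimParams,
    bootstrap_ci,
    generate_corpus,
    perturb_typos,
    process_entry,
    relation_signatures,
    score_relations,
)

params = SimParams(n_patients=300, seed=7)
corpus = generate_corpus(params)
print(f"{len(corpus.entries())} entries for {params.n_patients} patients (seed {params.seed})")


def score(c):
    pred = {e.entry_id: relation_signatures(process_entry(e)) for e in c.entries()}
    gold = {eid: list(g.relations) for eid, g in c.gold.items()}
    return score_relations(pred, gold)


clean = score(corpus)
print("\nclean corpus:")
print(clean.table())

noisy = score(perturb_typos(corpus, rate=0.3, seed=11))
print("\nwith typos in 30% of condition terms:")
print(noisy.table())

ci = bootstrap_ci(noisy.per_entry_counts, "f1", B=1000, seed=1)
print(f"\nmicro F1 95% CI under typos: {ci[0]:.3f}-{ci[1]:.3f}")

# Clean recovery is exact (F1 = 1.0) because the templates only use
# vocabulary the extractor knows; typos are out-of-vocabulary by design,
# so only recall — never gold — changes.
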