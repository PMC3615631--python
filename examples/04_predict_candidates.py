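"""Train on all known associations and rank novel candidate diseases for
one miRNA of interest.

Every disease already confirmed for the miRNA becomes a restart seed;
every other disease is scored by its steady-state visiting probability.
High-scoring candidates are hypotheses for experimental follow-up.
"""

from omimwalk import (
    RWRConfig,
    benchmark_shaped_config,
    generate,
    normalize,
    score_candidates,
)

sim, assoc, ground_truth = generate(benchmark_shaped_config(rng_seed=42))
W = normalize(sim)

mirna = assoc.mirna_ids[0]
known = sorted(assoc.diseases_of(mirna))
print(f"miRNA {mirna}: {len(known)} known disease(s): {', '.join(known)}")
print(f"home cluster: {ground_truth[mirna]}")

records = score_candidates(mirna, assoc, W, RWRConfig())[:10]
print("rank\tdisease\tscore")
for r in records:
    print(f"{r.rank}\t{r.disease_id}\t{r.score:.6f}")
# The top-ranked candidates are the diseases most phenotypically similar
# to the miRNA's known diseases; none of them is already in the training
# associations.
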