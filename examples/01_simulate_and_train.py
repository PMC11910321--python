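"""Generate a planted-rule corpus and train the interaction model.

The synthetic corpus couples random peptides and receptors under a known
ground truth: a pair interacts exactly when the peptide contains the 5-mer
QFFGL and the receptor carries F at generic position 3.24 and G at 4.61.
Training a linear SVM on motif x z-scale outer-product features should
separate the classes and generalize to held-out pairings.
"""

from sklearn.metrics import roc_auc_score

from idlscore import PlantedRule, generate_corpus, predict, split_pairs, train

rule = PlantedRule("QFFGL", (("3.24", "F"), ("4.61", "G")), noise=0.05)
corpus, truth = generate_corpus(n_peptides=60, n_receptors=20, rule=rule, seed=1)
print(f"corpus: {len(corpus.peptides)} peptides x {len(corpus.receptors)} receptors "
      f"= {len(corpus.cpis)} labeled pairs ({len(corpus.positives)} positive)")

train_corpus, held_out = split_pairs(corpus, test_fraction=0.25, seed=1)
model = train(train_corpus, seed=1)

dists = [
    predict(model, corpus.peptides[r.peptide_id], corpus.receptors[r.receptor_id]).dist
    for r in held_out
]
labels = [1 if r.is_positive else 0 for r in held_out]
print(f"held-out ROC AUC over {len(held_out)} unseen pairings: "
      f"{roc_auc_score(labels, dists):.3f}")
print("a value near 1 means the signed decision value (dist) ranks unseen")
print("interacting pairs above non-interacting ones almost perfectly")
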