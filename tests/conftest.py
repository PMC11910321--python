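import numpy as np
import pytest
from hypothesis import settings

from idlscore import (
    PlantedRule,
    generate_corpus,
    train,
)
from idlscore.synthetic import default_reference_positions

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: noiseless planted rule used by most fixtures; positions exist in any
#: default reference list with >= 3 positions per helix
RULE = PlantedRule("QFFGL", (("3.24", "F"), ("4.61", "G")), noise=0.0)


@pytest.fixture(scope="session")
def small_corpus():
    corpus, truth = generate_corpus(
        n_peptides=24,
        n_receptors=10,
        peptide_length_range=(8, 12),
        reference_positions=default_reference_positions(21),
        rule=RULE,
        seed=7,
    )
    return corpus, truth


@pytest.fixture(scope="session")
def small_model(small_corpus):
    corpus, _ = small_corpus
    return train(corpus, seed=7)


def random_weight_model(n_peptides=4, n_positions=7, seed=0, gap_indices=(), mask_density=0.7):
    """A TrainedModel with random weights over a small random corpus's
    feature grid — decomposition identities hold for any weights, so tests
    need not pay for an SVM fit."""
    from idlscore.descriptors import ZScaleTable, build_vocabulary
    from idlscore.model import FeatureMask, TrainConfig, TrainedModel
    from idlscore.seqdata import AMINO_ACIDS, Peptide, Receptor

    rng = np.random.default_rng(seed)
    aas = np.array(list(AMINO_ACIDS))
    peptides = [
        Peptide(f"p{k}", "".join(rng.choice(aas, size=int(rng.integers(6, 11)))))
        for k in range(n_peptides)
    ]
    positions = default_reference_positions(max(7, n_positions))[:n_positions]
    vocab = build_vocabulary(peptides)
    n_j = 5 * n_positions
    sel = rng.random(len(vocab) * n_j) < mask_density
    if not sel.any():
        sel[0] = True
    weights = rng.normal(0, 1, int(sel.sum()))

    tm = {}
    seq_idx = 1
    residues = []
    for m, label in enumerate(positions):
        if m in gap_indices:
            tm[label] = None
        else:
            tm[label] = seq_idx
            residues.append(str(rng.choice(aas)))
            seq_idx += 1
    receptor = Receptor("r0", "".join(residues) or "A", tm)

    model = TrainedModel(
        vocab=vocab,
        zscales=ZScaleTable.default(),
        reference_positions=tuple(positions),
        mask=FeatureMask(len(vocab), n_j, sel),
        weights=weights,
        intercept=float(rng.normal()),
        config=TrainConfig(),
        seed=seed,
    )
    return model, peptides, receptor
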