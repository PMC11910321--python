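"""Combination features and the linear interaction model.

Each labeled pair is represented as the linearized outer product of its
peptide descriptor (binary motif occurrences, elements i) and receptor
descriptor (per-position z-scales, elements j): x[i,j] = pD_i * gD_j.  A
soft-margin linear SVM fit on these vectors yields a signed decision value

    dist(x) = sum_{i,j} w[i,j] * pD_i * gD_j + b

whose sign predicts interaction (positive side = interacting; an exact tie
at zero is called negative).  Because pD is binary and each receptor element
j belongs to exactly one generic position, the weighted sum decomposes
exactly into per-residue contributions — see :mod:`idlscore.idl`.

Negatives are generated by swapping: each non-interacting pair combines the
peptide of one known interaction with the receptor of a different one,
excluding any pair that is itself a known interaction.

Feature selection, where requested, is a seeded genetic algorithm over
binary masks of the combination features, scored by cross-validated ROC AUC
with a mild sparsity penalty.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .descriptors import (
    MotifVocabulary,
    PeptideDescriptor,
    ReceptorDescriptor,
    ZSCALE_DIM,
    ZScaleTable,
    build_gd,
    build_pd,
    build_vocabulary,
)
from .seqdata import CPIRecord, Corpus, NEGATIVE, Peptide, Receptor


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Swap negatives


def generate_negatives(positives: Sequence[CPIRecord], seed: int) -> list[CPIRecord]:
    """Generate |positives| non-interacting pairs by swapping partners.

    Every emitted pair takes its peptide and receptor from two *different*
    positive records, never duplicates a positive pair or another negative,
    and the multiset of emitted pairs is reproducible under ``seed``.
    """
    positives = list(positives)
    n = len(positives)
    positive_pairs = {p.pair for p in positives}
    candidates: set[tuple[str, str]] = set()
    for k, a in enumerate(positives):
        for l, b in enumerate(positives):
            if k == l:
                continue
            pair = (a.peptide_id, b.receptor_id)
            if pair not in positive_pairs:
                candidates.add(pair)
    if len(candidates) < n:
        raise ModelError(
            f"cannot generate {n} swap negatives: only {len(candidates)} distinct "
            f"non-positive swapped pairs exist (deficit {n - len(candidates)})"
        )
    ordered = sorted(candidates)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(ordered), size=n, replace=False)
    return [CPIRecord(*ordered[k], NEGATIVE) for k in sorted(chosen)]


# ---------------------------------------------------------------------------
# Combination features


@dataclass(frozen=True)
class FeatureMask:
    """Binary mask over the |vocab| x 5P combination-feature grid."""

    n_motifs: int
    n_receptor_elements: int
    selected: np.ndarray  # bool, flat length n_motifs * n_receptor_elements

    def __post_init__(self) -> None:
        sel = np.asarray(self.selected, dtype=bool).ravel()
        if sel.size != self.n_features:
            raise ModelError("mask length does not match the feature grid")
        object.__setattr__(self, "selected", sel)

    @property
    def n_features(self) -> int:
        return self.n_motifs * self.n_receptor_elements

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def pairs(self) -> list[tuple[int, int]]:
        """Selected features as 0-based (motif index i, receptor element j)."""
        flat = np.flatnonzero(self.selected)
        return [(int(f) // self.n_receptor_elements, int(f) % self.n_receptor_elements) for f in flat]

    @classmethod
    def full(cls, n_motifs: int, n_receptor_elements: int) -> "FeatureMask":
        return cls(n_motifs, n_receptor_elements, np.ones(n_motifs * n_receptor_elements, bool))


@dataclass(frozen=True)
class CombinationVector:
    """Sparse linearized outer product x[i,j] = pD_i * gD_j."""

    n_motifs: int
    n_receptor_elements: int
    indices: np.ndarray  # flat feature indices i * n_receptor_elements + j
    values: np.ndarray

    def dense(self) -> np.ndarray:
        v = np.zeros(self.n_motifs * self.n_receptor_elements)
        v[self.indices] = self.values
        return v

    def __getitem__(self, ij: tuple[int, int]) -> float:
        i, j = ij
        flat = i * self.n_receptor_elements + j
        hit = np.flatnonzero(self.indices == flat)
        return float(self.values[hit[0]]) if hit.size else 0.0


def featurize(
    pd: PeptideDescriptor,
    gd: ReceptorDescriptor,
    mask: Optional[FeatureMask] = None,
) -> CombinationVector:
    """Outer-product featurization of one peptide-receptor pair.

    With a mask, features outside it are dropped (their value is treated
    as absent, equivalently zero-weighted).
    """
    n_j = gd.values.size
    active = np.asarray(pd.active, dtype=int)
    if active.size == 0:
        indices = np.empty(0, dtype=int)
        values = np.empty(0)
    else:
        cols = np.arange(n_j)
        indices = (active[:, None] * n_j + cols[None, :]).ravel()
        values = np.tile(gd.values, active.size)
    if mask is not None:
        if mask.n_motifs != pd.n_motifs or mask.n_receptor_elements != n_j:
            raise ModelError("mask shape does not match the descriptors")
        keep = mask.selected[indices]
        indices, values = indices[keep], values[keep]
    return CombinationVector(pd.n_motifs, n_j, indices, values)


def design_matrix(
    pds: Sequence[PeptideDescriptor], gds: Sequence[ReceptorDescriptor]
) -> sp.csr_matrix:
    """Stack pairwise combination vectors into a sparse design matrix."""
    if len(pds) != len(gds):
        raise ModelError("pds and gds must pair up one-to-one")
    n_j = gds[0].values.size
    n_features = pds[0].n_motifs * n_j
    data, indices, indptr = [], [], [0]
    for pd_, gd_ in zip(pds, gds):
        cv = featurize(pd_, gd_)
        data.append(cv.values)
        indices.append(cv.indices)
        indptr.append(indptr[-1] + cv.indices.size)
    return sp.csr_matrix(
        (np.concatenate(data) if data else np.empty(0),
         np.concatenate(indices) if indices else np.empty(0, int),
         np.array(indptr)),
        shape=(len(pds), n_features),
    )


# ---------------------------------------------------------------------------
# Genetic-algorithm feature selection


@dataclass
class GAConfig:
    """Knobs of the genetic algorithm over feature masks.

    Fitness of a chromosome = mean k-fold cross-validated ROC AUC of a
    linear SVM restricted to the selected features, minus
    ``sparsity_penalty`` times the selected fraction.
    """

    population_size: int = 50
    generations: int = 20
    tournament_size: int = 3
    crossover_prob: float = 0.5
    mutation_rate: Optional[float] = None  # default 1 / n_features
    cv_folds: int = 5
    sparsity_penalty: float = 0.01


def _cv_auc(X: sp.csr_matrix, y: np.ndarray, C: float, folds: int, seed: int) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        clf = LinearSVC(C=C, random_state=seed)
        clf.fit(X[tr], y[tr])
        aucs.append(roc_auc_score(y[te], clf.decision_function(X[te])))
    return float(np.mean(aucs))


def mask_fitness(
    X: sp.csr_matrix,
    y: np.ndarray,
    chromosome: np.ndarray,
    config: GAConfig,
    seed: int,
    C: float = 1.0,
) -> float:
    """Penalized CV-AUC fitness of one binary chromosome."""
    cols = np.flatnonzero(chromosome)
    if cols.size == 0:
        return -np.inf
    auc = _cv_auc(X[:, cols], y, C, config.cv_folds, seed)
    return auc - config.sparsity_penalty * cols.size / chromosome.size


def select_features_ga(
    X: sp.csr_matrix,
    y: np.ndarray,
    config: Optional[GAConfig] = None,
    seed: int = 0,
    C: float = 1.0,
) -> np.ndarray:
    """Evolve a binary feature mask maximizing penalized CV AUC.

    The initial population seeds one all-features chromosome (so the GA can
    never end below the unselected baseline it started from) plus random
    half-density chromosomes.  Tournament selection, uniform crossover,
    per-bit mutation, and single-elite carryover; fully deterministic under
    ``seed``.  Returns the best chromosome as a boolean array.
    """
    config = config or GAConfig()
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ModelError("feature selection needs both labels present")
    ptp = X.max(axis=0).toarray().ravel() - X.min(axis=0).toarray().ravel()
    if not np.any(ptp > 0):
        raise ModelError("all features are constant; nothing to select")
    n_features = X.shape[1]
    mut = config.mutation_rate if config.mutation_rate is not None else 1.0 / n_features
    rng = np.random.default_rng(seed)

    population = [np.ones(n_features, dtype=bool)]
    while len(population) < config.population_size:
        population.append(rng.random(n_features) < 0.5)

    cache: dict[bytes, float] = {}

    def fitness(chrom: np.ndarray) -> float:
        key = np.packbits(chrom).tobytes()
        if key not in cache:
            cache[key] = mask_fitness(X, y, chrom, config, seed, C)
        return cache[key]

    scores = np.array([fitness(c) for c in population])
    for _ in range(config.generations):
        elite_idx = int(np.argmax(scores))
        next_pop = [population[elite_idx].copy()]
        while len(next_pop) < config.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, len(population), size=config.tournament_size)
                parents.append(population[contenders[np.argmax(scores[contenders])]])
            child = parents[0].copy()
            if rng.random() < config.crossover_prob:
                take = rng.random(n_features) < 0.5
                child[take] = parents[1][take]
            flip = rng.random(n_features) < mut
            child[flip] = ~child[flip]
            if not child.any():
                child[rng.integers(0, n_features)] = True
            next_pop.append(child)
        population = next_pop
        scores = np.array([fitness(c) for c in population])
    return population[int(np.argmax(scores))].copy()


# ---------------------------------------------------------------------------
# Training and prediction


@dataclass
class TrainConfig:
    """Training knobs: SVM cost and optional GA feature selection."""

    C: float = 1.0
    feature_selection: Optional[GAConfig] = None
    tol: float = 1e-6
    max_iter: int = 20000


@dataclass(frozen=True)
class DecisionResult:
    """Signed decision value and its sign-based interaction call."""

    dist: float
    predicted_label: str

    @property
    def is_positive(self) -> bool:
        return self.predicted_label == "positive"


@dataclass
class TrainedModel:
    """Self-contained linear interaction model.

    Holds everything needed to score a new peptide-receptor pair: the motif
    vocabulary, the z-scale table, the reference generic-position list, the
    selected combination features with their weights, and the intercept.
    """

    vocab: MotifVocabulary
    zscales: ZScaleTable
    reference_positions: tuple[str, ...]
    mask: FeatureMask
    weights: np.ndarray  # aligned with mask.pairs()
    intercept: float
    config: TrainConfig
    seed: int

    @property
    def n_receptor_elements(self) -> int:
        return ZSCALE_DIM * len(self.reference_positions)

    def weight_matrix(self) -> np.ndarray:
        """Dense w[i, j] over the full grid; zeros outside the mask."""
        W = np.zeros(self.mask.n_features)
        W[np.flatnonzero(self.mask.selected)] = self.weights
        return W.reshape(self.mask.n_motifs, self.mask.n_receptor_elements)

    def describe_pair(
        self, peptide: Peptide, receptor: Receptor
    ) -> tuple[PeptideDescriptor, ReceptorDescriptor]:
        return (
            build_pd(peptide, self.vocab),
            build_gd(receptor, self.zscales, self.reference_positions),
        )

    def decision_value(self, peptide: Peptide, receptor: Receptor) -> float:
        pd_, gd_ = self.describe_pair(peptide, receptor)
        cv = featurize(pd_, gd_, self.mask)
        W = self.weight_matrix().ravel()
        return float(W[cv.indices] @ cv.values + self.intercept)

    # -- serialization (single JSON archive) --

    def save(self, path: Path | str) -> Path:
        path = Path(path)
        payload = {
            "format": "idlscore-model",
            "version": 1,
            "vocab": list(self.vocab.motifs),
            "zscales": self.zscales.as_dict(),
            "reference_positions": list(self.reference_positions),
            "selected_features": [[i, j] for i, j in self.mask.pairs()],
            "weights": [float(w) for w in self.weights],
            "intercept": self.intercept,
            "config": {
                "C": self.config.C,
                "tol": self.config.tol,
                "max_iter": self.config.max_iter,
                "feature_selection": asdict(self.config.feature_selection)
                if self.config.feature_selection
                else None,
            },
            "seed": self.seed,
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def load(cls, path: Path | str) -> "TrainedModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "idlscore-model":
            raise ModelError(f"{path}: not an idlscore model archive")
        vocab = MotifVocabulary(tuple(payload["vocab"]))
        positions = tuple(payload["reference_positions"])
        n_j = ZSCALE_DIM * len(positions)
        sel = np.zeros(len(vocab) * n_j, dtype=bool)
        for i, j in payload["selected_features"]:
            sel[i * n_j + j] = True
        cfg = payload["config"]
        fs = cfg.get("feature_selection")
        return cls(
            vocab=vocab,
            zscales=ZScaleTable(payload["zscales"]),
            reference_positions=positions,
            mask=FeatureMask(len(vocab), n_j, sel),
            weights=np.asarray(payload["weights"], dtype=float),
            intercept=float(payload["intercept"]),
            config=TrainConfig(
                C=cfg["C"], tol=cfg["tol"], max_iter=cfg["max_iter"],
                feature_selection=GAConfig(**fs) if fs else None,
            ),
            seed=int(payload["seed"]),
        )


def _corpus_design(
    corpus: Corpus,
    vocab: MotifVocabulary,
    zscales: ZScaleTable,
    records: Sequence[CPIRecord],
) -> tuple[sp.csr_matrix, np.ndarray]:
    gd_cache = {
        rid: build_gd(rec, zscales, corpus.reference_positions)
        for rid, rec in corpus.receptors.items()
    }
    pd_cache = {pid: build_pd(p, vocab) for pid, p in corpus.peptides.items()}
    pds = [pd_cache[r.peptide_id] for r in records]
    gds = [gd_cache[r.receptor_id] for r in records]
    y = np.array([1 if r.is_positive else 0 for r in records])
    return design_matrix(pds, gds), y


def train(
    corpus: Corpus,
    config: Optional[TrainConfig] = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit the linear interaction model on a corpus.

    The motif vocabulary is frozen from the corpus peptides.  If the corpus
    carries no negative records, swap negatives are generated to match the
    positives.  With ``config.feature_selection`` set, a GA mask is evolved
    first and the final SVM is refit on the selected features.
    """
    config = config or TrainConfig()
    positives = corpus.positives
    negatives = corpus.negatives
    if not positives:
        raise ModelError("corpus has no positive records")
    if not negatives:
        negatives = generate_negatives(positives, seed)
    records = positives + negatives

    vocab = build_vocabulary(list(corpus.peptides.values()))
    zscales = ZScaleTable.default()
    X, y = _corpus_design(corpus, vocab, zscales, records)
    if len(np.unique(y)) < 2:
        raise ModelError("training requires both positive and negative examples")

    n_j = ZSCALE_DIM * len(corpus.reference_positions)
    if config.feature_selection is not None:
        chrom = select_features_ga(X, y, config.feature_selection, seed=seed, C=config.C)
        mask = FeatureMask(len(vocab), n_j, chrom)
    else:
        mask = FeatureMask.full(len(vocab), n_j)

    cols = np.flatnonzero(mask.selected)
    clf = LinearSVC(C=config.C, tol=config.tol, max_iter=config.max_iter, random_state=seed)
    clf.fit(X[:, cols], y)
    return TrainedModel(
        vocab=vocab,
        zscales=zscales,
        reference_positions=tuple(corpus.reference_positions),
        mask=mask,
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        config=config,
        seed=seed,
    )


def predict(model: TrainedModel, peptide: Peptide, receptor: Receptor) -> DecisionResult:
    """Score one pair; positive dist predicts interaction (ties -> negative)."""
    missing = [p for p in model.reference_positions if p not in receptor.tm_map]
    if missing:
        raise ModelError(
            f"receptor {receptor.id!r} lacks reference position(s) {missing}"
        )
    dist = model.decision_value(peptide, receptor)
    return DecisionResult(dist, "positive" if dist > 0 else "negative")
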