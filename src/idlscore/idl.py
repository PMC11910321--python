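"""Decomposition of the linear decision value into per-residue scores.

For a scored pair, the weighted-feature part of the decision value,
dist_linear = sum_{i,j} w[i,j] pD_i gD_j, is redistributed over residues:

* receptor residue M collects the terms of its five descriptor elements
  (j = 5M-4 ... 5M) — these partition j, so the receptor profile sums
  exactly back to dist_linear;
* peptide residue N collects the full term of every motif whose occurrence
  window covers N — a motif covers five residues (more if it occurs more
  than once), so the peptide profile sums to a covered-residue-weighted
  total, not to dist_linear;
* the pair score (N, M) takes the intersection of the two collections.

A positive score marks a contribution pushing the pair toward the
interacting side of the hyperplane.  The intercept is a property of the
decision axis, not of any residue, and is left out of all scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .descriptors import ZSCALE_DIM
from .model import TrainedModel
from .seqdata import Peptide, Receptor


@dataclass(frozen=True)
class IDLMatrix:
    """Per-residue and per-residue-pair contribution scores for one pair.

    ``pair_scores[N-1, M-1]`` is the contribution of peptide residue N with
    receptor generic position M (1-based); profiles are the per-axis scores;
    ``dist_linear`` is the intercept-free decision value they decompose.
    """

    peptide_id: str
    receptor_id: str
    peptide_sequence: str
    reference_positions: tuple[str, ...]
    receptor_residues: tuple[Optional[str], ...]
    pair_scores: np.ndarray  # L x P
    peptide_profile: np.ndarray  # L
    receptor_profile: np.ndarray  # P
    dist_linear: float
    intercept: float

    @property
    def dist(self) -> float:
        """Full decision value (linear part plus intercept)."""
        return self.dist_linear + self.intercept

    def receptor_score(self, label: str) -> float:
        return float(self.receptor_profile[self.reference_positions.index(label)])

    def to_frame(self):
        """Pair scores as a DataFrame (rows: residues, cols: generic positions)."""
        import pandas as pd

        return pd.DataFrame(
            self.pair_scores,
            index=[f"{aa}{n}" for n, aa in enumerate(self.peptide_sequence, 1)],
            columns=list(self.reference_positions),
        )


def idl_pair_matrix(model: TrainedModel, peptide: Peptide, receptor: Receptor) -> IDLMatrix:
    """Compute the full residue-pair score matrix with both profiles."""
    pd_, gd_ = model.describe_pair(peptide, receptor)
    W = model.weight_matrix()  # n_motifs x 5P

    L = len(peptide)
    P = len(model.reference_positions)
    active = list(pd_.active)

    # per-motif, per-position contribution: for active motif i, position M,
    # sum over the five elements of M of w[i,j] * gD_j  (pD_i = 1)
    if active:
        contrib = (W[active, :] * gd_.values[None, :]).reshape(len(active), P, ZSCALE_DIM).sum(axis=2)
    else:
        contrib = np.zeros((0, P))
    motif_terms = contrib.sum(axis=1)  # t_i per active motif

    cover = np.zeros((L, len(active)))
    for k, i in enumerate(active):
        for n in pd_.position_map[i]:
            cover[n - 1, k] = 1.0

    pair_scores = cover @ contrib
    receptor_profile = contrib.sum(axis=0)
    peptide_profile = cover @ motif_terms
    dist_linear = float(motif_terms.sum())

    return IDLMatrix(
        peptide_id=peptide.id,
        receptor_id=receptor.id,
        peptide_sequence=peptide.sequence,
        reference_positions=tuple(model.reference_positions),
        receptor_residues=tuple(receptor.residue_at(p) for p in model.reference_positions),
        pair_scores=pair_scores,
        peptide_profile=peptide_profile,
        receptor_profile=receptor_profile,
        dist_linear=dist_linear,
        intercept=model.intercept,
    )


def idl_receptor_profile(model: TrainedModel, peptide: Peptide, receptor: Receptor) -> np.ndarray:
    """Score of each receptor generic position M; sums to dist - b exactly."""
    return idl_pair_matrix(model, peptide, receptor).receptor_profile


def idl_peptide_profile(model: TrainedModel, peptide: Peptide, receptor: Receptor) -> np.ndarray:
    """Score of each peptide residue N (motif terms counted once per covered residue)."""
    return idl_pair_matrix(model, peptide, receptor).peptide_profile


def plot_heatmap(matrix: IDLMatrix, path: Path | str) -> Path:
    """Render the residue-pair score matrix as a signed heatmap (optional;
    needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, len(matrix.reference_positions) * 0.22),
                                    max(3, len(matrix.peptide_sequence) * 0.3)))
    vmax = float(np.abs(matrix.pair_scores).max()) or 1.0
    im = ax.imshow(matrix.pair_scores, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(len(matrix.reference_positions)))
    ax.set_xticklabels(matrix.reference_positions, rotation=90, fontsize=6)
    ax.set_yticks(range(len(matrix.peptide_sequence)))
    ax.set_yticklabels(
        [f"{aa}{n}" for n, aa in enumerate(matrix.peptide_sequence, 1)], fontsize=7
    )
    ax.set_xlabel("receptor generic position")
    ax.set_ylabel("peptide residue")
    ax.set_title(f"{matrix.peptide_id} x {matrix.receptor_id} (dist {matrix.dist:.3g})")
    fig.colorbar(im, ax=ax, label="contribution score")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def write_idl(matrix: IDLMatrix, directory: Path | str) -> dict[str, Path]:
    """Write the pair matrix, both profiles, and dist as TSV files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{matrix.peptide_id}__{matrix.receptor_id}"
    paths = {
        "pairs": directory / f"{stem}.pairs.tsv",
        "peptide_profile": directory / f"{stem}.peptide_profile.tsv",
        "receptor_profile": directory / f"{stem}.receptor_profile.tsv",
        "summary": directory / f"{stem}.summary.tsv",
    }
    matrix.to_frame().to_csv(paths["pairs"], sep="\t", index_label="peptide_residue")
    with open(paths["peptide_profile"], "w") as fh:
        fh.write("residue_index\tresidue\tidl_score\n")
        for n, (aa, s) in enumerate(zip(matrix.peptide_sequence, matrix.peptide_profile), 1):
            fh.write(f"{n}\t{aa}\t{s:.10g}\n")
    with open(paths["receptor_profile"], "w") as fh:
        fh.write("generic_position\tresidue\tidl_score\n")
        for label, aa, s in zip(
            matrix.reference_positions, matrix.receptor_residues, matrix.receptor_profile
        ):
            fh.write(f"{label}\t{aa or '-'}\t{s:.10g}\n")
    with open(paths["summary"], "w") as fh:
        fh.write("peptide_id\treceptor_id\tdist\tdist_linear\tintercept\n")
        fh.write(
            f"{matrix.peptide_id}\t{matrix.receptor_id}\t"
            f"{matrix.dist:.10g}\t{matrix.dist_linear:.10g}\t{matrix.intercept:.10g}\n"
        )
    return paths
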