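"""Downstream analysis of residue contribution profiles.

Given the receptor profiles of the same peptide scored against an *active*
receptor (known interactor) and an *inactive* paralog, positions that score
positive on the active receptor but not on the inactive one are nominated
as candidate selectivity determinants, ranked by the score difference.
Determinant-candidate-exchange (DCE) mutants then swap the background
receptor's residues at chosen positions for the donor paralog's residues,
named in the conventional style ``(L1.35P, I3.24F, W4.61G)-MRGPRX1``
(from-residue, generic position, to-residue, on the background receptor).

Mutation-effect prediction is scored by ranking experimentally annotated
receptor mutations by the wild-type receptor's position score (a high
positive score predicts that mutating the position decreases the
interaction) and computing the ROC AUC of that ranking, "decreasing" being
the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .idl import IDLMatrix, idl_pair_matrix
from .model import TrainedModel
from .seqdata import DECREASING, MutationRecord, Peptide, Receptor


class AnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class NominationThresholds:
    """A position is nominated when score_active > tau_pos and
    score_inactive <= tau_neg (defaults: sign rule at zero)."""

    tau_pos: float = 0.0
    tau_neg: float = 0.0


@dataclass(frozen=True)
class DeterminantReport:
    """Per-generic-position comparison of an active vs inactive paralog.

    ``table`` rows (one per reference position, sorted by descending delta):
    generic_position, residue_active, residue_inactive, score_active,
    score_inactive, delta, nominated, cavity_exposed.
    """

    peptide_id: str
    active_receptor_id: str
    inactive_receptor_id: str
    table: pd.DataFrame
    thresholds: NominationThresholds

    @property
    def nominated(self) -> list[str]:
        return list(self.table.loc[self.table["nominated"], "generic_position"])

    @property
    def ranking(self) -> list[str]:
        """All reference positions ordered by descending delta."""
        return list(self.table["generic_position"])

    def row(self, label: str) -> pd.Series:
        hit = self.table[self.table["generic_position"] == label]
        if hit.empty:
            raise AnalysisError(f"generic position {label} not in report")
        return hit.iloc[0]

    def write(self, path: Path | str) -> Path:
        path = Path(path)
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")
        return path


def compare_paralogs(
    idl_active: IDLMatrix,
    idl_inactive: IDLMatrix,
    thresholds: Optional[NominationThresholds] = None,
) -> DeterminantReport:
    """Contrast receptor profiles of one peptide on two paralogs.

    Both matrices must be computed for the same peptide over the same
    reference generic-position list.
    """
    thresholds = thresholds or NominationThresholds()
    if idl_active.reference_positions != idl_inactive.reference_positions:
        raise AnalysisError("reference positions differ between the two profiles")
    if idl_active.peptide_id != idl_inactive.peptide_id:
        raise AnalysisError(
            f"profiles were computed for different peptides "
            f"({idl_active.peptide_id!r} vs {idl_inactive.peptide_id!r})"
        )
    sa = idl_active.receptor_profile
    si = idl_inactive.receptor_profile
    table = pd.DataFrame(
        {
            "generic_position": list(idl_active.reference_positions),
            "residue_active": [r or "-" for r in idl_active.receptor_residues],
            "residue_inactive": [r or "-" for r in idl_inactive.receptor_residues],
            "score_active": sa,
            "score_inactive": si,
            "delta": sa - si,
            "nominated": (sa > thresholds.tau_pos) & (si <= thresholds.tau_neg),
            "cavity_exposed": False,
        }
    )
    table = table.sort_values("delta", ascending=False, kind="mergesort").reset_index(drop=True)
    return DeterminantReport(
        peptide_id=idl_active.peptide_id,
        active_receptor_id=idl_active.receptor_id,
        inactive_receptor_id=idl_inactive.receptor_id,
        table=table,
        thresholds=thresholds,
    )


def annotate_cavity(report: DeterminantReport, cavity_positions: Iterable[str]) -> DeterminantReport:
    """Flag the alignment-defined cavity-exposed positions in a report."""
    cavity = set(cavity_positions)
    unknown = cavity - set(report.table["generic_position"])
    if unknown:
        raise AnalysisError(f"cavity position(s) {sorted(unknown)} not in the reference list")
    table = report.table.copy()
    table["cavity_exposed"] = table["generic_position"].isin(cavity)
    return replace(report, table=table)


def determinant_screen(
    model: TrainedModel,
    corpus,
    ligand_min_fraction: float = 0.25,
    active_min_fraction: float = 0.5,
    inactive_max_fraction: float = 0.25,
    thresholds: Optional[NominationThresholds] = None,
) -> DeterminantReport:
    """Corpus-wide determinant screen over label-derived receptor panels.

    When the two receptors being compared are unrelated sequences (as in a
    synthetic corpus, where receptors are independent random residue
    assignments), a single active/inactive pair differs at every position
    and each difference injects noise into the score delta; true paralogs
    differ at few positions, which is what makes the one-vs-one comparison
    of :func:`compare_paralogs` clean.  The screen restores that robustness
    by averaging receptor profiles over *panels* classified purely from the
    observed interaction labels:

    * ligand peptides — positive with more than ``ligand_min_fraction`` of
      receptors;
    * active receptors — positive with more than ``active_min_fraction`` of
      the ligand peptides; inactive — with at most ``inactive_max_fraction``
      (receptors in between are ambiguous and excluded).

    Returns a :class:`DeterminantReport` whose scores are panel means; the
    residue columns hold the panel consensus residue (``-`` when mixed).
    """
    thresholds = thresholds or NominationThresholds()
    from collections import Counter

    pos_by_pep: Counter = Counter()
    pos_by_rec_with_ligand: Counter = Counter()
    for rec in corpus.cpis:
        if rec.is_positive:
            pos_by_pep[rec.peptide_id] += 1
    n_receptors = len(corpus.receptors)
    ligands = sorted(
        pid for pid in corpus.peptides if pos_by_pep[pid] > ligand_min_fraction * n_receptors
    )
    if not ligands:
        raise AnalysisError("no ligand peptides: no peptide is positive with enough receptors")
    ligand_set = set(ligands)
    for rec in corpus.cpis:
        if rec.is_positive and rec.peptide_id in ligand_set:
            pos_by_rec_with_ligand[rec.receptor_id] += 1
    n_lig = len(ligands)
    active = sorted(
        rid for rid in corpus.receptors
        if pos_by_rec_with_ligand[rid] > active_min_fraction * n_lig
    )
    inactive = sorted(
        rid for rid in corpus.receptors
        if pos_by_rec_with_ligand[rid] <= inactive_max_fraction * n_lig
    )
    if not active or not inactive:
        raise AnalysisError(
            f"cannot form receptor panels: {len(active)} active, {len(inactive)} inactive"
        )

    def panel_profile(rids: list[str]) -> np.ndarray:
        return np.mean(
            [
                idl_pair_matrix(model, corpus.peptides[pid], corpus.receptors[rid]).receptor_profile
                for pid in ligands
                for rid in rids
            ],
            axis=0,
        )

    def consensus(rids: list[str], label: str) -> str:
        residues = {corpus.receptors[rid].residue_at(label) for rid in rids}
        return residues.pop() or "-" if len(residues) == 1 else "-"

    sa = panel_profile(active)
    si = panel_profile(inactive)
    positions = list(model.reference_positions)
    table = pd.DataFrame(
        {
            "generic_position": positions,
            "residue_active": [consensus(active, p) for p in positions],
            "residue_inactive": [consensus(inactive, p) for p in positions],
            "score_active": sa,
            "score_inactive": si,
            "delta": sa - si,
            "nominated": (sa > thresholds.tau_pos) & (si <= thresholds.tau_neg),
            "cavity_exposed": False,
        }
    )
    table = table.sort_values("delta", ascending=False, kind="mergesort").reset_index(drop=True)
    return DeterminantReport(
        peptide_id="|".join(ligands),
        active_receptor_id="|".join(active),
        inactive_receptor_id="|".join(inactive),
        table=table,
        thresholds=thresholds,
    )


# ---------------------------------------------------------------------------
# DCE mutants


@dataclass(frozen=True)
class DCEMutantSpec:
    """A determinant-candidate-exchange mutant of a background receptor.

    ``substitutions`` are (generic position, from_residue, to_residue),
    sorted by generic position.
    """

    background_receptor_id: str
    substitutions: tuple[tuple[str, str, str], ...]

    @property
    def name(self) -> str:
        inner = ", ".join(f"{frm}{pos}{to}" for pos, frm, to in self.substitutions)
        return f"({inner})-{self.background_receptor_id}"

    def apply(self, background: Receptor) -> str:
        """Background sequence with the substitutions applied."""
        seq = list(background.sequence)
        for pos, frm, to in self.substitutions:
            idx = background.tm_map[pos]
            if seq[idx - 1] != frm:
                raise AnalysisError(
                    f"background {background.id!r} has {seq[idx - 1]} at {pos}, expected {frm}"
                )
            seq[idx - 1] = to
        return "".join(seq)


def propose_dce(
    report: DeterminantReport,
    donor: Receptor,
    background: Receptor,
    subset: Sequence[str],
) -> DCEMutantSpec:
    """Build the DCE mutant exchanging the subset positions of the
    background receptor for the donor paralog's residues."""
    if not subset:
        raise AnalysisError("empty position subset: no mutant to propose")
    nominated = set(report.nominated)
    stray = [p for p in subset if p not in nominated]
    if stray:
        raise AnalysisError(f"position(s) {stray} are not nominated in the report")
    from .seqdata import sort_generic_positions

    subs = []
    for pos in sort_generic_positions(subset):
        frm = background.residue_at(pos)
        to = donor.residue_at(pos)
        if frm is None:
            raise AnalysisError(f"background {background.id!r} has a gap at {pos}")
        if to is None:
            raise AnalysisError(f"donor {donor.id!r} has a gap at {pos}")
        if frm == to:
            raise AnalysisError(
                f"no-op substitution at {pos}: both receptors carry {frm}"
            )
        subs.append((pos, frm, to))
    return DCEMutantSpec(background.id, tuple(subs))


def plot_paralog_scatter(report: DeterminantReport, path: Path | str) -> Path:
    """Scatter of per-position scores, inactive (x) vs active (y): the upper
    left quadrant holds the nominated determinants (optional; needs
    matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = report.table
    fig, ax = plt.subplots(figsize=(5, 5))
    colors = np.where(t["nominated"], "tab:orange", "tab:gray")
    ax.scatter(t["score_inactive"], t["score_active"], c=colors, s=18)
    for _, row in t[t["nominated"]].iterrows():
        ax.annotate(row["generic_position"],
                    (row["score_inactive"], row["score_active"]), fontsize=7)
    ax.axhline(report.thresholds.tau_pos, lw=0.5, color="k")
    ax.axvline(report.thresholds.tau_neg, lw=0.5, color="k")
    ax.set_xlabel(f"score on {report.inactive_receptor_id}")
    ax.set_ylabel(f"score on {report.active_receptor_id}")
    ax.set_title(f"{report.peptide_id}: determinant candidates")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# Mutation-effect AUC


@dataclass(frozen=True)
class MutationAUCResult:
    auc: float
    roc_points: pd.DataFrame  # columns fpr, tpr, threshold
    scores: np.ndarray
    labels: np.ndarray  # 1 = decreasing

    def write_roc(self, path: Path | str) -> Path:
        path = Path(path)
        self.roc_points.to_csv(path, sep="\t", index=False, float_format="%.10g")
        return path


def _auc_from_scores(scores: np.ndarray, labels: np.ndarray) -> MutationAUCResult:
    if len(np.unique(labels)) < 2:
        raise AnalysisError("mutation records must include both effect classes")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thr = roc_curve(labels, scores)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return MutationAUCResult(auc, roc, np.asarray(scores, float), np.asarray(labels, int))


def evaluate_mutation_auc(
    model: TrainedModel,
    peptide: Peptide,
    receptor: Receptor,
    mutations: Sequence[MutationRecord],
) -> MutationAUCResult:
    """ROC AUC for predicting interaction-decreasing mutations of one receptor.

    Each record is scored by the wild-type receptor profile at its generic
    position; ``decreasing`` is the positive class.  The AUC is the
    tie-corrected rank statistic and is reported as-is (never flipped).
    """
    matrix = idl_pair_matrix(model, peptide, receptor)
    scores, labels = [], []
    for rec in mutations:
        if rec.receptor_id != receptor.id:
            raise AnalysisError(
                f"mutation record for {rec.receptor_id!r} passed with receptor {receptor.id!r}"
            )
        scores.append(matrix.receptor_score(rec.generic_position))
        labels.append(1 if rec.effect == DECREASING else 0)
    return _auc_from_scores(np.asarray(scores), np.asarray(labels))


def evaluate_mutation_auc_pooled(
    model: TrainedModel,
    cases: Sequence[tuple[Peptide, Receptor, Sequence[MutationRecord]]],
    mode: str = "pooled",
) -> float:
    """Combine mutation records across several receptor/peptide cases.

    ``pooled`` ranks all records together in one AUC; ``mean`` computes one
    AUC per case (each case needs both classes) and averages them.
    """
    if mode not in ("pooled", "mean"):
        raise AnalysisError(f"unknown pooling mode {mode!r}")
    if mode == "mean":
        aucs = [float(evaluate_mutation_auc(model, p, r, muts).auc) for p, r, muts in cases]
        return float(np.mean(aucs))
    scores, labels = [], []
    for pep, rec, muts in cases:
        matrix = idl_pair_matrix(model, pep, rec)
        for m in muts:
            scores.append(matrix.receptor_score(m.generic_position))
            labels.append(1 if m.effect == DECREASING else 0)
    return float(_auc_from_scores(np.asarray(scores), np.asarray(labels)).auc)
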