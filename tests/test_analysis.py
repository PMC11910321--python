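import numpy as np
import pandas as pd
import pytest

from idlscore.analysis import (
    AnalysisError,
    DCEMutantSpec,
    DeterminantReport,
    NominationThresholds,
    annotate_cavity,
    compare_paralogs,
    determinant_screen,
    evaluate_mutation_auc,
    evaluate_mutation_auc_pooled,
    propose_dce,
)
from idlscore.idl import IDLMatrix, idl_pair_matrix
from idlscore.seqdata import MutationRecord, Peptide, Receptor
from idlscore.synthetic import generate_corpus
from idlscore.model import train
from tests.conftest import RULE


POSITIONS = ("1.35", "3.24", "4.61", "5.38")


def make_matrix(peptide_id, receptor_id, residues, profile):
    """Hand-built IDLMatrix with the given receptor profile (single-residue
    peptide rows are irrelevant for paralog comparison)."""
    profile = np.asarray(profile, dtype=float)
    pair = np.tile(profile, (5, 1))
    return IDLMatrix(
        peptide_id=peptide_id,
        receptor_id=receptor_id,
        peptide_sequence="QFFGL",
        reference_positions=POSITIONS,
        receptor_residues=tuple(residues),
        pair_scores=pair,
        peptide_profile=pair.sum(axis=1),
        receptor_profile=profile,
        dist_linear=float(profile.sum()),
        intercept=0.0,
    )


def mrgprx_pair():
    active = make_matrix("SP", "MRGPRX2", "PFGD", [0.8, 1.2, 0.9, -0.3])
    inactive = make_matrix("SP", "MRGPRX1", "LIWD", [-0.2, -0.5, -0.25, -0.3])
    return active, inactive


class TestCompareParalogs:
    def test_sign_separated_positions_are_nominated(self):
        report = compare_paralogs(*mrgprx_pair())
        assert set(report.nominated) == {"1.35", "3.24", "4.61"}
        # ranked by delta: 3.24 (1.7) > 4.61 (1.15) > 1.35 (1.0)
        assert report.ranking[0] == "3.24"

    def test_identical_profiles_nominate_nothing(self):
        a, _ = mrgprx_pair()
        report = compare_paralogs(a, a)
        assert report.nominated == []

    def test_all_negative_profiles_nominate_nothing(self):
        a = make_matrix("SP", "A", "PFGD", [-1, -2, -3, -4])
        b = make_matrix("SP", "B", "LIWD", [-4, -3, -2, -1])
        assert compare_paralogs(a, b).nominated == []

    def test_mismatched_reference_positions_error(self):
        a, b = mrgprx_pair()
        from dataclasses import replace

        b = replace(b, reference_positions=("1.35", "3.24", "4.61", "6.30"))
        with pytest.raises(AnalysisError, match="reference positions"):
            compare_paralogs(a, b)

    def test_mismatched_peptides_error(self):
        a, b = mrgprx_pair()
        from dataclasses import replace

        b = replace(b, peptide_id="BAM8-22")
        with pytest.raises(AnalysisError, match="different peptides"):
            compare_paralogs(a, b)

    def test_delta_ranking_invariant_under_constant_shift(self):
        a, b = mrgprx_pair()
        shifted = compare_paralogs(
            make_matrix("SP", a.receptor_id, "PFGD", a.receptor_profile + 3.7),
            make_matrix("SP", b.receptor_id, "LIWD", b.receptor_profile + 3.7),
        )
        assert shifted.ranking == compare_paralogs(a, b).ranking

    def test_thresholds_tighten_nomination(self):
        report = compare_paralogs(*mrgprx_pair(), NominationThresholds(tau_pos=1.0))
        assert report.nominated == ["3.24"]


class TestAnnotateCavity:
    def test_listed_positions_flagged_and_others_not(self):
        report = compare_paralogs(*mrgprx_pair())
        annotated = annotate_cavity(report, ["1.35"])
        assert bool(annotated.row("1.35")["cavity_exposed"])
        assert not bool(annotated.row("3.24")["cavity_exposed"])

    def test_empty_list_flags_nothing(self):
        report = annotate_cavity(compare_paralogs(*mrgprx_pair()), [])
        assert not report.table["cavity_exposed"].any()

    def test_unknown_position_is_an_error(self):
        with pytest.raises(AnalysisError, match="2.50"):
            annotate_cavity(compare_paralogs(*mrgprx_pair()), ["2.50"])


class TestProposeDCE:
    def receptors(self):
        tm = {p: k + 1 for k, p in enumerate(POSITIONS)}
        background = Receptor("MRGPRX1", "LIWD", tm)
        donor = Receptor("MRGPRX2", "PFGD", tm)
        return donor, background

    def test_triple_mutant_name(self):
        donor, background = self.receptors()
        report = compare_paralogs(*mrgprx_pair())
        spec = propose_dce(report, donor, background, ["1.35", "3.24", "4.61"])
        assert spec.name == "(L1.35P, I3.24F, W4.61G)-MRGPRX1"

    def test_single_mutant_name(self):
        donor, background = self.receptors()
        report = compare_paralogs(*mrgprx_pair())
        spec = propose_dce(report, donor, background, ["1.35"])
        assert spec.name == "(L1.35P)-MRGPRX1"

    def test_substitutions_sorted_by_generic_position(self):
        donor, background = self.receptors()
        report = compare_paralogs(*mrgprx_pair())
        spec = propose_dce(report, donor, background, ["4.61", "1.35"])
        assert [s[0] for s in spec.substitutions] == ["1.35", "4.61"]

    def test_empty_subset_error(self):
        donor, background = self.receptors()
        with pytest.raises(AnalysisError, match="empty"):
            propose_dce(compare_paralogs(*mrgprx_pair()), donor, background, [])

    def test_non_nominated_position_error(self):
        donor, background = self.receptors()
        with pytest.raises(AnalysisError, match="5.38"):
            propose_dce(compare_paralogs(*mrgprx_pair()), donor, background, ["5.38"])

    def test_no_op_substitution_error(self):
        tm = {p: k + 1 for k, p in enumerate(POSITIONS)}
        background = Receptor("MRGPRX1", "PIWD", tm)  # already P at 1.35
        donor = Receptor("MRGPRX2", "PFGD", tm)
        with pytest.raises(AnalysisError, match="no-op"):
            propose_dce(compare_paralogs(*mrgprx_pair()), donor, background, ["1.35"])

    def test_applying_substitutions_transfers_donor_residues(self):
        donor, background = self.receptors()
        report = compare_paralogs(*mrgprx_pair())
        subset = ["1.35", "3.24", "4.61"]
        mutated = propose_dce(report, donor, background, subset).apply(background)
        for pos in subset:
            idx = background.tm_map[pos]
            assert mutated[idx - 1] == donor.residue_at(pos)

    def test_gap_at_requested_position_error(self):
        report = compare_paralogs(*mrgprx_pair())
        tm = {p: k + 1 for k, p in enumerate(POSITIONS)}
        gap_tm = dict(tm, **{"1.35": None})
        background = Receptor("MRGPRX1", "LIWD", gap_tm)
        donor = Receptor("MRGPRX2", "PFGD", tm)
        with pytest.raises(AnalysisError, match="gap"):
            propose_dce(report, donor, background, ["1.35"])


def mann_whitney_auc(scores, labels):
    """Exhaustive pairwise estimate U / (n1 * n0), ties counted half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    u = 0.0
    for p in pos:
        for n in neg:
            u += 1.0 if p > n else (0.5 if p == n else 0.0)
    return u / (len(pos) * len(neg))


@pytest.fixture(scope="module")
def scored():
    corpus, truth = generate_corpus(16, 8, rule=RULE, seed=23)
    model = train(corpus, seed=23)
    pid = sorted(truth.motif_peptides)[0]
    rid = sorted(truth.rule_receptors)[0]
    return model, corpus.peptides[pid], corpus.receptors[rid], corpus


class TestMutationAUC:
    def records_for(self, receptor, positions, effects):
        return [
            MutationRecord(receptor.id, pos, receptor.residue_at(pos), "A"
                           if receptor.residue_at(pos) != "A" else "G", eff)
            for pos, eff in zip(positions, effects)
        ]

    def test_matches_pairwise_mann_whitney_on_random_sets(self):
        rng = np.random.default_rng(0)
        from idlscore.analysis import _auc_from_scores

        for _ in range(50):
            n = int(rng.integers(4, 20))
            scores = rng.choice([-1.5, -0.5, 0.0, 0.5, 1.5], size=n)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            result = _auc_from_scores(np.asarray(scores, float), labels)
            assert result.auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    def test_perfectly_separated_scores_give_auc_one(self, scored):
        model, pep, rec, _ = scored
        matrix = idl_pair_matrix(model, pep, rec)
        order = np.argsort(-matrix.receptor_profile)
        positions = [model.reference_positions[k] for k in order]
        # label the top half decreasing: scores then separate the classes
        effects = ["decreasing"] * (len(positions) // 2) + ["non_decreasing"] * (
            len(positions) - len(positions) // 2
        )
        records = self.records_for(rec, positions, effects)
        # only valid if no tie spans the class boundary
        result = evaluate_mutation_auc(model, pep, rec, records)
        assert result.auc == pytest.approx(1.0)

    def test_all_tied_scores_give_auc_half(self):
        from idlscore.analysis import _auc_from_scores

        result = _auc_from_scores(np.zeros(10), np.array([1, 0] * 5))
        assert result.auc == pytest.approx(0.5)

    def test_single_class_input_error(self, scored):
        model, pep, rec, _ = scored
        records = self.records_for(rec, ["1.35", "3.24"], ["decreasing", "decreasing"])
        with pytest.raises(AnalysisError, match="both effect classes"):
            evaluate_mutation_auc(model, pep, rec, records)

    def test_invariant_under_monotone_transform(self):
        from idlscore.analysis import _auc_from_scores

        rng = np.random.default_rng(5)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        a = _auc_from_scores(scores, labels).auc
        b = _auc_from_scores(np.exp(3 * scores) + 7, labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_wrong_receptor_record_error(self, scored):
        model, pep, rec, _ = scored
        bad = MutationRecord("someone_else", "1.35", "A", "G", "decreasing")
        with pytest.raises(AnalysisError, match="someone_else"):
            evaluate_mutation_auc(model, pep, rec, [bad])

    def test_pooled_and_mean_modes(self, scored):
        model, pep, rec, corpus = scored
        other = corpus.receptors[sorted(corpus.receptors)[0]]
        cases = []
        for r in (rec, other):
            recs = self.records_for(
                r, ["1.35", "3.24", "4.61", "7.51"],
                ["decreasing", "decreasing", "non_decreasing", "non_decreasing"],
            )
            cases.append((pep, r, recs))
        pooled = evaluate_mutation_auc_pooled(model, cases, mode="pooled")
        mean = evaluate_mutation_auc_pooled(model, cases, mode="mean")
        assert 0.0 <= pooled <= 1.0 and 0.0 <= mean <= 1.0
        with pytest.raises(AnalysisError):
            evaluate_mutation_auc_pooled(model, cases, mode="other")


class TestDeterminantScreen:
    def test_screen_ranks_planted_determinants_first(self):
        # panel averaging needs a handful of receptors per panel to suppress
        # position noise, hence the receptor-heavy corpus
        corpus, truth = generate_corpus(30, 30, rule=RULE, seed=31)
        model = train(corpus, seed=31)
        report = determinant_screen(model, corpus)
        assert set(truth.rule.positions) <= set(report.ranking[:5])
        assert set(report.nominated) >= set(truth.rule.positions)

    def test_screen_needs_formable_panels(self, small_corpus, small_model):
        corpus, _ = small_corpus
        from idlscore.seqdata import Corpus, CPIRecord, NEGATIVE

        all_neg = Corpus(
            corpus.peptides,
            corpus.receptors,
            [CPIRecord(r.peptide_id, r.receptor_id, NEGATIVE) for r in corpus.cpis],
            list(corpus.reference_positions),
        )
        with pytest.raises(AnalysisError, match="ligand"):
            determinant_screen(small_model, all_neg)
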