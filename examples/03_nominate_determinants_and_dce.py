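"""Nominate selectivity determinants between paralogs and name DCE mutants.

Scoring the same peptide against an interacting ('active') receptor and a
non-interacting ('inactive') one, positions scoring positive on the active
receptor but not on the inactive one are nominated as determinant
candidates.  A determinant-candidate-exchange (DCE) mutant then swaps the
background receptor's residues at chosen positions for the donor's, named
like '(L1.35P, I3.24F, W4.61G)-MRGPRX1'.
"""

from idlscore import (
    PlantedRule,
    compare_paralogs,
    determinant_screen,
    generate_corpus,
    idl_pair_matrix,
    propose_dce,
    train,
)

rule = PlantedRule("QFFGL", (("3.24", "F"), ("4.61", "G")), noise=0.0)
corpus, truth = generate_corpus(n_peptides=30, n_receptors=30, rule=rule, seed=31)
model = train(corpus, seed=31)

peptide = corpus.peptides[sorted(truth.motif_peptides)[0]]
active_id, inactive_id = truth.pick_paralog_pair()
active, inactive = corpus.receptors[active_id], corpus.receptors[inactive_id]

report = compare_paralogs(
    idl_pair_matrix(model, peptide, active),
    idl_pair_matrix(model, peptide, inactive),
)
print(f"one-vs-one comparison {active_id} vs {inactive_id}:")
print(f"  nominated (active-positive, inactive-nonpositive): {report.nominated[:6]}")

screen = determinant_screen(model, corpus)
print("corpus-wide panel screen, top 5 positions by score delta:")
for _, row in screen.table.head(5).iterrows():
    planted = " <- planted" if row["generic_position"] in dict(rule.determinant_positions) else ""
    print(f"  {row['generic_position']}: delta {row['delta']:+.4f}{planted}")

subset = [p for p in truth.rule.positions if p in report.nominated]
if subset:
    spec = propose_dce(report, donor=active, background=inactive, subset=subset)
    print(f"proposed DCE mutant: {spec.name}")
    print("applying it transfers the donor's residues onto the background sequence")
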