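"""Staged workflow: simulate/validate -> train -> decompose -> compare.

The pipeline is a thin orchestration over the library: it generates or
loads a corpus, trains the model, computes contribution profiles for an
active/inactive receptor pair, writes the determinant report, and records
a manifest (tool version, config hash, seeds, and a hash of every numeric
output) so a rerun with identical config and seeds is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .analysis import (
    NominationThresholds,
    annotate_cavity,
    compare_paralogs,
    determinant_screen,
)
from .idl import idl_pair_matrix, write_idl
from .model import GAConfig, TrainConfig, train
from .seqdata import Corpus, CorpusError, read_corpus, write_corpus
from .synthetic import PlantedRule, default_reference_positions, generate_corpus

log = logging.getLogger("idlscore")


@dataclass
class SimulateConfig:
    n_peptides: int = 60
    n_receptors: int = 20
    n_positions: int = 40
    peptide_length_min: int = 8
    peptide_length_max: int = 16
    motif: str = "QFFGL"
    determinant_positions: dict[str, str] = field(
        default_factory=lambda: {"3.24": "F", "4.61": "G"}
    )
    noise: float = 0.05
    motif_fraction: float = 0.5
    determinant_fraction: float = 0.5

    def rule(self) -> PlantedRule:
        return PlantedRule(
            motif=self.motif,
            determinant_positions=tuple(sorted(self.determinant_positions.items())),
            noise=self.noise,
        )


@dataclass
class RunConfig:
    """Everything one pipeline run needs; every stochastic stage is seeded."""

    out_dir: str = "idlscore_run"
    seed: int = 0
    simulate: Optional[SimulateConfig] = field(default_factory=SimulateConfig)
    # used instead of simulation when set: paths to an existing corpus
    peptide_fasta: Optional[str] = None
    receptor_fasta: Optional[str] = None
    tm_table: Optional[str] = None
    cpi_table: Optional[str] = None
    # comparison: explicit ids, or (simulated corpora) picked from ground truth
    peptide_id: Optional[str] = None
    active_receptor_id: Optional[str] = None
    inactive_receptor_id: Optional[str] = None
    svm_C: float = 1.0
    ga: Optional[dict] = None  # GAConfig fields; None disables feature selection
    tau_pos: float = 0.0
    tau_neg: float = 0.0
    cavity_positions: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", "default")
        cfg = cls(**raw)
        if sim is None:
            cfg.simulate = None
        elif sim != "default":
            cfg.simulate = SimulateConfig(**sim)
        return cfg

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("peptide_fasta", "receptor_fasta", "tm_table", "cpi_table"):
                p = getattr(self, name)
                if p is None:
                    raise CorpusError(f"config: {name} is required when simulate is disabled")
                if not Path(p).exists():
                    raise CorpusError(f"config: {name} path {p!r} does not exist")
            for name in ("peptide_id", "active_receptor_id", "inactive_receptor_id"):
                if getattr(self, name) is None:
                    raise CorpusError(f"config: {name} is required when simulate is disabled")

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            C=self.svm_C,
            feature_selection=GAConfig(**self.ga) if self.ga else None,
        )


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the staged workflow and return the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "simulate" if config.simulate else "load"
        if config.simulate is not None:
            sim = config.simulate
            corpus, truth = generate_corpus(
                n_peptides=sim.n_peptides,
                n_receptors=sim.n_receptors,
                peptide_length_range=(sim.peptide_length_min, sim.peptide_length_max),
                reference_positions=default_reference_positions(sim.n_positions),
                rule=sim.rule(),
                seed=config.seed,
                motif_fraction=sim.motif_fraction,
                determinant_fraction=sim.determinant_fraction,
            )
            write_corpus(corpus, out / "corpus")
            peptide_id = config.peptide_id or sorted(truth.motif_peptides)[0]
            active_id, inactive_id = (
                (config.active_receptor_id, config.inactive_receptor_id)
                if config.active_receptor_id and config.inactive_receptor_id
                else truth.pick_paralog_pair()
            )
        else:
            corpus = read_corpus(
                config.peptide_fasta, config.receptor_fasta, config.tm_table, config.cpi_table
            )
            peptide_id = config.peptide_id
            active_id, inactive_id = config.active_receptor_id, config.inactive_receptor_id
        log.info("%s: %d peptides, %d receptors, %d pairs", stage,
                 len(corpus.peptides), len(corpus.receptors), len(corpus.cpis))

        stage = "train"
        model = train(corpus, config.train_config(), seed=config.seed)
        model_path = model.save(out / "model.json")
        log.info("train: %d selected features, intercept %.4g",
                 model.mask.n_selected, model.intercept)

        stage = "idl"
        peptide = corpus.peptides[peptide_id]
        idl_active = idl_pair_matrix(model, peptide, corpus.receptors[active_id])
        idl_inactive = idl_pair_matrix(model, peptide, corpus.receptors[inactive_id])
        write_idl(idl_active, out / "idl")
        write_idl(idl_inactive, out / "idl")

        stage = "compare"
        thresholds = NominationThresholds(config.tau_pos, config.tau_neg)
        report = compare_paralogs(idl_active, idl_inactive, thresholds)
        if config.cavity_positions:
            report = annotate_cavity(report, config.cavity_positions)
        report.write(out / "determinant_report.tsv")
        log.info("compare: %d nominated position(s): %s",
                 len(report.nominated), ", ".join(report.nominated) or "-")
        if config.simulate is not None:
            # corpus-wide panel screen: the robust readout when receptors
            # are unrelated random sequences rather than true paralogs
            screen = determinant_screen(model, corpus, thresholds=thresholds)
            if config.cavity_positions:
                screen = annotate_cavity(screen, config.cavity_positions)
            screen.write(out / "screen_report.tsv")
            log.info("screen: top positions %s", ", ".join(screen.ranking[:5]))
    except Exception as exc:
        raise CorpusError(f"pipeline stage {stage!r} failed: {exc}") from exc

    numeric_outputs = sorted(
        p
        for p in out.rglob("*")
        if p.is_file()
        and p.suffix in (".tsv", ".json")
        and p.name not in ("manifest.json", "config.yaml")
    )
    manifest = {
        "tool": "idlscore",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {str(p.relative_to(out)): _hash_file(p) for p in numeric_outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(config), sort_keys=True))
    return out
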