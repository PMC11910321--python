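"""Sequence corpus model and I/O.

A corpus couples peptides (FASTA), receptors (FASTA) with a transmembrane
generic-number annotation (Ballesteros-Weinstein labels such as ``3.24``
mapped to 1-based sequence indices), and a table of labeled peptide-receptor
interaction pairs.  Mutation-effect records in the style of GPCRdb entries
are an optional side table.

All files are plain text: FASTA for sequences, tab-separated tables with a
header line for everything else.  Sequence coordinates are 1-based in every
file and report, matching mutant nomenclature such as ``L1.35P``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

GAP_TOKEN = "-"

POSITIVE = "positive"
NEGATIVE = "negative"

DECREASING = "decreasing"
NON_DECREASING = "non_decreasing"

#: N- and C-terminal bounds of the conserved transmembrane region; receptors
#: lacking a residue at either are treated as partial sequences.
TM_START = "1.35"
TM_END = "7.51"

_GENERIC_RE = re.compile(r"^([1-8])\.(\d{1,3})$")


class CorpusError(ValueError):
    """A corpus violates referential integrity or a domain invariant."""


class ParseError(CorpusError):
    """A corpus file is malformed; the message carries file and line."""


def parse_generic_position(label: str) -> tuple[int, int]:
    """Parse a Ballesteros-Weinstein label like ``"3.24"`` into (helix, index).

    Raises :class:`ParseError` on anything that is not ``H.N`` with helix 1-8.
    """
    m = _GENERIC_RE.match(label.strip())
    if m is None:
        raise ParseError(f"malformed generic position label {label!r}")
    return int(m.group(1)), int(m.group(2))


def sort_generic_positions(labels: Iterable[str]) -> list[str]:
    """Sort labels by (helix, residue index) — the reference order."""
    return sorted(labels, key=parse_generic_position)


def _check_sequence(seq: str, what: str, ident: str, min_len: int = 1) -> str:
    seq = seq.strip().upper()
    bad = set(seq) - _AA_SET
    if bad:
        raise CorpusError(
            f"{what} {ident!r}: non-canonical residue(s) {sorted(bad)}; "
            f"only the 20 canonical one-letter codes are accepted"
        )
    if len(seq) < min_len:
        raise CorpusError(f"{what} {ident!r}: length {len(seq)} < minimum {min_len}")
    return seq


@dataclass(frozen=True)
class Peptide:
    """A peptide ligand; at least 5 residues (the motif window length)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_sequence(self.sequence, "peptide", self.id, 5))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Receptor:
    """A receptor with a generic-number annotation of its TM region.

    ``tm_map`` maps each generic label to a 1-based index into ``sequence``,
    or to ``None`` for an alignment gap (no residue at that position).
    Loop and terminal residues are simply absent from the map and carry no
    descriptor elements.
    """

    id: str
    sequence: str
    tm_map: Mapping[str, Optional[int]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_sequence(self.sequence, "receptor", self.id))
        tm = dict(self.tm_map)
        for label, idx in tm.items():
            parse_generic_position(label)
            if idx is not None and not (1 <= idx <= len(self.sequence)):
                raise CorpusError(
                    f"receptor {self.id!r}: generic position {label} maps to index "
                    f"{idx}, outside sequence of length {len(self.sequence)}"
                )
        object.__setattr__(self, "tm_map", tm)

    def residue_at(self, label: str) -> Optional[str]:
        """One-letter residue at a generic position, or None for a gap."""
        idx = self.tm_map.get(label)
        if idx is None:
            return None
        return self.sequence[idx - 1]

    def has_residue(self, label: str) -> bool:
        return self.tm_map.get(label) is not None


@dataclass(frozen=True)
class CPIRecord:
    """A labeled peptide-receptor interaction pair."""

    peptide_id: str
    receptor_id: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE):
            raise CorpusError(
                f"CPI ({self.peptide_id}, {self.receptor_id}): label must be "
                f"{POSITIVE!r} or {NEGATIVE!r}, got {self.label!r}"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.peptide_id, self.receptor_id)

    @property
    def is_positive(self) -> bool:
        return self.label == POSITIVE


@dataclass(frozen=True)
class MutationRecord:
    """An experimentally observed receptor point mutation and its effect
    on peptide recognition (``decreasing`` vs ``non_decreasing``)."""

    receptor_id: str
    generic_position: str
    wt_residue: str
    mut_residue: str
    effect: str

    def __post_init__(self) -> None:
        parse_generic_position(self.generic_position)
        for r, what in ((self.wt_residue, "wild-type"), (self.mut_residue, "mutant")):
            if r not in _AA_SET:
                raise CorpusError(
                    f"mutation {self.receptor_id} {self.generic_position}: "
                    f"{what} residue {r!r} is not a canonical one-letter code"
                )
        if self.effect not in (DECREASING, NON_DECREASING):
            raise CorpusError(
                f"mutation {self.receptor_id} {self.generic_position}: effect must be "
                f"{DECREASING!r} or {NON_DECREASING!r}, got {self.effect!r}"
            )


@dataclass
class Corpus:
    """Validated peptides, receptors and interaction records.

    ``reference_positions`` is the totally ordered generic-position list
    shared by every receptor in the corpus.
    """

    peptides: dict[str, Peptide]
    receptors: dict[str, Receptor]
    cpis: list[CPIRecord]
    reference_positions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for rec in self.cpis:
            if rec.peptide_id not in self.peptides:
                raise CorpusError(f"CPI references unknown peptide id {rec.peptide_id!r}")
            if rec.receptor_id not in self.receptors:
                raise CorpusError(f"CPI references unknown receptor id {rec.receptor_id!r}")
            if rec.pair in seen:
                raise CorpusError(f"duplicate CPI pair {rec.pair}")
            seen.add(rec.pair)
        ref = set(self.reference_positions)
        for rid, rec in self.receptors.items():
            missing = ref - set(rec.tm_map)
            if missing:
                raise CorpusError(
                    f"receptor {rid!r}: tm_map lacks reference position(s) "
                    f"{sort_generic_positions(missing)}"
                )

    @property
    def positives(self) -> list[CPIRecord]:
        return [r for r in self.cpis if r.is_positive]

    @property
    def negatives(self) -> list[CPIRecord]:
        return [r for r in self.cpis if not r.is_positive]


# ---------------------------------------------------------------------------
# Reading


def _read_fasta(path: Path) -> list[tuple[str, str]]:
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    ids = [i for i, _ in records]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate sequence ids")
    return records


def _read_tsv(path: Path, columns: Sequence[str]) -> list[tuple[int, list[str]]]:
    """Read a header-checked TSV; yields (1-based line number, fields)."""
    rows: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(columns):
            raise ParseError(f"{path}:1: expected header {list(columns)}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(columns):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(columns)} fields, got {len(fields)}"
                )
            rows.append((lineno, fields))
    return rows


def read_tm_table(path: Path | str) -> dict[str, dict[str, Optional[int]]]:
    """Read the receptor_id / generic_position / seq_index table.

    A ``-`` in the index column marks an alignment gap.
    """
    path = Path(path)
    maps: dict[str, dict[str, Optional[int]]] = {}
    for lineno, (rid, label, idx_s) in _read_tsv(
        path, ("receptor_id", "generic_position", "seq_index")
    ):
        try:
            parse_generic_position(label)
        except ParseError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        if idx_s == GAP_TOKEN:
            idx: Optional[int] = None
        else:
            try:
                idx = int(idx_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: seq_index {idx_s!r} is not an integer or '-'")
        rmap = maps.setdefault(rid, {})
        if label in rmap:
            raise ParseError(f"{path}:{lineno}: duplicate generic position {label} for {rid!r}")
        rmap[label] = idx
    return maps


def read_cpi_table(path: Path | str) -> list[CPIRecord]:
    path = Path(path)
    out = []
    for lineno, (pid, rid, label) in _read_tsv(path, ("peptide_id", "receptor_id", "label")):
        try:
            out.append(CPIRecord(pid, rid, label))
        except CorpusError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    return out


def read_mutation_table(
    path: Path | str, receptors: Optional[Mapping[str, Receptor]] = None
) -> list[MutationRecord]:
    """Read mutation-effect records; with ``receptors`` given, check that each
    wild-type residue matches the receptor sequence at the mapped index."""
    path = Path(path)
    out = []
    for lineno, (rid, label, wt, mut, effect) in _read_tsv(
        path, ("receptor_id", "generic_position", "wt", "mut", "effect")
    ):
        try:
            rec = MutationRecord(rid, label, wt, mut, effect)
        except CorpusError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        if receptors is not None:
            if rid not in receptors:
                raise CorpusError(f"{path}:{lineno}: unknown receptor id {rid!r}")
            actual = receptors[rid].residue_at(label)
            if actual != wt:
                raise CorpusError(
                    f"{path}:{lineno}: wild-type residue {wt} does not match receptor "
                    f"{rid!r} at {label} (found {actual})"
                )
        out.append(rec)
    return out


def read_corpus(
    peptide_fasta: Path | str,
    receptor_fasta: Path | str,
    tm_table: Path | str,
    cpi_table: Path | str,
) -> Corpus:
    """Load and cross-validate a full corpus from its four files."""
    peptides = {pid: Peptide(pid, seq) for pid, seq in _read_fasta(Path(peptide_fasta))}
    raw_receptors = _read_fasta(Path(receptor_fasta))
    tm_maps = read_tm_table(tm_table)
    receptors: dict[str, Receptor] = {}
    for rid, seq in raw_receptors:
        if rid not in tm_maps:
            raise CorpusError(f"tm table has no annotation for receptor id {rid!r}")
        receptors[rid] = Receptor(rid, seq, tm_maps[rid])
    orphan = set(tm_maps) - set(receptors)
    if orphan:
        raise CorpusError(f"tm table annotates unknown receptor id(s) {sorted(orphan)}")
    label_sets = {frozenset(r.tm_map) for r in receptors.values()}
    if len(label_sets) > 1:
        raise CorpusError("receptors do not share one reference generic-position list")
    reference = sort_generic_positions(next(iter(label_sets))) if label_sets else []
    cpis = read_cpi_table(cpi_table)
    return Corpus(peptides, receptors, cpis, reference)


# ---------------------------------------------------------------------------
# Writing


def write_corpus(corpus: Corpus, directory: Path | str) -> dict[str, Path]:
    """Write a corpus to ``directory`` in the canonical four-file layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "peptide_fasta": directory / "peptides.fasta",
        "receptor_fasta": directory / "receptors.fasta",
        "tm_table": directory / "tm.tsv",
        "cpi_table": directory / "cpi.tsv",
    }
    SeqIO.write(
        [SeqRecord(Seq(p.sequence), id=pid, description="") for pid, p in sorted(corpus.peptides.items())],
        str(paths["peptide_fasta"]),
        "fasta",
    )
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=rid, description="") for rid, r in sorted(corpus.receptors.items())],
        str(paths["receptor_fasta"]),
        "fasta",
    )
    with open(paths["tm_table"], "w") as fh:
        fh.write("receptor_id\tgeneric_position\tseq_index\n")
        for rid, rec in sorted(corpus.receptors.items()):
            for label in sort_generic_positions(rec.tm_map):
                idx = rec.tm_map[label]
                fh.write(f"{rid}\t{label}\t{GAP_TOKEN if idx is None else idx}\n")
    with open(paths["cpi_table"], "w") as fh:
        fh.write("peptide_id\treceptor_id\tlabel\n")
        for rec in corpus.cpis:
            fh.write(f"{rec.peptide_id}\t{rec.receptor_id}\t{rec.label}\n")
    return paths


def write_mutation_table(records: Sequence[MutationRecord], path: Path | str) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("receptor_id\tgeneric_position\twt\tmut\teffect\n")
        for m in records:
            fh.write(
                f"{m.receptor_id}\t{m.generic_position}\t{m.wt_residue}\t{m.mut_residue}\t{m.effect}\n"
            )
    return path


# ---------------------------------------------------------------------------
# Full-length filter


@dataclass(frozen=True)
class DroppedReceptor:
    receptor: Receptor
    reason: str


def filter_full_length(
    receptors: Sequence[Receptor],
) -> tuple[list[Receptor], list[DroppedReceptor]]:
    """Partition receptors into full-length TM sequences and partial ones.

    A receptor is full-length when it carries a residue (not a gap) at both
    generic position 1.35 and 7.51, the termini of the conserved
    transmembrane region; anything else is dropped as a partial sequence.
    """
    kept: list[Receptor] = []
    dropped: list[DroppedReceptor] = []
    for rec in receptors:
        missing = [p for p in (TM_START, TM_END) if not rec.has_residue(p)]
        if missing:
            dropped.append(
                DroppedReceptor(rec, f"no residue at generic position(s) {', '.join(missing)}")
            )
        else:
            kept.append(rec)
    return kept, dropped
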