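"""Peptide and receptor descriptors.

Peptides become binary occurrence vectors over a vocabulary of 5-residue
motifs (the windows observed in the training peptides); the descriptor also
retains, per motif, the set of peptide residue positions covered by its
occurrences, which is what lets the linear decision value be attributed back
to individual residues.

Receptors become numeric vectors of length 5P: each of the P reference
generic positions owns a block of five elements holding the z-scale values
(five physicochemical property scales per residue) of the residue aligned
there, or five zeros for an alignment gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqdata import AMINO_ACIDS, Peptide, Receptor

MOTIF_LENGTH = 5

#: Elements per generic position in the receptor descriptor (the five
#: z-scales); generic position M (1-based) owns elements 5M-4 ... 5M.
ZSCALE_DIM = 5


class DescriptorError(ValueError):
    pass


@dataclass(frozen=True)
class MotifVocabulary:
    """Ordered (lexicographic) set of 5-mer motifs with index lookup."""

    motifs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.motifs)) != len(self.motifs):
            raise DescriptorError("vocabulary motifs must be unique")
        if any(len(m) != MOTIF_LENGTH for m in self.motifs):
            raise DescriptorError(f"every motif must have length {MOTIF_LENGTH}")
        if list(self.motifs) != sorted(self.motifs):
            raise DescriptorError("vocabulary must be lexicographically ordered")
        object.__setattr__(self, "_index", {m: i for i, m in enumerate(self.motifs)})

    def __len__(self) -> int:
        return len(self.motifs)

    def __contains__(self, motif: str) -> bool:
        return motif in self._index  # type: ignore[attr-defined]

    def index(self, motif: str) -> int:
        return self._index[motif]  # type: ignore[attr-defined]


def iter_windows(sequence: str) -> Iterable[tuple[int, str]]:
    """Yield (1-based start, 5-mer) for every window of the sequence."""
    for start in range(len(sequence) - MOTIF_LENGTH + 1):
        yield start + 1, sequence[start : start + MOTIF_LENGTH]


def build_vocabulary(peptides: Sequence[Peptide]) -> MotifVocabulary:
    """Collect every distinct 5-mer window over the peptides, sorted."""
    if not peptides:
        raise DescriptorError("cannot build a motif vocabulary from zero peptides")
    motifs: set[str] = set()
    for pep in peptides:
        for _, w in iter_windows(pep.sequence):
            motifs.add(w)
    return MotifVocabulary(tuple(sorted(motifs)))


@dataclass(frozen=True)
class PeptideDescriptor:
    """Binary motif-occurrence vector plus the motif -> residue map.

    ``position_map[i]`` is the set of 1-based residue positions of the
    peptide covered by any occurrence of motif ``i``; the descriptor element
    is 1 exactly when that set is nonempty.  Multiple occurrences of one
    motif do not increment the element (occurrence is binary) but every
    occurrence contributes its five residues to the map.
    """

    peptide_id: str
    length: int
    n_motifs: int
    active: tuple[int, ...]
    position_map: Mapping[int, frozenset[int]]

    def dense(self) -> np.ndarray:
        v = np.zeros(self.n_motifs)
        v[list(self.active)] = 1.0
        return v

    def covering_motifs(self, residue: int) -> list[int]:
        """Motif element indices whose occurrences cover the given residue."""
        return [i for i in self.active if residue in self.position_map[i]]


def build_pd(peptide: Peptide, vocab: MotifVocabulary) -> PeptideDescriptor:
    """Encode a peptide against a (closed-world) motif vocabulary.

    Windows absent from the vocabulary contribute nothing: the model's
    weights exist only for motifs seen at training time.
    """
    if len(peptide) < MOTIF_LENGTH:
        raise DescriptorError(f"peptide {peptide.id!r} shorter than {MOTIF_LENGTH} residues")
    position_map: dict[int, set[int]] = {}
    for start, window in iter_windows(peptide.sequence):
        if window in vocab:
            i = vocab.index(window)
            position_map.setdefault(i, set()).update(range(start, start + MOTIF_LENGTH))
    return PeptideDescriptor(
        peptide_id=peptide.id,
        length=len(peptide),
        n_motifs=len(vocab),
        active=tuple(sorted(position_map)),
        position_map={i: frozenset(s) for i, s in position_map.items()},
    )


# ---------------------------------------------------------------------------
# Receptor descriptors


class ZScaleTable:
    """Five z-scale values (z1...z5) per canonical residue.

    The packaged default is the extended five-scale set derived from
    principal-component analysis of amino-acid physicochemical properties.
    """

    def __init__(self, table: Mapping[str, Sequence[float]]):
        missing = set(AMINO_ACIDS) - set(table)
        if missing:
            raise DescriptorError(f"z-scale table lacks residue(s) {sorted(missing)}")
        self._table = {}
        for res, vals in table.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != (ZSCALE_DIM,):
                raise DescriptorError(f"residue {res!r}: expected {ZSCALE_DIM} z-scale values")
            self._table[res] = vals

    def __getitem__(self, residue: str) -> np.ndarray:
        try:
            return self._table[residue]
        except KeyError:
            raise DescriptorError(f"residue {residue!r} absent from z-scale table") from None

    def __contains__(self, residue: str) -> bool:
        return residue in self._table

    def as_dict(self) -> dict[str, list[float]]:
        return {r: list(map(float, v)) for r, v in sorted(self._table.items())}

    @classmethod
    def from_tsv(cls, path: Path | str) -> "ZScaleTable":
        table: dict[str, list[float]] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[0] != "residue" or len(header) != ZSCALE_DIM + 1:
                raise DescriptorError(f"{path}: expected header 'residue\\tz1...z{ZSCALE_DIM}'")
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) != ZSCALE_DIM + 1:
                    continue
                table[fields[0]] = [float(x) for x in fields[1:]]
        return cls(table)

    @classmethod
    def default(cls) -> "ZScaleTable":
        with resources.as_file(
            resources.files("idlscore").joinpath("data/zscales_sandberg.tsv")
        ) as p:
            return cls.from_tsv(p)


@dataclass(frozen=True)
class ReceptorDescriptor:
    """Length-5P numeric vector; reference position M owns elements 5M-4...5M."""

    receptor_id: str
    reference_positions: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (ZSCALE_DIM * len(self.reference_positions),):
            raise DescriptorError("receptor descriptor length must be 5 x P")

    def block(self, m: int) -> np.ndarray:
        """The five elements owned by 1-based generic position index m."""
        return self.values[ZSCALE_DIM * (m - 1) : ZSCALE_DIM * m]


def position_of_element(j: int) -> int:
    """1-based generic-position index owning 1-based descriptor element j."""
    return (j - 1) // ZSCALE_DIM + 1


def build_gd(
    receptor: Receptor,
    zscales: ZScaleTable,
    reference_positions: Sequence[str],
) -> ReceptorDescriptor:
    """Encode a receptor's TM region as concatenated per-position z-scales.

    Gap positions contribute five zeros, so they carry no weight in the
    decision value and decompose to a zero contribution.
    """
    values = np.zeros(ZSCALE_DIM * len(reference_positions))
    for m, label in enumerate(reference_positions, start=1):
        if label not in receptor.tm_map:
            raise DescriptorError(
                f"receptor {receptor.id!r}: reference position {label} missing from tm_map"
            )
        res = receptor.residue_at(label)
        if res is not None:
            values[ZSCALE_DIM * (m - 1) : ZSCALE_DIM * m] = zscales[res]
    return ReceptorDescriptor(receptor.id, tuple(reference_positions), values)
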