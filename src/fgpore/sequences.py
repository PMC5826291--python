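"""FG-domain sequences and composition metrics.

The two built-in sequences are the yeast Nsp1 FG-domain construct (with its
His/TEV expression leader and C-terminal cysteine used for maleimide surface
attachment) and its "SG" mutant, in which the hydrophobic residues F, I, L
and V of the FG domain are replaced by serine.  Composition metrics (charged
vs hydrophobic content) are the sequence-level quantities that rationalise
the very different in-pore behaviour of the wildtype and the mutant.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import IO, Iterable

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

CANONICAL_CODES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: default residue classes for composition reports; H is treated as neutral
#: at pH 7.4.  Both sets are parameters of :func:`composition`.
CHARGED_SET = frozenset("DEKR")
HYDROPHOBIC_SET = frozenset("ACFILMVWY")

#: residues replaced by serine in the SG ("Nsp1-S") mutant
SG_TARGETS = "FILV"

_BUILTIN_FILES = {"Nsp1": "nsp1.fasta", "Nsp1-S": "nsp1s.fasta"}

# average residue masses in Da (amino acid minus water)
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence with a declared anchor terminus.

    ``anchor_terminus`` records which end is grafted to the pore wall; for
    Nsp1 and its mutant this is the C terminus (terminal cysteine).
    """

    id: str
    residues: str
    anchor_terminus: str = "C"

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("sequence must contain at least one residue")
        bad = set(self.residues) - CANONICAL_CODES
        if bad:
            pos = next(i for i, r in enumerate(self.residues) if r in bad)
            raise ValueError(
                f"non-canonical residue code {self.residues[pos]!r} at "
                f"position {pos + 1} in {self.id!r}"
            )
        if self.anchor_terminus not in ("C", "N"):
            raise ValueError("anchor_terminus must be 'C' or 'N'")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def anchor_index(self) -> int:
        """0-based index of the anchored bead."""
        return len(self.residues) - 1 if self.anchor_terminus == "C" else 0

    def molecular_weight(self) -> float:
        """Molecular weight in Da from summed average residue masses."""
        return sum(RESIDUE_MASS[r] for r in self.residues) + WATER_MASS


@dataclass(frozen=True)
class CompositionReport:
    counts: dict
    n_charged: int
    n_hydrophobic: int
    ratio_charged_over_hydrophobic: float  # NaN when undefined
    molecular_weight: float

    @property
    def ratio_defined(self) -> bool:
        return not math.isnan(self.ratio_charged_over_hydrophobic)


def load_builtin(name: str) -> ProteinSequence:
    """Return a built-in sequence (``"Nsp1"`` or ``"Nsp1-S"``) verbatim."""
    try:
        fname = _BUILTIN_FILES[name]
    except KeyError:
        raise KeyError(
            f"unknown built-in sequence {name!r}; choose from {sorted(_BUILTIN_FILES)}"
        ) from None
    with resources.files("fgpore.data").joinpath(fname).open() as fh:
        seqs = read_fasta(fh)
    return replace(seqs[0], id=name, anchor_terminus="C")


def read_fasta(stream: IO[str] | str) -> list[ProteinSequence]:
    """Parse FASTA into :class:`ProteinSequence` records (order preserved)."""
    records = list(SeqIO.parse(stream, "fasta"))
    if not records:
        raise ValueError("no FASTA records found")
    out = []
    for rec in records:
        out.append(ProteinSequence(id=rec.id, residues=str(rec.seq).upper()))
    return out


def write_fasta(seqs: Iterable[ProteinSequence], stream: IO[str] | str) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, stream, "fasta")


def sg_mutate(seq: ProteinSequence) -> ProteinSequence:
    """Replace every F, I, L, V by serine (the FG -> SG mutation)."""
    table = str.maketrans(SG_TARGETS, "S" * len(SG_TARGETS))
    return replace(seq, id=f"{seq.id}-SG", residues=seq.residues.translate(table))


def segment(seq: ProteinSequence, first: int, last: int) -> ProteinSequence:
    """1-based inclusive contiguous subsequence, id annotated with the range."""
    if not (1 <= first <= last <= len(seq.residues)):
        raise IndexError(
            f"segment [{first}, {last}] out of range for length {len(seq.residues)}"
        )
    return replace(
        seq, id=f"{seq.id}[{first}-{last}]", residues=seq.residues[first - 1 : last]
    )


def composition(
    seq: ProteinSequence,
    hydrophobic_set: frozenset | set = HYDROPHOBIC_SET,
    charged_set: frozenset | set = CHARGED_SET,
) -> CompositionReport:
    """Residue counts and the charged/hydrophobic ratio.

    The ratio is reported as NaN (flagged via ``ratio_defined``) when the
    sequence contains no hydrophobic residues.
    """
    counts = {c: seq.residues.count(c) for c in sorted(set(seq.residues))}
    n_charged = sum(counts.get(c, 0) for c in charged_set)
    n_hydro = sum(counts.get(c, 0) for c in hydrophobic_set)
    ratio = n_charged / n_hydro if n_hydro > 0 else math.nan
    return CompositionReport(
        counts=counts,
        n_charged=n_charged,
        n_hydrophobic=n_hydro,
        ratio_charged_over_hydrophobic=ratio,
        molecular_weight=seq.molecular_weight(),
    )
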