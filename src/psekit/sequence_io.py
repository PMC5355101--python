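"""FASTA ingestion and validation for DNA, RNA and protein benchmarks.

Sequences are read with Biopython, uppercased, and validated against the
strict alphabet of the declared molecule type: ambiguity codes (N, X, B, Z,
...) and gap characters are rejected rather than silently dropped, because
removing residues would shift every sequence-order correlation lag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("psekit")


class Molecule(str, Enum):
    DNA = "DNA"
    RNA = "RNA"
    PROTEIN = "PROTEIN"


#: Canonical alphabets in canonical symbol order (lexicographic; amino acids
#: alphabetical by one-letter code).
ALPHABETS: dict[Molecule, str] = {
    Molecule.DNA: "ACGT",
    Molecule.RNA: "ACGU",
    Molecule.PROTEIN: "ACDEFGHIKLMNPQRSTVWY",
}


class SequenceError(ValueError):
    """Raised for malformed or alphabet-violating sequence input."""


@dataclass(frozen=True)
class BioSequence:
    """A validated one-letter sequence with identifier and molecule tag."""

    id: str
    residues: str
    molecule: Molecule

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise SequenceError(f"empty sequence for {self.id}")
        alphabet = set(ALPHABETS[self.molecule])
        for pos, symbol in enumerate(self.residues, start=1):
            if symbol not in alphabet:
                raise SequenceError(
                    f"invalid symbol {symbol!r} at position {pos} in record "
                    f"{self.id!r} (alphabet {ALPHABETS[self.molecule]})"
                )

    @property
    def L(self) -> int:
        return len(self.residues)


@dataclass
class LabeledDataset:
    """Ordered sequences with parallel ±1 labels, all of one molecule type."""

    sequences: list[BioSequence]
    labels: np.ndarray  # shape (N,), values in {+1, -1}
    molecule: Molecule

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.sequences) != len(self.labels):
            raise SequenceError("sequences and labels differ in count")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise SequenceError("labels must be +1 or -1")
        for seq in self.sequences:
            if seq.molecule is not self.molecule:
                raise SequenceError(
                    f"record {seq.id!r} is {seq.molecule.value}, "
                    f"dataset is {self.molecule.value}"
                )

    def __len__(self) -> int:
        return len(self.sequences)

    def subset(self, idx: Sequence[int]) -> "LabeledDataset":
        idx = list(idx)
        return LabeledDataset(
            [self.sequences[i] for i in idx], self.labels[idx], self.molecule
        )


def read_fasta(
    path: str | Path,
    molecule: Molecule,
    skip_invalid: bool = False,
) -> list[BioSequence]:
    """Read a FASTA file into validated :class:`BioSequence` records.

    Records are returned in file order; sequence lines are concatenated,
    whitespace-stripped and uppercased, so lowercase input is accepted.
    With ``skip_invalid`` whole offending records are dropped (count
    logged) instead of aborting.
    """
    path = Path(path)
    molecule = Molecule(molecule)
    records: list[BioSequence] = []
    n_dropped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).replace(" ", "").replace("\t", "").upper()
        try:
            records.append(BioSequence(rec.id, residues, molecule))
        except SequenceError:
            if skip_invalid:
                n_dropped += 1
                continue
            raise
    if n_dropped:
        logger.warning("%s: dropped %d invalid record(s)", path, n_dropped)
    if not records and not n_dropped:
        raise SequenceError(f"no records in {path}")
    if not records:
        raise SequenceError(f"no valid records in {path}")
    return records


def write_fasta(records: Iterable[BioSequence], path: str | Path, width: int = 70) -> None:
    """Write records as multi-line FASTA (round-trips with :func:`read_fasta`)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.L, width):
                fh.write(rec.residues[i : i + width] + "\n")


def load_benchmark(
    pos_path: str | Path,
    neg_path: str | Path,
    molecule: Molecule,
    skip_invalid: bool = False,
) -> LabeledDataset:
    """Load a two-file benchmark: positives labeled +1, then negatives -1.

    File order is preserved within each class.  Duplicate identifiers across
    the two files are permitted but logged as a warning.
    """
    molecule = Molecule(molecule)
    pos = read_fasta(pos_path, molecule, skip_invalid=skip_invalid)
    neg = read_fasta(neg_path, molecule, skip_invalid=skip_invalid)
    if not pos or not neg:
        raise SequenceError("benchmark requires both classes")
    dup = {r.id for r in pos} & {r.id for r in neg}
    if dup:
        logger.warning(
            "%d identifier(s) appear in both classes: %s",
            len(dup),
            ", ".join(sorted(dup)[:5]),
        )
    labels = np.concatenate([np.ones(len(pos), int), -np.ones(len(neg), int)])
    return LabeledDataset(pos + neg, labels, molecule)
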