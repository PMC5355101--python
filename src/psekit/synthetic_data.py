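"""Seeded two-class benchmark generators with controllable planted signal.

Three signal types:

* ``motif`` — positives carry a fixed motif inserted (overwritten in place)
  at a uniformly random position with probability ``insertion_prob``;
  negatives are i.i.d. uniform over the alphabet.
* ``composition_shift`` — positive symbol frequencies are tilted: the first
  half of the alphabet gains ``shift_delta`` of probability mass at the
  expense of the second half (renormalized); negatives stay uniform.
* ``null`` — both classes i.i.d. uniform; the labels carry no signal, so
  any downstream cross-validated AUC should hover near 0.5.

Per-sequence randomness is derived from the master seed by counter-based
sub-seeding (``SeedSequence(seed, spawn_key=(class, i))``), so generating
more sequences never perturbs the ones already generated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sequence_io import ALPHABETS, BioSequence, LabeledDataset, Molecule, write_fasta


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    molecule: Molecule = Molecule.DNA
    n_per_class: int = 100
    length: int = 100
    signal: str = "motif"  # motif | composition_shift | null
    motif: str = "ACGTACGT"
    insertion_prob: float = 1.0
    shift_delta: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signal not in ("motif", "composition_shift", "null"):
            raise SyntheticError(f"unknown signal type {self.signal!r}")
        if not 0.0 <= self.insertion_prob <= 1.0:
            raise SyntheticError("insertion_prob must lie in [0, 1]")
        if self.signal == "motif":
            alphabet = set(ALPHABETS[Molecule(self.molecule)])
            if not set(self.motif) <= alphabet:
                raise SyntheticError("motif uses symbols outside the alphabet")
            if len(self.motif) > self.length:
                raise SyntheticError("motif longer than sequence length")
        if self.n_per_class < 1 or self.length < 1:
            raise SyntheticError("n_per_class and length must be >= 1")


def _rng(spec: SyntheticSpec, cls: int, i: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(cls, i)))


def _uniform_seq(rng: np.random.Generator, alphabet: str, length: int) -> str:
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), length)])


def _shifted_seq(rng: np.random.Generator, alphabet: str, length: int,
                 delta: float) -> str:
    n = len(alphabet)
    probs = np.full(n, 1.0 / n)
    half = n // 2
    probs[:half] += delta / half
    probs[half:] -= delta / (n - half)
    if (probs < 0).any():
        raise SyntheticError("shift_delta too large: negative probabilities")
    probs /= probs.sum()
    return "".join(np.array(list(alphabet))[rng.choice(n, size=length, p=probs)])


def generate(spec: SyntheticSpec) -> tuple[LabeledDataset, list[dict]]:
    """Generate the benchmark and a manifest of planted ground truth.

    The manifest holds one record per sequence: id, label, and (for motif
    positives) the 1-based insertion position or -1 when the coin flip left
    the sequence unmodified.
    """
    molecule = Molecule(spec.molecule)
    alphabet = ALPHABETS[molecule]
    sequences: list[BioSequence] = []
    manifest: list[dict] = []
    for cls_idx, (cls_tag, label) in enumerate((("pos", 1), ("neg", -1))):
        for i in range(spec.n_per_class):
            rng = _rng(spec, cls_idx, i)
            pos = -1
            if spec.signal == "composition_shift" and label == 1:
                residues = _shifted_seq(rng, alphabet, spec.length,
                                        spec.shift_delta)
            else:
                residues = _uniform_seq(rng, alphabet, spec.length)
            if (spec.signal == "motif" and label == 1
                    and rng.random() < spec.insertion_prob):
                start = int(rng.integers(0, spec.length - len(spec.motif) + 1))
                residues = (residues[:start] + spec.motif
                            + residues[start + len(spec.motif):])
                pos = start + 1
            seq_id = f"{cls_tag}_{i:04d}"
            sequences.append(BioSequence(seq_id, residues, molecule))
            manifest.append({"id": seq_id, "label": label, "motif_pos": pos})
    labels = np.array([m["label"] for m in manifest], dtype=int)
    return LabeledDataset(sequences, labels, molecule), manifest


def write_benchmark(
    spec: SyntheticSpec, outdir: str | Path
) -> tuple[Path, Path, Path]:
    """Emit pos.fasta / neg.fasta / manifest.tsv under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset, manifest = generate(spec)
    pos_path = outdir / "pos.fasta"
    neg_path = outdir / "neg.fasta"
    man_path = outdir / "manifest.tsv"
    pos = [s for s, l in zip(dataset.sequences, dataset.labels) if l == 1]
    neg = [s for s, l in zip(dataset.sequences, dataset.labels) if l == -1]
    write_fasta(pos, pos_path)
    write_fasta(neg, neg_path)
    with open(man_path, "w") as fh:
        fh.write("id\tlabel\tmotif_pos\n")
        for m in manifest:
            fh.write(f"{m['id']}\t{m['label']}\t{m['motif_pos']}\n")
    return pos_path, neg_path, man_path
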