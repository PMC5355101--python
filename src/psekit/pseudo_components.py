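"""Pseudo-component feature vectors: PseKNC for DNA/RNA, PseAAC for protein.

A feature vector has two blocks.  The composition block is the vector of
overlapping k-mer frequencies (4^k for nucleic acids, 20^k for protein; the
classic protein composition uses k=1).  The pseudo block carries λ
sequence-order correlation factors computed from standardized physicochemical
property values of the correlation unit — the DINUCLEOTIDE for DNA/RNA
(regardless of the composition-block k) and the residue for protein.

Two correlation modes are supported.  In *parallel* (type-I) mode the tier-j
factor is

    θ_j = mean_i Θ(u_i, u_{i+j}),   Θ(a, b) = (1/Λ) Σ_ξ [P_ξ(a) − P_ξ(b)]²

averaged over all positions i for which both units exist; there are n − j
terms when the sequence yields n units (n = L − 1 for dinucleotides, n = L
for residues).  In *series* (type-II, amphiphilic-style) mode each tier
contributes Λ per-property product correlations

    τ_{(j−1)Λ+ξ} = mean_i P_ξ(u_i) · P_ξ(u_{i+j}),

nested tiers-outer, properties-inner.  With f the composition block (Σf = 1)
and T the sum of all correlation factors, the assembled vector is

    x_u = f_u / (1 + wT)            for u ≤ M,
    x_{M+j} = w c_j / (1 + wT)      for the pseudo block,

so all components sum to one whenever 1 + wT > 0.

Property values are standardized to mean 0 and population SD 1 over the unit
alphabet before any correlation is computed, which makes the features
invariant to the scale and offset of the raw property tables.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .sequence_io import ALPHABETS, BioSequence, LabeledDataset, Molecule

logger = logging.getLogger("psekit")


class PseError(ValueError):
    """Raised for inadmissible feature parameters or degenerate inputs."""


# ---------------------------------------------------------------------------
# Parameters and property tables
# ---------------------------------------------------------------------------

PARALLEL = "parallel"
SERIES = "series"


@dataclass(frozen=True)
class PseParams:
    """Feature hyperparameters: tuple size k, correlation depth λ, weight w."""

    k: int = 1
    lam: int = 1
    w: float = 0.5
    mode: str = PARALLEL

    def __post_init__(self) -> None:
        if self.k < 1:
            raise PseError("k must be >= 1")
        if self.lam < 0:
            raise PseError("lambda must be >= 0")
        if not self.w > 0:
            raise PseError("w must be > 0")
        if self.mode not in (PARALLEL, SERIES):
            raise PseError(f"unknown correlation mode {self.mode!r}")


def unit_alphabet(molecule: Molecule, unit: str) -> list[str]:
    """Symbols of the correlation unit in canonical (lexicographic) order."""
    base = ALPHABETS[molecule]
    if unit == "residue":
        return list(base)
    if unit == "dinucleotide":
        if molecule is Molecule.PROTEIN:
            raise PseError("dinucleotide unit is undefined for protein")
        return ["".join(p) for p in itertools.product(base, repeat=2)]
    raise PseError(f"unknown unit {unit!r}")


def correlation_unit(molecule: Molecule) -> str:
    """Default correlation unit per molecule type."""
    return "residue" if molecule is Molecule.PROTEIN else "dinucleotide"


@dataclass(frozen=True)
class PropertyTable:
    """Raw physicochemical values per unit symbol, Λ properties."""

    molecule: Molecule
    unit: str
    names: tuple[str, ...]
    raw_values: Mapping[str, Mapping[str, float]]  # name -> symbol -> value
    set_name: str = "custom"

    def __post_init__(self) -> None:
        symbols = set(unit_alphabet(self.molecule, self.unit))
        if len(self.names) < 1:
            raise PseError("property table needs at least one property")
        for name in self.names:
            missing = symbols - set(self.raw_values[name])
            if missing:
                raise PseError(
                    f"property {name!r} misses symbols: {sorted(missing)}"
                )


@dataclass(frozen=True)
class PropertyIndex:
    """Standardized property values: per property, mean 0 / population SD 1."""

    molecule: Molecule
    unit: str
    names: tuple[str, ...]
    matrix: np.ndarray  # shape (Λ, n_symbols), columns in unit-alphabet order
    set_name: str = "custom"

    @property
    def n_properties(self) -> int:
        return len(self.names)

    def value(self, name: str, symbol: str) -> float:
        symbols = unit_alphabet(self.molecule, self.unit)
        return float(self.matrix[self.names.index(name), symbols.index(symbol)])


def standardize_properties(table: PropertyTable) -> PropertyIndex:
    """Center and scale each property by its population SD over the alphabet.

    Raises :class:`PseError` for a constant property (zero SD).
    """
    symbols = unit_alphabet(table.molecule, table.unit)
    mat = np.array(
        [[float(table.raw_values[name][s]) for s in symbols] for name in table.names],
        dtype=float,
    )
    mu = mat.mean(axis=1, keepdims=True)
    sigma = mat.std(axis=1, keepdims=True)  # population SD
    for i, name in enumerate(table.names):
        if sigma[i, 0] == 0.0:
            raise PseError(f"property {name!r} is constant; cannot standardize")
    return PropertyIndex(
        table.molecule, table.unit, tuple(table.names), (mat - mu) / sigma,
        set_name=table.set_name,
    )


# --- shipped default property sets -----------------------------------------
# DNA: six dinucleotide helical parameters (standardized values as published
# for the pseudo dinucleotide composition).  RNA: the corresponding
# ribodinucleotide geometric set.  Protein: the classic hydrophobicity /
# hydrophilicity / side-chain-mass triple.  All sets pass through
# standardize_properties at load, so downstream math never depends on the
# scale of the stored numbers.

_DNA_ROWS = """
AA  0.06  0.50  0.27  1.59  0.11 -0.11
AC  1.50  0.50  0.80  0.13  1.29  1.04
AG  0.78  0.36  0.09  0.68 -0.24 -0.62
AT  1.07  0.22  0.62 -1.02  2.51  1.17
CA -1.38 -1.36 -0.27 -0.86 -0.62 -1.25
CC  0.06  1.08  0.09  0.56 -0.82  0.24
CG -1.66 -1.22 -0.44 -0.82 -0.29 -1.39
CT  0.78  0.36  0.09  0.68 -0.24 -0.62
GA -0.08  0.50  0.27  0.13 -0.39  0.71
GC -0.08  0.22  1.33 -0.35  0.65  1.59
GG  0.06  1.08  0.09  0.56 -0.82  0.24
GT  1.50  0.50  0.80  0.13  1.29  1.04
TA -1.23 -2.37 -1.38 -2.24 -1.51 -1.39
TC -0.08  0.50  0.27  0.13 -0.39  0.71
TG -1.38 -1.36 -0.27 -0.86 -0.62 -1.25
TT  0.06  0.50  0.27  1.59  0.11 -0.11
"""
_DNA_NAMES = ("Twist", "Tilt", "Roll", "Shift", "Slide", "Rise")

_RNA_ROWS = """
AA -0.08 -1.27  3.18 -0.80  7.00 31.00
AC  0.23 -1.43  3.24  0.80  4.80 32.00
AG -0.04 -1.50  3.30  0.50  8.50 30.00
AU -0.06 -1.36  3.24  1.10  7.10 33.00
CA  0.11 -1.46  3.09  1.00  9.90 31.00
CC -0.01 -1.78  3.32  0.30  8.70 32.00
CG  0.30 -1.89  3.30 -0.10 12.10 27.00
CU -0.04 -1.50  3.30  0.50  8.50 30.00
GA  0.07 -1.70  3.38  1.30  9.40 32.00
GC  0.07 -1.39  3.22  0.00  6.10 35.00
GG -0.01 -1.78  3.32  0.30  8.70 32.00
GU  0.23 -1.43  3.24  0.80  4.80 32.00
UA -0.02 -1.45  3.26 -0.20 10.70 32.00
UC  0.07 -1.70  3.38  1.30  9.40 32.00
UG  0.11 -1.46  3.09  1.00  9.90 31.00
UU -0.08 -1.27  3.18 -0.80  7.00 31.00
"""
_RNA_NAMES = ("Shift", "Slide", "Rise", "Tilt", "Roll", "Twist")

_PROTEIN_ROWS = """
A  0.62 -0.5   15.0
C  0.29 -1.0   47.0
D -0.90  3.0   59.0
E -0.74  3.0   73.0
F  1.19 -2.5   91.0
G  0.48  0.0    1.0
H -0.40 -0.5   82.0
I  1.38 -1.8   57.0
K -1.50  3.0   73.0
L  1.06 -1.8   57.0
M  0.64 -1.3   75.0
N -0.78  0.2   58.0
P  0.12  0.0   42.0
Q -0.85  0.2   72.0
R -2.53  3.0  101.0
S -0.18  0.3   31.0
T -0.05 -0.4   45.0
V  1.08 -1.5   43.0
W  0.81 -3.4  130.0
Y  0.26 -2.3  107.0
"""
_PROTEIN_NAMES = ("Hydrophobicity", "Hydrophilicity", "SideChainMass")


def _parse_rows(rows: str, names: tuple[str, ...]) -> dict[str, dict[str, float]]:
    values: dict[str, dict[str, float]] = {n: {} for n in names}
    for line in rows.strip().splitlines():
        parts = line.split()
        symbol, vals = parts[0], [float(v) for v in parts[1:]]
        for name, v in zip(names, vals):
            values[name][symbol] = v
    return values


def default_property_table(molecule: Molecule) -> PropertyTable:
    """The shipped property set for a molecule type."""
    molecule = Molecule(molecule)
    if molecule is Molecule.DNA:
        return PropertyTable(
            molecule, "dinucleotide", _DNA_NAMES,
            _parse_rows(_DNA_ROWS, _DNA_NAMES), set_name="dna-helical-6",
        )
    if molecule is Molecule.RNA:
        return PropertyTable(
            molecule, "dinucleotide", _RNA_NAMES,
            _parse_rows(_RNA_ROWS, _RNA_NAMES), set_name="rna-helical-6",
        )
    return PropertyTable(
        molecule, "residue", _PROTEIN_NAMES,
        _parse_rows(_PROTEIN_ROWS, _PROTEIN_NAMES), set_name="protein-classic-3",
    )


def default_property_index(molecule: Molecule) -> PropertyIndex:
    return standardize_properties(default_property_table(molecule))


def read_property_table(
    path: str | Path, molecule: Molecule, unit: str | None = None
) -> PropertyTable:
    """Read a user property table: TSV, header of property names, first
    column the unit symbol."""
    molecule = Molecule(molecule)
    if unit is None:
        unit = correlation_unit(molecule)
    lines = Path(path).read_text().strip().splitlines()
    header = lines[0].rstrip("\n").split("\t")
    names = tuple(h.strip() for h in header[1:])
    values: dict[str, dict[str, float]] = {n: {} for n in names}
    for line in lines[1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        symbol = parts[0].strip().upper()
        for name, v in zip(names, parts[1:]):
            values[name][symbol] = float(v)
    return PropertyTable(molecule, unit, names, values,
                         set_name=Path(path).name)


# ---------------------------------------------------------------------------
# Composition block
# ---------------------------------------------------------------------------

def _encode(seq: BioSequence) -> np.ndarray:
    alphabet = ALPHABETS[seq.molecule]
    lut = np.full(128, -1, dtype=np.int64)
    for i, s in enumerate(alphabet):
        lut[ord(s)] = i
    return lut[np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)]


def kmer_composition(seq: BioSequence, k: int) -> np.ndarray:
    """Overlapping k-mer frequencies in lexicographic k-mer order.

    Components sum to one; raises for sequences shorter than k.
    """
    if k < 1:
        raise PseError("k must be >= 1")
    if seq.L < k:
        raise PseError(f"sequence {seq.id!r} shorter than k={k}")
    codes = _encode(seq)
    base = len(ALPHABETS[seq.molecule])
    idx = np.zeros(seq.L - k + 1, dtype=np.int64)
    for offset in range(k):
        idx = idx * base + codes[offset : seq.L - k + 1 + offset]
    counts = np.bincount(idx, minlength=base**k).astype(float)
    return counts / (seq.L - k + 1)


# ---------------------------------------------------------------------------
# Correlation factors
# ---------------------------------------------------------------------------

def _unit_codes(seq: BioSequence, index: PropertyIndex) -> np.ndarray:
    if index.molecule is not seq.molecule:
        raise PseError(
            f"property index is for {index.molecule.value}, "
            f"sequence {seq.id!r} is {seq.molecule.value}"
        )
    codes = _encode(seq)
    if index.unit == "residue":
        return codes
    return codes[:-1] * len(ALPHABETS[seq.molecule]) + codes[1:]


def _check_lambda(seq: BioSequence, n_units: int, lam: int) -> None:
    if lam > n_units - 1:
        raise PseError(
            f"lambda={lam} inadmissible for sequence {seq.id!r} "
            f"(L={seq.L}; maximum lambda is {n_units - 1})"
        )


def parallel_correlation(
    seq: BioSequence, index: PropertyIndex, lam: int
) -> np.ndarray:
    """Type-I tier factors θ_1..θ_λ (property-averaged squared differences)."""
    units = _unit_codes(seq, index)
    _check_lambda(seq, len(units), lam)
    if lam == 0:
        return np.zeros(0)
    vals = index.matrix[:, units]  # (Λ, n_units)
    theta = np.empty(lam)
    for j in range(1, lam + 1):
        diff = vals[:, :-j] - vals[:, j:]
        theta[j - 1] = np.mean(diff * diff, axis=0).mean()
    return theta


def series_correlation(
    seq: BioSequence, index: PropertyIndex, lam: int
) -> np.ndarray:
    """Type-II factors τ, tiers outer and properties inner (length λ·Λ)."""
    units = _unit_codes(seq, index)
    _check_lambda(seq, len(units), lam)
    if lam == 0:
        return np.zeros(0)
    vals = index.matrix[:, units]
    tau = np.empty(lam * index.n_properties)
    for j in range(1, lam + 1):
        prod = vals[:, :-j] * vals[:, j:]
        tau[(j - 1) * index.n_properties : j * index.n_properties] = prod.mean(axis=1)
    return tau


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    params: PseParams
    property_set: str

    @property
    def dim(self) -> int:
        return len(self.values)


def pse_vector(
    seq: BioSequence, params: PseParams, index: PropertyIndex
) -> FeatureVector:
    """Assemble the normalized composition + pseudo-component vector."""
    f = kmer_composition(seq, params.k)
    if params.mode == PARALLEL:
        corr = parallel_correlation(seq, index, params.lam)
    else:
        corr = series_correlation(seq, index, params.lam)
    T = float(corr.sum())
    denom = 1.0 + params.w * T
    if denom <= 0:
        raise PseError(
            f"degenerate normalization for {seq.id!r}: 1 + w*T = {denom}"
        )
    values = np.concatenate([f, params.w * corr]) / denom
    return FeatureVector(values, params, index.set_name)


def feature_names(
    molecule: Molecule, params: PseParams, index: PropertyIndex
) -> list[str]:
    """Column names: k-mers, then 'pse.j' (parallel) or 'pse.j.ξ' (series)."""
    kmers = ["".join(p) for p in itertools.product(ALPHABETS[molecule],
                                                   repeat=params.k)]
    if params.mode == PARALLEL:
        pseudo = [f"pse.{j}" for j in range(1, params.lam + 1)]
    else:
        pseudo = [
            f"pse.{j}.{x}"
            for j in range(1, params.lam + 1)
            for x in range(1, index.n_properties + 1)
        ]
    return kmers + pseudo


def extract_features(
    dataset: LabeledDataset, params: PseParams, index: PropertyIndex
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix (rows in dataset order) and ±1 label vector.

    Inadmissible sequences are reported all at once, not first-only.
    """
    bad: list[str] = []
    n_min = 1 if index.unit == "residue" else 2
    for seq in dataset.sequences:
        n_units = seq.L - (n_min - 1)
        if params.lam > n_units - 1 or seq.L < params.k:
            bad.append(seq.id)
    if bad:
        raise PseError(
            f"{len(bad)} sequence(s) inadmissible for k={params.k}, "
            f"lambda={params.lam}: {', '.join(bad)}"
        )
    rows = [pse_vector(seq, params, index).values for seq in dataset.sequences]
    return np.vstack(rows), dataset.labels.copy()


def min_length(params: PseParams, index: PropertyIndex) -> int:
    """Shortest admissible sequence length for a feature recipe."""
    unit_extra = 0 if index.unit == "residue" else 1
    return max(params.k, params.lam + 1 + unit_extra)


def write_feature_matrix(
    path: str | Path,
    matrix: np.ndarray,
    labels: np.ndarray,
    ids: Iterable[str],
    names: list[str],
) -> None:
    """Debug export: TSV with named k-mer / pseudo-component columns."""
    with open(path, "w") as fh:
        fh.write("id\tlabel\t" + "\t".join(names) + "\n")
        for sid, lab, row in zip(ids, labels, matrix):
            fh.write(
                f"{sid}\t{int(lab)}\t" + "\t".join(repr(float(v)) for v in row) + "\n"
            )
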