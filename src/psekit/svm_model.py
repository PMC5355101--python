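"""RBF-kernel SVM training, scoring, and single-file model persistence.

The solver is the libsvm engine behind scikit-learn's ``SVC``; this module
owns the contract around it: the kernel form K(x, y) = exp(−γ‖x−y‖²),
deterministic decision values recomputed from the stored support-vector
expansion, and a version-stamped archive holding the classifier in the
LIBSVM text-model dialect next to the full feature recipe, so prediction on
new sequences is reproducible from the archive alone.

Features arrive already normalized (every pseudo-component vector sums to
one), so no internal rescaling is applied before training.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from sklearn.svm import SVC

from .pseudo_components import (
    PropertyIndex,
    PseParams,
    extract_features,
    min_length,
    pse_vector,
)
from .sequence_io import BioSequence, LabeledDataset, Molecule

FORMAT_VERSION = "1"


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class SvmParams:
    """Soft-margin cost C and RBF width gamma."""

    C: float
    gamma: float

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ModelError("C must be > 0")
        if not self.gamma > 0:
            raise ModelError("gamma must be > 0")


@dataclass(frozen=True)
class RbfSvmState:
    """Fitted classifier: support vectors, dual coefficients, bias.

    Decision values are computed directly from this expansion,
    f(x) = Σ_i α_i K(sv_i, x) + b, elementwise and per-row, so scores are
    invariant to the order of rows in the prediction matrix and reproduce
    bit-identically after a save/load round trip.
    """

    support_vectors: np.ndarray  # (n_sv, d)
    dual_coef: np.ndarray        # (n_sv,), positive entries back the +1 class
    intercept: float
    n_sv_by_class: tuple[int, int]  # (class -1, class +1) blocks, in order
    params: SvmParams

    @property
    def n_features(self) -> int:
        return self.support_vectors.shape[1]

    def decision_scores(self, matrix: np.ndarray) -> np.ndarray:
        matrix = np.asarray(matrix, float)
        if matrix.ndim == 1:
            matrix = matrix[None, :]
        if matrix.shape[1] != self.n_features:
            raise ModelError(
                f"feature dimension mismatch: expected {self.n_features}, "
                f"got {matrix.shape[1]}"
            )
        diff = matrix[:, None, :] - self.support_vectors[None, :, :]
        sq = (diff * diff).sum(axis=2)
        kernel = np.exp(-self.params.gamma * sq)
        return kernel @ self.dual_coef + self.intercept


def train_svm(
    matrix: np.ndarray, labels: np.ndarray, params: SvmParams
) -> RbfSvmState:
    """Fit the RBF-SVM; deterministic given inputs and solver tolerance."""
    matrix = np.asarray(matrix, float)
    labels = np.asarray(labels, int)
    if not np.isfinite(matrix).all():
        raise ModelError("feature matrix contains non-finite values")
    classes = set(labels.tolist())
    if classes != {-1, 1}:
        raise ModelError(
            f"training requires both classes (+1/-1); got labels {sorted(classes)}"
        )
    clf = SVC(C=params.C, gamma=params.gamma, kernel="rbf", shrinking=True,
              tol=1e-3, cache_size=100)
    clf.fit(matrix, labels)
    # sklearn orders classes_ as [-1, +1]; decision_function > 0 <-> +1,
    # matching the sign convention used throughout.
    return RbfSvmState(
        support_vectors=np.array(clf.support_vectors_, dtype=float),
        dual_coef=np.array(clf.dual_coef_[0], dtype=float),
        intercept=float(clf.intercept_[0]),
        n_sv_by_class=(int(clf.n_support_[0]), int(clf.n_support_[1])),
        params=params,
    )


@dataclass
class TrainedModel:
    """A fitted SVM plus everything needed to re-extract features."""

    state: RbfSvmState
    pse_params: PseParams
    index: PropertyIndex
    molecule: Molecule
    training_summary: dict[str, Any] = field(default_factory=dict)
    format_version: str = FORMAT_VERSION

    def extract(self, sequences: list[BioSequence]) -> np.ndarray:
        rows = [
            pse_vector(s, self.pse_params, self.index).values for s in sequences
        ]
        return np.vstack(rows)

    @property
    def min_length(self) -> int:
        return min_length(self.pse_params, self.index)


def decision_scores(model: TrainedModel, matrix: np.ndarray) -> np.ndarray:
    """Signed decision values; positive predicts the +1 class."""
    return model.state.decision_scores(matrix)


def predict_labels(model: TrainedModel, matrix: np.ndarray) -> np.ndarray:
    """±1 labels by the sign of the decision score; exact 0 maps to +1."""
    return np.where(decision_scores(model, matrix) >= 0, 1, -1)


# ---------------------------------------------------------------------------
# Persistence: zip archive of metadata.json + LIBSVM text model
# ---------------------------------------------------------------------------

def _libsvm_text(state: RbfSvmState) -> str:
    """Serialize in the libsvm c_svc dialect.

    The file's labels are "-1 1" (the internal class order); libsvm's
    decision convention makes a positive value vote for the FIRST label, so
    the stored coefficients are the negated dual coefficients and rho is the
    intercept.  Negation is exact in floating point, hence bit-identical
    round trips.  Floats use shortest round-trip repr.
    """
    lines = [
        "svm_type c_svc",
        "kernel_type rbf",
        f"gamma {float(state.params.gamma)!r}",
        "nr_class 2",
        f"total_sv {len(state.dual_coef)}",
        f"rho {float(state.intercept)!r}",
        "label -1 1",
        f"nr_sv {state.n_sv_by_class[0]} {state.n_sv_by_class[1]}",
        "SV",
    ]
    for coef, sv in zip(-state.dual_coef, state.support_vectors):
        feats = " ".join(f"{i + 1}:{float(v)!r}" for i, v in enumerate(sv))
        lines.append(f"{float(coef)!r} {feats}")
    return "\n".join(lines) + "\n"


def _parse_libsvm_text(text: str, C: float) -> RbfSvmState:
    header: dict[str, str] = {}
    lines = text.strip().splitlines()
    sv_start = None
    for i, line in enumerate(lines):
        if line.strip() == "SV":
            sv_start = i + 1
            break
        key, _, value = line.partition(" ")
        header[key] = value
    if sv_start is None:
        raise ModelError("corrupt model text: missing SV section")
    if header.get("svm_type") != "c_svc" or header.get("kernel_type") != "rbf":
        raise ModelError("unsupported svm_type/kernel_type in model text")
    gamma = float(header["gamma"])
    rho = float(header["rho"])
    labels = [int(x) for x in header["label"].split()]
    nr_sv = tuple(int(x) for x in header["nr_sv"].split())
    if labels != [-1, 1]:
        raise ModelError(f"unexpected label order {labels} in model text")
    coefs, svs = [], []
    for line in lines[sv_start:]:
        parts = line.split()
        coefs.append(float(parts[0]))
        row = {}
        for tok in parts[1:]:
            idx, _, val = tok.partition(":")
            row[int(idx) - 1] = float(val)
        d = max(row) + 1
        svs.append([row.get(i, 0.0) for i in range(d)])
    d = max(len(r) for r in svs)
    mat = np.zeros((len(svs), d))
    for i, r in enumerate(svs):
        mat[i, : len(r)] = r
    return RbfSvmState(
        support_vectors=mat,
        dual_coef=-np.array(coefs),
        intercept=rho,
        n_sv_by_class=(nr_sv[0], nr_sv[1]),
        params=SvmParams(C=C, gamma=gamma),
    )


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write the single-file model archive (zip: metadata.json + model.libsvm)."""
    meta = {
        "format_version": model.format_version,
        "molecule": model.molecule.value,
        "pse_params": {
            "k": model.pse_params.k,
            "lambda": model.pse_params.lam,
            "w": model.pse_params.w,
            "mode": model.pse_params.mode,
        },
        "svm_params": {"C": model.state.params.C,
                       "gamma": model.state.params.gamma},
        "property_index": {
            "set_name": model.index.set_name,
            "unit": model.index.unit,
            "names": list(model.index.names),
            "matrix": model.index.matrix.tolist(),
        },
        "training_summary": model.training_summary,
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("metadata.json", json.dumps(meta, indent=1))
        zf.writestr("model.libsvm", _libsvm_text(model.state))


def load_model(path: str | Path) -> TrainedModel:
    """Read a model archive; refuses unknown members or future versions."""
    try:
        zf = zipfile.ZipFile(path)
    except (zipfile.BadZipFile, FileNotFoundError) as exc:
        raise ModelError(f"cannot open model archive {path}: {exc}") from exc
    with zf:
        names = set(zf.namelist())
        for member in ("metadata.json", "model.libsvm"):
            if member not in names:
                raise ModelError(f"model archive missing member {member!r}")
        meta = json.loads(zf.read("metadata.json"))
        version = str(meta.get("format_version", "?"))
        if version != FORMAT_VERSION:
            raise ModelError(
                f"unsupported model format_version {version!r} "
                f"(this build reads {FORMAT_VERSION!r})"
            )
        state = _parse_libsvm_text(
            zf.read("model.libsvm").decode(), C=float(meta["svm_params"]["C"])
        )
    p = meta["pse_params"]
    pse_params = PseParams(k=int(p["k"]), lam=int(p["lambda"]),
                           w=float(p["w"]), mode=p["mode"])
    pi = meta["property_index"]
    index = PropertyIndex(
        molecule=Molecule(meta["molecule"]),
        unit=pi["unit"],
        names=tuple(pi["names"]),
        matrix=np.array(pi["matrix"], dtype=float),
        set_name=pi["set_name"],
    )
    return TrainedModel(
        state=state,
        pse_params=pse_params,
        index=index,
        molecule=Molecule(meta["molecule"]),
        training_summary=meta.get("training_summary", {}),
        format_version=version,
    )


def fit_final_model(
    dataset: LabeledDataset,
    pse_params: PseParams,
    svm_params: SvmParams,
    index: PropertyIndex,
    training_summary: dict[str, Any] | None = None,
) -> TrainedModel:
    """Refit on the full benchmark with chosen parameters."""
    matrix, labels = extract_features(dataset, pse_params, index)
    state = train_svm(matrix, labels, svm_params)
    return TrainedModel(state, pse_params, index, dataset.molecule,
                        training_summary or {})
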