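"""Joint grid search over feature (k, λ, w, mode) and SVM (C, γ) parameters.

Every candidate is scored by pooled cross-validation on ONE shared fold
assignment (computed once from the master seed), so candidate comparisons
are paired and fold noise cancels out of the selection.  The winner
maximizes the chosen objective (Acc by default; AUC or MCC selectable);
ties go to the lexicographically earlier candidate, i.e. the simpler model.

Candidates the dataset cannot support (λ too deep for its shortest
sequence) are skipped with a logged reason rather than aborting the search.
Evaluation may be spread over worker processes; the result is identical for
any worker count because candidates are independent and reassembled in grid
order.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from joblib import Parallel, delayed

from .evaluation import FoldAssignment, MetricReport, pooled_cv_from_matrix
from .pseudo_components import (
    PropertyIndex,
    PseParams,
    extract_features,
    min_length,
)
from .sequence_io import LabeledDataset, Molecule
from .svm_model import SvmParams

logger = logging.getLogger("psekit")

OBJECTIVES = ("acc", "auc", "mcc")


class SelectionError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class Candidate:
    """One point of the joint grid, ordered lexicographically (simpler first)."""

    k: int
    lam: int
    w: float
    mode: str
    C: float
    gamma: float

    @property
    def pse_params(self) -> PseParams:
        return PseParams(k=self.k, lam=self.lam, w=self.w, mode=self.mode)

    @property
    def svm_params(self) -> SvmParams:
        return SvmParams(C=self.C, gamma=self.gamma)


DEFAULTS = {
    "lams": (1, 2, 3, 4, 5),
    "ws": (0.1, 0.3, 0.5, 0.7, 0.9),
    "modes": ("parallel",),
    "Cs": (2.0**-2, 2.0**0, 2.0**2, 2.0**4, 2.0**6),
    "gammas": (2.0**-6, 2.0**-4, 2.0**-2, 2.0**0, 2.0**2, 2.0**4, 2.0**6),
}


@dataclass(frozen=True)
class ParameterGrid:
    ks: tuple[int, ...]
    lams: tuple[int, ...]
    ws: tuple[float, ...]
    modes: tuple[str, ...]
    Cs: tuple[float, ...]
    gammas: tuple[float, ...]
    objective: str = "acc"

    def candidates(self) -> list[Candidate]:
        cands = [
            Candidate(k, lam, w, mode, C, g)
            for k in self.ks
            for lam in self.lams
            for w in self.ws
            for mode in self.modes
            for C in self.Cs
            for g in self.gammas
        ]
        return sorted(cands)

    def __len__(self) -> int:
        return (len(self.ks) * len(self.lams) * len(self.ws) * len(self.modes)
                * len(self.Cs) * len(self.gammas))


def build_grid(
    molecule: Molecule,
    ks=None,
    lams=None,
    ws=None,
    modes=None,
    Cs=None,
    gammas=None,
    objective: str = "acc",
) -> ParameterGrid:
    """Assemble the grid, filling unset lists with the documented defaults.

    Defaults: k ∈ {2, 3, 4, 5} for DNA/RNA and k = 1 for protein; λ ∈ 1..5;
    w ∈ {0.1, 0.3, 0.5, 0.7, 0.9}; parallel mode; C ∈ {2⁻², 2⁰, 2², 2⁴, 2⁶};
    γ ∈ {2⁻⁶, 2⁻⁴, ..., 2⁴, 2⁶}.  The γ range runs well above 1 because the
    feature vectors are normalized to sum to one, so pairwise squared
    distances are typically far below 1 and the RBF width must be able to
    match that scale; likewise k reaches 5 so the composition block can
    resolve signals the length of a short motif.
    """
    molecule = Molecule(molecule)
    if ks is None:
        ks = (1,) if molecule is Molecule.PROTEIN else (2, 3, 4, 5)
    lams = DEFAULTS["lams"] if lams is None else tuple(lams)
    ws = DEFAULTS["ws"] if ws is None else tuple(ws)
    modes = DEFAULTS["modes"] if modes is None else tuple(modes)
    Cs = DEFAULTS["Cs"] if Cs is None else tuple(Cs)
    gammas = DEFAULTS["gammas"] if gammas is None else tuple(gammas)
    ks = tuple(ks)
    for name, lst in (("k", ks), ("lambda", lams), ("w", ws),
                      ("mode", modes), ("C", Cs), ("gamma", gammas)):
        if len(lst) == 0:
            raise SelectionError(f"empty candidate list for {name}")
    if any(k < 1 for k in ks):
        raise SelectionError("k candidates must be >= 1")
    if any(l < 0 for l in lams):
        raise SelectionError("lambda candidates must be >= 0")
    if any(not (w > 0) for w in ws):
        raise SelectionError("w candidates must be > 0")
    if any(m not in ("parallel", "series") for m in modes):
        raise SelectionError("mode must be parallel or series")
    if any(not (c > 0) for c in Cs):
        raise SelectionError("C candidates must be > 0")
    if any(not (g > 0) for g in gammas):
        raise SelectionError("gamma candidates must be > 0")
    if objective not in OBJECTIVES:
        raise SelectionError(f"objective must be one of {OBJECTIVES}")
    return ParameterGrid(ks, lams, ws, modes, Cs, gammas, objective)


@dataclass
class GridResult:
    candidates: list[Candidate]          # evaluated, in grid order
    reports: list[MetricReport]          # parallel to candidates
    best: Candidate
    best_report: MetricReport
    objective: str
    n_evaluated: int
    skipped: list[tuple[Candidate, str]] = field(default_factory=list)


def _objective_value(report: MetricReport, objective: str) -> float:
    return report.scores()[objective]


def _eval_feature_group(
    dataset: LabeledDataset,
    pse_params: PseParams,
    svm_list: list[SvmParams],
    folds: FoldAssignment,
    index: PropertyIndex,
) -> list[MetricReport]:
    """Score all SVM candidates sharing one feature recipe.

    Features are extracted once per recipe; each (C, γ) then runs pooled CV
    on the shared folds.
    """
    matrix, labels = extract_features(dataset, pse_params, index)
    return [pooled_cv_from_matrix(matrix, labels, sp, folds) for sp in svm_list]


def search(
    dataset: LabeledDataset,
    grid: ParameterGrid,
    folds: FoldAssignment,
    index: PropertyIndex,
    n_workers: int = 1,
) -> GridResult:
    """Evaluate every admissible candidate and pick the objective maximizer."""
    if n_workers < 1:
        raise SelectionError("n_workers must be >= 1")
    shortest = min(s.L for s in dataset.sequences)
    evaluated: list[Candidate] = []
    skipped: list[tuple[Candidate, str]] = []
    for cand in grid.candidates():
        need = min_length(cand.pse_params, index)
        if shortest < need:
            skipped.append(
                (cand, f"shortest sequence L={shortest} < required {need}")
            )
        else:
            evaluated.append(cand)
    for cand, reason in skipped:
        logger.info("skipping candidate %s: %s", cand, reason)
    if not evaluated:
        raise SelectionError(
            "no admissible candidate: every grid point needs longer sequences"
        )

    # Group by feature recipe so extraction is shared across (C, gamma).
    groups: dict[PseParams, list[Candidate]] = {}
    for cand in evaluated:
        groups.setdefault(cand.pse_params, []).append(cand)
    group_items = list(groups.items())
    if n_workers == 1:
        group_reports = [
            _eval_feature_group(dataset, pp, [c.svm_params for c in cands],
                                folds, index)
            for pp, cands in group_items
        ]
    else:
        group_reports = Parallel(n_jobs=n_workers)(
            delayed(_eval_feature_group)(
                dataset, pp, [c.svm_params for c in cands], folds, index
            )
            for pp, cands in group_items
        )
    report_of: dict[Candidate, MetricReport] = {}
    for (pp, cands), reports in zip(group_items, group_reports):
        for cand, rep in zip(cands, reports):
            report_of[cand] = rep

    reports = [report_of[c] for c in evaluated]
    best_i = 0
    best_val = _objective_value(reports[0], grid.objective)
    for i in range(1, len(evaluated)):
        val = _objective_value(reports[i], grid.objective)
        if val > best_val:  # strict: earlier (simpler) candidate wins ties
            best_i, best_val = i, val
    return GridResult(
        candidates=evaluated,
        reports=reports,
        best=evaluated[best_i],
        best_report=reports[best_i],
        objective=grid.objective,
        n_evaluated=len(evaluated),
        skipped=skipped,
    )


def write_grid_report(path: str | Path, result: GridResult) -> None:
    """TSV grid report: one row per evaluated candidate with all five scores."""
    with open(path, "w") as fh:
        fh.write("k\tlambda\tw\tmode\tC\tgamma\tacc\tmcc\tsn\tsp\tauc\tbest\n")
        for cand, rep in zip(result.candidates, result.reports):
            s = rep.scores()
            fh.write(
                f"{cand.k}\t{cand.lam}\t{cand.w!r}\t{cand.mode}\t"
                f"{cand.C!r}\t{cand.gamma!r}\t"
                f"{s['acc']!r}\t{s['mcc']!r}\t{s['sn']!r}\t{s['sp']!r}\t"
                f"{s['auc']!r}\t{'*' if cand == result.best else ''}\n"
            )
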