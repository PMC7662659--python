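"""PCA exploration, accuracy scoring, and the three classification designs.

The study asks three questions of the same spectra: can we tell the four
geographic origins apart; can we tell varieties apart *within* one origin;
and can we discriminate all 10 varieties at once.  ``run_task`` executes
one (task, variable subset, classifier) cell of that grid — trimming and
denoising, splitting, fitting the wavelength selection on the training
rows only, training the classifier, and scoring the held-out test rows —
and ``build_report_tables`` assembles the cells into the familiar
per-class + overall accuracy tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import ClassifierSpec, fit_classifier
from .preprocess import WaveletConfig, denoise_dataset
from .spectra_io import Partition, SpectralDataset, trim_range
from .variable_selection import GAPLSConfig, ga_pls_select, uve_spa

__all__ = ["PCAResult", "EvalReport", "TaskConfig", "run_pca", "accuracy",
           "confusion_matrix", "run_task", "build_report_tables",
           "report_markdown"]

TASKS = ("origins", "varieties_within", "all_varieties")
VARIABLE_INPUTS = ("full", "uve_spa", "ga_pls")


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAResult:
    scores: np.ndarray        # (n, n_pc)
    loadings: np.ndarray      # (p, n_pc), orthonormal columns
    explained_pct: np.ndarray  # per retained PC, % of total variance
    mean: np.ndarray


def run_pca(ds: SpectralDataset, n_pc: int) -> PCAResult:
    """Column-mean-centred SVD; explained % from the full singular spectrum."""
    X = ds.absorbance
    n, p = X.shape
    if not 1 <= n_pc <= min(n - 1, p):
        raise ValueError(f"n_pc must lie in [1, {min(n - 1, p)}]")
    mean = X.mean(axis=0)
    Xc = X - mean
    if not np.any(np.abs(Xc) > 1e-13):
        raise ValueError("zero variance: dataset is constant")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    pct = 100.0 * var / var.sum()
    return PCAResult(scores=U[:, :n_pc] * s[:n_pc], loadings=Vt[:n_pc].T,
                     explained_pct=pct[:n_pc], mean=mean)


# ---------------------------------------------------------------------------
# accuracy

def confusion_matrix(y_true, y_pred, labels: list) -> np.ndarray:
    idx = {str(l): i for i, l in enumerate(labels)}
    M = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        M[idx[str(t)], idx[str(p)]] += 1
    return M


def accuracy(confusion: np.ndarray) -> tuple[np.ndarray, float]:
    """(per-class %, overall %), both rounded to 2 decimals.

    Per-class accuracy is the row-wise recall (diagonal over row sum);
    overall is 100 * trace / total.
    """
    M = np.asarray(confusion)
    if M.size == 0:
        raise ValueError("empty confusion matrix")
    if np.any(M < 0) or not np.issubdtype(M.dtype, np.integer):
        raise ValueError("confusion matrix must hold non-negative integers")
    rows = M.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = 100.0 * np.diag(M) / rows
    per_class = np.round(np.where(rows > 0, per_class, np.nan), 2)
    overall = round(100.0 * np.trace(M) / M.sum(), 2)
    return per_class, overall


# ---------------------------------------------------------------------------
# task runner

@dataclass(frozen=True)
class TaskConfig:
    trim: tuple[float, float] | None = (700.0, 3450.0)
    wavelet: WaveletConfig | None = WaveletConfig()
    uve_params: dict = field(default_factory=dict)
    spa_params: dict = field(default_factory=dict)
    ga_config: GAPLSConfig = GAPLSConfig(n_runs=10)


@dataclass
class EvalReport:
    task: str
    origin: str | None
    variable_input: str
    classifier: str
    parameter: int | str
    class_labels: list
    per_class_acc: np.ndarray
    overall_acc: float
    confusion: np.ndarray
    selected_index: np.ndarray | None
    n_train: int
    n_test: int


def _one_hot_labels(labels) -> np.ndarray:
    classes = sorted(set(map(str, labels)))
    T = np.zeros((len(labels), len(classes)))
    for i, l in enumerate(labels):
        T[i, classes.index(str(l))] = 1.0
    return T


def _fit_selection(Xtr, labels_tr, variable_input: str, cfg: TaskConfig):
    if variable_input == "full":
        return None
    T = _one_hot_labels(labels_tr)
    if variable_input == "uve_spa":
        res = uve_spa(Xtr, T, uve_cfg=cfg.uve_params, spa_cfg=cfg.spa_params)
        return np.sort(res.selected_index)
    if variable_input == "ga_pls":
        res = ga_pls_select(Xtr, T, cfg.ga_config)
        return np.sort(res.selected_index)
    raise ValueError(f"unknown variable_input {variable_input!r}")


def run_task(ds: SpectralDataset, task: str, variable_input: str,
             spec: ClassifierSpec, partition: Partition,
             cfg: TaskConfig = TaskConfig(),
             origin: str | None = None) -> EvalReport:
    """One cell of the evaluation grid; selection is fitted on train only."""
    if task not in TASKS:
        raise ValueError(f"task must be one of {TASKS}")
    if variable_input not in VARIABLE_INPUTS:
        raise ValueError(f"variable_input must be one of {VARIABLE_INPUTS}")
    if spec.kind == "BPNN" and variable_input == "full":
        raise ValueError(
            "BPNN on the full spectral range is not supported; use a "
            "selected variable subset (uve_spa or ga_pls)")
    work = ds
    if cfg.trim is not None:
        work = trim_range(work, *cfg.trim)
    if cfg.wavelet is not None:
        work = denoise_dataset(work, cfg.wavelet)
    if task == "varieties_within":
        if origin is None:
            raise ValueError("varieties_within task needs an origin")
        work = work.subset(np.asarray(
            [str(o) == str(origin) for o in work.origin]))
        if len(set(map(str, work.variety))) < 2:
            raise ValueError(
                f"origin {origin!r} holds a single variety; nothing to classify")
        label_by = "variety"
    else:
        label_by = "origin" if task == "origins" else "variety"
    tr = work.select_ids(partition.train_index)
    te = work.select_ids(partition.test_index)
    sel = _fit_selection(tr.absorbance, tr.labels(label_by),
                         variable_input, cfg)
    Xtr = tr.absorbance if sel is None else tr.absorbance[:, sel]
    Xte = te.absorbance if sel is None else te.absorbance[:, sel]
    model = fit_classifier(Xtr, tr.labels(label_by), spec)
    pred = model.predict(Xte)
    M = confusion_matrix(te.labels(label_by), pred, model.class_labels)
    per_class, overall = accuracy(M)
    return EvalReport(task=task, origin=origin, variable_input=variable_input,
                      classifier=spec.kind, parameter=model.spec.parameter,
                      class_labels=model.class_labels,
                      per_class_acc=per_class, overall_acc=overall,
                      confusion=M, selected_index=sel,
                      n_train=tr.n_samples, n_test=te.n_samples)


# ---------------------------------------------------------------------------
# report assembly

_VI_ORDER = {"full": 0, "uve_spa": 1, "ga_pls": 2}


def build_report_tables(reports: list[EvalReport]) -> pd.DataFrame:
    """Flat table of all cells, sorted full -> UVE-SPA -> GA-PLS per task."""
    rows = []
    for r in reports:
        row = {"task": r.task, "origin": r.origin or "",
               "variable_input": r.variable_input,
               "classifier": r.classifier, "parameter": r.parameter}
        for c, a in zip(r.class_labels, r.per_class_acc):
            row[str(c)] = a
        row["overall"] = r.overall_acc
        rows.append(row)
    df = pd.DataFrame(rows)
    df["_vi"] = df["variable_input"].map(_VI_ORDER)
    df = df.sort_values(["task", "origin", "_vi", "classifier"],
                        kind="stable").drop(columns="_vi")
    return df.reset_index(drop=True)


def report_markdown(df: pd.DataFrame) -> str:
    lines = []
    for task, sub in df.groupby("task", sort=False):
        lines.append(f"## Task: {task}\n")
        sub = sub.dropna(axis=1, how="all")
        cols = list(sub.columns)
        lines.append("| " + " | ".join(cols) + " |")
        lines.append("|" + "|".join(["---"] * len(cols)) + "|")
        for _, row in sub.iterrows():
            lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
        lines.append("")
    return "\n".join(lines)
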