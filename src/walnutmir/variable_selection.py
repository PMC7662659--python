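"""Wavelength selection: UVE, SPA (chained as UVE-SPA), and GA-PLS.

Three strategies for picking informative wavenumbers out of a spectrum:

* **UVE** (uninformative variable elimination) appends artificial noise
  columns to X, collects the PLS regression coefficient of every column
  across leave-one-out folds, and scores each column by the stability
  ``c_j = mean(b_j) / std(b_j)``.  Real columns whose |stability| does not
  exceed the largest artificial-column |stability| carry no more
  information than noise and are discarded.

* **SPA** (successive projections algorithm) greedily grows a chain from
  each candidate start column, always adding the column with the largest
  projection onto the orthogonal complement of the current span — a
  minimum-collinearity subset.  Chains are scored by leave-one-out RMSE of
  a linear regression on the subset.

* **GA-PLS** runs a binary-chromosome genetic algorithm whose fitness is
  the cross-validated PLS error of the encoded subset, repeats it over
  several runs, ranks variables by a fitness-weighted selection frequency,
  and reads the final subset off the RMSECV-versus-subset-size trace
  (global minimum / one-standard-error / 2 % conventions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pls_core import _as_2d, _cv_press, _nipals, fit_pls, make_folds

__all__ = [
    "UVEResult", "SPAResult", "GAPLSConfig", "GAPLSResult", "SelectionResult",
    "uve_select", "spa_select", "uve_spa", "ga_pls_select", "selection_frame",
]


# ---------------------------------------------------------------------------
# UVE

@dataclass
class UVEResult:
    stability: np.ndarray        # over real + artificial columns
    cutoff_lo: float
    cutoff_hi: float
    retained_index: np.ndarray   # indices into the real columns
    n_artificial: int
    pls_factor: int


def uve_select(X: np.ndarray, Y: np.ndarray, pls_factor: int = 12,
               n_artificial: int | None = None, seed: int = 0,
               noise_scale: float | None = None) -> UVEResult:
    """Eliminate variables whose coefficient stability is within the noise band.

    ``n_artificial`` defaults to the number of real variables.  The noise
    amplitude defaults to 1e-2 of the mean |X| — stability is scale-free,
    the small amplitude only keeps the augmented matrix well conditioned.
    For a multi-column (one-hot) Y the stability of a variable is the
    signed value of largest magnitude across response columns.
    """
    X = np.asarray(X, dtype=float)
    Y = _as_2d(Y)
    n, p = X.shape
    if n_artificial is None:
        n_artificial = p
    rng = np.random.default_rng(seed)
    amp = noise_scale if noise_scale is not None \
        else 1e-2 * float(np.mean(np.abs(X)))
    Xa = np.hstack([X, rng.uniform(0.0, 1.0, size=(n, n_artificial)) * amp])
    A = min(pls_factor, n - 2, Xa.shape[1])
    folds = make_folds(n, "leave_one_out")
    q = Y.shape[1]
    B = np.empty((len(folds), p + n_artificial, q))
    for i, te in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[te] = False
        m = fit_pls(Xa[mask], Y[mask], A)
        B[i] = m.coefficients
    mean = B.mean(axis=0)
    std = B.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = mean / std
    c = np.where((std == 0) & (mean != 0), np.sign(mean) * np.inf, c)
    c = np.nan_to_num(c, nan=0.0, posinf=np.inf, neginf=-np.inf)
    # aggregate across response columns: keep the signed max-|.| entry
    pick = np.argmax(np.abs(c), axis=1)
    stab = c[np.arange(c.shape[0]), pick]
    cut = float(np.max(np.abs(stab[p:]))) if n_artificial else 0.0
    retained = np.nonzero(np.abs(stab[:p]) > cut)[0]
    return UVEResult(stability=stab, cutoff_lo=-cut, cutoff_hi=cut,
                     retained_index=retained, n_artificial=n_artificial,
                     pls_factor=A)


# ---------------------------------------------------------------------------
# SPA

@dataclass
class SPAResult:
    selected_index: np.ndarray
    rmse_by_k: np.ndarray        # validation RMSE for k = k_min..k_max (best start)
    k_range: tuple[int, int]
    start_policy: str = "all_columns"


def _chain(Xc: np.ndarray, start: int, k_max: int) -> list[int]:
    """SPA projection chain from one start column on centered data."""
    R = Xc.copy()
    sel = [start]
    norms0 = np.linalg.norm(Xc, axis=0)
    for _ in range(k_max - 1):
        v = R[:, sel[-1]]
        nv = np.linalg.norm(v)
        if nv < 1e-12 * max(norms0[sel[-1]], 1e-30):
            break  # rank-deficient span
        qv = v / nv
        R = R - np.outer(qv, qv @ R)
        norms = np.einsum("ij,ij->j", R, R)
        norms[sel] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] <= 1e-20:
            break
        sel.append(nxt)
    return sel


def _loo_rmse_prefixes(Z: np.ndarray, Y: np.ndarray,
                       ks: np.ndarray) -> np.ndarray:
    """LOO RMSE of linear regressions on leading-column prefixes of Z.

    Z includes an intercept as column 0; ``ks`` are subset sizes, i.e. a
    prefix uses columns 0..k.  Nested QR makes all prefixes one
    factorization.
    """
    Q, _ = np.linalg.qr(Z)
    C = Q.T @ Y
    h = np.zeros(Z.shape[0])
    yhat = np.zeros_like(Y, dtype=float)
    out = np.full(ks.size, np.inf)
    kmap = {k: i for i, k in enumerate(ks)}
    for j in range(Q.shape[1]):
        h = h + Q[:, j] ** 2
        yhat = yhat + np.outer(Q[:, j], C[j])
        k = j  # j columns of X + intercept -> subset size j
        if k in kmap:
            denom = 1.0 - h
            if np.any(denom < 1e-10):
                continue
            loo = (Y - yhat) / denom[:, None]
            out[kmap[k]] = np.sqrt(np.mean(loo ** 2))
    return out


def spa_select(X: np.ndarray, Y: np.ndarray, k_min: int = 5, k_max: int = 30,
               validation: str = "loo",
               candidate_index: np.ndarray | None = None) -> SPAResult:
    """Minimum-collinearity forward selection scored by LOO regression RMSE.

    Every candidate column seeds a chain; the returned subset is the
    (start, k) prefix with the smallest validation RMSE over
    ``k_min..k_max``.
    """
    if validation != "loo":
        raise ValueError("only 'loo' validation is implemented")
    X = np.asarray(X, dtype=float)
    Y = _as_2d(Y)
    n, p = X.shape
    cand = np.arange(p) if candidate_index is None \
        else np.asarray(candidate_index, dtype=int)
    k_max = min(k_max, n - 2, cand.size)
    if k_min > k_max:
        raise ValueError(f"k_min={k_min} exceeds feasible k_max={k_max}")
    Xs = X[:, cand]
    ks = np.arange(k_min, k_max + 1)
    best = (np.inf, None, None)  # rmse, chain prefix, rmse_by_k
    ones = np.ones((n, 1))
    for s in range(cand.size):
        chain = _chain(Xs, s, k_max)
        if len(chain) < k_min:
            continue
        Z = np.hstack([ones, Xs[:, chain]])
        ks_here = ks[ks <= len(chain)]
        rmse = _loo_rmse_prefixes(Z, Y, ks_here)
        i = int(np.argmin(rmse))
        if rmse[i] < best[0]:
            full = np.full(ks.size, np.inf)
            full[: rmse.size] = rmse
            best = (rmse[i], chain[: ks_here[i]], full)
    if best[1] is None:
        raise ValueError("SPA found no feasible subset (rank-deficient input)")
    return SPAResult(selected_index=cand[np.asarray(best[1])],
                     rmse_by_k=best[2], k_range=(k_min, k_max))


# ---------------------------------------------------------------------------
# UVE-SPA chain

@dataclass
class SelectionResult:
    method: str
    selected_index: np.ndarray
    uve: UVEResult | None = None
    spa: SPAResult | None = None
    ga: "GAPLSResult | None" = None


def uve_spa(X: np.ndarray, Y: np.ndarray, uve_cfg: dict | None = None,
            spa_cfg: dict | None = None) -> SelectionResult:
    """UVE screening followed by SPA on the retained pool."""
    uve_cfg = dict(uve_cfg or {})
    spa_cfg = dict(spa_cfg or {})
    u = uve_select(X, Y, **uve_cfg)
    k_min = spa_cfg.get("k_min", 5)
    if u.retained_index.size < k_min:
        raise ValueError(
            f"UVE retained only {u.retained_index.size} variables, fewer "
            f"than SPA's k_min={k_min}; widen the cutoff (e.g. fewer "
            f"artificial columns) or lower k_min")
    s = spa_select(X, Y, candidate_index=u.retained_index, **spa_cfg)
    return SelectionResult(method="uve_spa", selected_index=s.selected_index,
                           uve=u, spa=s)


# ---------------------------------------------------------------------------
# GA-PLS

@dataclass(frozen=True)
class GAPLSConfig:
    population: int = 30
    p_crossover: float = 0.5
    p_mutation: float = 0.01
    n_evaluations: int = 1000    # chromosome evaluations per run
    n_runs: int = 100
    fitness: str = "rmsecv"      # or "cv_variance"
    seed: int = 0
    a_max: int = 10
    folds: tuple = ("k_fold", 5)
    window_target: int = 500     # window-average to at most this many genes
    init_density: float = 0.05
    trace_len: int = 150

    def __post_init__(self) -> None:
        if not (0 <= self.p_crossover <= 1 and 0 <= self.p_mutation <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.population % 2:
            raise ValueError("population must be even")


@dataclass
class GAPLSResult:
    frequency: np.ndarray        # per original variable
    gene_frequency: np.ndarray   # per gene (window)
    gene_members: list           # gene -> original variable indices
    rmsecv_trace: np.ndarray     # adding genes in decreasing-frequency order
    model_marks: dict            # {"global": k, "better": k, "suggested": k}
    selected_index: np.ndarray   # original variables of the "better" model
    best_rmsecv: float
    best_subset: np.ndarray      # gene indices of the best chromosome seen


def _windows(p: int, target: int):
    """Adjacent window averaging down to <= target genes."""
    w = max(1, -(-p // target))
    members = [np.arange(i, min(i + w, p)) for i in range(0, p, w)]
    return members


def _fold_rmse(X, Y, a_max, folds):
    """Per-fold RMSE at the best component count (for the 1-SE rule)."""
    best_a = None
    press = _cv_press(X, Y, a_max, folds)
    best_a = int(np.argmin(press))
    out = []
    n_resp = Y.shape[1]
    for te in folds:
        press_f = _cv_press(X, Y, a_max, [te])
        out.append(np.sqrt(press_f[best_a] / (te.size * n_resp)))
    return np.asarray(out)


def ga_pls_select(X: np.ndarray, Y: np.ndarray,
                  cfg: GAPLSConfig = GAPLSConfig()) -> GAPLSResult:
    X = np.asarray(X, dtype=float)
    Y = _as_2d(Y)
    n, p = X.shape
    members = _windows(p, cfg.window_target)
    G = len(members)
    Xg = np.column_stack([X[:, m].mean(axis=1) for m in members])
    folds = make_folds(n, cfg.folds if cfg.folds[0] != "loo" else "loo")
    n_resp = Y.shape[1]
    min_train = min(n - f.size for f in folds)
    cache: dict[bytes, float] = {}

    def evaluate(chrom: np.ndarray) -> float:
        key = chrom.tobytes()
        if key in cache:
            return cache[key]
        cols = np.nonzero(chrom)[0]
        a = min(cfg.a_max, cols.size, min_train - 1)
        press = _cv_press(Xg[:, cols], Y, a, folds)
        if cfg.fitness == "rmsecv":
            val = float(np.sqrt(press.min() / (n * n_resp)))
        elif cfg.fitness == "cv_variance":
            val = float(press.min() / (n * n_resp))
        else:
            raise ValueError(f"unknown fitness {cfg.fitness!r}")
        cache[key] = val
        return val

    def repair(chrom: np.ndarray, rng) -> np.ndarray:
        if not chrom.any():
            chrom[rng.integers(G)] = True
        return chrom

    counts = np.zeros(G)
    weights_total = 0.0
    best_overall = (np.inf, None)
    for run in range(cfg.n_runs):
        rng = np.random.default_rng([cfg.seed, run])
        pop = [repair(rng.random(G) < cfg.init_density, rng)
               for _ in range(cfg.population)]
        fit = [evaluate(c) for c in pop]
        # evaluation budget: initial population + (population-1) per generation
        gens = max(0, (cfg.n_evaluations - cfg.population)
                   // (cfg.population - 1))
        for _ in range(gens):
            i_el = int(np.argmin(fit))
            new_pop = [pop[i_el].copy()]  # elitism 1
            new_fit = [fit[i_el]]
            while len(new_pop) < cfg.population:
                # tournament of 2, twice, for the two parents
                pick = rng.integers(cfg.population, size=4)
                pa = pop[pick[0]] if fit[pick[0]] <= fit[pick[1]] else pop[pick[1]]
                pb = pop[pick[2]] if fit[pick[2]] <= fit[pick[3]] else pop[pick[3]]
                c1, c2 = pa.copy(), pb.copy()
                if rng.random() < cfg.p_crossover:
                    mix = rng.random(G) < 0.5
                    c1[mix], c2[mix] = pb[mix], pa[mix]
                for c in (c1, c2):
                    flip = rng.random(G) < cfg.p_mutation
                    c[flip] = ~c[flip]
                    repair(c, rng)
                    if len(new_pop) < cfg.population:
                        new_pop.append(c)
                        new_fit.append(evaluate(c))
            pop, fit = new_pop, new_fit
        i_best = int(np.argmin(fit))
        if fit[i_best] < best_overall[0]:
            best_overall = (fit[i_best], pop[i_best].copy())
        w = 1.0 / max(fit[i_best], 1e-12)
        counts += w * np.sum(pop, axis=0)
        weights_total += w

    gene_freq = counts / weights_total
    # RMSECV trace: add genes in decreasing-frequency order
    order = np.lexsort((np.arange(G), -gene_freq))
    K = min(cfg.trace_len, G)
    trace = np.empty(K)
    for k in range(1, K + 1):
        chrom = np.zeros(G, dtype=bool)
        chrom[order[:k]] = True
        trace[k - 1] = evaluate(chrom)
    g_min = int(np.argmin(trace))
    # 1-SE band at the global minimum
    cols = order[: g_min + 1]
    fold_rmse = _fold_rmse(Xg[:, cols], Y,
                           min(cfg.a_max, cols.size, min_train - 1), folds)
    se = float(np.std(fold_rmse, ddof=1) / np.sqrt(len(folds))) \
        if len(folds) > 1 else 0.0
    suggested = int(np.nonzero(trace <= trace[g_min] + se)[0][0])
    better = int(np.nonzero(trace <= 1.02 * trace[g_min])[0][0])
    marks = {"global": g_min + 1, "better": better + 1,
             "suggested": suggested + 1}
    sel_genes = np.sort(order[: better + 1])
    sel_vars = np.sort(np.concatenate([members[g] for g in sel_genes]))
    freq = np.empty(p)
    for g, m in enumerate(members):
        freq[m] = gene_freq[g]
    return GAPLSResult(frequency=freq, gene_frequency=gene_freq,
                       gene_members=members, rmsecv_trace=trace,
                       model_marks=marks, selected_index=sel_vars,
                       best_rmsecv=float(best_overall[0]),
                       best_subset=np.nonzero(best_overall[1])[0])


# ---------------------------------------------------------------------------
# export

def selection_frame(result: SelectionResult | GAPLSResult,
                    wavenumbers: np.ndarray) -> pd.DataFrame:
    """Diagnostic table: wavenumber, score (stability or frequency), selected."""
    wavenumbers = np.asarray(wavenumbers)
    p = wavenumbers.size
    if isinstance(result, GAPLSResult):
        score = result.frequency
        sel = np.zeros(p, dtype=bool)
        sel[result.selected_index] = True
        name = "frequency"
    else:
        score = result.uve.stability[:p] if result.uve is not None \
            else np.full(p, np.nan)
        sel = np.zeros(p, dtype=bool)
        sel[result.selected_index] = True
        name = "stability"
    return pd.DataFrame({"wavenumber": wavenumbers, name: score,
                         "selected": sel})
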