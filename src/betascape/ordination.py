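"""Unconstrained and constrained ordination.

* :func:`pca` — principal components of a correlation (or covariance)
  matrix, used to summarize collinear climate variables.
* :func:`nmds` — non-metric multidimensional scaling of a dissimilarity
  matrix (Kruskal stress-1, monotone regression, best of many random
  starts), used to describe compositional variation.
* :func:`rda` — redundancy analysis: least-squares projection of a
  multivariate response on predictors followed by an eigen-analysis of the
  fitted values.
* :func:`db_rda` — distance-based RDA: principal coordinates of an
  arbitrary dissimilarity matrix (positive eigenvalues retained) used as
  the response of an ordinary RDA.
* :func:`permutation_pseudo_f` — permutation test of the pseudo-F
  statistic, with Freedman-Lane residual permutation when a conditioning
  matrix is present.
* :func:`forward_select` — greedy predictor selection under the double
  stopping rule: each added variable must pass the permutation test at
  alpha AND the cumulative adjusted R^2 may not exceed that of the
  full-candidate model.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.manifold import MDS

from .datasets import DissimilarityMatrix

log = logging.getLogger("betascape")

__all__ = [
    "OrdinationResult",
    "SelectionStep",
    "SelectionTrace",
    "pca",
    "nmds",
    "pcoa_axes",
    "rda",
    "db_rda",
    "permutation_pseudo_f",
    "adjusted_r2",
    "forward_select",
]


@dataclass(frozen=True)
class OrdinationResult:
    """Scores, eigenvalues and fit statistics of one ordination."""

    method: str
    scores: np.ndarray                      # plots x axes
    eigenvalues: np.ndarray = None          # descending
    proportion_explained: np.ndarray = None
    r2: float = None
    adj_r2: float = None
    predictor_scores: pd.DataFrame = None   # biplot arrows
    axis_f: np.ndarray = None
    axis_p: np.ndarray = None
    stress: float = None                    # NMDS only
    n_predictors: int = None

    @property
    def cumulative_proportion(self) -> np.ndarray:
        return np.cumsum(self.proportion_explained)


def _as_matrix(x) -> np.ndarray:
    m = np.asarray(x, dtype=float)
    if m.ndim == 1:
        m = m[:, None]
    return m


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=0, keepdims=True)


def _ss(x: np.ndarray) -> float:
    return float((x * x).sum())


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel adjustment: 1 - (1 - R^2)(n - 1)/(n - m - 1)."""
    if n - m - 1 <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


# ---------------------------------------------------------------------------
# PCA

def pca(table, use_correlation: bool = True) -> OrdinationResult:
    """Principal components of a plot x variable table.

    With ``use_correlation`` (the default) variables are standardized
    first, so scale differences between variables cannot dominate —
    appropriate for a table of heterogeneous climate summaries.
    """
    if isinstance(table, pd.DataFrame):
        names = list(table.columns)
        x = table.to_numpy(dtype=float)
    else:
        x = _as_matrix(table)
        names = [f"v{i+1}" for i in range(x.shape[1])]
    if x.shape[1] < 2:
        raise ValueError("PCA needs at least 2 variables")
    if not np.isfinite(x).all():
        raise ValueError("missing values in PCA input")
    xc = _center(x)
    sd = x.std(axis=0, ddof=1)
    if use_correlation:
        zero = [names[i] for i in np.flatnonzero(sd == 0)]
        if zero:
            raise ValueError(f"zero-variance columns with correlation "
                             f"matrix: {zero}")
        xc = xc / sd
    n = x.shape[0]
    cov = xc.T @ xc / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    for col in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, col]))
        if evecs[i, col] < 0:
            evecs[:, col] = -evecs[:, col]
    scores = xc @ evecs
    total = evals.sum()
    return OrdinationResult(
        method="pca", scores=scores, eigenvalues=evals,
        proportion_explained=evals / total if total > 0 else evals,
        predictor_scores=pd.DataFrame(evecs, index=names,
                                      columns=[f"PC{i+1}" for i in
                                               range(evecs.shape[1])]))


# ---------------------------------------------------------------------------
# NMDS

def nmds(dissimilarity: DissimilarityMatrix, k: int = 2,
         n_starts: int = 20, rng=None, tol: float = 1e-6,
         max_iter: int = 300) -> OrdinationResult:
    """Non-metric MDS: best-of-``n_starts`` minimization of Kruskal
    stress-1 with monotone (isotonic) regression.

    The returned configuration is centered and rotated to its principal
    axes; ``stress`` is the normalized stress-1 of the best start.
    """
    if k < 1 or n_starts < 1:
        raise ValueError("k and n_starts must be >= 1")
    d = dissimilarity.values
    if not d[np.triu_indices(d.shape[0], 1)].any():
        raise ValueError("all dissimilarities are zero; NMDS degenerate")
    seed = None
    if rng is not None:
        seed = int(np.random.default_rng(rng).integers(2 ** 31 - 1)) \
            if not isinstance(rng, (int, np.integer)) else int(rng)
    model = MDS(n_components=k, metric_mds=False, metric="precomputed",
                n_init=n_starts, max_iter=max_iter, eps=tol, init="random",
                random_state=seed, normalized_stress=True)
    scores = model.fit_transform(d)
    scores = _center(scores)
    # principal-axis rotation for a reproducible orientation
    u, s, vt = np.linalg.svd(scores, full_matrices=False)
    scores = scores @ vt.T
    for col in range(scores.shape[1]):
        i = np.argmax(np.abs(scores[:, col]))
        if scores[i, col] < 0:
            scores[:, col] = -scores[:, col]
    return OrdinationResult(method="nmds", scores=scores,
                            stress=float(model.stress_))


# ---------------------------------------------------------------------------
# RDA / db-RDA

def _check_full_rank(x: np.ndarray, what: str) -> None:
    if x.size == 0:
        return
    rank = np.linalg.matrix_rank(_center(x))
    if rank < x.shape[1]:
        # name a minimal dependent column set for the error message
        dep = []
        acc = np.empty((x.shape[0], 0))
        for j in range(x.shape[1]):
            cand = np.hstack([acc, _center(x[:, [j]])])
            if np.linalg.matrix_rank(cand) == cand.shape[1]:
                acc = cand
            else:
                dep.append(j)
        raise ValueError(f"{what} rank-deficient after centering; "
                         f"dependent columns (0-based): {dep}")


def rda(response, predictors, n_perm_axes: int = 0, rng=None,
        predictor_names=None) -> OrdinationResult:
    """Redundancy analysis of a multivariate response on predictors.

    The centered response is projected onto the column space of the
    centered predictors; the fitted values are eigen-analysed (SVD) to
    give constrained axes.  R^2 = SS(fitted)/SS(total); adjusted R^2 uses
    the Ezekiel correction with m = number of predictor columns.
    """
    y = _center(_as_matrix(response))
    if isinstance(predictors, pd.DataFrame):
        predictor_names = predictor_names or list(predictors.columns)
    x = _as_matrix(predictors)
    n, m = x.shape
    if y.shape[0] != n:
        raise ValueError("response/predictor row mismatch")
    if n <= m + 1:
        raise ValueError(f"need n > m + 1 (n={n}, m={m})")
    _check_full_rank(x, "predictors")
    xc = _center(x)
    beta, *_ = np.linalg.lstsq(xc, y, rcond=None)
    yfit = xc @ beta
    ss_tot = _ss(y)
    if ss_tot == 0:
        raise ValueError("response has no variance")
    ss_fit = _ss(yfit)
    r2 = ss_fit / ss_tot
    u, s, vt = np.linalg.svd(yfit, full_matrices=False)
    evals = s ** 2 / (n - 1)
    keep = evals > max(evals[0] if evals.size else 0.0, 1.0) * 1e-12
    evals = evals[keep]
    scores = (u[:, keep] * s[keep])
    for col in range(scores.shape[1]):
        i = np.argmax(np.abs(scores[:, col]))
        if scores[i, col] < 0:
            scores[:, col] = -scores[:, col]
    total_var = ss_tot / (n - 1)
    prop = evals / total_var
    pred_scores = None
    if scores.shape[1]:
        names = predictor_names or [f"x{i+1}" for i in range(m)]
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.array([
                [_safe_corr(xc[:, a], scores[:, b])
                 for b in range(scores.shape[1])]
                for a in range(m)])
        pred_scores = pd.DataFrame(
            corr, index=names,
            columns=[f"RDA{i+1}" for i in range(scores.shape[1])])
    axis_f = axis_p = None
    if n_perm_axes > 0 and scores.shape[1]:
        axis_f, axis_p = _axis_permutation_tests(y, xc, evals, n, m,
                                                 n_perm_axes, rng)
    return OrdinationResult(
        method="rda", scores=scores, eigenvalues=evals,
        proportion_explained=prop, r2=r2,
        adj_r2=adjusted_r2(r2, n, m), predictor_scores=pred_scores,
        axis_f=axis_f, axis_p=axis_p, n_predictors=m)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _axis_permutation_tests(y, xc, evals, n, m, n_perm, rng):
    """Marginal permutation test per constrained axis: the axis eigenvalue
    against its permutation distribution (rows of the response permuted)."""
    rng = np.random.default_rng(rng)
    resid = y - xc @ np.linalg.lstsq(xc, y, rcond=None)[0]
    ms_res = _ss(resid) / (n - m - 1)
    f_obs = evals * (n - 1) / ms_res
    count = np.ones_like(f_obs)
    for _ in range(n_perm):
        yp = y[rng.permutation(n)]
        beta = np.linalg.lstsq(xc, yp, rcond=None)[0]
        yfit = xc @ beta
        s = np.linalg.svd(yfit, compute_uv=False)
        ev = s ** 2 / (n - 1)
        ev = np.pad(ev, (0, max(0, len(evals) - len(ev))))[:len(evals)]
        msr = (_ss(yp) - _ss(yfit)) / (n - m - 1)
        count += (ev * (n - 1) / msr) >= f_obs
    return f_obs, count / (n_perm + 1)


def pcoa_axes(dissimilarity: DissimilarityMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate axes of a dissimilarity matrix.

    Returns ``(coordinates, eigenvalues)`` for the positive-eigenvalue
    axes only (coordinates scaled by sqrt(eigenvalue), the standard PCoA
    scaling); negative eigenvalues are discarded with a log message.
    """
    d = dissimilarity.values
    n = d.shape[0]
    a = -0.5 * d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    g = 0.5 * (g + g.T)
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-9 * max(abs(evals).max(), 1.0)
    pos = evals > tol
    n_neg = int((evals < -tol).sum())
    if n_neg:
        log.info("pcoa: discarded %d negative eigenvalue axes", n_neg)
    if not pos.any():
        raise ValueError("no positive eigenvalues in PCoA")
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    for col in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, col]))
        if coords[i, col] < 0:
            coords[:, col] = -coords[:, col]
    return coords, evals[pos]


def db_rda(dissimilarity: DissimilarityMatrix, predictors,
           n_perm_axes: int = 0, rng=None,
           predictor_names=None) -> OrdinationResult:
    """Distance-based RDA: RDA with the positive-eigenvalue principal
    coordinates of ``dissimilarity`` as the multivariate response."""
    coords, _ = pcoa_axes(dissimilarity)
    res = rda(coords, predictors, n_perm_axes=n_perm_axes, rng=rng,
              predictor_names=predictor_names)
    object.__setattr__(res, "method", "db_rda")
    return res


# ---------------------------------------------------------------------------
# Permutation pseudo-F

def permutation_pseudo_f(response, predictors, n_perm: int = 999, rng=None,
                         condition=None) -> tuple[float, float]:
    """Permutation test of the RDA pseudo-F.

    Without a condition the rows of the response are permuted freely.
    With a condition Z, the test is of the predictors given Z, using
    Freedman-Lane permutation: residuals of the reduced (Z-only) model are
    permuted and added back to the reduced fit.
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    rng = np.random.default_rng(rng)
    y = _center(_as_matrix(response))
    x = _center(_as_matrix(predictors))
    n, m = x.shape
    _check_full_rank(x, "predictors")
    if condition is None:
        f_obs = _pseudo_f(y, x)
        count = 1
        for _ in range(n_perm):
            if _pseudo_f(y[rng.permutation(n)], x) >= f_obs - 1e-12:
                count += 1
        return f_obs, count / (n_perm + 1)
    z = _center(_as_matrix(condition))
    _check_full_rank(z, "condition")
    mz = z.shape[1]
    fit_z = z @ np.linalg.lstsq(z, y, rcond=None)[0]
    resid_z = y - fit_z
    xz = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
    _check_full_rank(np.hstack([z, x]), "condition + predictors")
    f_obs = _partial_pseudo_f(resid_z, xz, n, m, mz)
    count = 1
    for _ in range(n_perm):
        ystar = fit_z + resid_z[rng.permutation(n)]
        rz = ystar - z @ np.linalg.lstsq(z, ystar, rcond=None)[0]
        if _partial_pseudo_f(rz, xz, n, m, mz) >= f_obs - 1e-12:
            count += 1
    return f_obs, count / (n_perm + 1)


def _pseudo_f(y: np.ndarray, x: np.ndarray) -> float:
    n, m = x.shape
    yfit = x @ np.linalg.lstsq(x, y, rcond=None)[0]
    ss_fit = _ss(yfit)
    ss_res = _ss(y) - ss_fit
    if ss_res <= 0:
        return np.inf
    return (ss_fit / m) / (ss_res / (n - m - 1))


def _partial_pseudo_f(y_res: np.ndarray, x_res: np.ndarray,
                      n: int, m: int, mz: int) -> float:
    yfit = x_res @ np.linalg.lstsq(x_res, y_res, rcond=None)[0]
    ss_fit = _ss(yfit)
    ss_res = _ss(y_res) - ss_fit
    df_res = n - m - mz - 1
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    if ss_res <= 0:
        return np.inf
    return (ss_fit / m) / (ss_res / df_res)


# ---------------------------------------------------------------------------
# Forward selection

@dataclass(frozen=True)
class SelectionStep:
    name: str
    pseudo_f: float
    p: float
    cum_adj_r2: float


@dataclass(frozen=True)
class SelectionTrace:
    """Ordered record of a forward-selection run."""

    steps: tuple
    global_adj_r2: float
    global_p: float = None
    stopped_by: str = None  # "alpha" | "adj_r2_cap" | "exhausted" | "global_gate"

    @property
    def selected(self) -> list:
        return [s.name for s in self.steps]


def forward_select(response, candidates: pd.DataFrame, alpha: float = 0.05,
                   n_perm: int = 999, rng=None,
                   global_gate: bool = True) -> SelectionTrace:
    """Greedy forward selection of predictor columns with the double
    stopping criterion.

    At each step the candidate maximizing added explained variance is
    tested by partial permutation pseudo-F (conditioning on the variables
    already selected).  Selection stops when the best candidate's p
    exceeds ``alpha`` or when the model's cumulative adjusted R^2 would
    exceed that of the all-candidates model.  With ``global_gate`` the
    all-candidates model is first tested at ``alpha`` and selection is
    abandoned if it fails (this keeps the overall type-I error near
    ``alpha`` with pure-noise candidates).
    """
    if not isinstance(candidates, pd.DataFrame):
        candidates = pd.DataFrame(
            _as_matrix(candidates),
            columns=[f"x{i+1}" for i in range(_as_matrix(candidates).shape[1])])
    rng = np.random.default_rng(rng)
    y = _center(_as_matrix(response))
    xall = candidates.to_numpy(dtype=float)
    n = y.shape[0]
    _check_full_rank(xall, "candidates")
    res_all = rda(y, xall)
    cap = res_all.adj_r2
    global_p = None
    if global_gate:
        _, global_p = permutation_pseudo_f(
            y, xall, n_perm=n_perm,
            rng=rng.integers(2 ** 31 - 1))
        if global_p > alpha:
            log.info("forward_select: global test p=%.4f > alpha, "
                     "no selection", global_p)
            return SelectionTrace(steps=(), global_adj_r2=cap,
                                  global_p=global_p, stopped_by="global_gate")
    remaining = list(candidates.columns)
    chosen: list = []
    steps = []
    stopped_by = "exhausted"
    while remaining:
        best_name, best_r2 = None, -np.inf
        for name in remaining:
            cols = chosen + [name]
            r2 = rda(y, candidates[cols].to_numpy(float)).r2
            if r2 > best_r2:
                best_name, best_r2 = name, r2
        cols = chosen + [best_name]
        adj = adjusted_r2(best_r2, n, len(cols))
        cond = candidates[chosen].to_numpy(float) if chosen else None
        f, p = permutation_pseudo_f(
            y, candidates[[best_name]].to_numpy(float),
            n_perm=n_perm, rng=rng.integers(2 ** 31 - 1), condition=cond)
        if p > alpha:
            stopped_by = "alpha"
            break
        if adj > cap + 1e-12:
            stopped_by = "adj_r2_cap"
            log.info("forward_select: %s would push adj R2 %.4f past the "
                     "all-variable cap %.4f", best_name, adj, cap)
            break
        steps.append(SelectionStep(name=best_name, pseudo_f=f, p=p,
                                   cum_adj_r2=adj))
        chosen.append(best_name)
        remaining.remove(best_name)
    return SelectionTrace(steps=tuple(steps), global_adj_r2=cap,
                          global_p=global_p, stopped_by=stopped_by)
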