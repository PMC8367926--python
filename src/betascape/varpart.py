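"""Variance partitioning of compositional variation among explanatory sets.

Explained variation (adjusted R^2 from RDA) of a multivariate response is
partitioned among 2-4 named predictor sets — typically climate, soils,
geomorphology and spatial eigenfunctions — into the unique fraction of
each set, the fractions shared by each subset of sets, and the residual.

Fractions are obtained by inclusion-exclusion over the adjusted R^2 of
every union of sets: writing R(S) for the adjusted R^2 of the model with
the union of the sets in S, the 2^k - 1 Venn "atoms" solve the linear
system  R(S) = sum of atoms intersecting S.  Atoms may be (slightly)
negative — adjusted R^2 is an estimator — and are reported as computed;
``clamped`` gives a non-negative presentation view.  Unique fractions are
testable by partial permutation pseudo-F (the set given all others,
Freedman-Lane).
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .ordination import (_as_matrix, _center, _check_full_rank, adjusted_r2,
                         permutation_pseudo_f, rda)
from .pcnm import PCNMBasis

__all__ = [
    "VariancePartition",
    "partial_rda",
    "partition_variation",
    "scale_stratified_partition",
]


@dataclass(frozen=True)
class VariancePartition:
    """Unique / shared / residual fractions of explained variation.

    ``fractions`` maps a frozenset of set names (the Venn atom: shared by
    exactly those sets) to its adjusted-R^2 fraction; ``residual`` is
    1 - adjusted R^2 of the joint model.  ``unique_p`` holds permutation
    p-values for the testable (unique) fractions.
    """

    set_names: tuple
    fractions: dict
    residual: float
    unique_p: dict = None
    subset_adj_r2: dict = None

    def unique(self, name: str) -> float:
        return self.fractions[frozenset([name])]

    def shared(self, *names) -> float:
        return self.fractions[frozenset(names)]

    @property
    def total_explained(self) -> float:
        return sum(self.fractions.values())

    def clamped(self) -> dict:
        """Non-negative presentation view (negative atoms shown as 0)."""
        return {k: max(v, 0.0) for k, v in self.fractions.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.fractions, key=lambda k: (len(k), sorted(k))):
            label = " & ".join(sorted(key)) if len(key) > 1 else next(iter(key))
            p = (self.unique_p or {}).get(key)
            rows.append({"fraction": label, "value": self.fractions[key],
                         "p": p})
        rows.append({"fraction": "residual", "value": self.residual,
                     "p": None})
        return pd.DataFrame(rows)


def partial_rda(response, predictors, condition, n_perm: int = 0, rng=None):
    """RDA of the response on predictors after removing the condition.

    Both the response and the predictors are residualized on the
    (centered) condition matrix.  The returned result's ``r2`` is the raw
    semi-partial R^2 (R^2 of condition + predictors minus R^2 of the
    condition alone) and ``adj_r2`` the same difference on adjusted R^2 —
    the conditioned set's contribution on the scale of the original
    response variance.  Scores and eigenvalues describe the residualized
    fit.
    """
    y = _center(_as_matrix(response))
    x = _center(_as_matrix(predictors))
    z = _center(_as_matrix(condition))
    _check_full_rank(z, "condition")
    overlap = _column_overlap(x, z)
    if overlap:
        raise ValueError(f"predictor columns duplicated in condition "
                         f"(0-based predictor indices): {overlap}")
    n = y.shape[0]
    zfit = np.linalg.lstsq(z, y, rcond=None)[0]
    yr = y - z @ zfit
    xr = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
    res = rda(yr, xr)
    full = rda(y, np.hstack([z, x]))
    only_z = rda(y, z)
    object.__setattr__(res, "method", "partial_rda")
    object.__setattr__(res, "r2", full.r2 - only_z.r2)
    object.__setattr__(res, "adj_r2", full.adj_r2 - only_z.adj_r2)
    if n_perm:
        _, p = permutation_pseudo_f(y, x, n_perm=n_perm, rng=rng,
                                    condition=z)
        object.__setattr__(res, "axis_p", np.array([p]))
    return res


def _column_overlap(x: np.ndarray, z: np.ndarray) -> list:
    out = []
    for j in range(x.shape[1]):
        col = x[:, j]
        if col.std() == 0:
            continue
        for k in range(z.shape[1]):
            zc = z[:, k]
            if zc.std() == 0:
                continue
            if abs(np.corrcoef(col, zc)[0, 1]) > 1 - 1e-12:
                out.append(j)
                break
    return out


def partition_variation(response, sets: dict, n_perm: int = 0,
                        rng=None) -> VariancePartition:
    """Partition explained variation among 2-4 named predictor sets.

    ``sets`` maps set name -> plot x variables matrix (array or
    DataFrame).  With ``n_perm`` > 0 each unique fraction is tested by a
    partial permutation pseudo-F of its set conditioned on all others.
    """
    names = tuple(sets)
    k = len(names)
    if not 2 <= k <= 4:
        raise ValueError("need between 2 and 4 predictor sets")
    mats = {nm: _as_matrix(sets[nm] if not isinstance(sets[nm], pd.DataFrame)
                           else sets[nm].to_numpy(float)) for nm in names}
    y = _center(_as_matrix(response))
    n = y.shape[0]
    total_m = sum(m.shape[1] for m in mats.values())
    if n <= total_m + 1:
        raise ValueError(f"joint model saturated: n={n} <= m+1={total_m + 1}")
    for nm, m in mats.items():
        _check_full_rank(m, f"set {nm!r}")
    # adjusted R^2 of every union of sets
    subsets = [frozenset(c) for r in range(1, k + 1)
               for c in combinations(names, r)]
    adj = {}
    for sub in subsets:
        x = np.hstack([mats[nm] for nm in names if nm in sub])
        adj[sub] = rda(y, x).adj_r2
    # solve R(S) = sum of atoms intersecting S
    atoms = subsets  # same index set
    a = np.zeros((len(subsets), len(atoms)))
    for i, s in enumerate(subsets):
        for j, t in enumerate(atoms):
            a[i, j] = 1.0 if s & t else 0.0
    vals = np.linalg.solve(a, np.array([adj[s] for s in subsets]))
    fractions = {atoms[j]: float(vals[j]) for j in range(len(atoms))}
    full = frozenset(names)
    residual = 1.0 - adj[full]
    unique_p = None
    if n_perm:
        rng = np.random.default_rng(rng)
        unique_p = {}
        for nm in names:
            others = np.hstack([mats[o] for o in names if o != nm])
            _, p = permutation_pseudo_f(
                y, mats[nm], n_perm=n_perm,
                rng=rng.integers(2 ** 31 - 1), condition=others)
            unique_p[frozenset([nm])] = p
    return VariancePartition(set_names=names, fractions=fractions,
                             residual=residual, unique_p=unique_p,
                             subset_adj_r2=adj)


def scale_stratified_partition(response, env_sets: dict, basis: PCNMBasis,
                               scale: str, n_perm: int = 0,
                               rng=None) -> VariancePartition:
    """Variance partition with the spatial set restricted to the
    eigenvectors of one scale class (``"broad"``, ``"mid"`` or
    ``"fine"``)."""
    space = basis.select(scale)
    if space.shape[1] == 0:
        raise ValueError(f"no eigenvectors in scale class {scale!r}")
    sets = dict(env_sets)
    sets["space"] = space
    return partition_variation(response, sets, n_perm=n_perm, rng=rng)
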