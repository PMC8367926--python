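"""Randomization null models and standardized effect sizes.

Two nulls are implemented, matching the inference they support:

* **richness-preserving random draws** — each plot keeps its observed
  species richness but its members are drawn uniformly without replacement
  from the regional pool (all species of the table, or all tips of the
  phylogeny for phylogenetic metrics).  Used to build null distributions of
  taxonomic and phylogenetic turnover.
* **tip shuffling** — species labels are permuted uniformly across the
  tips of the regional phylogeny, leaving topology, branch lengths and
  community membership untouched.  Used for beta NRI / beta NTI.

Standardized effect sizes are reported as SES = (obs - null mean)/null sd,
so that *positive* values mean the observed between-community phylogenetic
distances exceed the null (phylogenetic evenness) and *negative* values
mean closer-than-null relatives (phylogenetic clustering).  This is the
inverse of Webb's classical NRI/NTI orientation, which multiplies by -1.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import betadiv
from .datasets import CommunityTable, DissimilarityMatrix, Phylogeny

__all__ = [
    "NullEnsemble",
    "SESMatrix",
    "randomize_richness",
    "shuffle_tips",
    "null_turnover",
    "standardized_effect",
    "inter_mpd",
    "inter_mntd",
    "beta_nri",
    "beta_nti",
    "null_envelope",
]

SIGN_CONVENTION = "positive = evenness, negative = clustering"


@dataclass(frozen=True)
class NullEnsemble:
    """Per-pair null mean and SD of one metric over randomized draws."""

    metric_tag: str
    n_iterations: int
    mean: np.ndarray
    sd: np.ndarray
    seed: int | None = None
    draws: np.ndarray | None = None  # (n_iter, n, n) when stored
    low_precision: bool = False

    def __post_init__(self):
        if self.n_iterations < 2:
            raise ValueError("need at least 2 iterations")
        if (self.sd < 0).any():
            raise ValueError("negative null sd")

    @property
    def degenerate_pairs(self) -> np.ndarray:
        """Boolean mask of off-diagonal pairs with zero null variation."""
        mask = self.sd == 0
        np.fill_diagonal(mask, False)
        return mask


@dataclass(frozen=True)
class SESMatrix:
    """Plot x plot standardized effect sizes for one metric."""

    plot_ids: tuple
    values: np.ndarray  # NaN where the null sd is zero
    metric_tag: str
    observed: np.ndarray = None
    null_mean: np.ndarray = None
    null_sd: np.ndarray = None
    sign_convention: str = SIGN_CONVENTION

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.plot_ids), k=1)
        return self.values[iu]


def _as_generator(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# The two randomization schemes

def _random_incidence(richness: np.ndarray, pool_size: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Rows drawn uniformly without replacement, row sums fixed."""
    n = len(richness)
    inc = np.zeros((n, pool_size), dtype=bool)
    # argpartition of random keys = uniform subset without replacement
    keys = rng.random((n, pool_size))
    for i, k in enumerate(richness):
        inc[i, np.argpartition(keys[i], k - 1)[:k]] = True
    return inc


def randomize_richness(community: CommunityTable, rng) -> CommunityTable:
    """One richness-preserving draw from the regional pool.

    Every plot keeps its richness; its members are a uniform subset of all
    species in the table (equiprobable colonization).
    """
    rng = _as_generator(rng)
    rich = community.richness
    if rich.max() > community.n_species:
        raise ValueError("plot richness exceeds pool size")
    inc = _random_incidence(rich, community.n_species, rng)
    return CommunityTable(community.plot_ids, community.species_ids,
                          inc.astype(np.int8))


def shuffle_tips(phylogeny: Phylogeny, rng) -> Phylogeny:
    """Permute tip labels uniformly; topology and branch lengths fixed."""
    rng = _as_generator(rng)
    labels = list(phylogeny.tip_labels)
    perm = rng.permutation(len(labels))
    return phylogeny.relabel_tips(
        {labels[i]: labels[perm[i]] for i in range(len(labels))})


# ---------------------------------------------------------------------------
# Null distributions of turnover metrics

def null_turnover(community: CommunityTable, metric_tag: str, n_iter: int,
                  rng, phylogeny: Phylogeny | None = None,
                  store_draws: bool = False) -> NullEnsemble:
    """Per-pair null mean/SD of a beta-diversity metric under
    richness-preserving equiprobable draws.

    For taxonomic tags the pool is the species of the table; for
    ``phylosor*`` tags every tip of the regional phylogeny is an equally
    likely colonist, so the pool is the full tip set.
    """
    rng = _as_generator(rng)
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    low_precision = n_iter < 99
    rich = community.richness
    phylo = metric_tag.startswith("phylosor")
    if phylo:
        if phylogeny is None:
            raise ValueError(f"{metric_tag} requires a phylogeny")
        pool = phylogeny.tip_labels
        memb = betadiv.edge_membership(phylogeny, pool)
        wl = phylogeny.edge_lengths
    else:
        pool = community.species_ids
        memb = wl = None
    if rich.max() > len(pool):
        raise ValueError("plot richness exceeds pool size")
    n = community.n_plots
    acc = np.zeros((n, n))
    acc2 = np.zeros((n, n))
    draws = np.empty((n_iter, n, n)) if store_draws else None
    for it in range(n_iter):
        inc = _random_incidence(rich, len(pool), rng)
        vals = betadiv.pairwise_values(inc, metric_tag, memb, wl)
        acc += vals
        acc2 += vals * vals
        if store_draws:
            draws[it] = vals
    mean = acc / n_iter
    var = np.maximum(acc2 / n_iter - mean * mean, 0.0)
    sd = np.sqrt(var * n_iter / (n_iter - 1))
    return NullEnsemble(metric_tag=metric_tag, n_iterations=n_iter,
                        mean=mean, sd=sd, draws=draws,
                        low_precision=low_precision)


def standardized_effect(observed: DissimilarityMatrix,
                        ensemble: NullEnsemble) -> SESMatrix:
    """SES = (observed - null mean) / null sd; NaN where sd = 0."""
    with np.errstate(invalid="ignore", divide="ignore"):
        ses = (observed.values - ensemble.mean) / ensemble.sd
    ses = np.where(ensemble.sd > 0, ses, np.nan)
    np.fill_diagonal(ses, 0.0)
    return SESMatrix(plot_ids=observed.plot_ids, values=ses,
                     metric_tag=f"SES-{observed.metric_tag}",
                     observed=observed.values, null_mean=ensemble.mean,
                     null_sd=ensemble.sd)


def null_envelope(ensemble: NullEnsemble) -> tuple[np.ndarray, np.ndarray]:
    """95% envelope around the null expectation: mean -/+ 1.96 SD."""
    return ensemble.mean - 1.96 * ensemble.sd, ensemble.mean + 1.96 * ensemble.sd


# ---------------------------------------------------------------------------
# Between-community phylogenetic distances and beta NRI / beta NTI

def inter_mpd(tips_i, tips_j, dist: np.ndarray, tip_order=None) -> float:
    """Mean patristic distance over all cross pairs (x in i, y in j)."""
    ii, jj = _resolve(tips_i, tips_j, dist, tip_order)
    return float(dist[np.ix_(ii, jj)].mean())


def inter_mntd(tips_i, tips_j, dist: np.ndarray, tip_order=None) -> float:
    """Mean nearest-taxon distance between two communities.

    Symmetric average of the two directional means (for each taxon of one
    community, the distance to its nearest taxon in the other).  A taxon
    shared by both communities has nearest distance zero.
    """
    ii, jj = _resolve(tips_i, tips_j, dist, tip_order)
    sub = dist[np.ix_(ii, jj)]
    return float(0.5 * (sub.min(axis=1).mean() + sub.min(axis=0).mean()))


def _resolve(tips_i, tips_j, dist, tip_order):
    if tip_order is not None:
        lookup = {t: k for k, t in enumerate(tip_order)}
        ii = np.array([lookup[t] for t in tips_i], dtype=np.intp)
        jj = np.array([lookup[t] for t in tips_j], dtype=np.intp)
    else:
        ii = np.asarray(list(tips_i), dtype=np.intp)
        jj = np.asarray(list(tips_j), dtype=np.intp)
    if ii.size == 0 or jj.size == 0:
        raise ValueError("empty tip set")
    return ii, jj


def _all_pairs_mpd(pres: np.ndarray, dist: np.ndarray) -> np.ndarray:
    p = pres.astype(float)
    n = p.sum(axis=1)
    tot = p @ dist @ p.T
    out = tot / np.outer(n, n)
    np.fill_diagonal(out, 0.0)
    return out


def _all_pairs_mntd(pres: np.ndarray, dist: np.ndarray) -> np.ndarray:
    p = pres.astype(bool)
    n_plots = p.shape[0]
    rich = p.sum(axis=1).astype(float)
    # colmin[x, j] = distance from species x to its nearest member of plot j
    colmin = np.empty((dist.shape[0], n_plots))
    for j in range(n_plots):
        colmin[:, j] = dist[:, p[j]].min(axis=1)
    directed = (p.astype(float) @ colmin) / rich[:, None]  # i -> j
    out = 0.5 * (directed + directed.T)
    np.fill_diagonal(out, 0.0)
    return out


def _beta_ses(community: CommunityTable, phylogeny: Phylogeny, n_iter: int,
              rng, pairwise_fn, tag: str, store_draws: bool) -> SESMatrix:
    rng = _as_generator(rng)
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    dist = phylogeny.cophenetic()
    tips = phylogeny.tip_labels
    lookup = {t: k for k, t in enumerate(tips)}
    n_tips = len(tips)
    pres = np.zeros((community.n_plots, n_tips), dtype=bool)
    cols = np.array([lookup[s] for s in community.species_ids], dtype=np.intp)
    pres[:, cols] = community.incidence.astype(bool)
    obs = pairwise_fn(pres, dist)
    n = community.n_plots
    acc = np.zeros((n, n))
    acc2 = np.zeros((n, n))
    draws = np.empty((n_iter, n, n)) if store_draws else None
    for it in range(n_iter):
        # shuffling labels across tips == permuting the columns of `pres`
        perm = rng.permutation(n_tips)
        vals = pairwise_fn(pres[:, perm], dist)
        acc += vals
        acc2 += vals * vals
        if store_draws:
            draws[it] = vals
    mean = acc / n_iter
    var = np.maximum(acc2 / n_iter - mean * mean, 0.0)
    sd = np.sqrt(var * n_iter / (n_iter - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        ses = (obs - mean) / sd
    ses = np.where(sd > 0, ses, np.nan)
    np.fill_diagonal(ses, 0.0)
    return SESMatrix(plot_ids=community.plot_ids, values=ses, metric_tag=tag,
                     observed=obs, null_mean=mean, null_sd=sd)


def beta_nri(community: CommunityTable, phylogeny: Phylogeny,
             n_iter: int, rng, store_draws: bool = False) -> SESMatrix:
    """SES of between-community mean pairwise distance under tip shuffling.

    Sensitive to clustering/evenness at deep nodes of the phylogeny
    (basal phylogenetic beta diversity).  Positive = evenness.
    """
    return _beta_ses(community, phylogeny, n_iter, rng,
                     _all_pairs_mpd, "betaNRI", store_draws)


def beta_nti(community: CommunityTable, phylogeny: Phylogeny,
             n_iter: int, rng, store_draws: bool = False) -> SESMatrix:
    """SES of between-community mean nearest-taxon distance under tip
    shuffling (terminal phylogenetic beta diversity).  Positive = evenness.
    """
    return _beta_ses(community, phylogeny, n_iter, rng,
                     _all_pairs_mntd, "betaNTI", store_draws)
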