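"""Pairwise taxonomic and phylogenetic beta diversity with the
turnover / nestedness decomposition.

Taxonomic indices come from the incidence components of a plot pair
(a = shared species, b = species only in plot i, c = only in plot j):

* total dissimilarity (Sorensen):        (b + c) / (2a + b + c)
* turnover (Simpson-based replacement):  min(b, c) / (a + min(b, c))
* nestedness-resultant component:        total - turnover  (always >= 0)

The phylogenetic family substitutes shared / unique branch length for
shared / unique species counts, using Faith's PD (root-inclusive sum of
branch lengths spanning a tip set).  With PD_i, PD_j the plot PDs and
PD_tot the PD of the pooled pair,

    a_pd = PD_i + PD_j - PD_tot        (branch length shared by the pair)
    b_pd = PD_tot - PD_j               (unique to plot i)
    c_pd = PD_tot - PD_i               (unique to plot j)

and the PhyloSorensen total / turnover / nestedness mirror the taxonomic
formulas with (a_pd, b_pd, c_pd).  On a star tree with equal branch
lengths the phylogenetic indices collapse exactly to the taxonomic ones.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import CommunityTable, DissimilarityMatrix, Phylogeny

__all__ = [
    "PairComponents",
    "PhyloPairComponents",
    "pair_components",
    "sorensen_total",
    "sorensen_turnover",
    "sorensen_nestedness",
    "faith_pd",
    "phylo_pair_components",
    "phylosor_total",
    "phylosor_turnover",
    "phylosor_nestedness",
    "dissimilarity_matrix",
    "pairwise_values",
    "edge_membership",
    "multiple_site_sorensen_turnover",
    "METRIC_TAGS",
]


@dataclass(frozen=True)
class PairComponents:
    """Incidence components of one plot pair."""
    a: int  # shared
    b: int  # only in i
    c: int  # only in j

    def __post_init__(self):
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("components must be non-negative")


@dataclass(frozen=True)
class PhyloPairComponents:
    """Branch-length components of one plot pair."""
    pd_i: float
    pd_j: float
    pd_tot: float

    @property
    def a_pd(self) -> float:
        return self.pd_i + self.pd_j - self.pd_tot

    @property
    def b_pd(self) -> float:
        return self.pd_tot - self.pd_j

    @property
    def c_pd(self) -> float:
        return self.pd_tot - self.pd_i


def pair_components(community: CommunityTable, i, j) -> PairComponents:
    """Exact set components for plots ``i`` and ``j`` (ids or indices)."""
    i = i if isinstance(i, (int, np.integer)) else community.plot_index(i)
    j = j if isinstance(j, (int, np.integer)) else community.plot_index(j)
    ri = community.incidence[i].astype(bool)
    rj = community.incidence[j].astype(bool)
    a = int((ri & rj).sum())
    return PairComponents(a=a, b=int(ri.sum()) - a, c=int(rj.sum()) - a)


def _require_nonempty(pc: PairComponents) -> None:
    if pc.a + pc.b == 0 or pc.a + pc.c == 0:
        raise ValueError("dissimilarity undefined for an empty plot")


def sorensen_total(pc: PairComponents) -> float:
    _require_nonempty(pc)
    return (pc.b + pc.c) / (2 * pc.a + pc.b + pc.c)


def sorensen_turnover(pc: PairComponents) -> float:
    _require_nonempty(pc)
    m = min(pc.b, pc.c)
    if m == 0:
        return 0.0
    return m / (pc.a + m)


def sorensen_nestedness(pc: PairComponents) -> float:
    return sorensen_total(pc) - sorensen_turnover(pc)


# ---------------------------------------------------------------------------
# Phylogenetic family

def faith_pd(tip_set, phylogeny: Phylogeny) -> float:
    """Root-inclusive Faith's PD of ``tip_set``.

    Sum of lengths of every edge on the union of root-to-tip paths.
    Root-inclusive so that shared branch length a_pd is never negative and
    the pooled-pair identity PD_i + PD_j - PD_tot = a_pd holds.
    """
    tips = list(tip_set)
    if not tips:
        raise ValueError("faith_pd of an empty tip set")
    idx = phylogeny.tip_index(tips)
    on_path = phylogeny.edge_tip_matrix[:, idx].any(axis=1)
    return float(phylogeny.edge_lengths[on_path].sum())


def phylo_pair_components(community: CommunityTable, phylogeny: Phylogeny,
                          i, j) -> PhyloPairComponents:
    si = community.species_set(
        i if isinstance(i, (int, np.integer)) else community.plot_index(i))
    sj = community.species_set(
        j if isinstance(j, (int, np.integer)) else community.plot_index(j))
    return PhyloPairComponents(
        pd_i=faith_pd(si, phylogeny),
        pd_j=faith_pd(sj, phylogeny),
        pd_tot=faith_pd(si | sj, phylogeny),
    )


def _require_positive_pd(ppc: PhyloPairComponents) -> None:
    if ppc.pd_i <= 0 or ppc.pd_j <= 0:
        raise ValueError("dissimilarity undefined for a zero-PD plot")


def phylosor_total(ppc: PhyloPairComponents) -> float:
    """(2 PD_tot - PD_i - PD_j) / (PD_i + PD_j); equals
    (b_pd + c_pd) / (2 a_pd + b_pd + c_pd)."""
    _require_positive_pd(ppc)
    return (2.0 * ppc.pd_tot - ppc.pd_i - ppc.pd_j) / (ppc.pd_i + ppc.pd_j)


def phylosor_turnover(ppc: PhyloPairComponents) -> float:
    _require_positive_pd(ppc)
    m = min(ppc.b_pd, ppc.c_pd)
    if m <= 0.0:
        return 0.0
    return m / (ppc.a_pd + m)


def phylosor_nestedness(ppc: PhyloPairComponents) -> float:
    return phylosor_total(ppc) - phylosor_turnover(ppc)


# ---------------------------------------------------------------------------
# Matrix assembly (vectorized; per-pair functions above are the reference)

METRIC_TAGS = ("sorensen", "sorensen_turnover", "sorensen_nestedness",
               "phylosor", "phylosor_turnover", "phylosor_nestedness")

_PHYLO_TAGS = frozenset(t for t in METRIC_TAGS if t.startswith("phylosor"))


def _taxonomic_components(incidence: np.ndarray):
    inc = incidence.astype(float)
    a = inc @ inc.T
    s = inc.sum(axis=1)
    b = s[:, None] - a
    c = s[None, :] - a
    return a, b, c


def _phylo_components_raw(incidence: np.ndarray, edge_memb: np.ndarray,
                          edge_lengths: np.ndarray):
    pres = incidence.astype(bool)
    # plot x edge: does any present tip descend from the edge
    on = (pres @ edge_memb.T.astype(np.int64)) > 0
    pd_plot = on @ edge_lengths
    onf = on.astype(float)
    shared = (onf * edge_lengths[None, :]) @ onf.T  # shared branch length a_pd
    pd_tot = pd_plot[:, None] + pd_plot[None, :] - shared
    return pd_plot, pd_tot, shared


def edge_membership(phylogeny: Phylogeny, species_ids) -> np.ndarray:
    """Edge x species boolean matrix in ``species_ids`` column order."""
    idx = phylogeny.tip_index(species_ids)
    return phylogeny.edge_tip_matrix[:, idx]


def pairwise_values(incidence: np.ndarray, metric_tag: str,
                    edge_memb: np.ndarray | None = None,
                    edge_lengths: np.ndarray | None = None) -> np.ndarray:
    """Raw all-pairs dissimilarity values from a binary incidence array.

    Low-level path shared by :func:`dissimilarity_matrix` and the null
    models (which evaluate it on thousands of randomized incidences).
    For ``phylosor*`` tags pass ``edge_memb``/``edge_lengths``
    (see :func:`edge_membership`).
    """
    if metric_tag in _PHYLO_TAGS:
        if edge_memb is None or edge_lengths is None:
            raise ValueError(f"{metric_tag} requires edge membership data")
        pd_plot, pd_tot, a = _phylo_components_raw(
            incidence, edge_memb, edge_lengths)
        b = pd_tot - pd_plot[None, :]
        c = pd_tot - pd_plot[:, None]
    else:
        a, b, c = _taxonomic_components(incidence)
    with np.errstate(invalid="ignore", divide="ignore"):
        total = (b + c) / (2.0 * a + b + c)
        m = np.minimum(b, c)
        turn = np.where(m > 0, m / (a + m), 0.0)
    if metric_tag.endswith("_turnover"):
        vals = turn
    elif metric_tag.endswith("_nestedness"):
        vals = total - turn
    else:
        vals = total
    vals = np.asarray(vals, dtype=float)
    np.fill_diagonal(vals, 0.0)
    return 0.5 * (vals + vals.T)  # cancel last-bit asymmetry


def dissimilarity_matrix(community: CommunityTable, metric_tag: str,
                         phylogeny: Phylogeny | None = None
                         ) -> DissimilarityMatrix:
    """All-pairs dissimilarity for one metric tag.

    ``metric_tag`` is one of ``METRIC_TAGS``; the phylogeny is required for
    the ``phylosor*`` tags.
    """
    if metric_tag not in METRIC_TAGS:
        raise ValueError(f"unknown metric tag {metric_tag!r}; "
                         f"choose from {METRIC_TAGS}")
    if metric_tag in _PHYLO_TAGS:
        if phylogeny is None:
            raise ValueError(f"{metric_tag} requires a phylogeny")
        memb = edge_membership(phylogeny, community.species_ids)
        vals = pairwise_values(community.incidence, metric_tag,
                               memb, phylogeny.edge_lengths)
    else:
        vals = pairwise_values(community.incidence, metric_tag)
    return DissimilarityMatrix(community.plot_ids, vals, metric_tag)


def multiple_site_sorensen_turnover(community: CommunityTable) -> float:
    """Multiple-site turnover over the whole plot network, exactly as the
    single printed summary statistic:

        [sum min(b_ij, b_ji) + sum max(b_ij, b_ji)] /
        (2 [sum S_i - S_T] + sum min(b_ij, b_ji) + sum max(b_ij, b_ji))

    where the sums run over all unordered plot pairs, S_i is plot richness
    and S_T the pooled richness of the network.
    """
    _, b, c = _taxonomic_components(community.incidence)
    iu = np.triu_indices(community.n_plots, k=1)
    sum_min = np.minimum(b, c)[iu].sum()
    sum_max = np.maximum(b, c)[iu].sum()
    core = community.richness.sum() - community.pooled_richness
    return float((sum_min + sum_max) /
                 (2.0 * core + sum_min + sum_max))
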