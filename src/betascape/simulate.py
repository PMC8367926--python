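"""Synthetic metacommunities with known filtering and dispersal strengths.

The generator builds, from one seed, everything the inference chain
consumes — a birth-death regional phylogeny (with genus-style polytomies),
Brownian niche evolution along it, a landscape of spatially structured
environmental gradients, and plot communities assembled by Gaussian
environmental filtering plus an exponential dispersal kernel — together
with the ground truth (per-species niche optima and seed-source
locations) needed to verify that the analyses recover what was put in.

Assembly weight of species s in plot p:

    exp(-w * sum_axes (g_axis(p) - opt_{s,axis})^2) * exp(-dist(p, src_s)/delta)

where g_axis is the standardized latent gradient of the axis, w the
filter strength (0 = neutral), src_s the species' seed source and delta
the dispersal range in km (inf = unlimited).  Each plot draws its target
richness without replacement with these weights; at w = 0, delta = inf
this is exactly the richness-preserving equiprobable null.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd
from dendropy.model import birthdeath

from .datasets import (CommunityTable, Coordinates, EnvironmentTable,
                       Phylogeny, ValidatedDataset, validate_dataset)

__all__ = [
    "SimulationParams",
    "Landscape",
    "SyntheticDataset",
    "simulate_phylogeny",
    "evolve_niche_traits",
    "build_landscape",
    "assemble_communities",
    "generate_dataset",
]

# One degree is ~111 km; the emulated extent is ~2 deg x 1.5 deg.
_EXTENT_KM = (222.0, 167.0)


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the generator; defaults emulate a 41-plot / ~1,687-species
    western-Amazon plot network with correlated climate and soil gradients.
    """

    n_plots: int = 41
    n_species: int = 1687
    birth_rate: float = 1.0
    death_rate: float = 0.5
    polytomy_epsilon: float = 0.03   # collapse internal edges shorter than
                                     # this fraction of tree depth
    sigma2: dict = field(default_factory=lambda: {"climate": 1.0,
                                                  "soil": 1.0})
    extent_km: tuple = _EXTENT_KM
    # latent gradient wavelengths (km): climate varies across the whole
    # extent (the west-east regional gradient), soils at landscape scale,
    # geomorphology in between
    gradient_wavelengths: dict = field(default_factory=lambda: {
        "climate": (444.0,), "soil": (20.0,), "geomorphology": (80.0,)})
    n_variables: dict = field(default_factory=lambda: {
        "climate": 19, "soil": 9, "geomorphology": 4})
    between_class_correlation: float = 0.3  # climate-soil latent correlation
    noise_sd: float = 0.3                   # observed-variable white noise
    filter_strength: float = 1.0            # w
    dispersal_scale: float = 100.0          # delta, km; inf = none
    target_richness: int = 250
    grid: bool = False                      # place plots on a grid

    def __post_init__(self):
        if self.birth_rate <= self.death_rate or self.death_rate < 0:
            raise ValueError("need birth > death >= 0")
        if self.target_richness > self.n_species:
            raise ValueError("target richness exceeds species pool")
        if self.filter_strength < 0 or self.dispersal_scale <= 0:
            raise ValueError("need filter_strength >= 0, dispersal_scale > 0")


@dataclass(frozen=True)
class Landscape:
    coordinates: Coordinates
    environment: EnvironmentTable
    latent: pd.DataFrame  # plot x latent-gradient values (standardized)


@dataclass(frozen=True)
class SyntheticDataset:
    dataset: ValidatedDataset
    niche_optima: pd.DataFrame     # species x niche axes
    seed_sources: pd.DataFrame     # species x (x, y) km
    latent: pd.DataFrame
    params: SimulationParams
    seed: int


# ---------------------------------------------------------------------------
# Phylogeny

def simulate_phylogeny(n_species: int, birth: float, death: float, rng,
                       polytomy_epsilon: float = 0.0,
                       max_retries: int = 20) -> Phylogeny:
    """Birth-death tree conditioned on ``n_species`` extant tips.

    Branch lengths are in time units; the tree is ultrametric.  With
    ``polytomy_epsilon`` > 0, internal edges shorter than that fraction of
    the tree depth are collapsed into polytomies (children keep their
    root-to-tip depths), mimicking genus-level unresolved clades.
    """
    if birth <= death or death < 0:
        raise ValueError("need birth > death >= 0")
    pyrng = rng if isinstance(rng, random.Random) else random.Random(
        int(np.random.default_rng(rng).integers(2 ** 31 - 1)))
    tree = None
    for _ in range(max_retries):
        try:
            tree = birthdeath.birth_death_tree(
                birth_rate=birth, death_rate=death,
                num_extant_tips=n_species, rng=pyrng,
                repeat_until_success=False)
            break
        except Exception:
            continue
    if tree is None:
        raise RuntimeError("birth-death simulation failed repeatedly "
                           "(extinction rate too high?)")
    # drop the stem edge above the root: depths are measured from the crown
    tree.seed_node.edge.length = 0.0
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i + 1:04d}"
    if polytomy_epsilon > 0:
        depth = max(lf.distance_from_root() for lf in tree.leaf_node_iter())
        _collapse_short_edges(tree, polytomy_epsilon * depth)
    return Phylogeny(tree)


def _collapse_short_edges(tree: dendropy.Tree, eps: float) -> None:
    """Collapse internal edges shorter than eps, preserving tip depths."""
    changed = True
    while changed:
        changed = False
        for node in list(tree.preorder_node_iter()):
            if node is tree.seed_node or node.is_leaf():
                continue
            if node.edge.length is not None and node.edge.length < eps:
                parent = node.parent_node
                for ch in list(node.child_nodes()):
                    ch.edge.length = (ch.edge.length or 0.0) + node.edge.length
                    node.remove_child(ch)
                    parent.add_child(ch)
                parent.remove_child(node)
                changed = True


def normalize_depth(phylogeny: Phylogeny) -> Phylogeny:
    """Rescale branch lengths so the maximum root-to-tip depth is 1."""
    t = phylogeny.tree.clone(depth=1)
    depth = max(lf.distance_from_root() for lf in t.leaf_node_iter())
    for edge in t.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / depth
    return Phylogeny(t)


# ---------------------------------------------------------------------------
# Trait evolution

def evolve_niche_traits(phylogeny: Phylogeny, sigma2: dict, rng
                        ) -> pd.DataFrame:
    """Brownian-motion niche optima along the tree, one column per axis.

    The root starts at 0; each branch adds a Normal(0, sigma2 * length)
    increment.  ``sigma2 = 0`` gives perfect niche conservatism (all tips
    share the root optimum).
    """
    rng = np.random.default_rng(rng)
    axes = list(sigma2)
    vals: dict = {}
    tree = phylogeny.tree
    for axis in axes:
        s2 = float(sigma2[axis])
        if s2 < 0:
            raise ValueError("sigma2 must be >= 0")
        node_val = {tree.seed_node: 0.0}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            parent = node_val[node.parent_node]
            bl = node.edge.length or 0.0
            node_val[node] = parent + (
                rng.normal(0.0, np.sqrt(s2 * bl)) if s2 > 0 and bl > 0
                else 0.0)
        vals[axis] = {lf.taxon.label: node_val[lf]
                      for lf in tree.leaf_node_iter()}
    return pd.DataFrame(vals).loc[list(phylogeny.tip_labels)]


# ---------------------------------------------------------------------------
# Landscape

def _sinusoid_field(xy: np.ndarray, wavelengths, rng: np.random.Generator
                    ) -> np.ndarray:
    """Sum of sinusoids at given wavelengths.

    The first component runs along the x (long) axis of the landscape —
    the dominant west-east gradient — so its configured wavelength is the
    true along-gradient wavelength; further components get random
    orientations.
    """
    out = np.zeros(xy.shape[0])
    for k, wl in enumerate(wavelengths):
        theta = 0.0 if k == 0 else rng.uniform(0, 2 * np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        proj = xy[:, 0] * np.cos(theta) + xy[:, 1] * np.sin(theta)
        out += np.sin(2 * np.pi * proj / wl + phase)
    return out


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


def build_landscape(params: SimulationParams, rng) -> Landscape:
    """Plot coordinates plus spatially structured environmental variables.

    One latent gradient per variable class (smooth sinusoid field at the
    class's wavelengths, standardized across plots); climate and soil
    latents are blended to the configured between-class correlation.
    Observed variables load on their class latent with white noise.
    """
    rng = np.random.default_rng(rng)
    ex, ey = params.extent_km
    n = params.n_plots
    if params.grid:
        nx = int(np.ceil(np.sqrt(n * ex / ey)))
        ny = int(np.ceil(n / nx))
        gx, gy = np.meshgrid(np.linspace(0, ex, nx), np.linspace(0, ey, ny))
        xy = np.column_stack([gx.ravel(), gy.ravel()])[:n]
    else:
        xy = np.column_stack([rng.uniform(0, ex, n), rng.uniform(0, ey, n)])
    plot_ids = tuple(f"plot{i + 1:02d}" for i in range(n))
    latent = {}
    for cls, wls in params.gradient_wavelengths.items():
        latent[cls] = _standardize(_sinusoid_field(xy, wls, rng))
    rho = params.between_class_correlation
    if rho != 0:
        # blend the soil latent toward the climate latent
        latent["soil"] = _standardize(
            rho * latent["climate"] + np.sqrt(1 - rho ** 2) * latent["soil"])
    cols, classes = {}, {}
    for cls, n_vars in params.n_variables.items():
        for v in range(n_vars):
            loading = rng.uniform(0.5, 1.0) * rng.choice([-1.0, 1.0])
            raw = loading * latent[cls] + rng.normal(
                0, params.noise_sd, n)
            name = f"{cls[:4]}_{v + 1:02d}"
            # soil/climate tables are non-negative measurements; shift up
            cols[name] = raw - raw.min() + 0.1 if cls != "geomorphology" \
                else raw
            classes[name] = cls
    env = EnvironmentTable(plot_ids, pd.DataFrame(cols, index=list(plot_ids)),
                           classes)
    coords = Coordinates(plot_ids, xy[:, 0], xy[:, 1])
    return Landscape(coordinates=coords, environment=env,
                     latent=pd.DataFrame(latent, index=list(plot_ids)))


# ---------------------------------------------------------------------------
# Community assembly

def assemble_communities(phylogeny: Phylogeny, niche_optima: pd.DataFrame,
                         landscape: Landscape, params: SimulationParams,
                         rng, seed_sources: pd.DataFrame | None = None
                         ) -> tuple[CommunityTable, pd.DataFrame]:
    """Weighted sampling of plot communities; returns the table and the
    seed-source locations used (drawn here if not supplied)."""
    rng = np.random.default_rng(rng)
    species = list(phylogeny.tip_labels)
    if params.target_richness > len(species):
        raise ValueError("target richness exceeds species pool")
    if seed_sources is None:
        ex, ey = params.extent_km
        seed_sources = pd.DataFrame(
            {"x": rng.uniform(0, ex, len(species)),
             "y": rng.uniform(0, ey, len(species))}, index=species)
    xy = landscape.coordinates.xy
    n_plots = xy.shape[0]
    opt = niche_optima.loc[species]
    logw = np.zeros((n_plots, len(species)))
    w = params.filter_strength
    if w > 0:
        for axis in opt.columns:
            g = landscape.latent[axis].to_numpy()
            logw -= w * (g[:, None] - opt[axis].to_numpy()[None, :]) ** 2
    delta = params.dispersal_scale
    if np.isfinite(delta):
        src = seed_sources.loc[species, ["x", "y"]].to_numpy()
        dist = np.sqrt(((xy[:, None, :] - src[None, :, :]) ** 2).sum(-1))
        logw -= dist / delta
    inc = np.zeros((n_plots, len(species)), dtype=np.int8)
    k = params.target_richness
    # Gumbel top-k == weighted sampling without replacement
    gumbel = -np.log(-np.log(rng.random(logw.shape)))
    keys = logw + gumbel
    for p in range(n_plots):
        inc[p, np.argpartition(-keys[p], k - 1)[:k]] = 1
    table = CommunityTable(landscape.coordinates.plot_ids, tuple(species), inc)
    return table, seed_sources


def generate_dataset(params: SimulationParams | None = None,
                     seed: int = 0) -> SyntheticDataset:
    """Full generator pipeline; identical seed gives identical output.

    Tree depth is normalized to 1 before trait evolution so that sigma2 is
    the expected tip-trait variance and the latent gradients (sd 1) and
    niche optima share a scale, making the filter strength w directly
    interpretable.
    """
    params = params or SimulationParams()
    master = np.random.default_rng(seed)
    tree_seed, trait_seed, land_seed, comm_seed = master.integers(
        2 ** 31 - 1, size=4)
    phy = simulate_phylogeny(params.n_species, params.birth_rate,
                             params.death_rate, int(tree_seed),
                             polytomy_epsilon=params.polytomy_epsilon)
    phy = normalize_depth(phy)
    optima = evolve_niche_traits(phy, params.sigma2, int(trait_seed))
    land = build_landscape(params, int(land_seed))
    community, sources = assemble_communities(
        phy, optima, land, params, int(comm_seed))
    vd = validate_dataset(community, phy, land.environment,
                          land.coordinates, on_missing_tip="error")
    return SyntheticDataset(dataset=vd, niche_optima=optima,
                            seed_sources=sources, latent=land.latent,
                            params=params, seed=seed)
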