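"""Domain types, file readers/writers and cross-dataset validation.

The containers here carry a plot network through the whole inference chain:
a plot x species incidence table, a rooted phylogeny over the regional
species pool, plot-level environment tables (soil / climate / geomorphology)
and projected plot coordinates.  Everything downstream (beta diversity,
null models, ordination, variance partitioning) consumes these types.
"""
from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

log = logging.getLogger("betascape")

VARIABLE_CLASSES = ("soil", "climate", "geomorphology")

__all__ = [
    "CommunityTable",
    "Phylogeny",
    "EnvironmentTable",
    "Coordinates",
    "DissimilarityMatrix",
    "ValidatedDataset",
    "read_community_table",
    "write_community_table",
    "read_newick",
    "write_newick",
    "read_environment_table",
    "write_environment_table",
    "read_coordinates",
    "write_coordinates",
    "read_dissimilarity_matrix",
    "write_dissimilarity_matrix",
    "validate_dataset",
    "apply_transforms",
    "degrees_to_km",
]


class FormatError(ValueError):
    """Malformed input file (duplicates, bad header, unparseable cells)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a dataset invariant."""


def _check_unique(ids, what: str) -> None:
    seen, dups = set(), []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen.add(x)
    if dups:
        raise FormatError(f"duplicate {what}: {sorted(set(map(str, dups)))}")


# ---------------------------------------------------------------------------
# CommunityTable

@dataclass(frozen=True)
class CommunityTable:
    """Plot x species presence/absence matrix.

    All beta-diversity computation is incidence based: counts are collapsed
    to presence (1) / absence (0) at construction.  Row sums give S_i, the
    species richness of plot i; the number of non-empty columns gives S_T,
    the pooled richness of the plot network.
    """

    plot_ids: tuple
    species_ids: tuple
    incidence: np.ndarray  # (n_plots, n_species) int8 in {0, 1}

    def __post_init__(self):
        _check_unique(self.plot_ids, "plot ids")
        _check_unique(self.species_ids, "species ids")
        inc = np.asarray(self.incidence)
        if inc.shape != (len(self.plot_ids), len(self.species_ids)):
            raise ValidationError(
                f"incidence shape {inc.shape} does not match "
                f"{len(self.plot_ids)} plots x {len(self.species_ids)} species")
        if not np.isin(inc, (0, 1)).all():
            raise ValidationError("incidence entries must be 0 or 1")
        empty = np.flatnonzero(inc.sum(axis=1) == 0)
        if empty.size:
            names = [self.plot_ids[i] for i in empty]
            raise ValidationError(f"plots with no presences: {names}")
        object.__setattr__(self, "incidence",
                           np.ascontiguousarray(inc, dtype=np.int8))

    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def richness(self) -> np.ndarray:
        """S_i: per-plot species counts."""
        return self.incidence.sum(axis=1)

    @property
    def pooled_richness(self) -> int:
        """S_T: species present in at least one plot."""
        return int((self.incidence.sum(axis=0) > 0).sum())

    def plot_index(self, plot_id) -> int:
        try:
            return self.plot_ids.index(plot_id)
        except ValueError:
            raise KeyError(f"unknown plot id: {plot_id!r}") from None

    def species_set(self, i: int) -> set:
        """Species identifiers present in plot ``i`` (integer index)."""
        row = self.incidence[i]
        return {self.species_ids[j] for j in np.flatnonzero(row)}

    def select_species(self, keep: "list | np.ndarray") -> "CommunityTable":
        keep_idx = [i for i, s in enumerate(self.species_ids) if s in set(keep)]
        return CommunityTable(self.plot_ids,
                              tuple(self.species_ids[i] for i in keep_idx),
                              self.incidence[:, keep_idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.incidence, index=list(self.plot_ids),
                            columns=list(self.species_ids))


def read_community_table(path) -> CommunityTable:
    """Read a delimited plot x species table; counts > 0 become presences."""
    df = _read_table(path)
    _check_unique(df.index.tolist(), "plot ids")
    _check_unique(df.columns.tolist(), "species ids")
    vals = df.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise FormatError(f"{path}: non-numeric or missing cells")
    if (vals < 0).any():
        raise FormatError(f"{path}: negative counts")
    return CommunityTable(tuple(df.index), tuple(df.columns),
                          (vals > 0).astype(np.int8))


def write_community_table(table: CommunityTable, path) -> None:
    table.to_frame().to_csv(path, index_label="plot")


def _read_table(path) -> pd.DataFrame:
    """Comma-delimited by default; tabs accepted by sniffing the header."""
    with open(path, "r", encoding="utf-8") as fh:
        head = fh.readline()
        fh.seek(0)
        sep = "\t" if head.count("\t") > head.count(",") else ","
        # pandas silently renames duplicate header fields; check the raw line
        _check_unique([h.strip() for h in head.rstrip("\n").split(sep)[1:]],
                      "column ids")
        df = pd.read_csv(fh, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


# ---------------------------------------------------------------------------
# Phylogeny

@dataclass
class Phylogeny:
    """Rooted tree with branch lengths over the regional species pool.

    Wraps a :class:`dendropy.Tree` and exposes the array forms the metrics
    need: an edge x tip membership matrix (which tips descend from each
    edge) and the patristic (cophenetic) distance matrix.  Polytomies are
    allowed; branch lengths must be non-negative.
    """

    tree: dendropy.Tree
    _tip_labels: tuple = field(default=None, repr=False)
    _edge_lengths: np.ndarray = field(default=None, repr=False)
    _edge_tips: np.ndarray = field(default=None, repr=False)  # bool (n_edges, n_tips)
    _cophenetic: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        tips = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        _check_unique(tips, "tip labels")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                raise ValidationError(
                    f"edge above {_node_name(edge.head_node)} has no length")
            if edge.length < 0:
                raise ValidationError(
                    f"negative branch length above {_node_name(edge.head_node)}")
        self._tip_labels = tuple(tips)
        self._index_edges()

    def _index_edges(self) -> None:
        tips = self._tip_labels
        tip_idx = {t: i for i, t in enumerate(tips)}
        edges, lengths = [], []
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            edges.append(edge)
            lengths.append(float(edge.length))
        memb = np.zeros((len(edges), len(tips)), dtype=bool)
        # postorder accumulation of tip sets
        below: dict = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                below[node] = [tip_idx[node.taxon.label]]
            else:
                acc = []
                for ch in node.child_nodes():
                    acc.extend(below[ch])
                below[node] = acc
        for k, edge in enumerate(edges):
            memb[k, below[edge.head_node]] = True
        self._edge_lengths = np.asarray(lengths)
        self._edge_tips = memb

    # -- array views -------------------------------------------------------
    @property
    def tip_labels(self) -> tuple:
        return self._tip_labels

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    @property
    def n_internal(self) -> int:
        return sum(1 for n in self.tree.preorder_node_iter() if not n.is_leaf())

    @property
    def edge_lengths(self) -> np.ndarray:
        return self._edge_lengths

    @property
    def edge_tip_matrix(self) -> np.ndarray:
        """Boolean (n_edges, n_tips): tip j descends from edge k."""
        return self._edge_tips

    @property
    def total_branch_length(self) -> float:
        return float(self._edge_lengths.sum())

    def tip_index(self, labels) -> np.ndarray:
        lookup = {t: i for i, t in enumerate(self._tip_labels)}
        try:
            return np.array([lookup[x] for x in labels], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"unknown tip: {e.args[0]!r}") from None

    def cophenetic(self) -> np.ndarray:
        """Patristic tip-tip distance matrix, ordered as ``tip_labels``.

        d(x, y) = depth(x) + depth(y) - 2 * shared root path, computed from
        the edge membership matrix; cached after the first call.
        """
        if self._cophenetic is None:
            m = self._edge_tips.astype(float)
            wl = self._edge_lengths
            shared = (m * wl[:, None]).T @ m  # shared root-path length
            depth = m.T @ wl
            self._cophenetic = depth[:, None] + depth[None, :] - 2.0 * shared
            np.fill_diagonal(self._cophenetic, 0.0)
        return self._cophenetic

    def relabel_tips(self, mapping: dict) -> "Phylogeny":
        """Return a copy with tip labels replaced via ``mapping``."""
        t = self.tree.clone(depth=1)
        t.taxon_namespace = dendropy.TaxonNamespace()
        for lf in t.leaf_node_iter():
            lf.taxon = t.taxon_namespace.new_taxon(mapping[lf.taxon.label])
        return Phylogeny(t)

    def prune_to(self, keep) -> "Phylogeny":
        keep = set(keep)
        t = self.tree.clone(depth=1)
        taxa = [tx for tx in t.taxon_namespace if tx.label in keep]
        t.retain_taxa(taxa)
        return Phylogeny(t)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick",
                                   suppress_rooting=True).strip()


def _node_name(node) -> str:
    return node.taxon.label if node.taxon else f"<internal {id(node):#x}>"


def read_newick(path_or_string, default_branch_length: float | None = None) -> Phylogeny:
    """Parse a rooted newick tree with branch lengths.

    ``default_branch_length`` fills edges with no printed length (the root
    edge is always ignored); without it a missing length is an error.
    """
    src = str(path_or_string)
    try:
        if src.lstrip().startswith("("):
            tree = dendropy.Tree.get(data=src, schema="newick")
        else:
            tree = dendropy.Tree.get(path=src, schema="newick")
    except Exception as e:  # dendropy raises several parse error types
        raise FormatError(f"newick parse error: {e}") from None
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            edge.length = None
            continue
        if edge.length is None:
            if default_branch_length is None:
                raise ValidationError(
                    f"edge above {_node_name(edge.head_node)} has no branch "
                    "length (pass default_branch_length to fill)")
            edge.length = default_branch_length
    phy = Phylogeny(tree)
    log.info("read phylogeny: %d tips, %d internal nodes",
             phy.n_tips, phy.n_internal)
    return phy


def write_newick(phylogeny: Phylogeny, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(phylogeny.newick() + "\n")


# ---------------------------------------------------------------------------
# EnvironmentTable

@dataclass(frozen=True)
class EnvironmentTable:
    """Plot x variable matrix with a class label per column.

    Classes follow the field design: ``soil`` (pH, organic matter, texture
    fractions, P/Ca/Mg/K), ``climate`` (bioclim-style variables) and
    ``geomorphology`` (slope position, slope, elevation, land cover index).
    ``transform_applied`` records the per-column pre-analysis transform so
    it can never be applied twice.
    """

    plot_ids: tuple
    variables: pd.DataFrame  # index = plot ids
    variable_class: dict  # column -> class
    transform_applied: dict = None  # column -> {"none","sqrt","cubed"}

    def __post_init__(self):
        _check_unique(self.plot_ids, "plot ids")
        df = self.variables
        if tuple(df.index) != tuple(self.plot_ids):
            raise ValidationError("environment row index must equal plot_ids")
        missing = [c for c in df.columns if c not in self.variable_class]
        if missing:
            raise ValidationError(f"columns without a class label: {missing}")
        bad = {c: k for c, k in self.variable_class.items()
               if c in df.columns and k not in VARIABLE_CLASSES}
        if bad:
            raise ValidationError(f"unknown variable classes: {bad}")
        if not np.isfinite(df.to_numpy(dtype=float)).all():
            cols = df.columns[df.isna().any() |
                              ~np.isfinite(df.to_numpy(dtype=float)).all(axis=0)]
            raise ValidationError(f"missing/non-finite values in {list(cols)}")
        if self.transform_applied is None:
            object.__setattr__(self, "transform_applied",
                               {c: "none" for c in df.columns})

    def columns_of(self, var_class: str) -> list:
        return [c for c in self.variables.columns
                if self.variable_class[c] == var_class]

    def matrix_of(self, var_class: str) -> np.ndarray:
        return self.variables[self.columns_of(var_class)].to_numpy(dtype=float)

    def subset_plots(self, plot_ids) -> "EnvironmentTable":
        df = self.variables.loc[list(plot_ids)]
        return EnvironmentTable(tuple(plot_ids), df, dict(self.variable_class),
                                dict(self.transform_applied))


def read_environment_table(path, class_map_path) -> EnvironmentTable:
    """Read the environment CSV plus its sidecar column-class map (JSON/YAML)."""
    df = _read_table(path).astype(float)
    with open(class_map_path, "r", encoding="utf-8") as fh:
        text = fh.read()
    try:
        cmap = json.loads(text)
    except json.JSONDecodeError:
        import yaml
        cmap = yaml.safe_load(text)
    return EnvironmentTable(tuple(df.index), df, dict(cmap))


def write_environment_table(env: EnvironmentTable, path, class_map_path) -> None:
    env.variables.to_csv(path, index_label="plot",
                         float_format="%.12g")
    with open(class_map_path, "w", encoding="utf-8") as fh:
        json.dump(env.variable_class, fh, indent=1)


def apply_transforms(env: EnvironmentTable) -> EnvironmentTable:
    """Pre-analysis variable transforms.

    Soil and climate columns are square-root transformed (they are
    non-negative concentrations / bioclim summaries whose measurement scale
    is not the scale organisms respond to).  Each geomorphology column is
    z-standardized and augmented with the cube of the standardized value as
    an extra predictor column (a polynomial augmentation that lets a
    monotone-but-nonlinear response be picked up by linear ordination).
    """
    already = [c for c, t in env.transform_applied.items() if t != "none"]
    if already:
        raise ValidationError(f"transforms already applied to {already}")
    df = env.variables.copy()
    classes = dict(env.variable_class)
    applied = {}
    for col in env.variables.columns:
        cls = env.variable_class[col]
        if cls in ("soil", "climate"):
            neg = df.index[df[col] < 0]
            if len(neg):
                raise ValidationError(
                    f"negative value in {cls} variable {col!r} at plot "
                    f"{neg[0]!r}; square-root transform undefined")
            df[col] = np.sqrt(df[col].to_numpy(dtype=float))
            applied[col] = "sqrt"
        else:  # geomorphology
            x = df[col].to_numpy(dtype=float)
            sd = x.std(ddof=1) if len(x) > 1 else 0.0
            z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
            df[col] = z
            cubed = f"{col}^3"
            df[cubed] = z ** 3
            classes[cubed] = "geomorphology"
            applied[col] = "cubed"
            applied[cubed] = "cubed"
    return EnvironmentTable(env.plot_ids, df, classes, applied)


# ---------------------------------------------------------------------------
# Coordinates

@dataclass(frozen=True)
class Coordinates:
    """Projected planar plot coordinates in km."""

    plot_ids: tuple
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        _check_unique(self.plot_ids, "plot ids")
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != (len(self.plot_ids),) or y.shape != x.shape:
            raise ValidationError("x/y must be 1-D and match plot_ids")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValidationError("non-finite coordinates")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def subset_plots(self, plot_ids) -> "Coordinates":
        idx = [self.plot_ids.index(p) for p in plot_ids]
        return Coordinates(tuple(plot_ids), self.x[idx], self.y[idx])


def degrees_to_km(lon: np.ndarray, lat: np.ndarray) -> tuple:
    """Local equirectangular projection of decimal degrees to planar km.

    Adequate at the few-degree extents of a plot network; not a geodesic
    projection.
    """
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    lat0 = np.deg2rad(lat.mean())
    km_per_deg = 111.32
    log.info("converting degrees to km by equirectangular approximation "
             "about latitude %.3f", np.rad2deg(lat0))
    return (lon - lon.mean()) * km_per_deg * np.cos(lat0), \
           (lat - lat.mean()) * km_per_deg


def read_coordinates(path, degrees: bool = False) -> Coordinates:
    df = _read_table(path)
    cols = {c.lower(): c for c in df.columns}
    try:
        x = df[cols["x"]].to_numpy(float)
        y = df[cols["y"]].to_numpy(float)
    except KeyError:
        raise FormatError(f"{path}: need columns 'x' and 'y'") from None
    if degrees:
        x, y = degrees_to_km(x, y)
    return Coordinates(tuple(df.index), x, y)


def write_coordinates(coords: Coordinates, path) -> None:
    pd.DataFrame({"x": coords.x, "y": coords.y},
                 index=list(coords.plot_ids)).to_csv(
        path, index_label="plot", float_format="%.12g")


# ---------------------------------------------------------------------------
# DissimilarityMatrix

SORENSEN_FAMILY_TAGS = frozenset({
    "sorensen", "sorensen_turnover", "sorensen_nestedness",
    "phylosor", "phylosor_turnover", "phylosor_nestedness",
})


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric plot x plot matrix for one metric.

    Sorensen-family tags are bounded in [0, 1]; SES and distance tags are
    unbounded.
    """

    plot_ids: tuple
    values: np.ndarray
    metric_tag: str

    def __post_init__(self):
        _check_unique(self.plot_ids, "plot ids")
        v = np.asarray(self.values, dtype=float)
        n = len(self.plot_ids)
        if v.shape != (n, n):
            raise ValidationError(f"matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-12, equal_nan=True):
            raise ValidationError("matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValidationError("diagonal not zero")
        if self.metric_tag in SORENSEN_FAMILY_TAGS:
            finite = v[np.isfinite(v)]
            if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
                raise ValidationError(
                    f"{self.metric_tag} values outside [0, 1]")
        object.__setattr__(self, "values", v)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy's condensed order."""
        iu = np.triu_indices(len(self.plot_ids), k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.plot_ids),
                            columns=list(self.plot_ids))


def write_dissimilarity_matrix(dm: DissimilarityMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# metric_tag: {dm.metric_tag}\n")
        dm.to_frame().to_csv(fh, index_label="plot", float_format="%.12g")


def read_dissimilarity_matrix(path) -> DissimilarityMatrix:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        tag = "unknown"
        if first.startswith("#"):
            tag = first.split(":", 1)[1].strip()
        else:
            fh.seek(0)
        df = pd.read_csv(fh, index_col=0)
    df.index = df.index.astype(str)
    return DissimilarityMatrix(tuple(df.index), df.to_numpy(float), tag)


# ---------------------------------------------------------------------------
# ValidatedDataset

@dataclass(frozen=True)
class ValidatedDataset:
    """The four aligned components plus the count of species dropped
    because they were absent from the phylogeny."""

    community: CommunityTable
    phylogeny: Phylogeny
    environment: EnvironmentTable
    coordinates: Coordinates
    dropped_species: int = 0


def validate_dataset(community: CommunityTable,
                     phylogeny: Phylogeny,
                     environment: EnvironmentTable,
                     coordinates: Coordinates,
                     on_missing_tip: str = "drop") -> ValidatedDataset:
    """Align the four components on plot ids and reconcile the species pool.

    Species in the community absent from the phylogeny are dropped with a
    warning (``on_missing_tip="drop"``, the default, mirroring the routine
    exclusion of unplaced morphospecies) or raise (``"error"``).  Plot id
    sets must match exactly; ordering is normalized to the community's.
    """
    if on_missing_tip not in ("drop", "error"):
        raise ValueError("on_missing_tip must be 'drop' or 'error'")
    cset = set(community.plot_ids)
    for other, what in ((environment.plot_ids, "environment"),
                        (coordinates.plot_ids, "coordinates")):
        if set(other) != cset:
            diff = sorted(map(str, cset.symmetric_difference(other)))
            raise ValidationError(
                f"plot ids differ between community and {what}: {diff}")
    tips = set(phylogeny.tip_labels)
    missing = [s for s in community.species_ids if s not in tips]
    if missing:
        if on_missing_tip == "error":
            raise ValidationError(
                f"{len(missing)} community species not in the phylogeny: "
                f"{missing[:10]}{'...' if len(missing) > 10 else ''}")
        warnings.warn(f"dropping {len(missing)} species absent from the "
                      "phylogeny", stacklevel=2)
        community = community.select_species(
            [s for s in community.species_ids if s in tips])
    order = list(community.plot_ids)
    return ValidatedDataset(
        community=community,
        phylogeny=phylogeny,
        environment=environment.subset_plots(order),
        coordinates=coordinates.subset_plots(order),
        dropped_species=len(missing),
    )
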