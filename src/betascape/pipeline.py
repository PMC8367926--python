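"""Config-driven orchestration of the full inference chain.

``run_pipeline`` executes, in order: load or simulate the dataset ->
environment transforms -> dissimilarity matrices (Sorensen and
PhyloSorensen, total and turnover) -> NMDS -> climate PCA -> forward
selection of environment variables -> db-RDA with per-axis permutation
tests -> beta NRI / beta NTI with null envelopes -> PCNM construction and
scale classification -> scale-stratified variance partitioning.  Every
stage writes its tables under the output directory and the run ends with
a machine-readable manifest (config, seed, versions) sufficient to re-run
bit-identically.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, betadiv, nulls, ordination, pcnm, varpart
from .datasets import (DissimilarityMatrix, ValidatedDataset,
                       apply_transforms, read_community_table,
                       read_coordinates, read_environment_table, read_newick,
                       validate_dataset, write_dissimilarity_matrix)
from .simulate import SimulationParams, generate_dataset

log = logging.getLogger("betascape")

__all__ = ["PipelineConfig", "run_pipeline",
           "stage_simulate", "stage_betadiv", "stage_ses", "stage_pcnm",
           "stage_dbrda", "stage_varpart"]


@dataclass
class PipelineConfig:
    """Everything one run needs; the seed is mandatory.

    Either ``simulation`` (parameters for the synthetic generator) or the
    four input paths must be given.  The default counts mirror common
    practice for publication-grade inference (999 null iterations, 1000
    axis-test permutations, 9999 forward-selection permutations, 1000
    NMDS starts); the reduced test profile is available via
    :meth:`test_profile`.
    """

    seed: int
    output_dir: str = "betascape_out"
    # inputs: simulate...
    simulation: dict | None = None
    # ...or load
    community_path: str | None = None
    tree_path: str | None = None
    environment_path: str | None = None
    environment_classes_path: str | None = None
    coordinates_path: str | None = None
    # analysis choices
    metrics: tuple = ("sorensen", "sorensen_turnover",
                      "phylosor", "phylosor_turnover")
    null_iterations: int = 999
    axis_permutations: int = 1000
    selection_permutations: int = 9999
    alpha: float = 0.05
    nmds_starts: int = 1000
    nmds_dimensions: int = 2
    scale_boundaries: tuple = pcnm.DEFAULT_SCALE_BOUNDARIES

    @classmethod
    def test_profile(cls, seed: int, **kw) -> "PipelineConfig":
        kw.setdefault("null_iterations", 199)
        kw.setdefault("axis_permutations", 99)
        kw.setdefault("selection_permutations", 199)
        kw.setdefault("nmds_starts", 20)
        return cls(seed=seed, **kw)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml
            data = yaml.safe_load(text)
        if "seed" not in data:
            raise ValueError("config must set a seed")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["metrics"] = list(self.metrics)
        d["scale_boundaries"] = list(self.scale_boundaries)
        return d


def _load_or_simulate(config: PipelineConfig) -> ValidatedDataset:
    if config.simulation is not None:
        params = SimulationParams(**config.simulation)
        return generate_dataset(params, seed=config.seed).dataset
    paths = (config.community_path, config.tree_path,
             config.environment_path, config.environment_classes_path,
             config.coordinates_path)
    if any(p is None for p in paths):
        raise ValueError("config needs either 'simulation' or all five "
                         "input paths")
    for p in paths:
        if not Path(p).exists():
            raise FileNotFoundError(p)
    return validate_dataset(
        read_community_table(config.community_path),
        read_newick(config.tree_path),
        read_environment_table(config.environment_path,
                               config.environment_classes_path),
        read_coordinates(config.coordinates_path))


# --- stages ----------------------------------------------------------------

def stage_simulate(config: PipelineConfig) -> ValidatedDataset:
    return _load_or_simulate(config)


def stage_betadiv(ds: ValidatedDataset, metrics) -> dict:
    out = {}
    for tag in metrics:
        out[tag] = betadiv.dissimilarity_matrix(
            ds.community, tag,
            ds.phylogeny if tag.startswith("phylosor") else None)
    return out


def stage_ses(ds: ValidatedDataset, n_iter: int, rng) -> dict:
    rng = np.random.default_rng(rng)
    nri = nulls.beta_nri(ds.community, ds.phylogeny, n_iter,
                         rng.integers(2 ** 31 - 1))
    nti = nulls.beta_nti(ds.community, ds.phylogeny, n_iter,
                         rng.integers(2 ** 31 - 1))
    return {"betaNRI": nri, "betaNTI": nti}


def stage_pcnm(ds: ValidatedDataset, boundaries) -> pcnm.PCNMBasis:
    basis = pcnm.pcnm_basis(ds.coordinates)
    return pcnm.classify_scale(basis, boundaries,
                               coordinates=ds.coordinates)


def stage_dbrda(dm: DissimilarityMatrix, predictors: pd.DataFrame,
                n_perm: int, rng) -> ordination.OrdinationResult:
    if predictors.shape[1] == 0:
        raise ValueError("db-RDA needs at least one predictor")
    return ordination.db_rda(dm, predictors, n_perm_axes=n_perm, rng=rng)


def stage_varpart(response, env_sets: dict, basis: pcnm.PCNMBasis,
                  n_perm: int, rng) -> dict:
    rng = np.random.default_rng(rng)
    out = {}
    for scale in ("broad", "mid", "fine"):
        try:
            out[scale] = varpart.scale_stratified_partition(
                response, env_sets, basis, scale, n_perm=n_perm,
                rng=rng.integers(2 ** 31 - 1))
        except ValueError as e:
            log.warning("varpart skipped at %s scale: %s", scale, e)
    return out


# --- full run --------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the whole chain; returns the in-memory results and writes
    all tables plus a manifest under ``config.output_dir``."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    results: dict = {}
    t0 = time.time()

    def _log(stage):
        log.info("stage %-10s done at %6.1fs", stage, time.time() - t0)

    try:
        ds = stage_simulate(config)
        results["dataset"] = ds
        _log("load")

        env = apply_transforms(ds.environment)
        results["environment"] = env
        _log("transforms")

        dms = stage_betadiv(ds, config.metrics)
        results["dissimilarity"] = dms
        for tag, dm in dms.items():
            write_dissimilarity_matrix(dm, outdir / f"dissim_{tag}.csv")
        _log("betadiv")

        nmds_res = {}
        for tag in ("sorensen_turnover", "phylosor_turnover"):
            if tag in dms:
                nmds_res[tag] = ordination.nmds(
                    dms[tag], k=config.nmds_dimensions,
                    n_starts=config.nmds_starts,
                    rng=int(rng.integers(2 ** 31 - 1)))
                pd.DataFrame(nmds_res[tag].scores,
                             index=list(ds.community.plot_ids)).to_csv(
                    outdir / f"nmds_{tag}.csv")
        results["nmds"] = nmds_res
        _log("nmds")

        clim = env.variables[env.columns_of("climate")]
        clim_pca = ordination.pca(clim, use_correlation=True)
        results["climate_pca"] = clim_pca
        _log("pca")

        candidates = _candidate_table(env)
        sel = ordination.forward_select(
            _varpart_response(results, config), candidates,
            alpha=config.alpha, n_perm=config.selection_permutations,
            rng=int(rng.integers(2 ** 31 - 1)))
        results["forward_selection"] = sel
        pd.DataFrame([dataclasses.asdict(s) for s in sel.steps]).to_csv(
            outdir / "forward_selection.csv", index=False)
        _log("selection")

        predictors = (candidates[sel.selected] if sel.selected
                      else candidates)
        dbrda_res = {}
        for tag in ("sorensen_turnover", "phylosor_turnover"):
            if tag in dms:
                dbrda_res[tag] = stage_dbrda(
                    dms[tag], predictors, config.axis_permutations,
                    int(rng.integers(2 ** 31 - 1)))
        results["db_rda"] = dbrda_res
        _log("dbrda")

        ses = stage_ses(ds, config.null_iterations,
                        int(rng.integers(2 ** 31 - 1)))
        results["ses"] = ses
        for name, mat in ses.items():
            pd.DataFrame(mat.values,
                         index=list(mat.plot_ids),
                         columns=list(mat.plot_ids)).to_csv(
                outdir / f"ses_{name}.csv")
        _log("ses")

        basis = stage_pcnm(ds, config.scale_boundaries)
        results["pcnm"] = basis
        pd.DataFrame(basis.eigenvectors,
                     index=list(basis.plot_ids),
                     columns=[f"PCNM{i+1}" for i in range(basis.k)]).to_csv(
            outdir / "pcnm_eigenvectors.csv")
        pd.DataFrame({"eigenvalue": basis.eigenvalues,
                      "wavelength_km": basis.wavelengths,
                      "scale_class": list(basis.scale_class)}).to_csv(
            outdir / "pcnm_meta.csv", index=False)
        _log("pcnm")

        # one PCA axis per variable class keeps the joint model well away
        # from saturation on a plot network of tens of sites
        env_sets = {cls: _class_pc_scores(env, cls, 1)
                    for cls in ("climate", "soil", "geomorphology")
                    if env.columns_of(cls)}
        vp = stage_varpart(_varpart_response(results, config), env_sets,
                           basis, 0, int(rng.integers(2 ** 31 - 1)))
        results["varpart"] = vp
        for scale, part in vp.items():
            part.to_frame().to_csv(outdir / f"varpart_{scale}.csv",
                                   index=False)
        _log("varpart")
    except Exception as e:
        raise RuntimeError(
            f"pipeline failed (partial outputs in {outdir}): {e}") from e

    manifest = {
        "package": "betascape",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "numpy": np.__version__,
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    results["manifest"] = manifest
    return results


def _class_pc_scores(env, cls: str, k: int) -> np.ndarray:
    cols = env.variables[env.columns_of(cls)]
    if cols.shape[1] == 1:
        return cols.to_numpy(float)
    sd = cols.to_numpy(float).std(axis=0, ddof=1)
    res = ordination.pca(cols.loc[:, sd > 0], use_correlation=True)
    return res.scores[:, :k]


def _candidate_table(env) -> pd.DataFrame:
    """Forward-selection candidates: the raw variables when they fit in
    n - 2 columns at full rank, otherwise a few PCA axes per class."""
    df = env.variables
    n = df.shape[0]
    x = df.to_numpy(float)
    if df.shape[1] <= n - 2 and np.linalg.matrix_rank(
            x - x.mean(axis=0)) == df.shape[1]:
        return df
    quota = max(1, (n - 2) // 6)
    out = {}
    for cls in ("climate", "soil", "geomorphology"):
        if not env.columns_of(cls):
            continue
        scores = _class_pc_scores(env, cls, quota)
        for i in range(scores.shape[1]):
            out[f"{cls}_PC{i+1}"] = scores[:, i]
    log.info("forward-selection candidates reduced to %d per-class PCA "
             "axes (n=%d plots)", len(out), n)
    return pd.DataFrame(out, index=df.index)


def _varpart_response(results: dict, config: PipelineConfig) -> np.ndarray:
    """Compositional response: NMDS axes 1-2 of taxonomic turnover
    (PCoA axes would be the configurable alternative)."""
    tag = "sorensen_turnover"
    if results.get("nmds", {}).get(tag) is not None:
        return results["nmds"][tag].scores[:, :2]
    coords, _ = ordination.pcoa_axes(results["dissimilarity"][tag])
    return coords[:, :2]
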