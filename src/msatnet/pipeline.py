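"""End-to-end analysis pipeline.

Runs the full hierarchical analysis on a genotype dataset (read from a
GenePop file or freshly simulated): per-site diversity, AMOVA and
pairwise Fst with permutation significance, Fst upper bounds, Mantel
isolation-by-distance for linearised Fst and for the conditional genetic
distance, the individual-level threshold sweep, and the population graph
with spectral communities and random-walk betweenness.  All stochastic
stages derive their seeds deterministically from the single pipeline
seed, so a given (config, seed) pair reproduces its outputs byte for
byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotypes import SiteTable, allele_frequencies
from .genepop import read_genepop, read_site_table, write_genepop
from .simulate import (
    planted_communities_preset,
    simulate_hierarchical,
    simulate_stepping_stone,
    study_preset,
)
from .diversity import diversity_table
from .differentiation import (
    amova,
    combined_fst_p_table,
    fst_upper_bounds,
    geographic_distances,
    linearize_fst,
    mantel_test,
    pairwise_fst,
)
from .netstruct import similarity_matrix, threshold_sweep
from .popgraph import (
    conditional_genetic_distance,
    fit_population_graph,
    key_subpopulation_report,
    random_walk_betweenness,
    spectral_communities,
)

logger = logging.getLogger("msatnet.pipeline")

__all__ = ["PipelineConfig", "run_pipeline"]

_PRESETS = {
    "study": study_preset,
    "planted": planted_communities_preset,
}


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Either ``genotypes`` (GenePop path, with ``sites`` metadata CSV) or a
    simulation ``preset`` (``"study"`` or ``"planted"``, optionally with
    ``sim_overrides``) must be given.
    """

    out_dir: str = "msatnet_out"
    seed: int = 0
    genotypes: str | None = None
    sites: str | None = None
    preset: str | None = "study"
    sim_mode: str = "hierarchical"  # or "stepping_stone"
    sim_overrides: dict = field(default_factory=dict)
    rarefaction_g: int | None = None
    fst_estimator: str = "amova"
    n_permutations: int = 999
    fisher_mc: int = 100_000
    thresholds: list[float] | None = None
    alpha: float = 0.05
    similarity_weighting: str = "frequency"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_permutations < 1 or self.fisher_mc < 1:
            raise ValueError("permutation counts must be positive")
        if self.genotypes is None and self.preset not in _PRESETS:
            raise ValueError(
                f"no genotype file given and preset {self.preset!r} unknown "
                f"(choose from {sorted(_PRESETS)})"
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def _load_inputs(config: PipelineConfig, out: Path):
    """Return (table, site_table); simulate and persist when no file given."""
    if config.genotypes is not None:
        table = read_genepop(config.genotypes)
        site_table = read_site_table(config.sites) if config.sites else None
        return table, site_table
    sim_config = _PRESETS[config.preset](seed=config.seed, **config.sim_overrides)
    simulate = (
        simulate_hierarchical if config.sim_mode == "hierarchical" else simulate_stepping_stone
    )
    table, truth = simulate(sim_config)
    write_genepop(table, out / "simulated.gen")
    (out / "simulation_truth.json").write_text(truth.to_json())
    return table, sim_config.site_table()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle to ``out_dir``.

    Returns a manifest dict (also written as ``manifest.json``) listing
    the artifacts, per-stage seeds and timings.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage_seeds = {
        name: int(s)
        for name, s in zip(
            ["amova", "pairwise_fst", "mantel_fst", "mantel_cgd", "sweep"],
            rng.integers(2**31, size=5),
        )
    }
    manifest: dict = {
        "package": "msatnet",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "config": {k: v for k, v in asdict(config).items()},
        "artifacts": [],
        "timings_s": {},
        "results": {},
    }

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                fn()
            except Exception as exc:
                manifest["failed_stage"] = name
                (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            dt = time.perf_counter() - t0
            manifest["timings_s"][name] = round(dt, 3)
            logger.info("stage %s: done in %.2fs", name, dt)

        return deco

    state: dict = {}

    @stage("load")
    def _load():
        state["table"], state["sites"] = _load_inputs(config, out)
        state["table"].validate_multisite()

    @stage("diversity")
    def _diversity():
        summary = diversity_table(state["table"], g=config.rarefaction_g)
        summary.to_csv(out / "diversity.csv", sites=state["sites"])
        state["summary"] = summary
        manifest["artifacts"].append("diversity.csv")
        manifest["results"]["rarefaction_g"] = summary.g

    @stage("amova")
    def _amova():
        res = amova(
            state["table"], n_perm=config.n_permutations, seed=stage_seeds["amova"]
        )
        df = res.summary()
        df.loc["total"] = [res.df_among + res.df_within, res.ss_among + res.ss_within, np.nan]
        df.to_csv(out / "amova.csv", float_format="%.6g")
        with open(out / "amova.csv", "a") as fh:
            fh.write(f"# Fst,{res.fst:.6g}\n# p_value,{res.p_value:.6g}\n")
        state["amova"] = res
        manifest["artifacts"].append("amova.csv")
        manifest["results"]["overall_fst"] = res.fst
        manifest["results"]["amova_p"] = res.p_value

    @stage("pairwise_fst")
    def _pairwise():
        fst, pvals = pairwise_fst(
            state["table"],
            n_perm=config.n_permutations,
            seed=stage_seeds["pairwise_fst"],
            estimator=config.fst_estimator,
        )
        combined_fst_p_table(fst, pvals).to_csv(
            out / "pairwise_fst.csv", float_format="%.6g"
        )
        state["fst"] = fst
        manifest["artifacts"].append("pairwise_fst.csv")

    @stage("fst_bounds")
    def _bounds():
        freqs = allele_frequencies(state["table"])
        bounds = fst_upper_bounds(freqs, K=len(state["table"].sites))
        bounds.per_locus.to_csv(out / "fst_bounds.csv", index=False, float_format="%.6g")
        with open(out / "fst_bounds.csv", "a") as fh:
            fh.write(
                f"# mean_bound_M,{bounds.mean_bound_M:.6g}\n"
                f"# mean_bound_HT,{bounds.mean_bound_HT:.6g}\n"
            )
        state["bounds"] = bounds
        manifest["artifacts"].append("fst_bounds.csv")
        manifest["results"]["mean_bound_M"] = bounds.mean_bound_M
        manifest["results"]["mean_bound_HT"] = bounds.mean_bound_HT

    @stage("popgraph")
    def _popgraph():
        graph = fit_population_graph(state["table"], alpha=config.alpha)
        cgd = conditional_genetic_distance(graph)
        communities = spectral_communities(graph)
        rwb = random_walk_betweenness(graph)
        report = key_subpopulation_report(graph, rwb, state["summary"], communities)
        cgd.write_csv(out / "cgd_matrix.csv")
        report.to_csv(out / "key_subpopulations.csv", float_format="%.6g")
        graph.write_graphml(out / "popgraph.graphml", extra_node_attrs=report[["Ho", "AR", "RWB"]])
        state.update(graph=graph, cgd=cgd, communities=communities, rwb=rwb)
        manifest["artifacts"] += ["cgd_matrix.csv", "key_subpopulations.csv", "popgraph.graphml"]
        manifest["results"]["n_popgraph_edges"] = graph.n_edges
        manifest["results"]["n_communities"] = communities.n_communities
        manifest["results"]["modularity"] = communities.modularity

    @stage("mantel")
    def _mantel():
        if state["sites"] is None:
            logger.warning("no site coordinates: Mantel tests skipped")
            return
        order = state["table"].sites
        meta = state["sites"].data.set_index("site").loc[order].reset_index()
        geo = geographic_distances(SiteTable(meta))
        lin = linearize_fst(state["fst"])
        rows = []
        for name, mat, key in (
            ("linearized_fst", lin, "mantel_fst"),
            ("cgd", state["cgd"], "mantel_cgd"),
        ):
            res = mantel_test(
                mat, geo, n_perm=config.n_permutations, seed=stage_seeds[key]
            )
            rows.append((name, res.statistic, res.p_value, res.n_permutations))
            manifest["results"][f"mantel_r_{name}"] = res.statistic
            manifest["results"][f"mantel_p_{name}"] = res.p_value
        pd.DataFrame(rows, columns=["distance", "r", "p_value", "n_permutations"]).to_csv(
            out / "mantel.csv", index=False, float_format="%.6g"
        )
        manifest["artifacts"].append("mantel.csv")

    @stage("netstruct")
    def _netstruct():
        net = similarity_matrix(state["table"], weighting=config.similarity_weighting)
        sweep = threshold_sweep(
            net,
            thresholds=config.thresholds,
            n_mc=config.fisher_mc,
            seed=stage_seeds["sweep"],
            alpha=config.alpha,
        )
        sweep.table.to_csv(out / "netstruct_sweep.csv", index=False, float_format="%.6g")
        with open(out / "netstruct_sweep.csv", "a") as fh:
            fh.write(f"# all_thresholds_reject,{sweep.reject}\n")
        state["sweep"] = sweep
        manifest["artifacts"].append("netstruct_sweep.csv")
        manifest["results"]["netstruct_reject"] = sweep.reject

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    manifest["artifacts"].append("manifest.json")
    return manifest
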