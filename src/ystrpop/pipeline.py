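"""End-to-end analysis pipeline.

normalize → per-population diversity → Rst matrix with permutation
p-values and Bonferroni flagging → MDS coordinates → median-joining
network export → per-population TMRCA table, plus a JSON run manifest
(inputs, parameters, seed, version) and a plain-text log. Outputs are a
pure function of (input files, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .dating import date_population, write_age_report
from .diversity import diversity_summary, write_diversity_summary
from .distance import RstPermutation
from .exceptions import YstrError
from .io import (
    HaplotypeTable,
    read_haplotype_table,
    read_mutation_rates,
)
from .mds import ClassicalMDS
from .network import MedianJoiningNetwork, write_dot, write_graphml

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Settings for one pipeline run (YAML-compatible flat keys)."""

    haplotypes: str
    rates: str
    outdir: str
    permutations: int = 10_000
    seed: int | None = None
    generation_times: tuple[float, ...] = (25.0, 30.0)
    mds_dimensions: int = 2
    epsilon: int = 0
    alpha: float = 0.05
    bootstrap: int = 1000
    already_normalized: bool = False

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise YstrError(f"unknown pipeline config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.generation_times, (int, float)):
            cfg.generation_times = (float(cfg.generation_times),)
        else:
            cfg.generation_times = tuple(float(g) for g in cfg.generation_times)
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a manifest dict (also written to disk).

    Any stage failure aborts with the stage name; stages that are
    meaningless for the input (Rst/MDS with < 2 eligible populations)
    are skipped with a logged reason and flagged in the manifest.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root_logger = logging.getLogger("ystrpop")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)

    manifest: dict = {
        "version": __version__,
        "inputs": {"haplotypes": str(config.haplotypes), "rates": str(config.rates)},
        "parameters": {
            "permutations": config.permutations,
            "seed": config.seed,
            "generation_times": list(config.generation_times),
            "mds_dimensions": config.mds_dimensions,
            "epsilon": config.epsilon,
            "alpha": config.alpha,
            "bootstrap": config.bootstrap,
        },
        "stages": {},
        "outputs": {},
    }

    def stage(name):
        def wrap(fn):
            try:
                fn()
                manifest["stages"][name] = "ok"
            except YstrError as exc:
                manifest["stages"][name] = f"failed: {exc}"
                _write_manifest(outdir, manifest)
                raise YstrError(f"stage {name!r} failed: {exc}") from exc
            return fn

        return wrap

    state: dict = {}

    @stage("load")
    def _load():
        table = read_haplotype_table(config.haplotypes)
        if not config.already_normalized:
            table = table.normalize()
        else:
            table.normalized = True
        state["table"] = table
        state["rates"] = read_mutation_rates(config.rates)
        logger.info(
            "loaded %d records, %d loci, %d populations",
            len(table), len(table.panel), len(table.population_names),
        )

    @stage("diversity")
    def _diversity():
        frame = diversity_summary(state["table"])
        path = outdir / "diversity.tsv"
        write_diversity_summary(frame, path)
        manifest["outputs"]["diversity"] = path.name

    table: HaplotypeTable = state["table"]
    eligible = [
        p
        for p in table.population_names
        if len(table.for_population(p)) >= 2
    ]
    if len(eligible) >= 2:

        @stage("rst")
        def _rst():
            est = RstPermutation(
                n_permutations=config.permutations,
                alpha=config.alpha,
                random_state=config.seed,
            ).fit(table)
            est.distances_.to_csv(outdir / "rst_matrix.tsv", sep="\t")
            est.p_values_.to_csv(outdir / "rst_pvalues.tsv", sep="\t")
            est.significant_.to_csv(outdir / "rst_significant.tsv", sep="\t")
            manifest["outputs"]["rst"] = "rst_matrix.tsv"
            manifest["parameters"]["bonferroni_threshold"] = est.threshold_
            state["rst"] = est

        @stage("mds")
        def _mds():
            mds = ClassicalMDS(n_components=config.mds_dimensions).fit(
                state["rst"].distances_
            )
            mds.coordinates_frame().to_csv(outdir / "mds_coordinates.tsv", sep="\t")
            manifest["outputs"]["mds"] = "mds_coordinates.tsv"
            manifest["parameters"]["mds_stress"] = mds.stress_
            manifest["parameters"]["mds_r_squared"] = mds.r_squared_

    else:
        reason = "fewer than 2 populations with n >= 2; Rst/MDS skipped"
        logger.info(reason)
        manifest["stages"]["rst"] = manifest["stages"]["mds"] = f"skipped: {reason}"

    @stage("network")
    def _network():
        net = MedianJoiningNetwork(epsilon=config.epsilon).fit(table)
        write_graphml(net.graph_, outdir / "network.graphml")
        write_dot(net.graph_, outdir / "network.dot")
        manifest["outputs"]["network"] = "network.graphml"
        manifest["parameters"]["n_median_vectors"] = net.n_median_vectors_

    @stage("tmrca")
    def _tmrca():
        report = date_population(
            table,
            state["rates"],
            generation_times=config.generation_times,
            n_bootstrap=config.bootstrap,
            random_state=config.seed,
        )
        write_age_report(report, outdir / "tmrca.tsv")
        manifest["outputs"]["tmrca"] = "tmrca.tsv"

    _write_manifest(outdir, manifest)
    root_logger.removeHandler(handler)
    handler.close()
    return manifest


def _write_manifest(outdir: Path, manifest: dict) -> None:
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


__all__ = ["PipelineConfig", "run_pipeline"]
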