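"""End-to-end orchestration: simulate/load → diff → PAGE → signature → concordance.

A run takes a single config (YAML or dict), executes the stages in order,
writes every intermediate under the output directory, and records a
manifest with the package version, seed, parameters, and SHA-256 checksums
of all inputs and outputs. Reruns with the same config and seed produce
byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__ as _version
from . import io as cio
from .concordance import (
    model_bootstrap,
    model_permutation,
    overlap_correlation,
    pair_bootstrap,
    permutation_test,
)
from .errors import ConfigError, CRSigError, StageError
from .gsets import GeneSetCollection
from .page import page_matrix
from .probes import differential_stats, gene_consensus
from .signature import consensus_signature, median_z
from .simulate import SimulationConfig, simulate_collection, simulate_studies

log = logging.getLogger("crsig")

_SCHEMES = {
    "perm": "permutation",
    "pairboot": "pair_bootstrap",
    "modelperm": "model_permutation",
    "modelboot": "model_bootstrap",
}


@dataclass
class PipelineConfig:
    """All stage parameters plus input locations for one run."""

    seed: int = 0
    simulate: SimulationConfig | None = None
    study_paths: list[str] = field(default_factory=list)
    gmt_path: str | None = None
    term_meta_path: str | None = None
    # PAGE filters
    min_size: int = 10
    max_size: int = 1000
    depth_min: int = 3
    depth_max: int = 5
    # signature filters
    p_adj_max: float = 0.00285
    z_median_min: float = 2.58
    min_studies: int = 2
    # gene-level consensus
    gene_p_max: float = 0.05
    gene_min_studies: int | None = None
    # concordance (optional; run when both groups named)
    group_a: list[str] = field(default_factory=list)
    group_b: list[str] = field(default_factory=list)
    schemes: list[str] = field(default_factory=lambda: ["perm", "pairboot", "modelperm", "modelboot"])
    n_resamples: int = 999
    ci_level: float = 0.95
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.p_adj_max <= 1):
            raise ConfigError("p_adj_max must lie in (0, 1]")
        if self.z_median_min < 0:
            raise ConfigError("z_median_min must be >= 0")
        if self.min_size < 1 or self.max_size < self.min_size:
            raise ConfigError("need 1 <= min_size <= max_size")
        if self.depth_max < self.depth_min:
            raise ConfigError("depth range is empty")
        if not (0 < self.gene_p_max <= 1):
            raise ConfigError("gene_p_max must lie in (0, 1]")
        if not (0 < self.ci_level < 1):
            raise ConfigError("ci_level must lie in (0, 1)")
        unknown = [s for s in self.schemes if s not in _SCHEMES]
        if unknown:
            raise ConfigError(f"unknown concordance schemes {unknown}; choose from {list(_SCHEMES)}")
        if self.simulate is None and not self.study_paths:
            raise ConfigError("either a simulate block or study_paths is required")
        if self.simulate is None and self.gmt_path is None:
            raise ConfigError("gmt_path is required when studies are read from disk")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(simulate=sim, **raw)
        if sim is not None:
            # single global seed fans out to every stage
            cfg.simulate = dataclasses.replace(sim, seed=cfg.seed)
        return cfg

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
            d["simulate"]["set_size_range"] = list(self.simulate.set_size_range)
        return d


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages, write intermediates, return the manifest dict."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "crsig",
        "version": _version,
        "seed": config.seed,
        "parameters": config.to_jsonable(),
        "inputs": {},
        "outputs": {},
        "stages": [],
    }

    def record_output(name: str, rel: str) -> None:
        manifest["outputs"][name] = {"path": rel, "sha256": cio.sha256_file(outdir / rel)}

    def stage(name: str):
        manifest["stages"].append(name)
        log.info("stage: %s", name)

    try:
        # ---------------------------------------------------------- inputs
        if config.simulate is not None:
            stage("simulate")
            collection = simulate_collection(config.simulate)
            studies, truth = simulate_studies(collection, config.simulate)
            (outdir / "studies").mkdir(exist_ok=True)
            for s in studies:
                rel = f"studies/{s.study_id}.tsv"
                cio.write_study(s, outdir / rel)
                record_output(f"study:{s.study_id}", rel)
            cio.write_gmt(collection, outdir / "collection.gmt")
            cio.write_term_meta(collection, outdir / "terms.tsv")
            cio.write_truth(truth, outdir / "truth.json")
            record_output("collection", "collection.gmt")
            record_output("term_meta", "terms.tsv")
            record_output("truth", "truth.json")
        else:
            stage("load")
            studies = [cio.read_study(p) for p in config.study_paths]
            collection = cio.read_gmt(config.gmt_path)
            meta = cio.read_term_meta(config.term_meta_path)
            collection = cio.attach_depth(collection, meta)
            for p in list(config.study_paths) + [config.gmt_path, config.term_meta_path]:
                manifest["inputs"][Path(p).name] = cio.sha256_file(p)
    except CRSigError as exc:
        raise StageError(manifest["stages"][-1] if manifest["stages"] else "input", str(exc)) from exc

    def guarded(name: str, fn):
        stage(name)
        try:
            return fn()
        except CRSigError as exc:
            # retain partial outputs already written, then abort with the stage name
            cio.write_json(manifest, outdir / "manifest.partial.json")
            raise StageError(name, str(exc)) from exc

    diffs = guarded("diff", lambda: [differential_stats(s) for s in studies])
    (outdir / "diff").mkdir(exist_ok=True)
    for d in diffs:
        rel = f"diff/{d.study_id}.tsv"
        cio.write_differential(d, outdir / rel)
        record_output(f"diff:{d.study_id}", rel)

    zmat = guarded(
        "page",
        lambda: page_matrix(
            diffs, collection,
            min_size=config.min_size, max_size=config.max_size,
            depth_range=(config.depth_min, config.depth_max),
        ),
    )
    cio.write_zmatrix(zmat, outdir / "zmatrix.tsv")
    record_output("zmatrix", "zmatrix.tsv")

    sig = guarded(
        "signature",
        lambda: consensus_signature(
            zmat, p_adj_max=config.p_adj_max, z_median_min=config.z_median_min,
            min_studies=config.min_studies,
        ),
    )
    cio.write_table(sig, outdir / "signature.tsv")
    record_output("signature", "signature.tsv")

    genes = guarded(
        "gene-consensus",
        lambda: gene_consensus(diffs, p_max=config.gene_p_max, min_studies=config.gene_min_studies),
    )
    cio.write_table(genes, outdir / "gene_consensus.tsv")
    record_output("gene_consensus", "gene_consensus.tsv")

    if config.group_a and config.group_b:
        med_a = guarded("median-z", lambda: median_z(zmat, config.group_a))
        med_b = median_z(zmat, config.group_b)
        cio.write_series(med_a.rename("median_z_a"), outdir / "median_a.tsv")
        cio.write_series(med_b.rename("median_z_b"), outdir / "median_b.tsv")
        record_output("median_a", "median_a.tsv")
        record_output("median_b", "median_b.tsv")

        def run_concordance():
            results = {}
            common = med_a.dropna().index.intersection(med_b.dropna().index)
            corr = overlap_correlation(collection, list(common))
            n, lv, sd = config.n_resamples, config.ci_level, config.seed
            for key in config.schemes:
                if key == "perm":
                    res = permutation_test(med_a, med_b, n_perm=n, seed=sd)
                elif key == "pairboot":
                    res = pair_bootstrap(med_a, med_b, n_boot=n, seed=sd, level=lv)
                elif key == "modelperm":
                    res = model_permutation(med_a, med_b, corr, n_sim=n, seed=sd)
                else:
                    res = model_bootstrap(med_a, med_b, corr, n_sim=n, seed=sd, level=lv)
                results[_SCHEMES[key]] = res.to_dict()
            return results

        results = guarded("concordance", run_concordance)
        cio.write_json(results, outdir / "concordance.json")
        record_output("concordance", "concordance.json")

    cio.write_json(manifest, outdir / "manifest.json")
    return manifest
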