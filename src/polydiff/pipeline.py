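"""End-to-end orchestration: simulate/load -> diversity -> distances ->
differentiation -> structure -> Mantel -> report bundle.

The pipeline is a pure function of (inputs, config, seeds): rerunning with
the same config produces byte-identical numeric outputs.  Each stage is
tagged; a failure aborts with the stage name while earlier outputs are
retained on disk.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import polydiff
from polydiff import differentiation, distances, diversity, mantel, simulate, structure
from polydiff.data_model import (
    read_genotypes,
    read_phenotypes,
    read_populations,
    records_to_frame,
    write_genotypes,
    write_phenotypes,
    write_populations,
)


@dataclass
class PipelineConfig:
    """Inputs (paths or simulation), tuning knobs and output directory."""

    out_dir: str = "polydiff_out"
    genotypes: str | None = None
    phenotypes: str | None = None
    coordinates: str | None = None
    simulate_genotypes: bool = False
    simulate_phenotypes: bool = False
    seed: int = 0
    extent_km: float = 100.0
    rarefaction_g: int | None = None
    contrast_tolerance: float = 0.03
    h2_threshold: float = 0.25
    n_permutations: int = 10_000
    n_bootstrap: int = 100
    geno_config: dict = field(default_factory=dict)
    pheno_config: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"[{name}] {exc}") from exc

        return inner

    return wrap


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every applicable stage; returns {artifact name: path}."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    dataset = _load_genotypes(config, out, artifacts)
    records = _load_phenotypes(config, out, artifacts)

    if dataset is not None:
        _diversity_stage(config, dataset, out, artifacts)
        pop_bruvo = _distance_stage(dataset, out, artifacts)
    else:
        pop_bruvo = None

    if records is not None:
        _phenotype_stage(config, records, out, artifacts)

    _differentiation_stage(config, records, dataset, out, artifacts)

    if dataset is not None:
        _structure_stage(pop_bruvo, out, artifacts)
    if dataset is not None and _has_coordinates(dataset):
        _mantel_stage(config, dataset, out, artifacts)

    manifest = {
        "package": "polydiff",
        "version": polydiff.__version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "artifacts": artifacts,
    }
    _write_json(out / "manifest.json", manifest)
    artifacts["manifest"] = str(out / "manifest.json")
    return artifacts


@_stage("load-genotypes")
def _load_genotypes(config, out, artifacts):
    if config.genotypes:
        pops = read_populations(config.coordinates) if config.coordinates else None
        return read_genotypes(config.genotypes, populations=pops)
    if not config.simulate_genotypes:
        return None
    geno_cfg = simulate.GenoSimConfig(seed=config.seed, **config.geno_config)
    dataset = simulate.simulate_genotypes(geno_cfg)
    coords = simulate.simulate_coordinates(
        geno_cfg.n_populations, config.extent_km, seed=config.seed + 1
    )
    dataset.populations = [
        simulate.PopulationInfo(
            p.id, p.region, p.status, c.latitude, c.longitude, c.elevation
        )
        for p, c in zip(dataset.populations, coords)
    ]
    write_genotypes(dataset, out / "genotypes.csv")
    write_populations(dataset.populations, out / "populations.csv")
    artifacts["genotypes"] = str(out / "genotypes.csv")
    artifacts["populations"] = str(out / "populations.csv")
    return dataset


@_stage("load-phenotypes")
def _load_phenotypes(config, out, artifacts):
    if config.phenotypes:
        return read_phenotypes(config.phenotypes)
    if not config.simulate_phenotypes:
        return None
    pheno_cfg = simulate.PhenoSimConfig(seed=config.seed + 2, **config.pheno_config)
    records = simulate.simulate_phenotypes(pheno_cfg)
    write_phenotypes(records, out / "phenotypes.csv")
    artifacts["phenotypes"] = str(out / "phenotypes.csv")
    return records


@_stage("diversity")
def _diversity_stage(config, dataset, out, artifacts):
    summary = diversity.diversity_summary(dataset, rarefaction_g=config.rarefaction_g)
    table = summary.per_population.copy()
    overall = summary.overall.to_frame().T
    overall.index = ["overall_mean"]
    pd.concat([table, overall]).to_csv(out / "diversity.csv", index_label="population")
    artifacts["diversity"] = str(out / "diversity.csv")

    group_of = {p.id: p.id.rstrip("0123456789") or p.id for p in dataset.populations} or None
    loci = diversity.locus_report(dataset, group_of)
    loci.to_csv(out / "loci.csv")
    artifacts["loci"] = str(out / "loci.csv")

    ploidy = {
        pop: diversity.infer_ploidy(dataset, pop) for pop in dataset.population_ids
    }
    _write_json(out / "ploidy.json", ploidy)
    artifacts["ploidy"] = str(out / "ploidy.json")


@_stage("distances")
def _distance_stage(dataset, out, artifacts):
    ind = distances.bruvo_matrix(dataset, level="individual")
    pop = distances.bruvo_matrix(dataset, level="population")
    ind.to_csv(out / "bruvo_individual.csv")
    pop.to_csv(out / "bruvo_population.csv")
    pop.to_phylip(out / "bruvo_population.phy")
    artifacts["bruvo_individual"] = str(out / "bruvo_individual.csv")
    artifacts["bruvo_population"] = str(out / "bruvo_population.csv")
    artifacts["bruvo_population_phylip"] = str(out / "bruvo_population.phy")
    return pop


@_stage("phenotype-structure")
def _phenotype_stage(config, records, out, artifacts):
    frame = records_to_frame(records)
    pheno_d = distances.phenotype_euclidean(frame)
    pheno_d.to_csv(out / "phenotype_distance.csv")
    artifacts["phenotype_distance"] = str(out / "phenotype_distance.csv")

    pca = structure.pheno_pca(frame)
    pca.loadings.to_csv(out / "pca_loadings.csv")
    pd.DataFrame(
        {
            "sdev": pca.sdev,
            "proportion": pca.proportion,
            "cumulative": pca.cumulative,
        },
        index=pca.loadings.columns,
    ).to_csv(out / "pca_variance.csv")
    artifacts["pca_loadings"] = str(out / "pca_loadings.csv")
    artifacts["pca_variance"] = str(out / "pca_variance.csv")

    clust = structure.hclust_phenotypes(
        frame, n_bootstrap=config.n_bootstrap, seed=config.seed + 3
    )
    _write_json(
        out / "hclust_support.json",
        {"|".join(sorted(c)): v for c, v in clust.support.items()},
    )
    artifacts["hclust_support"] = str(out / "hclust_support.json")

    from polydiff.data_model import FACTOR_COLUMNS, plant_level

    per_plant = plant_level(frame)
    traits = [c for c in per_plant.columns if c not in FACTOR_COLUMNS]
    screen = {}
    for t in traits:
        values = per_plant[t].dropna()
        if len(values) >= 20 and values.nunique() > 1:
            res = structure.bimodality_screen(values, seed=config.seed + 4)
            screen[t] = {
                "classification": res.classification,
                "bic_difference": res.bic_difference,
            }
    _write_json(out / "bimodality.json", screen)
    artifacts["bimodality"] = str(out / "bimodality.json")


@_stage("differentiation")
def _differentiation_stage(config, records, dataset, out, artifacts):
    if records is None and dataset is None:
        return
    payload: dict = {"schema_version": 1}
    if records is not None:
        model = differentiation.DifferentiationModel(records_to_frame(records), dataset)
        results = model.fit(
            tolerance=config.contrast_tolerance, h2_threshold=config.h2_threshold
        )
        payload["variance_components"] = {
            t: c.as_series().to_dict() for t, c in results.components.items()
        }
        payload["P_ST"] = results.pst
        payload["h2"] = results.h2
        if results.report is not None:
            payload["classification"] = results.report.classification
            payload["local_adaptation"] = results.report.local_adaptation
        rst_result = results.rst
        duncan = {}
        frame = records_to_frame(records)
        for t in results.pst:
            try:
                table = differentiation.duncan_mrt(frame, t)
                duncan[t] = table["letters"].to_dict()
            except ValueError:
                continue
        payload["duncan_letters"] = duncan
    else:
        rst_result = differentiation.rst(dataset)
    if dataset is not None and rst_result is None:
        rst_result = differentiation.rst(dataset)
    if rst_result is not None:
        payload["R_ST"] = {
            "overall": rst_result.overall,
            "jackknife_se": rst_result.jackknife_se,
            "per_locus": rst_result.per_locus.to_dict(),
            "pairwise_labels": rst_result.pairwise.labels,
            "pairwise": rst_result.pairwise.values.tolist(),
        }
    _write_json(out / "differentiation.json", payload)
    artifacts["differentiation"] = str(out / "differentiation.json")


@_stage("structure")
def _structure_stage(pop_bruvo, out, artifacts):
    result = structure.pcoa(pop_bruvo)
    result.coordinates.to_csv(out / "pcoa_coordinates.csv")
    artifacts["pcoa"] = str(out / "pcoa_coordinates.csv")
    if len(pop_bruvo.labels) >= 3:
        tree = structure.nj_tree(pop_bruvo)
        (out / "nj_tree.nwk").write_text(structure.tree_to_newick(tree) + "\n")
        artifacts["nj_tree"] = str(out / "nj_tree.nwk")


def _has_coordinates(dataset) -> bool:
    return bool(dataset.populations) and all(
        np.isfinite([p.latitude, p.longitude]).all() for p in dataset.populations
    )


@_stage("mantel")
def _mantel_stage(config, dataset, out, artifacts):
    rst_result = differentiation.rst(dataset)
    gen = rst_result.pairwise
    geo = distances.geographic_matrix(dataset.populations).reorder(gen.labels)
    result = mantel.mantel_test(
        gen, geo, n_perm=config.n_permutations, seed=config.seed + 5
    )
    _write_json(
        out / "mantel.json",
        {
            "r": result.r,
            "r_squared": result.r_squared,
            "p": result.p,
            "n_perm": result.n_perm,
            "seed": result.seed,
            "alternative": result.alternative,
            "genetic": "pairwise population R_ST",
            "geographic": "haversine km",
        },
    )
    artifacts["mantel"] = str(out / "mantel.json")
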