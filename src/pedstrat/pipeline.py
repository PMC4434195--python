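"""End-to-end pipeline: simulate -> clean -> random-panel PCA -> divergent
pairs -> delta AIMs -> AIM PCA -> family classification -> association ->
power / Type I error evaluation, with a JSON run manifest recording config,
seeds, output digests and per-stage timings."""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from . import aims as aims_mod
from . import assoc as assoc_mod
from . import famclass as famclass_mod
from . import genoio
from . import pca as pca_mod
from . import simulate as sim_mod

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "read_config", "write_config"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat key-value configuration for the whole pipeline.  Simulation keys
    are forwarded to :class:`pedstrat.simulate.SimulationConfig`."""

    seed: int
    # simulation (None -> SimulationConfig defaults)
    simulation: dict = field(default_factory=dict)
    # cleaning
    mendel_max_violations: int = 0
    # random panel PCA
    panel_size: int = 10_000
    panel_maf: float = 0.1
    n_components: int = 200
    # AIMs
    delta_cutoff: float = aims_mod.DEFAULT_DELTA_CUTOFF
    aim_components: tuple[int, ...] = (1, 2)
    dedup_aims: bool = True
    # classification
    k_grid: tuple[int, ...] = famclass_mod.DEFAULT_K_GRID
    # association
    n_pcs_assoc: int = 6
    n_null_snps: int = 10_000
    null_maf_min: float = 0.01
    alpha: float = 0.05
    wald_reference: str = "normal"

    def sim_config(self) -> sim_mod.SimulationConfig:
        return sim_mod.SimulationConfig(seed=self.seed, **self.simulation)


_COERCE = {
    "seed": int, "mendel_max_violations": int, "panel_size": int,
    "n_components": int, "n_pcs_assoc": int, "n_null_snps": int,
    "panel_maf": float, "delta_cutoff": float, "null_maf_min": float,
    "alpha": float, "dedup_aims": lambda s: s.lower() in ("1", "true", "yes"),
    "aim_components": lambda s: tuple(int(x) for x in s.split(",")),
    "k_grid": lambda s: tuple(int(x) for x in s.split(",")),
    "wald_reference": str,
}

_SIM_COERCE = {
    "n_families": int, "n_variants": int, "n_causal": int, "n_pops": int,
    "causal_beta_sd": float, "causal_maf_min": float, "fst": float,
    "beta_intercept": float, "beta_medication": float, "beta_sex": float,
    "beta_age": float, "beta_sex_age": float, "sigma2_family": float,
    "sigma2_resid": float, "medication_rate": float,
    "admixture": str,
    "plant_divergent_pairs": lambda s: s.lower() in ("1", "true", "yes"),
    "family_size_range": lambda s: tuple(int(x) for x in s.split(",")),
    "age_range": lambda s: tuple(float(x) for x in s.split(",")),
    "admixture_concentration": lambda s: tuple(float(x) for x in s.split(",")),
}


def read_config(path: str | Path) -> PipelineConfig:
    """Parse a flat ``key = value`` text config ('#' comments allowed).
    Simulation keys use a ``sim.`` prefix; ``seed`` is mandatory."""
    kv: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected 'key = value'")
        k, v = (x.strip() for x in line.split("=", 1))
        kv[k] = v
    if "seed" not in kv:
        raise ValueError(f"{path}: 'seed' is mandatory")
    top: dict[str, Any] = {}
    sim: dict[str, Any] = {}
    for k, v in kv.items():
        if k.startswith("sim."):
            sk = k[4:]
            if sk == "seed":
                continue
            if sk not in _SIM_COERCE:
                raise ValueError(f"unknown simulation key {sk!r}")
            sim[sk] = _SIM_COERCE[sk](v)
        else:
            if k not in _COERCE:
                raise ValueError(f"unknown config key {k!r}")
            top[k] = _COERCE[k](v)
    return PipelineConfig(simulation=sim, **top)


def write_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in dataclasses.fields(config):
            if f.name == "simulation":
                continue
            v = getattr(config, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            fh.write(f"{f.name} = {v}\n")
        for k, v in config.simulation.items():
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            fh.write(f"sim.{k} = {v}\n")


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    outputs: dict[str, str]      # relative path -> sha256
    timings: dict[str, float]    # stage -> seconds
    stats: dict[str, Any]

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    data: sim_mod.SimulatedData | None = None,
) -> RunManifest:
    """Execute every stage, writing all outputs under ``outdir``.

    ``data`` may carry a pre-loaded dataset (e.g. read from user PED/MAP
    files) to skip the simulation stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    timings: dict[str, float] = {}
    stats: dict[str, Any] = {}
    paths: dict[str, Path] = {}

    def stage(name):
        log.info("=== stage: %s ===", name)
        return time.perf_counter()

    # 1. simulate (or accept external data)
    t0 = stage("simulate")
    if data is None:
        data = sim_mod.simulate_dataset(config.sim_config())
        paths.update(sim_mod.write_dataset(data, outdir))
    timings["simulate"] = time.perf_counter() - t0
    ped, gmat, traits = data.pedigree, data.genotypes, data.traits

    # 2. clean: Mendelian-error screen, then keep polymorphic variants
    t0 = stage("clean")
    violations = genoio.mendel_check(gmat, ped)
    gclean = genoio.filter_mendel(gmat, violations, config.mendel_max_violations)
    stats["n_variants_in"] = gmat.n_variants
    stats["mendel_violations"] = len(violations)
    stats["n_variants_clean"] = gclean.n_variants
    timings["clean"] = time.perf_counter() - t0

    # 3. random-panel PCA
    t0 = stage("random_pca")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]).spawn(1)[0])
    panel_n = min(config.panel_size, gclean.n_variants)
    random_panel = pca_mod.sample_panel(gclean, panel_n, config.panel_maf, rng)
    n_comp = min(config.n_components, len(random_panel), gclean.n_individuals - 1)
    random_pca = pca_mod.run_pca(gclean, random_panel, n_components=n_comp)
    pca_mod.write_scores(random_pca, outdir / "random_pca_scores.tsv", seed)
    pca_mod.write_eigen(random_pca, outdir / "random_pca_eigen.tsv", seed)
    paths["random_pca_scores"] = outdir / "random_pca_scores.tsv"
    paths["random_pca_eigen"] = outdir / "random_pca_eigen.tsv"
    stats["random_pc12_varfrac"] = float(random_pca.variance_fraction[:2].sum())
    stats["random_pc_varfrac"] = [float(x) for x in random_pca.variance_fraction[:2]]
    timings["random_pca"] = time.perf_counter() - t0

    # 4. divergent family pairs from the random-panel PC structure
    t0 = stage("find_pairs")
    means = aims_mod.family_pc_means(random_pca, ped)
    pairs = aims_mod.find_divergent_pairs(means, components=config.aim_components)
    stats["divergent_pairs"] = pairs
    timings["find_pairs"] = time.perf_counter() - t0

    # 5. delta AIM selection per pair
    t0 = stage("select_aims")
    panels = []
    for i, pair in enumerate(pairs, start=1):
        freqs = aims_mod.pair_frequencies(gclean, ped, pair)
        panel = aims_mod.select_aims(freqs, config.delta_cutoff, {"pair": pair, "seed": seed})
        aims_mod.write_panel(panel, outdir / f"aims_pair{i}.tsv", seed)
        paths[f"aims_pair{i}"] = outdir / f"aims_pair{i}.tsv"
        panels.append(panel)
        stats[f"n_aims_pair{i}"] = len(panel)
    aim_ids = aims_mod.merge_panels(panels, deduplicate=config.dedup_aims)
    stats["n_aims_merged"] = len(aim_ids)
    timings["select_aims"] = time.perf_counter() - t0
    if len(aim_ids) < 2:
        raise RuntimeError("select_aims: fewer than 2 AIMs selected; cannot continue")

    # 6. PCA on the merged AIM panel
    t0 = stage("aim_pca")
    n_comp = min(config.n_components, len(aim_ids), gclean.n_individuals - 1)
    aim_pca = pca_mod.run_pca(gclean, aim_ids, n_components=n_comp)
    pca_mod.write_scores(aim_pca, outdir / "aim_pca_scores.tsv", seed)
    pca_mod.write_eigen(aim_pca, outdir / "aim_pca_eigen.tsv", seed)
    paths["aim_pca_scores"] = outdir / "aim_pca_scores.tsv"
    paths["aim_pca_eigen"] = outdir / "aim_pca_eigen.tsv"
    stats["aim_pc12_varfrac"] = float(aim_pca.variance_fraction[:2].sum())
    stats["aim_pc_varfrac"] = [float(x) for x in aim_pca.variance_fraction[:2]]
    timings["aim_pca"] = time.perf_counter() - t0

    # 7. LDA family classification vs number of PCs
    t0 = stage("classify")
    report = famclass_mod.accuracy_by_k(aim_pca, ped, tuple(config.k_grid))
    report.write(outdir / "classification.tsv", seed)
    paths["classification"] = outdir / "classification.tsv"
    stats["classification_overall"] = {int(k): float(v) for k, v in report.overall.items()}
    timings["classify"] = time.perf_counter() - t0

    # 8. association: causal panel on the trait, null panel on the null trait
    t0 = stage("associate")
    pcs = aim_pca.scores[:, : config.n_pcs_assoc]
    causal_ids = [v for v in data.causal["variant_id"] if v in set(gclean.variant_ids)]
    rng_null = np.random.default_rng(np.random.SeedSequence([seed, 2]).spawn(1)[0])
    n_null = min(config.n_null_snps, gclean.n_variants)
    null_ids = pca_mod.sample_panel(gclean, n_null, config.null_maf_min, rng_null)

    causal_recs = pd.concat(
        [
            assoc_mod.association_scan(
                gclean, traits, ped, pcs=None, variant_ids=causal_ids,
                trait_column="trait", reference=config.wald_reference,
            ),
            assoc_mod.association_scan(
                gclean, traits, ped, pcs=pcs, variant_ids=causal_ids,
                trait_column="trait", reference=config.wald_reference,
            ),
        ],
        ignore_index=True,
    )
    null_recs = pd.concat(
        [
            assoc_mod.association_scan(
                gclean, traits, ped, pcs=None, variant_ids=null_ids,
                trait_column="null_trait", reference=config.wald_reference,
            ),
            assoc_mod.association_scan(
                gclean, traits, ped, pcs=pcs, variant_ids=null_ids,
                trait_column="null_trait", reference=config.wald_reference,
            ),
        ],
        ignore_index=True,
    )
    assoc_mod.write_records(causal_recs, outdir / "assoc_causal.tsv", seed)
    assoc_mod.write_records(null_recs, outdir / "assoc_null.tsv", seed)
    paths["assoc_causal"] = outdir / "assoc_causal.tsv"
    paths["assoc_null"] = outdir / "assoc_null.tsv"
    timings["associate"] = time.perf_counter() - t0

    # 9. evaluate
    t0 = stage("evaluate")
    ev = assoc_mod.evaluate(causal_recs, null_recs, config.alpha)
    assoc_mod.write_report(ev, outdir / "evaluation.tsv", seed)
    paths["evaluation"] = outdir / "evaluation.tsv"
    stats["evaluation"] = {
        "alpha": ev.alpha,
        "power_unadjusted": ev.power_unadjusted,
        "power_adjusted": ev.power_adjusted,
        "t1e_unadjusted": ev.t1e_unadjusted,
        "t1e_adjusted": ev.t1e_adjusted,
    }
    timings["evaluate"] = time.perf_counter() - t0

    manifest = RunManifest(
        config=dataclasses.asdict(config),
        seed=seed,
        version=__version__,
        outputs={str(p.relative_to(outdir)): _digest(p) for p in sorted(paths.values())},
        timings=timings,
        stats=stats,
    )
    manifest.write(outdir / "manifest.json")
    return manifest
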