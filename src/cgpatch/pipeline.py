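"""End-to-end orchestration: synthesize -> kinship -> stats -> SFS fit -> report.

A run is fully determined by its configuration (which must carry an explicit
seed) and the package version. Each stage derives its own random substream
from the master seed by stage name, writes its outputs as plain CSV under the
run directory, and records a SHA-256 checksum in a manifest; the final report
is a per-cohort CSV plus a short human-readable summary.

The numbered drivers under ``analysis/`` call the same stage functions; this
module is the library surface for scripted end-to-end runs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from .forward import MetapopParams, SweepstakeParams
from .kinship import cohort_kinship_summary
from .mmc import fit_models
from .popstats import folded_sfs, ld_r2, nucleotide_diversity
from .synth import FULL_SIB, HALF_SIB, UNRELATED, make_study_like_dataset
from .vcfio import write_vcf

logger = logging.getLogger("cgpatch.pipeline")

_DEFAULTS: dict = {
    "seed": None,  # required, no default
    "log_level": "INFO",
    "synth": {
        "L": 5000,
        "n_cohorts": 14,
        "cohort_size": 10,
        "sweepstake_cohorts": ["coh05"],
        "n_fathers": 5,
        "missing_rate": 0.0,
        "founder_dist": "neutral",
        "founder_params": [1e-3],
    },
    "kinship": {"min_loci": 100, "maf_min": 0.01},
    "stats": {"max_ld_pairs": 20000},
    "sfs": {"alpha_grid": [1.1, 1.3, 1.5, 1.7, 1.9], "replicates": 4000},
    "simulate": None,  # optional CD sweep: {cd_grid, F, K, St, m, replicates, sample_size, L}
}


@dataclass
class RunConfig:
    """Validated, defaults-filled run configuration."""

    data: dict
    version: str = ""

    def __getitem__(self, key: str):
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])


def _merge(defaults: dict, given: dict, path: str, errors: list[str]) -> dict:
    out = dict(defaults)
    for key, value in given.items():
        if key not in defaults:
            errors.append(f"{path}{key}: unknown key")
            continue
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, f"{path}{key}.", errors)
        else:
            out[key] = value
    return out


def validate_config(source) -> RunConfig:
    """Validate a config mapping or YAML file; raise an itemized
    :class:`ConfigurationError` on any violation."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    errors: list[str] = []
    cfg = _merge(_DEFAULTS, raw, "", errors)
    if cfg.get("seed") is None:
        errors.append("seed: required (every stochastic stage must be explicitly seeded)")

    syn = cfg["synth"]
    if not 0.0 <= float(syn["missing_rate"]) < 1.0:
        errors.append("synth.missing_rate: must be in [0, 1)")
    if int(syn["L"]) < 1:
        errors.append("synth.L: must be >= 1")

    for a in cfg["sfs"]["alpha_grid"]:
        if not 1.0 < float(a) < 2.0:
            errors.append(f"sfs.alpha_grid: value {a} outside the open interval (1, 2)")

    sim = cfg.get("simulate")
    if sim is not None:
        if int(sim.get("St", 10)) % 2 != 0:
            errors.append("simulate.St: must be even (balanced 1:1 stacks impossible otherwise)")
        for cd in sim.get("cd_grid", [sim.get("CD", 1.0)]):
            if not 0.0 <= float(cd) <= 1.0:
                errors.append(f"simulate.CD: value {cd} outside [0, 1]")
        if not 0.0 <= float(sim.get("m", 0.1)) < 0.5:
            errors.append("simulate.m: must be in [0, 0.5)")
    if errors:
        raise ConfigurationError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return RunConfig(data=cfg, version=__version__)


@dataclass
class Report:
    """Per-cohort table plus optional simulation summaries and file manifest."""

    cohort_table: pd.DataFrame
    simulation_table: pd.DataFrame | None
    manifest: dict[str, str] = field(default_factory=dict)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config, out_dir) -> Report:
    """Execute the configured stages in dependency order.

    ``config`` may be a mapping, a YAML path, or an already validated
    :class:`RunConfig`. Outputs land under ``out_dir``; a stage failure aborts
    with the stage named, leaving earlier outputs in place.
    """
    cfg = config if isinstance(config, RunConfig) else validate_config(config)
    logging.basicConfig(level=cfg.data["log_level"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed
    manifest: dict[str, str] = {}

    def _stage(name):
        logger.info("stage %s (master seed %d)", name, seed)

    stage = "synth"
    try:
        _stage(stage)
        syn = dict(cfg["synth"])
        syn["founder_params"] = tuple(syn["founder_params"])
        ds = make_study_like_dataset(syn, seed=seed)
        vcf_path = out / "dataset.vcf"
        write_vcf(ds.genotypes, vcf_path)
        manifest["dataset.vcf"] = _checksum(vcf_path)
        gm = ds.genotypes

        stage = "kinship"
        _stage(stage)
        kin_rows = []
        for cohort in gm.cohort_names():
            comp = cohort_kinship_summary(
                gm, cohort, min_loci=cfg["kinship"]["min_loci"], maf_min=cfg["kinship"]["maf_min"]
            )
            kin_rows.append({"cohort": cohort, **{f"frac_{k}": v for k, v in comp.items()}})
        kin = pd.DataFrame(kin_rows).set_index("cohort")

        stage = "stats"
        _stage(stage)
        stat_rows = []
        for cohort in gm.cohort_names():
            r2 = ld_r2(gm, cohort, max_pairs=cfg["stats"]["max_ld_pairs"], seed=seed)
            stat_rows.append(
                {
                    "cohort": cohort,
                    "pi": nucleotide_diversity(gm, cohort),
                    "r2_mean": float(np.mean(r2)),
                    "r2_median": float(np.median(r2)),
                    "r2_p90": float(np.quantile(r2, 0.9)),
                }
            )
        stats = pd.DataFrame(stat_rows).set_index("cohort")

        stage = "sfs"
        _stage(stage)
        cache: dict = {}
        fit_rows = []
        for cohort in gm.cohort_names():
            spec = folded_sfs(gm, cohort)
            fit = fit_models(
                spec,
                alpha_grid=cfg["sfs"]["alpha_grid"],
                replicates=cfg["sfs"]["replicates"],
                seed=seed,
                cache=cache,
            )
            fit_rows.append(
                {
                    "cohort": cohort,
                    "n_sequences": spec.n,
                    "l2_kingman": fit.l2_kingman,
                    "best_alpha": fit.best_alpha,
                    "l2_best_xi": fit.l2_best_xi,
                    "best_model": fit.best_model,
                }
            )
        fits = pd.DataFrame(fit_rows).set_index("cohort")

        stage = "report"
        _stage(stage)
        table = kin.join(stats).join(fits).reset_index()
        table_path = out / "cohort_report.csv"
        table.to_csv(table_path, index=False, float_format="%.6g")
        manifest["cohort_report.csv"] = _checksum(table_path)

        sim_table = None
        if cfg.data.get("simulate"):
            stage = "simulate"
            _stage(stage)
            from .forward import run_cd_experiment

            sim = cfg.data["simulate"]
            res = run_cd_experiment(
                sim.get("cd_grid", [1.0]),
                sw=SweepstakeParams(F=sim.get("F", 1), K=sim.get("K", 1000), St=sim.get("St", 10)),
                mp=MetapopParams(m=sim.get("m", 0.1)),
                replicates=sim.get("replicates", 100),
                sample_size=sim.get("sample_size", 10),
                L=sim.get("L", 1000),
                seed=seed,
            )
            sim_table = (
                res.table.groupby("CD")
                .agg(
                    success=("success", "mean"),
                    frac_full_sib=("frac_full_sib", "mean"),
                    frac_half_sib=("frac_half_sib", "mean"),
                    frac_unrelated=("frac_unrelated", "mean"),
                    pi_ratio=("pi_sink", "mean"),
                )
                .reset_index()
            )
            sim_table["pi_ratio"] = (
                res.table.groupby("CD").apply(lambda t: (t.pi_sink / t.pi_source).mean(), include_groups=False).values
            )
            sim_path = out / "cd_sweep.csv"
            sim_table.to_csv(sim_path, index=False, float_format="%.6g")
            manifest["cd_sweep.csv"] = _checksum(sim_path)

        summary_path = out / "summary.txt"
        family_cohorts = table.loc[table["frac_unrelated"] == 0.0, "cohort"].tolist()
        with open(summary_path, "w") as fh:
            fh.write(f"cgpatch {__version__} pipeline run (seed {seed})\n")
            fh.write(f"cohorts analysed: {len(table)}\n")
            fh.write(f"cohorts with only close kin (full/half-sib pairs): {family_cohorts}\n")
            fh.write(f"best coalescent model per cohort: {table['best_model'].value_counts().to_dict()}\n")
        manifest["summary.txt"] = _checksum(summary_path)
        return Report(cohort_table=table, simulation_table=sim_table, manifest=manifest)
    except Exception as err:  # noqa: BLE001 - annotate the failing stage, keep partial outputs
        raise type(err)(f"pipeline stage '{stage}' failed: {err}") from err
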