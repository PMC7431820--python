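"""End-to-end orchestration: simulate -> fit -> classify -> summarize ->
setcompare -> overlap, with a provenance manifest.

Every stage writes its artifacts into the run directory before the next
stage starts, so a failing stage leaves partial outputs in place; the
manifest records input/output hashes, the seed and the package version so an
identical configuration reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import estimates, io, setcompare
from .enrichment import hypergeom_overlap
from .fitting import VARIANTS, FitSettings, run_methylome
from .simulate import aging_methylome_sampler, default_cohorts, simulate_methylome

logger = logging.getLogger("twinmeth")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Pipeline configuration (mirrors the CLI flags; loadable from YAML)."""

    out_dir: str = "twinmeth_run"
    seed: int = 0
    threads: int = 1
    # simulation (used when no data/pairs paths are given)
    n_sites: int = 100
    variant_truth: str = "ADE"
    # existing data
    data: Optional[str] = None
    pairs: Optional[str] = None
    annotation: Optional[str] = None
    site_set: Optional[str] = None
    # fitting
    variants: Sequence[str] = VARIANTS
    n_restarts: int = 2
    # thresholds
    significance_strict: float = 1e-7
    significance_loose: float = 1e-2
    stability_p: float = 0.01
    e_dominance: float = 0.99
    mean_bound: float = 6.25
    sd_bound: float = 1.5
    # set comparison
    compare_component: str = "broad_h2"
    demo_set_fraction: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "significance_strict",
            "significance_loose",
            "stability_p",
            "e_dominance",
            "mean_bound",
            "sd_bound",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        for name in ("significance_strict", "significance_loose", "stability_p"):
            if getattr(self, name) >= 1:
                raise ValueError(f"significance threshold {name} must be < 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "inputs": {},
        "outputs": {},
    }

    # pre-flight
    for label in ("data", "pairs", "annotation", "site_set"):
        p = getattr(config, label)
        if p is not None and not Path(p).exists():
            raise PipelineError("preflight", f"missing {label} file: {p}")

    # ---- simulate ---------------------------------------------------------
    stage = "simulate"
    try:
        if config.data is None:
            cohorts = default_cohorts(seed=config.seed)
            sampler = aging_methylome_sampler(variant=config.variant_truth)
            dataset, truth = simulate_methylome(
                config.n_sites, sampler, cohorts, master_seed=config.seed
            )
            meth_df, pairs_df = io.records_to_frames(dataset)
            io.write_methylation(meth_df, out / "methylation.tsv")
            io.write_pairs(pairs_df, out / "pairs.tsv")
            truth.to_csv(out / "truth.tsv", sep="\t", index=False, float_format="%.17g")
            logger.info("simulated %d sites x %d pairs", config.n_sites, len(pairs_df))
        else:
            dataset = io.load_dataset(config.data, config.pairs)
            manifest["inputs"]["data"] = _sha256(Path(config.data))
            manifest["inputs"]["pairs"] = _sha256(Path(config.pairs))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- fit --------------------------------------------------------------
    stage = "fit"
    try:
        settings = FitSettings(n_restarts=config.n_restarts, seed=config.seed)
        results, failures = run_methylome(dataset, settings, variants=tuple(config.variants))
        io.write_results(results, out / "results.tsv")
        failures.to_csv(out / "failures.tsv", sep="\t", index=False)
        logger.info("fitted %d sites (%d failures)", results["site_id"].nunique(), len(failures))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- classify ---------------------------------------------------------
    stage = "classify"
    try:
        classes = estimates.classify_sites(results)
        classes.to_csv(out / "classifications.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- summarize --------------------------------------------------------
    stage = "summarize"
    try:
        summary = estimates.summarize_components(results)
        summary.to_csv(out / "summary.tsv", sep="\t", index=False, float_format="%.6g")
        best_ade = results[(results["variant"] == "ADE") & results["best"]]
        stats_payload: dict = {}
        if len(best_ade) >= 2:
            mean_d, tstat, df, ci = estimates.paired_change_test(
                best_ade["broad_h2_1"].to_numpy(), best_ade["broad_h2_2"].to_numpy()
            )
            stats_payload["h2_change"] = {
                "mean_diff": mean_d, "t": tstat, "df": df, "ci95": list(ci)
            }
        if len(best_ade) >= 3:
            stats_payload["sd_h2_correlation"] = estimates.sd_h2_correlation(results, "ADE")
        (out / "summary_stats.json").write_text(json.dumps(stats_payload, indent=2))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- setcompare -------------------------------------------------------
    stage = "setcompare"
    try:
        site_ids = sorted(results["site_id"].unique())
        if config.site_set is not None:
            site_set = io.read_site_set(config.site_set)
            usable, absent = io.match_site_set(site_set, site_ids)
            if absent:
                logger.warning("%d set sites absent from results", len(absent))
            site_set = usable
        else:
            rng = np.random.default_rng(config.seed)
            n_pick = max(2, int(round(config.demo_set_fraction * len(site_ids))))
            site_set = set(rng.choice(site_ids, size=min(n_pick, len(site_ids) - 1), replace=False))
        # a mixed model over a handful of sites is degenerate; skip tiny runs
        if len(site_ids) >= 10 and 0 < len(site_set) < len(site_ids):
            comparison = setcompare.compare_sets(
                results, site_set, components=(config.compare_component,)
            )
            comparison.to_csv(out / "setcompare.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- overlap ----------------------------------------------------------
    stage = "overlap"
    try:
        classes_best = estimates.classify_sites(results)
        significant = set(classes_best.loc[classes_best["significant_1e2"], "site_id"])
        universe = set(site_ids)
        if significant and site_set and significant != universe and site_set != universe:
            test = hypergeom_overlap(
                k=len(significant & site_set),
                K=len(site_set),
                n=len(significant),
                N=len(universe),
            )
            (out / "overlap.json").write_text(json.dumps(asdict(test), indent=2))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    for artifact in sorted(out.iterdir()):
        if artifact.name != "manifest.json" and artifact.is_file():
            manifest["outputs"][artifact.name] = _sha256(artifact)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
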