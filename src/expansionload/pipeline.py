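"""End-to-end orchestration: simulate/load data, filter, stats, load, report.

A run is described by a YAML config with exactly one input source (a VCF +
side tables, or a simulation scenario), filter thresholds, statistic
options, and an output directory.  Every output table carries the root seed
and a config hash in a header comment, and a machine-readable JSON summary
is written at the end, so reruns with the same seed are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotypes import filter_individuals, filter_sites
from .load import classify_deleterious, daf_spectra, load_counts, \
    load_regressions, pin_pis, polarize_table
from .simulate import ExpansionSimConfig, gen_outgroup_panel, gen_range_expansion
from .stats import beta_st, diversity, ibd_and_gradient_report, \
    singleton_rarefaction
from .vcfio import read_outgroups, read_popmap, read_scores, read_vcf

__all__ = ["RunConfig", "validate_config", "run_pipeline", "make_report"]

_FILTER_DEFAULTS = {"call_rate_initial": 0.60, "min_mean_depth": 7.0,
                    "max_het_obs": 0.60, "max_missing": 0.05,
                    "call_rate_final": 0.95}
_STATS_DEFAULTS = {"subsample": 13, "reps": 200, "boot": 1000,
                   "mantel_perms": 10_000}
_KNOWN_KEYS = {"inputs", "simulation", "filters", "stats", "load", "outdir",
               "seed", "stages"}
_INPUT_KEYS = {"vcf", "popmap", "outgroups", "scores", "annotations"}


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    inputs: dict | None = None
    simulation: dict | None = None
    filters: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    load: dict = field(default_factory=dict)
    stages: list[str] = field(default_factory=lambda: ["filter", "stats", "load"])

    def __post_init__(self):
        problems = []
        if (self.inputs is None) == (self.simulation is None):
            problems.append("exactly one of 'inputs' and 'simulation' must be set")
        if self.inputs is not None:
            unknown = set(self.inputs) - _INPUT_KEYS
            if unknown:
                problems.append(f"unknown input keys {sorted(unknown)}")
            if "vcf" not in (self.inputs or {}):
                problems.append("inputs.vcf is required")
            if "popmap" not in (self.inputs or {}):
                problems.append("inputs.popmap is required")
        merged_f = dict(_FILTER_DEFAULTS)
        merged_f.update(self.filters or {})
        unknown = set(merged_f) - set(_FILTER_DEFAULTS)
        if unknown:
            problems.append(f"unknown filter keys {sorted(unknown)}")
        for key, v in merged_f.items():
            if not isinstance(v, (int, float)) or v < 0:
                problems.append(f"filter threshold {key} must be non-negative, "
                                f"got {v!r}")
        merged_s = dict(_STATS_DEFAULTS)
        merged_s.update(self.stats or {})
        unknown = set(merged_s) - set(_STATS_DEFAULTS)
        if unknown:
            problems.append(f"unknown stats keys {sorted(unknown)}")
        for key, v in merged_s.items():
            if not isinstance(v, int) or v <= 0:
                problems.append(f"stats option {key} must be a positive integer, "
                                f"got {v!r}")
        if problems:
            raise ValueError("invalid run config:\n  - " + "\n  - ".join(problems))
        self.filters = merged_f
        self.stats = merged_s

    def to_dict(self) -> dict:
        return {"outdir": self.outdir, "seed": self.seed, "inputs": self.inputs,
                "simulation": self.simulation, "filters": self.filters,
                "stats": self.stats, "load": self.load, "stages": self.stages}

    def config_hash(self) -> str:
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def validate_config(path) -> RunConfig:
    """Parse, default and validate a YAML run config (all errors at once)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _KNOWN_KEYS
    problems = [f"unknown config key {k!r}" for k in sorted(unknown)]
    if "outdir" not in raw:
        problems.append("outdir is required")
    if problems:
        raise ValueError("invalid run config:\n  - " + "\n  - ".join(problems))
    return RunConfig(**{k: v for k, v in raw.items() if k in _KNOWN_KEYS})


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# expansionload {__version__} seed={cfg.seed} "
                 f"config={cfg.config_hash()}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in order and write the report bundle."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"expansionload {__version__}", f"seed {cfg.seed}",
                 f"config hash {cfg.config_hash()}"]
    summary: dict = {"seed": cfg.seed, "config_hash": cfg.config_hash(),
                     "version": __version__, "stages": {}}
    t_start = time.time()
    stage = "input"
    try:
        annotations = scores = outgroups = None
        if cfg.simulation is not None:
            sim = ExpansionSimConfig(**{**cfg.simulation, "seed": cfg.seed})
            gm, annotations, popmap = gen_range_expansion(sim)
            outgroups = gen_outgroup_panel(gm.sites, seed=cfg.seed + 1)
            scores = annotations[["chrom", "pos", "score"]]
        else:
            gm = read_vcf(cfg.inputs["vcf"])
            popmap = read_popmap(cfg.inputs["popmap"])
            if "outgroups" in cfg.inputs:
                outgroups = read_outgroups(cfg.inputs["outgroups"])
            if "scores" in cfg.inputs:
                scores = read_scores(cfg.inputs["scores"])
            if "annotations" in cfg.inputs:
                annotations = pd.read_csv(cfg.inputs["annotations"], sep="\t")
        summary["stages"]["input"] = {"individuals": gm.n_individuals,
                                      "sites": gm.n_sites}
        log_lines.append(f"input: {gm.n_individuals} individuals x "
                         f"{gm.n_sites} sites")

        if "filter" in cfg.stages:
            stage = "filter"
            f = cfg.filters
            gm, rep1 = filter_sites(gm, "initial",
                                    call_rate_initial=f["call_rate_initial"],
                                    min_mean_depth=f["min_mean_depth"],
                                    max_het_obs=f["max_het_obs"])
            gm, rep2 = filter_individuals(gm, max_missing=f["max_missing"])
            gm, rep3 = filter_sites(gm, "final",
                                    call_rate_final=f["call_rate_final"])
            summary["stages"]["filter"] = {
                "initial_removed": rep1.removed, "individuals_removed":
                rep2.removed, "final_removed": rep3.removed,
                "sites_out": gm.n_sites, "individuals_out": gm.n_individuals}
            log_lines.append(f"filter: {gm.n_individuals} individuals x "
                             f"{gm.n_sites} sites retained")

        results: dict = {}
        if "stats" in cfg.stages:
            stage = "stats"
            div = diversity(gm, popmap)
            div.beta_st = beta_st(gm, popmap, n_boot=cfg.stats["boot"],
                                  seed=cfg.seed)
            ibd = ibd_and_gradient_report(gm, popmap, div=div,
                                          mantel_perms=cfg.stats["mantel_perms"],
                                          seed=cfg.seed)
            results["diversity"] = ibd["per_population"]
            results["ibd"] = ibd
            _write_table(ibd["per_population"], outdir / "diversity.tsv", cfg)
            _write_table(ibd["regressions"], outdir / "ibd_regressions.tsv", cfg)
            _write_table(div.beta_st, outdir / "beta_st.tsv", cfg)
            try:
                sing = singleton_rarefaction(gm, popmap,
                                             subsample=cfg.stats["subsample"],
                                             reps=cfg.stats["reps"],
                                             seed=cfg.seed)
                _write_table(sing["per_population"], outdir / "singletons.tsv", cfg)
                results["singletons"] = sing
            except ValueError as exc:
                log_lines.append(f"stats: singleton rarefaction skipped ({exc})")
            summary["stages"]["stats"] = {
                "mantel_r": ibd["mantel_fst_geo"]["r"],
                "mantel_p": ibd["mantel_fst_geo"]["p"],
                "source_population": ibd["source_population"]}
            log_lines.append("stats: done")

        if "load" in cfg.stages and annotations is not None:
            stage = "load"
            sites = gm.sites[["chrom", "pos", "ref", "alt"]]
            if outgroups is not None:
                ancestral = polarize_table(sites, outgroups)
            else:
                ann = annotations.set_index(["chrom", "pos"]).reindex(
                    pd.MultiIndex.from_frame(gm.sites[["chrom", "pos"]]))
                ancestral = pd.Series(ann.get("ancestral", "unknown"),
                                      index=sites.index).fillna("unknown")
            ann_aligned = annotations.merge(gm.sites[["chrom", "pos"]],
                                            on=["chrom", "pos"], how="right")
            flags = classify_deleterious(ann_aligned, scores)
            counts = load_counts(gm, ancestral, flags, popmap)
            pin = pin_pis(gm, ann_aligned, popmap)
            div_for_load = results.get("ibd", {}).get("per_population") \
                if "stats" in cfg.stages else None
            regress = load_regressions(
                counts, pin,
                div if "stats" in cfg.stages else None, popmap,
                exclude=cfg.load.get("exclude"))
            daf = daf_spectra(gm, ancestral, ann_aligned, popmap,
                              deleterious_flags=flags,
                              normalize_n=cfg.load.get("normalize_n", 100))
            _write_table(counts["per_individual"], outdir / "load_individual.tsv", cfg)
            _write_table(counts["per_population"], outdir / "load_population.tsv", cfg)
            _write_table(pin, outdir / "pin_pis.tsv", cfg)
            _write_table(regress, outdir / "load_regressions.tsv", cfg)
            _write_table(daf["summary"], outdir / "daf_summary.tsv", cfg)
            results["load"] = counts
            results["pin_pis"] = pin
            results["load_regressions"] = regress
            summary["stages"]["load"] = {
                "het_fraction": counts["het_fraction"],
                "n_deleterious_sites": int(np.asarray(flags).sum())}
            log_lines.append("load: done")
    except Exception as exc:
        log_lines.append(f"FAILED at stage {stage}: {exc}")
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    summary["runtime_s"] = round(time.time() - t_start, 2)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    log_lines.append(f"total runtime {summary['runtime_s']}s")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    results["summary"] = summary
    return results


def make_report(outdir, *, formats=("png",)) -> list[str]:
    """Render figures (with CSV sidecars) from a pipeline output directory.

    Missing tables skip their section with a notice instead of failing.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    written: list[str] = []

    def _read(name):
        path = outdir / name
        if not path.exists():
            print(f"report: {name} absent; section skipped")
            return None
        return pd.read_csv(path, sep="\t", comment="#")

    div = _read("diversity.tsv")
    panels = []
    if div is not None:
        panels += [("He", "expected heterozygosity"),
                   ("beta", "beta_ST"), ("tajimas_d", "Tajima's D")]
    loadpop = _read("load_population.tsv")
    diversity_cols = div.columns if div is not None else []
    for col, label in panels:
        if col not in diversity_cols:
            continue
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(div["distance_km"], div[col])
        ax.set_xlabel("distance from source (km)")
        ax.set_ylabel(label)
        fig.tight_layout()
        side = outdir / f"fig_{col}_vs_distance.csv"
        div[["population", "distance_km", col]].to_csv(side, index=False)
        for ext in formats:
            path = outdir / f"fig_{col}_vs_distance.{ext}"
            fig.savefig(path)
            written.append(str(path))
        written.append(str(side))
        plt.close(fig)
    if loadpop is not None and div is not None:
        merged = loadpop.merge(div[["population", "distance_km"]], on="population")
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(merged["distance_km"], merged["n_homo"], label="recessive")
        ax.scatter(merged["distance_km"], merged["n_total"], label="total",
                   marker="x")
        ax.set_xlabel("distance from source (km)")
        ax.set_ylabel("mean deleterious load per individual")
        ax.legend(frameon=False)
        fig.tight_layout()
        side = outdir / "fig_load_vs_distance.csv"
        merged.to_csv(side, index=False)
        for ext in formats:
            path = outdir / f"fig_load_vs_distance.{ext}"
            fig.savefig(path)
            written.append(str(path))
        written.append(str(side))
        plt.close(fig)
    return written
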