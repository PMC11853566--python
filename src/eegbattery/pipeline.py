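"""Configured, resumable orchestration of the full analysis pipeline.

Stages: simulate -> stats -> replicate -> samplesize -> matchsample ->
report.  Each stage writes CSV outputs under the run directory and records
row counts in a JSON manifest keyed by the config hash; re-running an
unchanged config skips completed stages.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from eegbattery import __version__
from eegbattery.cohort import (
    CohortConfig,
    FeatureEffect,
    FeatureEffects,
    generate_demographics,
    simulate_feature_table,
)
from eegbattery.layout import default_layout
from eegbattery.registry import build_registry
from eegbattery.replication import (
    ETA2_THRESHOLD,
    RATE_THRESHOLD,
    replicate_effects,
    select_replicable,
)
from eegbattery.samplesize import bootstrap_curve, matched_sample, supra_threshold_pattern
from eegbattery.stats import assign_age_tertiles, count_fits, effect_table

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohort": {
        "n_per_stratum": {"AD": [15, 15, 15], "ASD": [15, 15, 15], "CON": [30, 30, 30]},
        "female_fraction": 0.4,
        "iq_mean": 100.0,
        "iq_sd": 15.0,
    },
    "effects": [],
    "noise_sd": 1.0,
    "registry_subset": None,
    "stages": {
        "simulate": True,
        "stats": True,
        "replicate": False,
        "samplesize": False,
        "matchsample": False,
        "report": False,
    },
    "stats": {"eta2_threshold": ETA2_THRESHOLD, "z_threshold": 3.5, "lrt_alpha": 0.05},
    "replication": {"n_splits": 150, "rate_threshold": RATE_THRESHOLD, "max_effects": None},
    "samplesize": {"fractions": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7], "reps": 100},
}


class ConfigError(ValueError):
    """Raised for malformed pipeline configuration."""


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge a YAML config file and overrides onto the defaults."""
    config = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst: dict, src: dict) -> None:
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a mapping")
        merge(config, loaded)
    if overrides:
        merge(config, overrides)
    return config


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _cohort_config(config: dict) -> CohortConfig:
    c = config["cohort"]
    try:
        return CohortConfig(
            n_per_stratum={k: tuple(v) for k, v in c["n_per_stratum"].items()},
            female_fraction=float(c.get("female_fraction", 0.4)),
            iq_mean=float(c.get("iq_mean", 100.0)),
            iq_sd=float(c.get("iq_sd", 15.0)),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"invalid cohort config: {exc}") from exc


def _feature_effects(config: dict) -> FeatureEffects:
    effects = []
    for entry in config.get("effects", []):
        effects.append(
            FeatureEffect(
                family=entry.get("family"),
                qualifier=entry.get("qualifier"),
                grouping=entry.get("grouping"),
                age_beta=float(entry.get("age_beta", 0.0)),
                sex_beta=float(entry.get("sex_beta", 0.0)),
                iq_beta=float(entry.get("iq_beta", 0.0)),
                diagnosis_betas={
                    k: float(v) for k, v in entry.get("diagnosis_betas", {}).items()
                },
            )
        )
    return FeatureEffects(effects=effects, noise_sd=float(config.get("noise_sd", 1.0)))


class PipelineRun:
    """Stateful run directory: outputs, manifest, stage execution."""

    def __init__(self, config: dict, out_dir: str | Path):
        self.config = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.hash = config_hash(config)
        self.manifest_path = self.out / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {"config_hash": self.hash, "version": __version__, "stages": {}}
        if self.manifest.get("config_hash") != self.hash:
            self.manifest = {"config_hash": self.hash, "version": __version__, "stages": {}}

    # -- manifest helpers -------------------------------------------------
    def _done(self, stage: str, outputs: list[str]) -> bool:
        rec = self.manifest["stages"].get(stage)
        return bool(rec) and all((self.out / f).exists() for f in outputs)

    def _record(self, stage: str, rows: dict[str, int], elapsed: float) -> None:
        self.manifest["stages"][stage] = {
            "rows": rows,
            "elapsed_s": round(elapsed, 3),
            "completed_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))

    def _read(self, name: str) -> pd.DataFrame:
        return pd.read_csv(self.out / name)

    # -- stages -----------------------------------------------------------
    def simulate(self) -> None:
        if self._done("simulate", ["demographics.csv", "features.csv", "registry.csv"]):
            return
        t0 = time.time()
        seed = int(self.config["seed"])
        demographics = generate_demographics(_cohort_config(self.config), seed)
        registry = build_registry(default_layout())
        subset = self.config.get("registry_subset")
        if subset:
            registry = registry.subset(int(subset))
        features = simulate_feature_table(
            demographics, registry, _feature_effects(self.config), seed=seed + 1
        )
        demographics.to_csv(self.out / "demographics.csv", index=False)
        features.to_csv(self.out / "features.csv", index=False)
        registry.to_manifest().to_csv(self.out / "registry.csv", index=False)
        self._record(
            "simulate",
            {"participants": len(demographics), "variables": len(registry)},
            time.time() - t0,
        )

    def stats(self) -> None:
        if self._done("stats", ["effects.csv", "age_groups.csv"]):
            return
        t0 = time.time()
        demographics = self._read("demographics.csv")
        features = self._read("features.csv")
        grouping = assign_age_tertiles(demographics)
        effects = effect_table(
            features,
            demographics,
            grouping,
            z_threshold=float(self.config["stats"]["z_threshold"]),
            lrt_alpha=float(self.config["stats"]["lrt_alpha"]),
        )
        grouping.labels.rename_axis("participant_id").to_frame().to_csv(
            self.out / "age_groups.csv"
        )
        effects.to_csv(self.out / "effects.csv", index=False)
        self._record(
            "stats",
            {"effect_records": len(effects), "model_fits": count_fits(effects)},
            time.time() - t0,
        )

    def replicate(self) -> None:
        if self._done("replicate", ["replication.csv"]):
            return
        t0 = time.time()
        demographics = self._read("demographics.csv")
        features = self._read("features.csv")
        effects = self._read("effects.csv")
        grouping = assign_age_tertiles(demographics)
        rcfg = self.config["replication"]
        threshold = float(self.config["stats"]["eta2_threshold"])
        supra = effects[(effects["eta2"] > threshold)]
        max_effects = rcfg.get("max_effects")
        if max_effects:
            supra = supra.sort_values("eta2", ascending=False).head(int(max_effects))
        summaries = replicate_effects(
            supra,
            features,
            demographics,
            grouping,
            n_splits=int(rcfg["n_splits"]),
            threshold=threshold,
            rate_threshold=float(rcfg["rate_threshold"]),
            seed=int(self.config["seed"]) + 2,
            z_threshold=float(self.config["stats"]["z_threshold"]),
        )
        summaries.to_csv(self.out / "replication.csv", index=False)
        replicable = select_replicable(
            summaries, float(rcfg["rate_threshold"]), threshold
        )
        replicable.to_csv(self.out / "replicable.csv", index=False)
        self._record(
            "replicate",
            {"summaries": len(summaries), "replicable": len(replicable)},
            time.time() - t0,
        )

    def samplesize(self) -> None:
        if self._done("samplesize", ["subsample_runs.csv", "subsample_nmi.csv"]):
            return
        t0 = time.time()
        demographics = self._read("demographics.csv")
        features = self._read("features.csv")
        grouping = assign_age_tertiles(demographics)
        scfg = self.config["samplesize"]
        runs, nmis = bootstrap_curve(
            features,
            demographics,
            grouping,
            fractions=tuple(float(f) for f in scfg["fractions"]),
            reps=int(scfg["reps"]),
            seed=int(self.config["seed"]) + 3,
            threshold=float(self.config["stats"]["eta2_threshold"]),
        )
        runs.to_csv(self.out / "subsample_runs.csv", index=False)
        nmis.to_csv(self.out / "subsample_nmi.csv", index=False)
        self._record(
            "samplesize", {"runs": len(runs), "nmi_pairs": len(nmis)}, time.time() - t0
        )

    def matchsample(self) -> None:
        if self._done("matchsample", ["matched_pairs.csv"]):
            return
        t0 = time.time()
        demographics = self._read("demographics.csv")
        pairs = matched_sample(demographics)
        pairs.to_csv(self.out / "matched_pairs.csv", index=False)
        self._record("matchsample", {"pairs": len(pairs)}, time.time() - t0)

    def report(self) -> None:
        t0 = time.time()
        sections = build_report(self.out, self.config)
        self._record("report", {"sections": len(sections)}, time.time() - t0)

    def run(self) -> dict:
        """Execute all enabled stages in order; returns the manifest."""
        stages = self.config["stages"]
        order = ["simulate", "stats", "replicate", "samplesize", "matchsample", "report"]
        for stage in order:
            if not stages.get(stage, False):
                continue
            try:
                getattr(self, stage)()
            except ConfigError:
                raise
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        return self.manifest


def run(config: dict, out_dir: str | Path) -> dict:
    """Run the pipeline for a config dict; convenience wrapper."""
    return PipelineRun(config, out_dir).run()


def build_report(out_dir: str | Path, config: dict | None = None) -> list[str]:
    """Emit summary figures and tables from completed stage outputs.

    Sections whose stage outputs are missing are skipped with a notice.
    Returns the list of emitted section names.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    threshold = ETA2_THRESHOLD if config is None else float(
        config["stats"]["eta2_threshold"]
    )
    sections: list[str] = []

    effects_path = out / "effects.csv"
    if effects_path.exists():
        effects = pd.read_csv(effects_path)
        terms = sorted(effects["term"].unique())
        groups = sorted(effects["age_group"].unique())
        fig, axes = plt.subplots(
            len(terms), len(groups), figsize=(3 * len(groups), 2 * len(terms)),
            squeeze=False,
        )
        for i, term in enumerate(terms):
            for j, group in enumerate(groups):
                vals = effects.query("term == @term and age_group == @group")["eta2"].dropna()
                axes[i][j].hist(vals, bins=40)
                axes[i][j].axvline(threshold, ls="--", color="k", lw=0.8)
                if i == 0:
                    axes[i][j].set_title(group, fontsize=8)
                if j == 0:
                    axes[i][j].set_ylabel(term, fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "report_eta2_histograms.png", dpi=120)
        plt.close(fig)
        sections.append("eta2_histograms")

        # proportion of supra-threshold effects per variable family x term x age group
        effects["family"] = effects["variable"].str.split(".").str[0]
        pattern = supra_threshold_pattern(effects, threshold)
        prop = (
            effects.assign(supra=pattern.to_numpy())
            .groupby(["age_group", "family", "term"])["supra"]
            .mean()
            .unstack("term")
        )
        prop.to_csv(out / "report_proportions.csv")
        sections.append("proportion_matrix")
    else:
        print("report: effects.csv missing; histogram/proportion sections omitted")

    repl_path = out / "replication.csv"
    if repl_path.exists():
        summaries = pd.read_csv(repl_path)
        if len(summaries):
            fig, ax = plt.subplots(figsize=(4, 3))
            ax.scatter(summaries["full_eta2"], summaries["rate"], s=8)
            ax.axhline(RATE_THRESHOLD, ls="--", color="k", lw=0.8)
            ax.set_xlabel("partial eta²")
            ax.set_ylabel("replication rate")
            fig.tight_layout()
            fig.savefig(out / "report_replication_scatter.png", dpi=120)
            plt.close(fig)
        sections.append("replication_scatter")
    else:
        print("report: replication.csv missing; replication section omitted")

    runs_path = out / "subsample_runs.csv"
    nmi_path = out / "subsample_nmi.csv"
    if runs_path.exists() and nmi_path.exists():
        runs = pd.read_csv(runs_path)
        nmis = pd.read_csv(nmi_path)
        fig, axes = plt.subplots(1, 2, figsize=(8, 3))
        for term, sub in runs.groupby("term"):
            curve = sub.groupby("fraction")["proportion"].mean()
            axes[0].plot(curve.index, curve.values, marker="o", ms=3, label=term)
        axes[0].set_xlabel("subsample fraction")
        axes[0].set_ylabel("proportion eta² > threshold")
        axes[0].legend(fontsize=5)
        for term, sub in nmis.groupby("term"):
            curve = sub.groupby("fraction")["nmi"].mean()
            axes[1].plot(curve.index, curve.values, marker="o", ms=3, label=term)
        axes[1].set_xlabel("subsample fraction")
        axes[1].set_ylabel("mean pairwise NMI")
        fig.tight_layout()
        fig.savefig(out / "report_samplesize.png", dpi=120)
        plt.close(fig)
        sections.append("samplesize_curves")
    else:
        print("report: subsample outputs missing; sample-size section omitted")

    return sections
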