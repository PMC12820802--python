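"""Orchestration: simulate -> harmonize (all methods) -> evaluate/benchmark.

A :class:`RunConfig` (YAML-serializable) names the methods, design, and
evaluation options. Harmonization always runs on the full recording set
(both conditions); the benchmark then deduplicates to one recording per
subject before site-effect and age analyses.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import synthetic
from .combat import harmonize_combat
from .covbat import harmonize_covbat
from .core_data import (
    DesignSpec,
    FeatureTable,
    OCCIPITAL_ROIS,
    read_feature_table,
    select_one_recording_per_subject,
    write_feature_table,
)
from .evaluation import condition_effect_tests, cv_delta_r2, evaluation_report
from .relief import harmonize_relief

log = logging.getLogger("megharm")

VALID_METHODS = ("combat", "gamcombat", "covbat", "relief")


@dataclass
class MethodSpec:
    name: str
    eb: bool = True
    pct_var: float = 0.95

    def __post_init__(self) -> None:
        if self.name not in VALID_METHODS:
            raise ValueError(
                f"unknown method {self.name!r}; expected one of {VALID_METHODS}"
            )

    @property
    def label(self) -> str:
        if self.name == "covbat":
            return f"covbat{int(round(self.pct_var * 100))}"
        return self.name


@dataclass
class RunConfig:
    band: str = "delta"
    methods: list[MethodSpec] = field(
        default_factory=lambda: [
            MethodSpec("combat"),
            MethodSpec("gamcombat"),
            MethodSpec("covbat", pct_var=0.90),
            MethodSpec("covbat", pct_var=0.95),
            MethodSpec("covbat", pct_var=1.00),
            MethodSpec("relief"),
        ]
    )
    age_degree: int = 3
    seed: int = 7
    rois: tuple[str, ...] = OCCIPITAL_ROIS
    cv_k: int = 10
    cv_repeats: int = 50
    age_bin: tuple[float, float] = (20.0, 30.0)
    min_n: int = 30
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        methods = [MethodSpec(**m) for m in raw.pop("methods", [])] or None
        cfg = cls(**raw) if methods is None else cls(methods=methods, **raw)
        return cfg


def harmonize_method(table: FeatureTable, method: MethodSpec) -> FeatureTable:
    if method.name == "combat":
        return harmonize_combat(table, mean_model="linear", eb=method.eb)
    if method.name == "gamcombat":
        return harmonize_combat(table, mean_model="gam", eb=method.eb)
    if method.name == "covbat":
        return harmonize_covbat(table, pct_var=method.pct_var, eb=method.eb)
    if method.name == "relief":
        return harmonize_relief(table)
    raise ValueError(method.name)


def run_simulate(config: RunConfig, out_dir=None) -> dict:
    """Generate the default 16-study table; write TSV plus YAML truth."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profiles = synthetic.consortium_profiles()
    effects = synthetic.default_effects(profiles)
    roster = synthetic.sample_roster(profiles, seed=config.seed)
    table, truth = synthetic.simulate_power(
        roster, effects, seed=config.seed + 1, band=config.band
    )
    table_path = out / f"power_{config.band}.tsv"
    write_feature_table(table, table_path)
    truth_path = out / f"truth_{config.band}.yaml"
    with open(truth_path, "w") as fh:
        yaml.safe_dump(
            {
                "seed": truth.seed,
                "clamp_fraction": float(truth.clamp_fraction),
                "gamma": truth.gamma.round(8).to_dict(),
                "delta2": truth.delta2.round(8).to_dict(),
            },
            fh,
        )
    log.info("simulated %d recordings from %d studies", table.n_records, len(profiles))
    return {"table": str(table_path), "truth": str(truth_path)}


def run_harmonize(config: RunConfig, table_path=None, out_dir=None) -> dict:
    """Apply every configured method to the full recording set."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    src = Path(table_path or out / f"power_{config.band}.tsv")
    table = read_feature_table(src, band=config.band)
    outputs = {}
    for method in config.methods:
        harmonized = harmonize_method(table, method)
        path = out / f"power_{config.band}_{method.label}.tsv"
        write_feature_table(harmonized, path)
        outputs[method.label] = str(path)
        log.info("harmonized with %s -> %s", method.label, path)
    return outputs


def run_evaluate(config: RunConfig, table_path, report_path=None) -> dict:
    table = read_feature_table(table_path, band=config.band)
    dedup = select_one_recording_per_subject(table, preferred="eyes-closed")
    report = evaluation_report(
        dedup,
        degree=config.age_degree,
        rois=config.rois,
        age_bin=config.age_bin,
        min_n=config.min_n,
    )
    if report_path:
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=1)
    return report


def run_benchmark(
    config: RunConfig,
    out_dir=None,
    compare: tuple[str, str] | None = ("gamcombat", "covbat100"),
) -> dict:
    """Simulate, harmonize with every method, and evaluate each output.

    Site-effect and age analyses are run on one recording per subject
    (eyes-closed preferred). Paired eyes-open/eyes-closed t-tests use the
    full table. ``compare`` names two methods for cross-validated Delta R^2.
    """
    out = Path(out_dir or config.out_dir)
    paths = run_simulate(config, out)
    harmonized_paths = run_harmonize(config, paths["table"], out)
    all_paths = {"raw": paths["table"], **harmonized_paths}

    report: dict = {"methods": {}, "config": {"band": config.band, "seed": config.seed}}
    tables = {}
    for label, path in all_paths.items():
        table = read_feature_table(path, band=config.band)
        tables[label] = table
        entry = run_evaluate(config, path)
        try:
            paired = condition_effect_tests(table, config.rois, mode="paired")
            entry["paired_t"] = paired["t"].to_dict()
        except ValueError:
            entry["paired_t"] = None
        report["methods"][label] = entry
        log.info(
            "%s: median partial R2 %.4g, median |logVR| %.4g",
            label,
            entry["summary"]["median_partial_r2"],
            entry["summary"]["median_mean_abs_log_vr"],
        )
    if compare is not None:
        a, b = compare
        ta = select_one_recording_per_subject(tables[a])
        tb = select_one_recording_per_subject(tables[b])
        cv = cv_delta_r2(
            ta, tb, degree=config.age_degree, k=config.cv_k,
            repeats=config.cv_repeats, seed=config.seed,
        )
        report["cv_delta_r2"] = {
            "pair": [a, b],
            "mean_delta_r2": cv["mean_delta_r2"].tolist(),
            "q": cv["q"].tolist(),
            "n_favoring_a": int(((cv["mean_delta_r2"] > 0) & (cv["q"] < 0.05)).sum()),
        }
    with open(out / f"benchmark_{config.band}.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report
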