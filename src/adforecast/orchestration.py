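"""Reproducible end-to-end runs: configuration, pipeline stages, reporting.

A :class:`RunConfig` (typically loaded from YAML) drives three stages —
simulate a cohort, validate model variants by forward chaining, and report
summary tables — each of which can also be called directly from Python.
Figures are rendered from persisted score tables alone, so any plot can be
regenerated without refitting.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .evaluation import (
    ScoreTable,
    coefficient_table,
    forward_chaining,
    learning_curve,
    paired_score_difference,
)
from .model import FitOptions, ModelSpec, fit_sign_model
from .panel import SIGNS, PanelDataset, extract_transition_pairs, filter_min_observations, read_panel
from .simulate import GeneratorConfig, generate_cohort, write_cohort

log = logging.getLogger("adforecast")

DEFAULT_VARIANTS = ("none",)


@dataclass
class RunConfig:
    """Everything needed to reproduce one experiment."""

    seed: int = 0
    generator: dict = field(default_factory=dict)
    min_days: int = 10
    variants: tuple = DEFAULT_VARIANTS
    refit_stride: int = 1
    min_train_days: int = 1
    quad_order: int = 9

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "variants" in raw:
            raw["variants"] = tuple(raw["variants"])
        return cls(**raw)

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(seed=self.seed, **self.generator)


def specs_for_variants(variants: Sequence[str]) -> list[ModelSpec]:
    """Expand variant labels to per-sign model specs.

    Labels: ``none`` (no covariates), ``single:<cov>`` or ``all``.
    """
    from .panel import COVARIATES

    specs = []
    for v in variants:
        if v == "none":
            covset: tuple = ()
        elif v == "all":
            covset = COVARIATES
        elif v.startswith("single:"):
            covset = (v.split(":", 1)[1],)
        else:
            raise ValueError(f"unknown variant label {v!r}")
        specs.extend(ModelSpec(sign, covset) for sign in SIGNS)
    return specs


def run_simulate(config: RunConfig, out_dir) -> tuple[Path, Path]:
    """Generate the synthetic cohort; write panel CSV + ground-truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen = config.generator_config()
    log.info("simulating cohort: %d patients x %d days (seed %d)",
             gen.n_patients, gen.n_days, gen.seed)
    t0 = time.time()
    ds, truth = generate_cohort(gen)
    csv_path, truth_path = out / "panel.csv", out / "ground_truth.json"
    write_cohort(ds, truth, csv_path, truth_path)
    log.info("wrote %s (%d rows) in %.1fs", csv_path, len(ds), time.time() - t0)
    return csv_path, truth_path


def run_validate(config: RunConfig, dataset_path, out_dir,
                 make_figures: bool = True) -> Path:
    """Filter, forward-chain all configured variants, write tables and figures."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = read_panel(dataset_path)
    ds = filter_min_observations(ds, config.min_days)
    specs = specs_for_variants(config.variants)
    opts = FitOptions(quad_order=config.quad_order)
    log.info("forward chaining %d specs (stride %d)", len(specs), config.refit_stride)
    t0 = time.time()
    table = forward_chaining(ds, specs, refit_stride=config.refit_stride,
                             min_train_days=config.min_train_days, fit_options=opts)
    log.info("scored %d records in %.1fs (%d flagged gaps)",
             len(table.records), time.time() - t0, len(table.metadata["gaps"]))
    table.to_csv(out / "scores.csv")
    table.metadata["seed"] = config.seed
    with open(out / "scores_meta.json", "w") as fh:
        json.dump(table.metadata, fh, indent=1, default=str)

    variant_labels = sorted(v for v in table.records["model_variant"].unique()
                            if v not in ("uniform", "historical"))
    if "no-covariate" in variant_labels and len(variant_labels) > 1:
        rows = []
        for v in variant_labels:
            if v == "no-covariate":
                continue
            diff = paired_score_difference(table, table, "no-covariate", v)
            diff.insert(0, "variant", v)
            rows.append(diff)
        pd.concat(rows).to_csv(out / "paired_differences.csv", index=False)

    single_covs = [v.split(":", 1)[1] for v in config.variants if v.startswith("single:")]
    if single_covs:
        models = []
        for sign in SIGNS:
            for cov in single_covs:
                pairs = extract_transition_pairs(ds, sign, (cov,))
                opts_se = FitOptions(quad_order=config.quad_order, compute_se=True)
                models.append(fit_sign_model(pairs, ModelSpec(sign, (cov,)), opts_se))
        coefficient_table(models).to_csv(out / "coefficients.csv", index=False)

    if make_figures:
        render_figures(table, out)
    return out / "scores.csv"


def render_figures(table: ScoreTable, out_dir) -> list[Path]:
    """Learning-curve figures per sign (model variants vs benchmarks)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    paths = []
    variants = table.records["model_variant"].unique()
    fig, axes = plt.subplots(2, 3, figsize=(13, 7), sharex=True)
    for ax, sign in zip(axes.ravel(), SIGNS):
        for v in variants:
            lc = learning_curve(table, v, sign)
            if lc.empty:
                continue
            ax.plot(lc["test_day"], lc["smoothed"], label=v)
            ax.fill_between(lc["test_day"], lc["lo"], lc["hi"], alpha=0.2)
        ax.set_title(sign)
        ax.set_xlabel("test day")
        ax.set_ylabel("RPS")
    axes[0, 0].legend(fontsize=7)
    fig.tight_layout()
    p = out / "learning_curves.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths


def run_report(score_table_paths: Sequence, out_path) -> Path:
    """Single text summary of one or more persisted score tables."""
    paths = [Path(p) for p in score_table_paths]
    if not paths:
        raise ValueError("no score tables given")
    lines = ["# adforecast validation report", ""]
    tables = []
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(p)
        t = ScoreTable.read_csv(p)
        tables.append((p, t))
        lines.append(f"## {p}")
        summary = (t.records.groupby(["sign", "model_variant", "score_type"])
                   ["score_value"].agg(["mean", "count"]))
        lines.append(summary.round(5).to_string())
        lines.append("")
    if len(tables) == 2:
        lines.append("## paired comparison (first vs second table)")

        def model_variant(t):
            vs = [v for v in t.records["model_variant"].unique()
                  if v not in ("uniform", "historical")]
            return "no-covariate" if "no-covariate" in vs else (vs[0] if vs else None)

        try:
            va, vb = model_variant(tables[0][1]), model_variant(tables[1][1])
            diff = paired_score_difference(tables[0][1], tables[1][1], va, vb)
            lines.append(f"{va} vs {vb}")
            lines.append(diff.round(5).to_string(index=False))
        except ValueError as exc:
            lines.append(f"not comparable: {exc}")
        lines.append("")
    out = Path(out_path)
    out.write_text("\n".join(lines))
    return out
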