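"""End-to-end orchestration: simulate → score → train → stratify → compare.

A run either generates a synthetic cohort or loads a cohort CSV, scores
the three instruments, trains the auto-associative network on the
standardized feature matrix, computes per-subject fit R, stratifies the
cohort at the 25th/75th R percentiles and writes the group-comparison
and multiplication-factor tables.  Every artifact lands in the output
directory and a JSON manifest records the configuration, the expanded
per-stage seeds, the package version and the pooled train/test/all R,
so identical config+seed reproduces every file byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from lbpanomaly import __version__ as _pkg_version
from lbpanomaly.cohort import (BASE_COLUMNS, CohortConfig, DASS_COLUMNS,
                               ODI_COLUMNS, PCS_COLUMNS, generate_cohort,
                               read_cohort_csv, write_cohort_csv)
from lbpanomaly.errors import PipelineError, ValidationError
from lbpanomaly.groupstats import build_comparison_table
from lbpanomaly.network import (TrainConfig, build_feature_matrix, forward,
                                save_model, train)
from lbpanomaly.scoring import score_cohort
from lbpanomaly.stratify import fit_all, fits_to_frame, stratify

__all__ = ["RunConfig", "run_pipeline", "validate_cohort_csv",
           "STAGE_EXIT_CODES"]

log = logging.getLogger("lbpanomaly")

STAGE_EXIT_CODES = {
    "simulate": 2,
    "validate": 3,
    "score": 4,
    "train": 5,
    "stratify": 6,
    "compare": 7,
    "write": 8,
}


@dataclass
class RunConfig:
    """One pipeline run: data source, training settings, outputs."""

    out_dir: str | Path = "run"
    seed: int = 0
    cohort_csv: str | Path | None = None       # load this cohort...
    cohort_config: CohortConfig | None = None  # ...or simulate one
    train_config: TrainConfig | None = None
    with_truth: bool = False
    make_plots: bool = False

    def __post_init__(self):
        if self.cohort_csv is not None and self.cohort_config is not None:
            raise ValidationError(
                "give either a cohort CSV or a generator config, not both")


def _expand_seeds(seed: int) -> dict[str, int]:
    """Derive per-stage seeds from the top-level seed (documented order)."""
    rng = np.random.default_rng(seed)
    return {
        "cohort": int(rng.integers(2 ** 31)),
        "train": int(rng.integers(2 ** 31)),
    }


def validate_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Load and validate a cohort CSV; raises with row/column detail."""
    path = Path(path)
    if not path.exists():
        raise PipelineError("validate", f"no such file: {path}")
    try:
        df = read_cohort_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface parse errors
        raise PipelineError("validate", f"cannot parse {path}: {exc}")
    if df.empty:
        raise PipelineError("validate", f"{path} holds no subjects")
    return validate_cohort(df)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Schema and range validation of an in-memory cohort table."""
    problems: list[str] = []
    required = BASE_COLUMNS + ODI_COLUMNS + DASS_COLUMNS + PCS_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PipelineError("validate", f"missing columns: {missing}")
    if df["id"].duplicated().any():
        problems.append("duplicate subject ids")

    def check_range(cols, lo, hi, allow_na=False):
        for c in cols:
            col = df[c]
            if not allow_na and col.isna().any():
                rows = df.index[col.isna()].tolist()[:5]
                problems.append(f"{c}: missing values at rows {rows}")
                continue
            bad = col.dropna().astype(float)
            out = bad[(bad < lo) | (bad > hi) | (bad % 1 != 0)]
            if len(out):
                problems.append(
                    f"{c}: values outside {lo}..{hi} at rows "
                    f"{out.index.tolist()[:5]}")

    check_range(ODI_COLUMNS, 0, 5, allow_na=True)
    check_range(DASS_COLUMNS, 0, 3)
    check_range(PCS_COLUMNS, 0, 4)
    check_range(["mental_illness_dx", "lumbar_pathology_dx"], 0, 1)
    if (df["lbp_events_6wk"] < 0).any():
        problems.append("lbp_events_6wk: negative counts")
    if not df["sex"].isin(["F", "M"]).all():
        problems.append("sex: values other than F/M")
    all_skipped = df[ODI_COLUMNS].isna().all(axis=1)
    if all_skipped.any():
        problems.append(
            f"ODI: all items skipped at rows {df.index[all_skipped].tolist()[:5]}")
    if problems:
        raise PipelineError("validate", "; ".join(problems))
    return df


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _expand_seeds(cfg.seed)
    log.info("pipeline start: seed=%d out=%s", cfg.seed, out)

    # -- stage: simulate / load -------------------------------------
    if cfg.cohort_csv is not None:
        cohort = validate_cohort_csv(cfg.cohort_csv)
        log.info("loaded cohort: %d subjects from %s", len(cohort),
                 cfg.cohort_csv)
    else:
        try:
            gen_cfg = cfg.cohort_config or CohortConfig(seed=seeds["cohort"])
            if cfg.cohort_config is not None:
                gen_cfg = dataclasses.replace(gen_cfg, seed=seeds["cohort"])
            cohort = generate_cohort(gen_cfg)
        except ValidationError as exc:
            raise PipelineError("simulate", str(exc))
        write_cohort_csv(cohort, out / "cohort.csv",
                         with_truth=cfg.with_truth)
        log.info("simulated cohort: %d subjects (seed %d)", len(cohort),
                 seeds["cohort"])
    if len(cohort) < 10:
        raise PipelineError("simulate", "cohort too small to analyse")

    # -- stage: score ------------------------------------------------
    try:
        scores = score_cohort(cohort)
    except ValidationError as exc:
        raise PipelineError("score", str(exc))
    scores.to_csv(out / "scores.csv", index=False)
    log.info("scored %d subjects", len(scores))

    # -- stage: train ------------------------------------------------
    tcfg = dataclasses.replace(cfg.train_config or TrainConfig(),
                               seed=seeds["train"])
    try:
        fm = build_feature_matrix(cohort, scores)
        params, report = train(fm, tcfg)
    except ValidationError as exc:
        raise PipelineError("train", str(exc))
    save_model(out / "model.json", params, fm, report)
    log.info("trained: epochs=%d stop=%s mse=%.3g R(train/test/all)="
             "%.4f/%.4f/%.4f", report.epochs, report.stop_reason,
             report.final_mse, report.r_train, report.r_test, report.r_all)

    # -- stage: stratify ---------------------------------------------
    try:
        outputs = forward(params, fm.values)
        fits = fit_all(fm.values, outputs, ids=fm.ids)
        groups = stratify(fits)
    except ValidationError as exc:
        raise PipelineError("stratify", str(exc))
    fit_frame = fits_to_frame(fits, groups)
    fit_frame[["id", "R", "slope", "intercept"]].to_csv(
        out / "fits.csv", index=False)
    fit_frame[["id", "R", "group", "change_flag"]].to_csv(
        out / "groups.csv", index=False)
    sizes = fit_frame["group"].value_counts().sort_index()
    log.info("stratified: group sizes %s", sizes.to_dict())

    # -- stage: compare ----------------------------------------------
    try:
        comparison, mf = build_comparison_table(cohort, scores, fit_frame)
    except ValidationError as exc:
        raise PipelineError("compare", str(exc))
    comparison.to_csv(out / "comparison.csv", index=False)
    mf.to_csv(out / "mf.csv", index=False)
    log.info("comparison table: %d cells", len(comparison))

    if cfg.make_plots:
        _plot_mf(mf, out / "mf_profiles.png")

    manifest = {
        "package_version": _pkg_version,
        "seed": cfg.seed,
        "stage_seeds": seeds,
        "cohort_source": (str(cfg.cohort_csv) if cfg.cohort_csv
                          else "simulated"),
        "cohort_config": (cohort.attrs.get("config")
                          if cfg.cohort_csv is None else None),
        "train_config": dataclasses.asdict(tcfg),
        "n_subjects": int(len(cohort)),
        "epochs": report.epochs,
        "stop_reason": report.stop_reason,
        "final_mse": report.final_mse,
        "alpha": report.alpha,
        "beta": report.beta,
        "gamma": report.gamma,
        "r_train": report.r_train,
        "r_test": report.r_test,
        "r_all": report.r_all,
        "group_sizes": {int(k): int(v) for k, v in sizes.items()},
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    log.info("pipeline done")
    return manifest


def _plot_mf(mf: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4.5))
    for g, sub in mf.groupby("group"):
        ax.plot(sub["variable"], sub["mf"], marker="o",
                label=f"group {g}")
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_ylabel("multiplication factor (group mean / grand mean)")
    ax.tick_params(axis="x", rotation=60)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
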