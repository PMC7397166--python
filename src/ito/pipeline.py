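"""End-to-end two-phase run: LIG phase, LIG ensemble, FT phase, final ensemble.

``run_ito`` executes the whole method on a training/validation dataset
pair: option-grid generation, randomized grid sampling, LIG training and
filtering, greedy LIG ensembling, FT training with per-family parameter
search, FT filtering and ensembling, then the combined and final
ensembles. The LIG ensemble is complete — and, when an output directory
is given, already serialized to ``lig_ensemble.json`` — before any FT
member starts training, so a usable interim model exists while the slow
tuned phase runs.

Every entity is evaluated on the validation set for reporting; filtering
and greedy construction only ever see selection-protocol (out-of-fold
training) predictions unless ``selection_on="holdout"`` is configured.
"""
from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset_io import SUMMARY_ENTITIES, write_report
from .ensembling import (
    build_final_ensemble,
    build_greedy_ensemble,
    filter_successful,
)
from .feature_selection import FSS_METHODS
from .metrics import EvaluationResult, improvement_percentage
from .preprocessing import SCALER_METHODS
from .soldiers import (
    DEFAULT_FT_GRIDS,
    FT_FAMILIES,
    LIG_FAMILIES,
    VALIDATIONS,
    derive_seed,
    evaluate_on_holdout,
    generate_options_grid,
    sample_grid,
    train_ft_soldier,
    train_lig_soldier,
)

log = logging.getLogger("ito")


class ConfigError(ValueError):
    pass


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Run configuration; defaults mirror the reference study conditions."""

    preps: list = field(default_factory=lambda: ["none", "quantile", "robust", "standard"])
    subset_sizes: list = field(default_factory=lambda: [10, 50, 100, 150, 200, 250])
    fss_methods: list = field(default_factory=lambda: ["jmi", "jmim", "mrmr"])
    validations: list = field(default_factory=lambda: ["tenfold_cv", "loocv"])
    lig_families: list = field(default_factory=lambda: ["adaboost", "decision_tree", "extra_trees"])
    ft_families: list = field(default_factory=lambda: ["mlp", "random_forest", "svm"])
    ft_grids: dict | None = None  # per-family overrides of the default grids
    grid_fraction: float = 0.5
    selection_fraction: float = 0.33
    epsilon_lig: float | None = None
    epsilon_ft: float | None = None
    final_strategy: str = "c"
    strict_improvement: bool = False
    selection_on: str = "cv"  # "cv" | "holdout"
    search: str = "exhaustive"  # FT parameter search: "exhaustive" | "random"
    n_random: int | None = None
    n_bins: int = 5
    seed: int = 0
    max_features: int = 5000

    def validate(self) -> None:
        for p in self.preps:
            if p not in SCALER_METHODS:
                raise ConfigError(f"unknown preprocessing method {p!r}")
        for m in self.fss_methods:
            if m not in FSS_METHODS:
                raise ConfigError(f"unknown FSS method {m!r}")
        for v in self.validations:
            if v not in VALIDATIONS:
                raise ConfigError(f"unknown validation method {v!r}")
        for fam in self.lig_families:
            if fam not in LIG_FAMILIES:
                raise ConfigError(f"unknown LIG family {fam!r}")
        for fam in self.ft_families:
            if fam not in FT_FAMILIES:
                raise ConfigError(f"unknown FT family {fam!r}")
        if not 0 < self.grid_fraction <= 1:
            raise ConfigError("grid_fraction must be in (0, 1]")
        if not 0 < self.selection_fraction <= 1:
            raise ConfigError("selection_fraction must be in (0, 1]")
        if self.final_strategy not in ("a", "b", "c"):
            raise ConfigError("final_strategy must be one of a/b/c")
        if self.selection_on not in ("cv", "holdout"):
            raise ConfigError("selection_on must be cv or holdout")
        if self.search not in ("exhaustive", "random"):
            raise ConfigError("search must be exhaustive or random")
        if self.n_bins < 2:
            raise ConfigError("n_bins must be >= 2")

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass
class RunReport:
    """Serializable record of one run: soldiers, ensembles, summary, improvements."""

    config: dict
    soldiers: list
    ensembles: dict
    summary: dict
    member_averages: dict
    improvements: dict
    # live objects for in-process use; not serialized
    objects: dict = field(default_factory=dict, repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "config": _plain(self.config),
            "soldiers": _plain(self.soldiers),
            "ensembles": _plain(self.ensembles),
            "summary": _plain(self.summary),
            "member_averages": _plain(self.member_averages),
            "improvements": _plain(self.improvements),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunReport":
        return cls(
            config=d["config"],
            soldiers=d["soldiers"],
            ensembles=d["ensembles"],
            summary=d["summary"],
            member_averages=d["member_averages"],
            improvements=d["improvements"],
        )


def _plain(obj):
    """Recursively coerce to JSON-stable builtin types."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    return obj


def _eval_dict(ev: EvaluationResult | None):
    return None if ev is None else ev.to_dict()


def _check_alignment(train, valid) -> None:
    if train.feature_ids != valid.feature_ids:
        raise PipelineError("training and validation datasets must share the feature space")


def run_ito(train, valid, config: RunConfig, out_dir=None, force: bool = False) -> RunReport:
    """Execute the full two-phase method and return a run report.

    With ``out_dir`` set, the LIG-phase ensemble is serialized there
    before FT training starts, and the final report files are written at
    the end. ``force`` bypasses the ``max_features`` desk-scale guard.
    """
    config.validate()
    _check_alignment(train, valid)
    if train.n_features > config.max_features and not force:
        raise PipelineError(
            f"{train.n_features} features exceeds max_features={config.max_features}; "
            "feature selection at this width can run for days — pass force=True to proceed"
        )
    out = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
    log.info("run starting: seed=%d, %d train / %d valid samples, %d features",
             config.seed, train.n_samples, valid.n_samples, train.n_features)

    grid = generate_options_grid(
        config.preps, config.subset_sizes, config.fss_methods, config.validations
    )
    log.info("options grid: %d attack vectors", len(grid))
    use_holdout = config.selection_on == "holdout"
    y_sel = valid.labels if use_holdout else train.labels

    def _retarget(soldier):
        # holdout-scored selection: rank/filter/vote on validation predictions
        if use_holdout:
            preds = soldier.predict(valid)
            soldier.selection_predictions = preds
            soldier.selection_eval = EvaluationResult.from_predictions(preds, valid.labels)
        return soldier

    # ---- LIG phase -------------------------------------------------------
    lig_vectors = sample_grid(grid, config.grid_fraction, derive_seed(config.seed, "lig-sample"))
    lig_soldiers = []
    for i, (av, family) in enumerate(itertools.product(lig_vectors, config.lig_families)):
        t0 = time.perf_counter()
        s = train_lig_soldier(train, av, family, derive_seed(config.seed, "lig", i), config.n_bins)
        lig_soldiers.append(_retarget(s))
        log.info("LIG %03d %s %s: rho=%.4f (%.2fs)", i, family, av, s.selection_eval.rho,
                 time.perf_counter() - t0)

    lig_filtered = filter_successful(
        lig_soldiers, epsilon=config.epsilon_lig, fraction=config.selection_fraction
    )
    if lig_filtered:
        lig_ens = build_greedy_ensemble(lig_filtered, y_sel, "lig", config.strict_improvement)
        log.info("LIG ensemble: %d members, selection rho=%.4f", len(lig_ens.members),
                 lig_ens.selection_eval.rho)
    else:
        lig_ens = None
        log.warning("no successful LIG soldiers; continuing to the FT phase")

    soldier_ids = {id(s): f"lig-{i:03d}" for i, s in enumerate(lig_soldiers)}
    if out is not None:
        payload = None if lig_ens is None else lig_ens.to_dict(
            [soldier_ids[id(m)] for m in lig_ens.members]
        )
        with open(out / "lig_ensemble.json", "w") as fh:
            json.dump(_plain(payload), fh, indent=2)
    log.info("LIG phase complete; FT training begins")

    # ---- FT phase --------------------------------------------------------
    ft_vectors = sample_grid(grid, config.grid_fraction, derive_seed(config.seed, "ft-sample"))
    ft_soldiers = []
    for i, (av, family) in enumerate(itertools.product(ft_vectors, config.ft_families)):
        t0 = time.perf_counter()
        grid_override = (config.ft_grids or {}).get(family)
        s = train_ft_soldier(
            train, av, family, derive_seed(config.seed, "ft", i),
            param_grid=grid_override, search=config.search,
            n_random=config.n_random, n_bins=config.n_bins,
        )
        ft_soldiers.append(_retarget(s))
        log.info("FT %03d %s %s: rho=%.4f (%.2fs)", i, family, av, s.selection_eval.rho,
                 time.perf_counter() - t0)
    soldier_ids.update({id(s): f"ft-{i:03d}" for i, s in enumerate(ft_soldiers)})

    ft_filtered = filter_successful(
        ft_soldiers, epsilon=config.epsilon_ft, fraction=config.selection_fraction
    )
    if ft_filtered:
        ft_ens = build_greedy_ensemble(ft_filtered, y_sel, "ft", config.strict_improvement)
    else:
        ft_ens = None
        log.warning("no successful FT soldiers")

    if not lig_filtered and not ft_filtered:
        raise PipelineError("no successful soldiers in either phase")

    combined = build_final_ensemble(
        lig_filtered, ft_filtered, "a", y_sel, lig_ens, ft_ens,
        strict=config.strict_improvement, tag="combined",
    )
    final = build_final_ensemble(
        lig_filtered, ft_filtered, config.final_strategy, y_sel, lig_ens, ft_ens,
        strict=config.strict_improvement, tag="final",
    )

    # construction guarantees, asserted on every run
    for ens in (e for e in (lig_ens, ft_ens, final) if e is not None):
        traj = ens.rho_trajectory
        assert all(b >= a for a, b in zip(traj, traj[1:])), "rho trajectory decreased"
        assert ens.selection_eval.rho >= max(ens.member_rhos) - 1e-12
    best_rho = max(s.selection_eval.rho for s in lig_filtered + ft_filtered)
    if config.final_strategy == "c":
        assert final.selection_eval.rho >= best_rho - 1e-12

    # ---- holdout evaluation and reporting -------------------------------
    for s in lig_soldiers + ft_soldiers:
        s.holdout_eval = evaluate_on_holdout(s, valid)
    ensembles = {"lig_ensemble": lig_ens, "ft_ensemble": ft_ens, "combined": combined, "final": final}
    for ens in ensembles.values():
        if ens is not None:
            ens.holdout_eval = evaluate_on_holdout(ens, valid)

    def _best(filtered):
        return filtered[0] if filtered else None

    lig_best, ft_best = _best(lig_filtered), _best(ft_filtered)
    summary = {
        "lig_member_best": _eval_dict(lig_best.holdout_eval if lig_best else None),
        "ft_member_best": _eval_dict(ft_best.holdout_eval if ft_best else None),
        "lig_ensemble": _eval_dict(lig_ens.holdout_eval if lig_ens else None),
        "ft_ensemble": _eval_dict(ft_ens.holdout_eval if ft_ens else None),
        "combined": _eval_dict(combined.holdout_eval),
        "final": _eval_dict(final.holdout_eval),
    }

    def _averages(filtered):
        if not filtered:
            return None
        evs = [s.holdout_eval for s in filtered]
        return {
            "n_members": len(filtered),
            "avg_accuracy": float(np.mean([e.accuracy for e in evs])),
            "avg_mcc": float(np.mean([e.mcc for e in evs])),
            "avg_rho": float(np.mean([e.rho for e in evs])),
        }

    member_averages = {"lig": _averages(lig_filtered), "ft": _averages(ft_filtered)}

    table5 = _summary_frame(summary)
    improvements = _improvement_dict(improvement_table(table5))

    report = RunReport(
        config=config.to_dict(),
        soldiers=[
            dict(s.to_dict(), id=soldier_ids[id(s)]) for s in lig_soldiers + ft_soldiers
        ],
        ensembles={
            name: None if ens is None else ens.to_dict([soldier_ids[id(m)] for m in ens.members])
            for name, ens in ensembles.items()
        },
        summary=summary,
        member_averages=member_averages,
        improvements=improvements,
        objects={
            "lig_soldiers": lig_soldiers,
            "ft_soldiers": ft_soldiers,
            "lig_filtered": lig_filtered,
            "ft_filtered": ft_filtered,
            **ensembles,
        },
    )
    if out is not None:
        write_report(report, out)
        log.info("report written to %s", out)
    return report


# ---------------------------------------------------------------------------
# summary tables
# ---------------------------------------------------------------------------

_MEASURES = ("accuracy", "mcc", "rho")


def _summary_frame(summary: dict) -> pd.DataFrame:
    data = {}
    for entity in SUMMARY_ENTITIES:
        row = summary.get(entity)
        data[entity] = [np.nan if row is None else row[m] for m in _MEASURES]
    return pd.DataFrame(data, index=list(_MEASURES))


def summary_table(report: RunReport) -> pd.DataFrame:
    """Measures x entities table of holdout metrics (NaN where unavailable)."""
    return _summary_frame(report.summary)


def improvement_table(table5: pd.DataFrame) -> pd.DataFrame:
    """Percentage improvement of the final column over every other, 2 dp."""
    final = table5["final"]
    cols = [c for c in table5.columns if c != "final"]
    out = {}
    for c in cols:
        vals = []
        for m in table5.index:
            f, b = final[m], table5.at[m, c]
            if np.isnan(f) or np.isnan(b):
                vals.append(np.nan)
            else:
                imp = improvement_percentage(f, b)
                vals.append(np.nan if imp is None else round(imp, 2))
        out[c] = vals
    return pd.DataFrame(out, index=table5.index)


def _improvement_dict(table6: pd.DataFrame) -> dict:
    return {
        m: {c: (None if np.isnan(table6.at[m, c]) else float(table6.at[m, c])) for c in table6.columns}
        for m in table6.index
    }


def make_summary_tables(report: RunReport):
    """(metrics table, improvement table) for a completed run."""
    t5 = summary_table(report)
    return t5, improvement_table(t5)
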