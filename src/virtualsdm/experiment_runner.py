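"""Factorial virtual-ecologist experiment.

Runs the full crossed design — species specialisation × SDM algorithm × grid
resolution × occurrence sample size × positional-accuracy level — with 25
model runs (5 CV folds × 5 background replicates) per cell, and collects for
every run both performance metrics (standard held-out AUC/TSS and independent
AUC/TSS against fresh true presences/absences) and reliability metrics
(Schoener's D and OCCC of the predicted surface against the true suitability,
plus D/OCCC of each degraded-occurrence prediction against the matching
precise-occurrence prediction).

Occurrence samples and background sets are shared across algorithms within a
factor cell, as when one dataset is handed to several modelling engines; all
randomness is derived from ``master_seed`` by hashing the factor levels, so
any cell is reproducible in isolation and results do not depend on execution
order.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._seeds import derive_seed
from .errors import ParameterError
from .metrics import evaluate_scores, independent_evaluation, occc, schoeners_d
from .occurrence_sampler import degrade_positions, sample_presences
from .predictor_prep import vifstep
from .raster import EnvStack, GridSpec, bilinear_resample
from .sdm_engine import CVPlan, ModelSpec, cross_validate, predict_surface
from .synthetic_env import default_correlation, generate_env_stack
from .virtual_species import SPECIALISATION_SIGMA, make_species

__all__ = [
    "ExperimentConfig",
    "build_environment",
    "run_experiment",
    "summarize",
    "min_sample_size",
]

log = logging.getLogger(__name__)

#: Results-table columns, one row per model run.
RESULT_COLUMNS = [
    "species",
    "algorithm",
    "resolution",
    "sample_size",
    "precision_level",
    "replicate",
    "fold",
    "auc_standard",
    "tss_standard",
    "sensitivity_standard",
    "specificity_standard",
    "tss_threshold_standard",
    "auc_independent",
    "tss_independent",
    "sensitivity_independent",
    "specificity_independent",
    "schoeners_d_truth",
    "occc_truth",
    "schoeners_d_vs_precise",
    "occc_vs_precise",
]


@dataclass
class ExperimentConfig:
    """Factor levels, environment geometry and seeds of one experiment."""

    species_labels: tuple[str, ...] = tuple(SPECIALISATION_SIGMA)
    algorithms: tuple[str, ...] = ("GLM", "GAM", "GBM", "RF", "MAXENT")
    resolutions: tuple[str, ...] = ("high", "low")
    sample_sizes: tuple[int, ...] = (5, 10, 20, 50, 100, 200)
    precision_levels: tuple[int, ...] = (0, 1, 2, 3)
    k_folds: int = 5
    background_replicates: int = 5
    background_size: int = 1000
    # synthetic environment
    n_rows: int = 100
    n_cols: int = 100
    n_layers: int = 27
    n_redundant_layers: int = 12
    smoothness: float = 5.0
    downscale_factor: int = 4
    species_n_layers: int = 4
    vif_threshold: float = 10.0
    # evaluation
    n_eval: int = 500
    auc_cut: float = 0.7
    tss_cut: float = 0.4
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "species_labels",
            "algorithms",
            "resolutions",
            "sample_sizes",
            "precision_levels",
        ):
            if not getattr(self, name):
                raise ParameterError(f"factor list {name!r} must be non-empty")

    @property
    def n_runs(self) -> int:
        """Closed-form row count of the full design."""
        return (
            len(self.species_labels)
            * len(self.algorithms)
            * len(self.resolutions)
            * len(self.sample_sizes)
            * len(self.precision_levels)
            * self.k_folds
            * self.background_replicates
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in (
            "species_labels",
            "algorithms",
            "resolutions",
            "sample_sizes",
            "precision_levels",
        ):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class Environment:
    """Per-resolution stacks and species shared by all factor cells."""

    stacks: dict[str, EnvStack]
    reduced_stacks: dict[str, EnvStack]
    species: dict[tuple[str, str], object]  # (resolution, label) -> VirtualSpecies
    removal_logs: dict[str, pd.DataFrame] = field(default_factory=dict)


def build_environment(config: ExperimentConfig) -> Environment:
    """Generate stacks, VIF-reduce them and build every species.

    The high-resolution stack is generated directly; the low-resolution stack
    is its factor-``downscale_factor`` bilinear resample, mirroring a
    coarse-grid version of the same predictors.  Species niches are built per
    resolution from the PCA of the first ``species_n_layers`` layers (the
    small set of eco-physiologically "causal" variables), while models see
    the full VIF-reduced stack.
    """
    spec_high = GridSpec(n_rows=config.n_rows, n_cols=config.n_cols)
    corr = default_correlation(config.n_layers, config.n_redundant_layers)
    stack_high = generate_env_stack(
        spec_high,
        config.n_layers,
        target_correlation=corr,
        smoothness=config.smoothness,
        seed=derive_seed(config.master_seed, "env"),
    )
    stacks = {"high": stack_high}
    if "low" in config.resolutions:
        spec_low = spec_high.coarsen(config.downscale_factor)
        stacks["low"] = EnvStack(
            [(n, bilinear_resample(stack_high[n], spec_low)) for n in stack_high.names]
        )
    reduced, species, logs = {}, {}, {}
    for res in config.resolutions:
        stack = stacks[res]
        reduced[res], logs[res] = vifstep(
            stack, threshold=config.vif_threshold,
            seed=derive_seed(config.master_seed, "vif", res),
        )
        niche_stack = stack.subset(stack.names[: config.species_n_layers])
        for label in config.species_labels:
            species[(res, label)] = make_species(
                niche_stack, label, resolution_tag=res
            )
    return Environment(
        stacks=stacks, reduced_stacks=reduced, species=species, removal_logs=logs
    )


def _cell_rows(
    config: ExperimentConfig,
    env: Environment,
    label: str,
    res: str,
    algorithm: str,
    n: int,
    level: int,
    precise_surfaces: dict[tuple[int, int], object] | None,
) -> tuple[list[dict], dict[tuple[int, int], object]]:
    """All 25 result rows of one factor cell (plus its surfaces if level 0)."""
    species = env.species[(res, label)]
    stack = env.reduced_stacks[res]
    occ_seed = derive_seed(config.master_seed, "occ", label, res, n)
    occs = sample_presences(species, n, seed=occ_seed)
    occs = degrade_positions(
        occs, level, species.spec,
        seed=derive_seed(config.master_seed, "degrade", label, res, n, level),
    )
    plan = CVPlan(
        k_folds=config.k_folds,
        n_background_replicates=config.background_replicates,
        background_size=config.background_size,
        seed=derive_seed(config.master_seed, "cv", label, res, n),
    )
    model_spec = ModelSpec(
        algorithm,
        seed=derive_seed(config.master_seed, "model", label, res, algorithm, n, level),
    )
    runs = cross_validate(model_spec, occs.points, stack, plan)

    rows = []
    surfaces: dict[tuple[int, int], object] = {}
    for run in runs:
        standard = evaluate_scores(
            run.test_scores, run.test_labels, mode="standard",
            replicate=run.replicate, fold=run.fold,
        )
        indep = independent_evaluation(
            run.model, species, stack, n_eval=config.n_eval,
            seed=derive_seed(
                config.master_seed, "indep", label, res, algorithm,
                n, level, run.replicate, run.fold,
            ),
            replicate=run.replicate, fold=run.fold,
        )
        surface = predict_surface(run.model, stack)
        if level == 0:
            surfaces[(run.replicate, run.fold)] = surface
            d_vs_precise = np.nan
            occc_vs_precise = np.nan
        elif precise_surfaces:
            ref = precise_surfaces[(run.replicate, run.fold)]
            d_vs_precise = schoeners_d(surface, ref)
            occc_vs_precise = occc(surface, ref)
        else:
            d_vs_precise = np.nan
            occc_vs_precise = np.nan
        rows.append(
            {
                "species": label,
                "algorithm": algorithm,
                "resolution": res,
                "sample_size": n,
                "precision_level": level,
                "replicate": run.replicate,
                "fold": run.fold,
                "auc_standard": standard.auc,
                "tss_standard": standard.tss,
                "sensitivity_standard": standard.sensitivity,
                "specificity_standard": standard.specificity,
                "tss_threshold_standard": standard.tss_threshold,
                "auc_independent": indep.auc,
                "tss_independent": indep.tss,
                "sensitivity_independent": indep.sensitivity,
                "specificity_independent": indep.specificity,
                "schoeners_d_truth": schoeners_d(surface, species.suitability),
                "occc_truth": occc(surface, species.suitability),
                "schoeners_d_vs_precise": d_vs_precise,
                "occc_vs_precise": occc_vs_precise,
            }
        )
    return rows, surfaces


def run_experiment(
    config: ExperimentConfig,
    env: Environment | None = None,
    checkpoint_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Execute every factor cell and return the per-run results table.

    Deterministic given ``config.master_seed``.  Per-cell failures are logged
    and recorded in ``results.attrs["failures"]`` instead of aborting the
    experiment.  With ``checkpoint_dir`` set, each (species, resolution,
    algorithm, sample size) group is written to CSV as it completes and
    skipped on re-run, making long experiments resumable.
    """
    if env is None:
        env = build_environment(config)
    if checkpoint_dir is not None:
        checkpoint_dir = Path(checkpoint_dir)
        checkpoint_dir.mkdir(parents=True, exist_ok=True)

    levels = sorted(config.precision_levels)  # level 0 first, if present
    frames: list[pd.DataFrame] = []
    failures: list[dict] = []
    for label in config.species_labels:
        for res in config.resolutions:
            for algorithm in config.algorithms:
                for n in config.sample_sizes:
                    tag = f"{label}_{res}_{algorithm}_{n}"
                    if checkpoint_dir is not None:
                        ckpt = checkpoint_dir / f"cell_{tag}.csv"
                        if ckpt.exists():
                            frames.append(pd.read_csv(ckpt))
                            continue
                    group_rows: list[dict] = []
                    precise_surfaces: dict = {}
                    for level in levels:
                        try:
                            rows, surfaces = _cell_rows(
                                config, env, label, res, algorithm, n, level,
                                precise_surfaces,
                            )
                        except Exception as exc:  # noqa: BLE001 - per-cell isolation
                            log.warning("cell %s level %s failed: %s", tag, level, exc)
                            failures.append(
                                {
                                    "species": label,
                                    "resolution": res,
                                    "algorithm": algorithm,
                                    "sample_size": n,
                                    "precision_level": level,
                                    "reason": str(exc),
                                }
                            )
                            continue
                        if level == 0:
                            precise_surfaces = surfaces
                        group_rows.extend(rows)
                    group = pd.DataFrame(group_rows, columns=RESULT_COLUMNS)
                    if checkpoint_dir is not None:
                        group.to_csv(checkpoint_dir / f"cell_{tag}.csv", index=False)
                    frames.append(group)
    results = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=RESULT_COLUMNS
    )
    results.attrs["failures"] = failures
    return results


_METRIC_COLUMNS = [c for c in RESULT_COLUMNS if c not in (
    "species", "algorithm", "resolution", "sample_size", "precision_level",
    "replicate", "fold",
)]


def summarize(
    results: pd.DataFrame,
    group_by: list[str],
    auc_col: str = "auc_standard",
    tss_col: str = "tss_standard",
    auc_cut: float = 0.7,
    tss_cut: float = 0.4,
) -> pd.DataFrame:
    """Per-group medians and IQRs of every metric, plus the good-model flag.

    A group is a "good model" when its median AUC ≥ ``auc_cut`` *or* its
    median TSS ≥ ``tss_cut``.
    """
    missing = [g for g in group_by if g not in results.columns]
    if missing:
        raise ParameterError(f"unknown grouping factors: {missing}")
    if results.empty:
        raise ParameterError("results table is empty")
    metric_cols = [c for c in _METRIC_COLUMNS if c in results.columns]
    grouped = results.groupby(group_by, sort=True, observed=True)
    out = []
    for key, df in grouped:
        if df.empty:
            raise ParameterError(f"empty group {key}")
        row = dict(zip(group_by, key if isinstance(key, tuple) else (key,)))
        row["n_runs"] = len(df)
        for col in metric_cols:
            vals = df[col].dropna()
            row[f"{col}_median"] = vals.median() if len(vals) else np.nan
            row[f"{col}_iqr"] = (
                vals.quantile(0.75) - vals.quantile(0.25) if len(vals) else np.nan
            )
        row["good"] = bool(
            row.get(f"{auc_col}_median", np.nan) >= auc_cut
            or row.get(f"{tss_col}_median", np.nan) >= tss_cut
        )
        out.append(row)
    return pd.DataFrame(out)


def min_sample_size(
    summary: pd.DataFrame,
    per: list[str] = ("species", "algorithm"),
) -> pd.DataFrame:
    """Smallest sample size flagged good per group, or None when none is.

    Expects a summary grouped at least by ``per`` + ["sample_size"] with a
    ``good`` column.
    """
    per = list(per)
    needed = per + ["sample_size", "good"]
    missing = [c for c in needed if c not in summary.columns]
    if missing:
        raise ParameterError(f"summary is missing columns: {missing}")
    rows = []
    for key, df in summary.groupby(per, sort=True):
        df = df.sort_values("sample_size")
        good_n = df.loc[df["good"], "sample_size"]
        row = dict(zip(per, key if isinstance(key, tuple) else (key,)))
        row["min_sample_size"] = int(good_n.iloc[0]) if len(good_n) else None
        rows.append(row)
    return pd.DataFrame(rows)
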