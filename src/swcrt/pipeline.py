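"""Orchestration of a full simulation study.

``run_study`` drives, for every configuration and replicate: simulate a
trial, fit by REML (with the small-sample correction), optionally fit by
MCMC, and record estimates/intervals — then applies the validity rules and
produces the performance table, the exclusion ledger and per-replicate
CSVs.  Replicates are batched; each batch is written as soon as it
completes, and an interrupted study resumes by skipping batches whose files
already exist.  Seeding is per-replicate (derived from the base seed, the
configuration index and the replicate index), so results are independent of
batch size and worker count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bayes import PriorSpec, SamplerSettings, check_validity, fit_bayes_model
from .datagen import replicate_seed, simulate_trial
from .design import TrialConfig, build_standard_sw, configs_to_frame, enumerate_configs
from .model import SteppedWedgeLMM
from .performance import PerformanceTable, performance_table
from .reml import fit_reml_model

logger = logging.getLogger("swcrt")

__all__ = ["StudySpec", "run_study", "make_report", "ci_preset", "full_preset"]

#: the configuration for which the KR computation is replaced by the
#: Satterthwaite ddf with the unadjusted SE in "auto" mode: at the largest
#: design full KR is memory-hungry in common implementations while, with 40
#: clusters, the cheaper Satterthwaite ddf on the unadjusted SE is adequate
LARGEST_CONFIG = {"S": 5, "T": 9, "m": 100}


@dataclass
class StudySpec:
    """Everything needed to run (and re-run) a study."""

    configs: list[TrialConfig]
    priors: PriorSpec = field(default_factory=PriorSpec)
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    out_dir: str | Path = "study_out"
    batch_size: int = 100
    workers: int = 1
    skip_bayes: bool = False
    skip_kr: bool = False
    keep_draws: bool = False
    kr_mode: str = "auto"  # "auto" | "kr" | "satterthwaite"

    def __post_init__(self) -> None:
        if not self.configs:
            raise ValueError("configs must be non-empty")
        if any(c.n_sim < 1 for c in self.configs):
            raise ValueError("every config needs n_sim >= 1")
        if self.kr_mode not in ("auto", "kr", "satterthwaite"):
            raise ValueError("kr_mode must be auto, kr or satterthwaite")

    def manifest(self) -> pd.DataFrame:
        """One row per (config, replicate) pair, with its seed spawn key."""
        rows = []
        for k, cfg in enumerate(self.configs):
            for rep in range(cfg.n_sim):
                rows.append(
                    {
                        "config": k,
                        "label": cfg.label,
                        "replicate": rep,
                        "base_seed": cfg.base_seed,
                    }
                )
        return pd.DataFrame(rows)


def full_preset(n_sim: int = 1000, base_seed: int = 0) -> list[TrialConfig]:
    """The full 48-configuration grid."""
    return enumerate_configs(n_sim=n_sim, base_seed=base_seed)


def ci_preset(n_sim: int = 100, base_seed: int = 0) -> list[TrialConfig]:
    """Reduced-scale profile: S in {1, 2}, m = 10 only (16 configurations)."""
    grid = {"S": (1, 2), "T": (5, 9), "m": (10,), "rho1": (0.05, 0.1), "cac": (0.8, 1.0)}
    return enumerate_configs(grid, n_sim=n_sim, base_seed=base_seed)


def _kr_method_for(cfg: TrialConfig, kr_mode: str) -> str:
    if kr_mode == "auto":
        is_largest = all(
            getattr(cfg, k) == v for k, v in LARGEST_CONFIG.items()
        )
        return "satterthwaite" if is_largest else "kr"
    return kr_mode


def run_replicate(
    cfg: TrialConfig,
    config_index: int,
    replicate: int,
    spec: StudySpec,
) -> list[dict]:
    """Simulate and fit one replicate; returns per-parameter record dicts."""
    seed = replicate_seed(cfg.base_seed, config_index, replicate)
    sim_seed, bayes_seed = seed.spawn(2)
    design = build_standard_sw(cfg.S, cfg.T)
    data = simulate_trial(cfg, design, seed=sim_seed)
    model = SteppedWedgeLMM.from_dataset(data)
    records: list[dict] = []
    base = {"config": config_index, "replicate": replicate}

    fit = fit_reml_model(model)
    unadj = fit.small_sample("none")
    records.append(
        base
        | {
            "method": "reml",
            "parameter": "theta",
            "estimate": fit.theta_hat,
            "ci_low": unadj.ci_low,
            "ci_upp": unadj.ci_upp,
            "model_variance": fit.se_theta**2,
            "bayes_valid": np.nan,
            "cac_defined": fit.cac_defined,
            "converged": fit.converged,
        }
    )
    if not spec.skip_kr:
        method = _kr_method_for(cfg, spec.kr_mode)
        adj = fit.small_sample(method)
        records.append(
            base
            | {
                "method": "reml_kr",
                "parameter": "theta",
                "estimate": fit.theta_hat,
                "ci_low": adj.ci_low,
                "ci_upp": adj.ci_upp,
                "model_variance": adj.se_adj**2,
                "bayes_valid": np.nan,
                "cac_defined": fit.cac_defined,
                "converged": fit.converged,
                "ddf": adj.ddf,
                "ss_method": adj.method_used,
            }
        )
    records.append(
        base
        | {
            "method": "reml",
            "parameter": "rho1",
            "estimate": fit.rho1_hat,
            "ci_low": np.nan,
            "ci_upp": np.nan,
            "model_variance": np.nan,
            "bayes_valid": np.nan,
            "cac_defined": fit.cac_defined,
        }
    )
    if cfg.structure == "block_exchangeable":
        records.append(
            base
            | {
                "method": "reml",
                "parameter": "cac",
                "estimate": fit.cac_hat if fit.cac_defined else np.nan,
                "ci_low": np.nan,
                "ci_upp": np.nan,
                "model_variance": np.nan,
                "bayes_valid": np.nan,
                "cac_defined": fit.cac_defined,
            }
        )

    if not spec.skip_bayes:
        bres = fit_bayes_model(
            model, priors=spec.priors, settings=spec.sampler, seed=bayes_seed
        )
        valid, reasons = check_validity(bres)
        params = ["theta", "rho1"] + (
            ["cac"] if cfg.structure == "block_exchangeable" else []
        )
        for par in params:
            pooled = bres.pooled(par)
            lo, up = bres.credible_interval(par)
            records.append(
                base
                | {
                    "method": "bayes",
                    "parameter": par,
                    "estimate": float(np.median(pooled)),
                    "ci_low": lo,
                    "ci_upp": up,
                    "model_variance": float(np.var(pooled, ddof=1))
                    if par == "theta"
                    else np.nan,
                    "bayes_valid": valid,
                    "cac_defined": True,
                    "reasons": ",".join(reasons),
                }
            )
        if spec.keep_draws:
            draw_dir = Path(spec.out_dir) / "draws"
            draw_dir.mkdir(parents=True, exist_ok=True)
            np.savez_compressed(
                draw_dir / f"config{config_index}_rep{replicate}.npz",
                **bres.draws,
            )
        logger.info(
            "config=%d rep=%d method=bayes valid=%s reasons=%s",
            config_index, replicate, valid, ",".join(reasons) or "-",
        )
    logger.info(
        "config=%d rep=%d method=reml converged=%s cac_defined=%s",
        config_index, replicate, fit.converged, fit.cac_defined,
    )
    return records


def _run_batch(spec, cfg, config_index, reps) -> pd.DataFrame:
    records = []
    for rep in reps:
        records.extend(run_replicate(cfg, config_index, rep, spec))
    return pd.DataFrame(records)


def run_study(spec: StudySpec) -> PerformanceTable:
    """Run the whole study and write all outputs to ``spec.out_dir``.

    Outputs: ``records.csv`` (per-replicate long format),
    ``performance.csv`` and ``ledger.csv`` (measures and % valid),
    ``configs.csv``, ``manifest.csv`` and ``spec.json``.  Batches that were
    already written by a previous (interrupted) run are not recomputed.
    """
    out = Path(spec.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    batches_dir = out / "batches"
    batches_dir.mkdir(exist_ok=True)

    configs_to_frame(spec.configs).to_csv(out / "configs.csv", index=False)
    spec.manifest().to_csv(out / "manifest.csv", index=False)
    meta = asdict(spec)
    meta["configs"] = [asdict(c) for c in spec.configs]
    meta["out_dir"] = str(spec.out_dir)
    try:
        from importlib.metadata import version

        meta["swcrt_version"] = version("swcrt")
    except Exception:  # pragma: no cover
        meta["swcrt_version"] = "unknown"
    (out / "spec.json").write_text(json.dumps(meta, indent=2))

    tasks = []  # (path, cfg, config_index, reps)
    for k, cfg in enumerate(spec.configs):
        for b0 in range(0, cfg.n_sim, spec.batch_size):
            reps = range(b0, min(b0 + spec.batch_size, cfg.n_sim))
            path = batches_dir / f"config{k}_batch{b0}.csv"
            tasks.append((path, cfg, k, reps))

    todo = [t for t in tasks if not t[0].exists()]
    if spec.workers > 1 and len(todo) > 1:
        from joblib import Parallel, delayed

        frames = Parallel(n_jobs=spec.workers)(
            delayed(_run_batch)(spec, cfg, k, reps) for _, cfg, k, reps in todo
        )
        for (path, *_), frame in zip(todo, frames):
            frame.to_csv(path, index=False)
    else:
        for path, cfg, k, reps in todo:
            _run_batch(spec, cfg, k, reps).to_csv(path, index=False)

    records = pd.concat(
        [pd.read_csv(t[0]) for t in tasks], ignore_index=True
    )
    records = records.sort_values(
        ["config", "replicate", "method", "parameter"], kind="stable"
    ).reset_index(drop=True)
    records.to_csv(out / "records.csv", index=False)

    truths = {
        k: {"theta": c.theta, "rho1": c.rho1, "cac": c.cac}
        for k, c in enumerate(spec.configs)
    }
    perf = performance_table(records, truths)
    perf.to_csv(out / "performance.csv", ledger_path=out / "ledger.csv")
    return perf


# ---------------------------------------------------------------------- #
# reporting


def make_report(perf: PerformanceTable, out_dir, configs: pd.DataFrame | None = None):
    """Render one panel per measure and parameter.

    Layout follows the study's figures: facet rows are the correlation
    scenarios (rho1, r), columns the (T, m) combinations, the x-axis is the
    number of clusters per sequence S, one line/marker set per method.
    Missing cells are left as gaps (with a warning).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = perf.table
    if table is None or len(table) == 0:
        raise ValueError("empty performance table")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if configs is None:
        raise ValueError("make_report needs the configs frame (configs.csv)")
    merged = table.merge(
        configs[["config", "S", "T", "m", "rho1", "cac"]], on="config"
    )

    measures = [
        ("bias", ["theta", "rho1", "cac"]),
        ("mse", ["theta", "rho1", "cac"]),
        ("coverage", ["theta"]),
        ("rel_error_pct", ["theta"]),
        ("width_mean", ["theta"]),
    ]
    written = []
    for measure, params in measures:
        if measure not in merged.columns:
            continue
        for par in params:
            sub = merged[(merged["parameter"] == par)].dropna(subset=[measure])
            if len(sub) == 0:
                continue
            scen = sorted(
                sub.groupby(["rho1", "cac"]).groups.keys()
            )
            cells = sorted(sub.groupby(["T", "m"]).groups.keys())
            fig, axes = plt.subplots(
                len(scen), len(cells),
                figsize=(3.0 * len(cells), 2.4 * len(scen)),
                squeeze=False, sharey=True,
            )
            for i, (rho1, cac) in enumerate(scen):
                for j, (T, m) in enumerate(cells):
                    ax = axes[i][j]
                    cell = sub[
                        (sub["rho1"] == rho1) & (sub["cac"] == cac)
                        & (sub["T"] == T) & (sub["m"] == m)
                    ]
                    if len(cell) == 0:
                        logger.warning(
                            "missing cell rho1=%s cac=%s T=%s m=%s",
                            rho1, cac, T, m,
                        )
                    for method, grp in cell.groupby("method"):
                        grp = grp.sort_values("S")
                        ax.plot(
                            grp["S"], grp[measure], "o-", ms=4, label=method
                        )
                    if measure == "coverage":
                        ax.axhline(0.95, color="grey", lw=0.6, ls="--")
                    elif measure in ("bias", "rel_error_pct"):
                        ax.axhline(0.0, color="grey", lw=0.6, ls="--")
                    ax.set_xticks(sorted(sub["S"].unique()))
                    if i == 0:
                        ax.set_title(f"T={T}, m={m}", fontsize=9)
                    if j == 0:
                        ax.set_ylabel(
                            f"rho1={rho1}\nr={cac}", fontsize=8
                        )
                    if i == len(scen) - 1:
                        ax.set_xlabel("S (clusters/sequence)", fontsize=8)
            axes[0][-1].legend(fontsize=7, loc="best")
            fig.suptitle(f"{measure} for {par}", fontsize=11)
            fig.tight_layout()
            path = out_dir / f"{measure}_{par}.png"
            fig.savefig(path, dpi=130)
            plt.close(fig)
            written.append(path)
    return written
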