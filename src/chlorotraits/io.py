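"""Table I/O, configuration, and the end-to-end pipeline.

Assay panels are interchanged as plain CSV tables with fixed,
case-sensitive headers; units are encoded in the column names
(``time_h``, ``pfu_per_ml``). Configuration is a flat YAML mapping; a
SHA-256 hash of the canonical config is stamped as a comment line on
every output table so results can be traced to the settings that
produced them. All randomness flows from the single config seed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimation, stats
from .growth import fit_observed_growth, predict_growth_rate
from .synthetic import AssayDataset

logger = logging.getLogger("chlorotraits.io")

__all__ = ["PanelConfig", "SCHEMAS", "read_panel", "write_panel", "run_pipeline"]

#: Exact, case-sensitive column schemas of the interchange tables.
SCHEMAS: dict[str, list[str]] = {
    "strains": ["strain_id", "species", "type_host", "genome_size_kb"],
    "adsorption": ["strain_id", "replicate", "time_h", "free_pfu_per_ml", "host_density"],
    "depolarization": ["strain_id", "replicate", "cells_total", "cells_depolarized",
                       "adsorbed_moi"],
    "onestep": ["strain_id", "replicate", "time_h", "infectious_centers_per_ml",
                "free_pfu_per_ml", "depolarized_cells_per_ml"],
    "decay": ["strain_id", "replicate", "time_h", "pfu_per_ml"],
    "growth": ["strain_id", "replicate", "time_h", "pfu_per_ml"],
}

ASSAY_TABLES = ("adsorption", "depolarization", "onestep", "decay", "growth")


@dataclass
class PanelConfig:
    """Settings for a full pipeline run."""

    data_dir: str | None = None          # directory holding the CSV tables
    simulate: bool = False               # generate a synthetic panel instead
    n_strains: int = 34                  # panel size when simulating
    out_dir: str = "results"
    seed: int = 0
    # estimation
    n_boot: int = 1000
    # growth
    host_density: float = 1e7            # cells/mL for growth predictions
    solver_tol: float = 1e-9
    growth_window: tuple[float, float] | None = None
    # comparative statistics
    n_perm: int = 9999
    weight_rule: str = "product"

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError(f"n_boot must be >= 1, got {self.n_boot}")
        if self.n_perm < 1:
            raise ValueError(f"n_perm must be >= 1, got {self.n_perm}")
        if self.host_density <= 0:
            raise ValueError("host_density must be positive")
        if self.weight_rule not in ("product", "sum"):
            raise ValueError(f"unknown weight_rule '{self.weight_rule}'")
        if not self.simulate and self.data_dir is None:
            raise ValueError("either data_dir or simulate=True is required")
        if self.n_strains < 1:
            raise ValueError("n_strains must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PanelConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if raw.get("growth_window") is not None:
            raw["growth_window"] = tuple(raw["growth_window"])
        return cls(**raw)

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir", None)  # analysis settings only, not output location
        if d.get("growth_window") is not None:
            d["growth_window"] = list(d["growth_window"])
        canon = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Reading and writing panels

def _check_header(df: pd.DataFrame, table: str, path) -> None:
    expected = SCHEMAS[table]
    actual = list(df.columns)
    unknown = [c for c in actual if c not in expected]
    missing = [c for c in expected if c not in actual]
    if unknown or missing:
        parts = []
        if unknown:
            parts.append(f"unknown columns {unknown}")
        if missing:
            parts.append(f"missing columns {missing}")
        raise ValueError(f"{path}: table '{table}' has {' and '.join(parts)}; "
                         f"expected exactly {expected}")


def read_panel(source) -> tuple[dict[str, AssayDataset], pd.DataFrame]:
    """Load a panel of assay tables from a directory (or a PanelConfig).

    Returns ``(datasets, strains)`` where ``datasets`` maps strain_id to
    an AssayDataset. A missing assay file marks that assay absent for
    every strain (downstream traits get flagged); missing ``strains.csv``
    is an error. Row counts are logged per table.
    """
    if isinstance(source, PanelConfig):
        if source.data_dir is None:
            raise ValueError("config has no data_dir to read from")
        directory = Path(source.data_dir)
    else:
        directory = Path(source)
    strains_path = directory / "strains.csv"
    if not strains_path.exists():
        raise FileNotFoundError(f"missing required table: {strains_path}")
    strains = pd.read_csv(strains_path, comment="#")
    _check_header(strains, "strains", strains_path)

    tables: dict[str, pd.DataFrame | None] = {}
    for name in ASSAY_TABLES:
        path = directory / f"{name}.csv"
        if not path.exists():
            logger.warning("assay table %s absent; dependent traits will be flagged", path)
            tables[name] = None
            continue
        df = pd.read_csv(path, comment="#")
        _check_header(df, name, path)
        logger.info("read %s: %d rows", path, len(df))
        tables[name] = df

    datasets: dict[str, AssayDataset] = {}
    for sid in strains["strain_id"]:
        kwargs = {}
        for name in ASSAY_TABLES:
            df = tables[name]
            if df is None:
                kwargs[name] = None
            else:
                sub = df[df["strain_id"] == sid].drop(columns="strain_id")
                kwargs[name] = sub.reset_index(drop=True) if len(sub) else None
        datasets[sid] = AssayDataset(strain_id=sid, **kwargs)
    return datasets, strains


def write_panel(datasets: dict[str, AssayDataset], strains: pd.DataFrame,
                outdir, truth: pd.DataFrame | None = None) -> None:
    """Write a panel to CSV tables (one file per assay, strains.csv, and
    optionally the ground-truth trait table for synthetic panels)."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        strains.to_csv(outdir / "strains.csv", index=False)
        for name in ASSAY_TABLES:
            parts = []
            for sid, ds in datasets.items():
                df = getattr(ds, name)
                if df is not None:
                    parts.append(df.assign(strain_id=sid))
            if parts:
                full = pd.concat(parts, ignore_index=True)
                full = full[SCHEMAS[name]]
                full.to_csv(outdir / f"{name}.csv", index=False)
        if truth is not None:
            truth.to_csv(outdir / "true_traits.csv", index=False)
    except OSError as e:
        raise OSError(f"failed writing panel to {outdir}: {e}") from e


# ---------------------------------------------------------------------------
# Pipeline

def _write_table(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as f:
        f.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(f, index=False)


def run_pipeline(config: PanelConfig) -> dict[str, pd.DataFrame]:
    """Run the full analysis: estimation, growth, comparative statistics.

    Deterministic given the config (including its seed). Per-strain
    estimation failures are logged and flagged, never fatal; outputs are
    written to ``config.out_dir`` with the config hash stamped on every
    table, alongside a line-structured run log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    log_lines = [f"config_hash={cfg_hash} seed={config.seed} "
                 f"numpy={np.__version__} pandas={pd.__version__}"]

    if config.simulate:
        from .synthetic import build_panel
        panel_dir = out / "panel"
        datasets, _truth, strains = build_panel(
            n_strains=config.n_strains, seed=config.seed, outdir=panel_dir)
        log_lines.append(f"simulated panel n_strains={config.n_strains} -> {panel_dir}")
    else:
        datasets, strains = read_panel(config)
        log_lines.append(f"read panel from {config.data_dir}: {len(datasets)} strains")

    rng = np.random.default_rng(config.seed)
    strain_seeds = rng.integers(0, 2**31 - 1, size=len(datasets))

    profiles = []
    obs_rows = []
    pred_rows = []
    for (sid, ds), sseed in zip(datasets.items(), strain_seeds):
        prof = estimation.estimate_profile(ds, n_boot=config.n_boot, seed=int(sseed))
        profiles.append(prof)
        flagged = prof.flagged_traits
        level = logging.WARNING if flagged else logging.INFO
        logger.log(level, "strain %s estimated; flagged traits: %s",
                   sid, ",".join(flagged) or "none")
        log_lines.append(f"strain={sid} stage=estimate flagged={','.join(flagged) or '-'}")

        tr = prof.traits
        if all(np.isfinite(tr[t].estimate) for t in ("s", "k", "mu_l", "b_r")):
            gp = predict_growth_rate(
                tr["s"].estimate, tr["k"].estimate, tr["mu_l"].estimate,
                tr["b_r"].estimate, config.host_density, strain_id=sid,
                residual_tol=config.solver_tol)
            pred_rows.append({
                "strain_id": sid, "lambda_pred": gp.lambda_pred,
                "host_density": gp.host_density, "converged": gp.converged,
                "residual": gp.residual, "flags": ";".join(gp.flags),
            })
        else:
            pred_rows.append({"strain_id": sid, "lambda_pred": np.nan,
                              "host_density": config.host_density,
                              "converged": False, "residual": np.nan,
                              "flags": "missing_inputs"})
            log_lines.append(f"strain={sid} stage=growth_prediction flagged=missing_inputs")

        if ds.growth is not None:
            og = fit_observed_growth(ds.growth, window=config.growth_window,
                                     n_boot=config.n_boot, seed=int(sseed), strain_id=sid)
            obs_rows.append({"strain_id": sid, "lambda_obs": og.lambda_obs,
                             "lambda_lo": og.ci_low, "lambda_hi": og.ci_high,
                             "n_points": og.n_points, "flags": ";".join(og.flags)})
        else:
            obs_rows.append({"strain_id": sid, "lambda_obs": np.nan,
                             "lambda_lo": np.nan, "lambda_hi": np.nan,
                             "n_points": 0, "flags": "missing:no_growth_data"})

    prof_df = estimation.profiles_to_frame(profiles)
    prof_masked = estimation.profiles_to_frame(profiles, drop_flagged=True)
    pred_df = pd.DataFrame(pred_rows)
    obs_df = pd.DataFrame(obs_rows)
    meta = strains.set_index("strain_id")
    prof_masked = prof_masked.merge(strains, on="strain_id", how="left")

    # fold ranges over non-missing positive estimates
    fold_rows = []
    for trait in estimation.TRAIT_NAMES:
        vals = prof_masked[trait].to_numpy(float)
        vals = vals[np.isfinite(vals) & (vals > 0)]
        try:
            fr = stats.fold_range(vals)
        except ValueError:
            fr = np.nan
        fold_rows.append({"trait": trait, "fold_range": fr, "n": len(vals)})
    fold_df = pd.DataFrame(fold_rows)

    stat_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    vp_rows = []
    for trait in estimation.TRAIT_NAMES:
        try:
            vp = stats.host_variance_partition(
                prof_masked, trait, n_perm=config.n_perm,
                seed=int(stat_rng.integers(0, 2**31 - 1)))
            vp_rows.append({"trait": trait, "r_squared": vp.r_squared,
                            "p_value": vp.p_value, "groups": vp.groups, "n": vp.n})
        except ValueError as e:
            log_lines.append(f"stage=variance_partition trait={trait} skipped: {e}")
    vp_df = pd.DataFrame(vp_rows)

    merged = pred_df.merge(obs_df, on="strain_id")
    try:
        rho, pval = stats.correlate_predicted_observed(
            merged["lambda_pred"], merged["lambda_obs"])
        corr_df = pd.DataFrame([{"rho_spearman": rho, "p_value": pval,
                                 "n": int(np.isfinite(merged["lambda_pred"].to_numpy(float) *
                                                      merged["lambda_obs"].to_numpy(float)).sum())}])
    except ValueError as e:
        corr_df = pd.DataFrame([{"rho_spearman": np.nan, "p_value": np.nan, "n": 0}])
        log_lines.append(f"stage=growth_correlation skipped: {e}")

    # all-subsets regression of observed growth on the four predictive
    # traits; rates/sizes enter on the log scale
    reg = prof_masked[["strain_id", "s"]].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        reg["ln_k"] = np.log(prof_masked["k"].to_numpy(float))
        reg["ln_mu_l"] = np.log(prof_masked["mu_l"].to_numpy(float))
        reg["ln_b_r"] = np.log(prof_masked["b_r"].to_numpy(float))
    reg = reg.merge(obs_df[["strain_id", "lambda_obs"]], on="strain_id")
    try:
        sel = stats.aic_subset_selection(
            reg["lambda_obs"], reg[["s", "ln_k", "ln_mu_l", "ln_b_r"]])
        sel_df = sel.table.copy()
        sel_df["predictors"] = sel_df["predictors"].map(lambda s: "+".join(s) or "(intercept)")
        sel_df["coefficients"] = sel_df["coefficients"].map(
            lambda c: ";".join(f"{v:.6g}" for v in np.atleast_1d(c)))
        sel_df.attrs["consensus"] = sorted(sel.consensus_predictors)
        log_lines.append(
            f"stage=aic_selection n={sel.n_strains} "
            f"consensus={','.join(sorted(sel.consensus_predictors)) or '-'}")
    except ValueError as e:
        sel_df = pd.DataFrame()
        log_lines.append(f"stage=aic_selection skipped: {e}")

    trade = stats.tradeoff_tests(
        prof_masked, genome_sizes=meta["genome_size_kb"],
        growth_rates=obs_df.rename(columns={"lambda_obs": "lambda_obs"}),
        n_perm=config.n_perm, seed=int(stat_rng.integers(0, 2**31 - 1)),
        rule=config.weight_rule)
    trade_df = pd.DataFrame([{
        "species": t.species, "trait_x": t.trait_x, "trait_y": t.trait_y,
        "r_weighted": t.r_weighted, "p_value": t.p_value, "n": t.n,
        "tested": t.tested, "note": t.note} for t in trade])

    results = {
        "profiles": prof_df, "predictions": pred_df, "observed_growth": obs_df,
        "fold_ranges": fold_df, "variance_partition": vp_df,
        "growth_correlation": corr_df, "model_selection": sel_df,
        "tradeoffs": trade_df,
    }
    for name, df in results.items():
        _write_table(df, out / f"{name}.csv", cfg_hash)
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    logger.info("pipeline complete: %d strains -> %s", len(datasets), out)
    return results
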