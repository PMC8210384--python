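"""Config-driven end-to-end inequity-trend pipeline.

Loads (or simulates) a person-wave cohort, then per analysis group
(pooled total plus each stratum, analyzed separately) and wave computes
the weighted utilization rate, the concentration-index family with
confidence limits, the concentration curve, and the probit decomposition
with the horizontal inequity index; the trend layer adds chi-square tests
of rate differences across waves and pooled logistic odds ratios with
wave dummies. Reporting follows the covariance-scale convention: the
"CI" column is the generalized index and "adjusted" divides it by
μ(1−μ), with decomposition contributions rescaled to match.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from .cohort import GeneratorConfig, generate_cohort, write_cohort
from .decomposition import DecompositionTable, decompose
from .ranks import (
    CurvePoints,
    IndexEstimate,
    concentration_curve,
    curve_position,
    fractional_rank,
    index_confidence_limits,
)
from .trend import chi_square_test, fit_logistic_or, rate_table, utilization_rate

__all__ = ["AnalysisConfig", "CellResult", "InequityTrendReport",
           "run_pipeline", "render_tables", "plot_curves", "load_config"]

log = logging.getLogger("equitrend")

DEFAULT_DETERMINANTS: dict[str, str] = {
    "female": "need",
    "age_51_60": "need",
    "age_61_70": "need",
    "age_ge_71": "need",
    "middle_or_above": "non-need",
    "insured": "non-need",
    "income_group_medium": "non-need",
    "income_group_high": "non-need",
    "lives_alone": "non-need",
    "sleep_le_6h": "non-need",
    "sleep_gt_8h": "non-need",
    "non_smoking": "non-need",
    "non_alcohol": "non-need",
    "disability": "need",
    "chronic_disease": "need",
}


@dataclass
class AnalysisConfig:
    """Everything the pipeline needs to run, YAML-serializable."""

    input_csv: str | None = None
    generator: GeneratorConfig | None = None
    outcome: str = "y"
    rank_var: str = "income_per_capita"
    weight_var: str | None = "weight"
    stratum_var: str = "stratum"
    wave_var: str = "wave"
    determinants: dict = field(default_factory=lambda: dict(DEFAULT_DETERMINANTS))
    normalization: str = "paper"
    cl_method: str = "delta"
    cl_level: float = 0.95
    n_boot: int = 1000
    link: str = "probit"
    seed: int = 0
    output_dir: str = "equitrend_out"

    def validate_roles(self, df: pd.DataFrame) -> None:
        roles = {"outcome": self.outcome, "rank": self.rank_var,
                 "wave": self.wave_var, "stratum": self.stratum_var}
        if self.weight_var:
            roles["weight"] = self.weight_var
        missing = {r: c for r, c in roles.items()
                   if c not in df.columns}
        if missing:
            raise ValueError(f"role-mapping failure: columns not found: {missing}")
        bad_roles = [v for v in self.determinants.values() if v not in ("need", "non-need")]
        if bad_roles:
            raise ValueError(f"determinant roles must be 'need'/'non-need', got {bad_roles}")


def load_config(path) -> AnalysisConfig:
    """Read an AnalysisConfig from YAML."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    gen = raw.pop("generator", None)
    cfg = AnalysisConfig(**raw)
    if gen is not None:
        for key in ("waves", "household_size_probs"):
            if key in gen:
                gen[key] = tuple(gen[key])
        cfg.generator = GeneratorConfig(**gen)
    return cfg


@dataclass
class CellResult:
    """Results for one analysis group in one wave."""

    group: str
    wave: str
    n: int
    rate: float
    estimate: IndexEstimate        # generalized-scale point + CL
    adjusted_index: float          # normalized per config
    curve: CurvePoints
    curve_side: str
    decomposition: DecompositionTable


@dataclass
class InequityTrendReport:
    cells: list
    rates: pd.DataFrame
    chi_square: pd.DataFrame
    odds_ratios: dict
    config: AnalysisConfig
    n_dropped: int


def _prepare(df: pd.DataFrame, config: AnalysisConfig) -> tuple[pd.DataFrame, int]:
    df = df.copy()
    # derived design definitions take precedence over same-named raw
    # categorical columns (e.g. disability yes/no -> 0/1 dummy)
    derived = {}
    for name in config.determinants:
        if name in cohort_mod._DERIVED_COLUMNS:
            derived[name] = np.asarray(cohort_mod._DERIVED_COLUMNS[name](df), dtype=float)
        elif name not in df.columns:
            raise ValueError(
                f"role-mapping failure: determinant {name!r} is neither a column "
                "nor a derivable design variable"
            )
    for name, col in derived.items():
        df[name] = col
    used = [config.outcome, config.rank_var, config.wave_var, config.stratum_var]
    if config.weight_var:
        used.append(config.weight_var)
    used += list(config.determinants)
    before = len(df)
    df = df.dropna(subset=used).reset_index(drop=True)
    dropped = before - len(df)
    if dropped:
        log.info("complete-case filter dropped %d rows", dropped)
    return df, dropped


def run_pipeline(config: AnalysisConfig) -> InequityTrendReport:
    """Run the full analysis; deterministic given config and seed."""
    if config.input_csv:
        df = pd.read_csv(config.input_csv)
    elif config.generator is not None:
        df = generate_cohort(config.generator)
    else:
        df = generate_cohort(GeneratorConfig(seed=config.seed))
    config.validate_roles(df)
    df, n_dropped = _prepare(df, config)
    waves = sorted(df[config.wave_var].astype(str).unique())
    df[config.wave_var] = df[config.wave_var].astype(str)

    groups = {"total": df}
    for s, g in df.groupby(config.stratum_var, observed=True, sort=True):
        groups[str(s)] = g

    cells = []
    rng = np.random.default_rng(config.seed)
    for gname, gdf in groups.items():
        for wave in waves:
            cell = gdf[gdf[config.wave_var] == wave].reset_index(drop=True)
            if cell.empty:
                continue
            w = (cell[config.weight_var].to_numpy()
                 if config.weight_var else np.ones(len(cell)))
            y = cell[config.outcome].to_numpy(dtype=float)
            gamma = fractional_rank(cell[config.rank_var].to_numpy(dtype=float), w)
            rate = utilization_rate(y, w)
            est = index_confidence_limits(
                y, gamma, w, level=config.cl_level, method=config.cl_method,
                kind="generalized", n_boot=config.n_boot,
                seed=rng.integers(0, 2**31 - 1),
            )
            if config.normalization == "paper":
                adjusted = est.value / (rate * (1.0 - rate))
            elif config.normalization == "wagstaff_standard":
                adjusted = est.value / rate / (1.0 - rate)
            else:  # erreygers on the standard index
                adjusted = 4.0 * est.value
            curve = concentration_curve(y, gamma, w)
            dec = decompose(cell, config.outcome, config.rank_var,
                            config.determinants,
                            config.weight_var, link=config.link)
            cells.append(CellResult(
                group=gname, wave=wave, n=len(cell), rate=rate,
                estimate=est, adjusted_index=adjusted, curve=curve,
                # binary outcomes make the empirical curve locally jagged;
                # classify against the diagonal at the sampling-noise scale
                curve_side=curve_position(curve, tolerance=1.0 / np.sqrt(len(cell))),
                decomposition=dec,
            ))

    rates = rate_table(df, config.outcome, [config.stratum_var, config.wave_var],
                       config.weight_var)
    chis = []
    for gname, gdf in groups.items():
        counts = pd.crosstab(gdf[config.wave_var], gdf[config.outcome])
        res = chi_square_test(counts.to_numpy())
        chis.append({"group": gname, "statistic": res.statistic,
                     "df": res.df, "p_value": res.p_value})
    chi_square = pd.DataFrame(chis)

    odds = {}
    for gname, gdf in groups.items():
        X = gdf[list(config.determinants)].astype(float).reset_index(drop=True)
        for wave in waves[1:]:
            X[f"wave_{wave}"] = (gdf[config.wave_var] == wave).astype(float).to_numpy()
        wv = (gdf[config.weight_var].to_numpy() if config.weight_var else None)
        odds[gname] = fit_logistic_or(X, gdf[config.outcome].to_numpy(), wv)

    return InequityTrendReport(cells=cells, rates=rates, chi_square=chi_square,
                               odds_ratios=odds, config=config,
                               n_dropped=n_dropped)


def render_tables(report: InequityTrendReport, out_dir=None) -> dict:
    """Write the report as deterministic CSV files; returns path map.

    Index and decomposition values are printed at 4 decimals, odds ratios
    and percentages at 2, mirroring common table precision. Ordering is
    byte-stable: groups, then waves, then determinants in config order.
    """
    out = Path(out_dir or report.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    rows = []
    for c in report.cells:
        rows.append({
            "group": c.group, "wave": c.wave, "n": c.n,
            "rate": round(c.rate, 4),
            "ci": round(c.estimate.value, 4),
            "cl_lower": round(c.estimate.cl_lower, 4),
            "cl_upper": round(c.estimate.cl_upper, 4),
            "ci_adjusted": round(c.adjusted_index, 4),
            "curve_side": c.curve_side,
        })
    idx = pd.DataFrame(rows)
    paths["index"] = out / "index.csv"
    idx.to_csv(paths["index"], index=False)

    drows = []
    for c in report.cells:
        frame = c.decomposition.to_frame(scale="covariance")
        for _, r in frame.iterrows():
            drows.append({
                "group": c.group, "wave": c.wave, "variable": r.variable,
                "role": r.role,
                "elasticity": round(r.elasticity, 4),
                "contribution": round(r.contribution, 4),
                "pct_contribution": round(r.pct_contribution, 2),
            })
        mu = c.decomposition.mu
        drows.append({"group": c.group, "wave": c.wave, "variable": "HI",
                      "role": "", "elasticity": np.nan,
                      "contribution": round(c.decomposition.hi * mu, 4),
                      "pct_contribution": np.nan})
        drows.append({"group": c.group, "wave": c.wave, "variable": "HI_adjusted",
                      "role": "", "elasticity": np.nan,
                      "contribution": round(c.decomposition.hi_adjusted, 4),
                      "pct_contribution": np.nan})
    paths["decomposition"] = out / "decomposition.csv"
    pd.DataFrame(drows).to_csv(paths["decomposition"], index=False)

    paths["rates"] = out / "rates.csv"
    report.rates.assign(rate=report.rates["rate"].round(4)).to_csv(
        paths["rates"], index=False)
    paths["chi_square"] = out / "chi_square.csv"
    report.chi_square.to_csv(paths["chi_square"], index=False)

    orows = []
    for gname, tab in report.odds_ratios.items():
        t = tab.copy()
        for col in ("odds_ratio", "cl_lower", "cl_upper"):
            t[col] = t[col].round(2)
        t.insert(0, "group", gname)
        orows.append(t)
    paths["odds_ratios"] = out / "odds_ratios.csv"
    pd.concat(orows, ignore_index=True).to_csv(paths["odds_ratios"], index=False)

    crows = []
    for c in report.cells:
        crows.append(pd.DataFrame({"group": c.group, "wave": c.wave,
                                   "p": c.curve.p, "L": c.curve.L}))
    paths["curves"] = out / "curves.csv"
    pd.concat(crows, ignore_index=True).to_csv(paths["curves"], index=False,
                                               float_format="%.6f")

    meta = {"seed": report.config.seed, "n_dropped": report.n_dropped,
            "normalization": report.config.normalization,
            "cl_method": report.config.cl_method}
    paths["metadata"] = out / "run_metadata.json"
    paths["metadata"].write_text(json.dumps(meta, indent=2, sort_keys=True))
    return paths


def plot_curves(report: InequityTrendReport, out_dir=None, fmt: str = "png") -> dict:
    """Concentration-curve panels per group plus the rate-by-wave plot."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir or report.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    groups = sorted({c.group for c in report.cells})

    fig, axes = plt.subplots(1, len(groups), figsize=(4.2 * len(groups), 4),
                             squeeze=False)
    for ax, gname in zip(axes[0], groups):
        ax.plot([0, 1], [0, 1], "k--", lw=1, label="equality")
        for c in report.cells:
            if c.group == gname:
                ax.plot(c.curve.p, c.curve.L, lw=1.2, label=c.wave)
        ax.set_title(gname)
        ax.set_xlabel("cumulative population share (poorest first)")
        ax.set_ylabel("cumulative outcome share")
        ax.legend(fontsize=7)
    fig.tight_layout()
    paths["curves"] = out / f"concentration_curves.{fmt}"
    fig.savefig(paths["curves"], dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    for c in sorted({c.group for c in report.cells}):
        sub = [(x.wave, x.rate) for x in report.cells if x.group == c]
        sub.sort()
        ax.plot([s[0] for s in sub], [100 * s[1] for s in sub], marker="o", label=c)
    ax.set_ylabel("utilization rate (%)")
    ax.set_xlabel("wave")
    ax.legend()
    fig.tight_layout()
    paths["rates"] = out / f"rates.{fmt}"
    fig.savefig(paths["rates"], dpi=120)
    plt.close(fig)
    return paths
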