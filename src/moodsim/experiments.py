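"""Seeded sweep experiments over the society simulation.

Seven canned experiments compare mean cumulative payoffs by agent type
while one model dimension is varied and everything else is held fixed:

- ``type_comparison``: the default society, no variation (baseline
  contrasts vs rational agents);
- ``composition``: representation of a focal type in the population;
- ``diversity``: the depressed-agent connection diversity ``pi``;
- ``forgetting``: the decay rate ``theta`` in powers of ten;
- ``bias``: positive vs negative emotional encoding bias;
- ``mood_dependence``: the retrieval selectivity ``gamma``;
- ``sensitivity``: trait reward sensitivity ``beta`` over the manic and
  depressed ranges.

Replicates use common random numbers (the same replicate seed at every
grid point) so grid contrasts are paired.  All percentage contrasts are
computed on replicate means, against the rational-type mean of the same
runs unless stated otherwise.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AGENT_TYPES, ConfigError, SimulationConfig
from .engine import SimulationResult, run_simulation

__all__ = [
    "THETA_GRID",
    "GAMMA_GRID",
    "PI_GRID",
    "COMPOSITION_GRID",
    "MANIC_BETA_GRID",
    "DEPRESSED_BETA_GRID",
    "BIAS_PRESETS",
    "SweepSpec",
    "sweep_spec",
    "apply_setting",
    "run_replicates",
    "run_sweep",
    "pooled_type_means",
    "pct_vs_rational",
    "bias_experiment",
    "sensitivity_correlation",
    "summarize",
    "recompute_agent_payoffs",
    "write_report",
]

logger = logging.getLogger(__name__)

THETA_GRID = (1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0)
GAMMA_GRID = (1e-2, 1e-1, 1.0, 10.0, 100.0)
PI_GRID = (0.2, 0.3, 0.4, 0.5)
COMPOSITION_GRID = (0.10, 0.25, 0.40, 0.625)
MANIC_BETA_GRID = (2.0, 4.0, 6.0, 8.0, 10.0)
DEPRESSED_BETA_GRID = (0.1, 0.3, 0.5, 0.7, 0.9)
BIAS_PRESETS: Dict[str, Dict[str, float]] = {
    "positive": {"grad_pos": 80.0, "grad_neg": 40.0},  # xi = 2
    "negative": {"grad_pos": 40.0, "grad_neg": 80.0},  # xi = 0.5
}

SWEEP_NAMES = (
    "type_comparison",
    "composition",
    "diversity",
    "forgetting",
    "bias",
    "mood_dependence",
    "sensitivity",
)


@dataclass
class SweepSpec:
    """A named grid of settings applied on top of a base configuration."""

    name: str
    grid: List[Mapping]
    n_replicates: int
    base_config: SimulationConfig = field(default_factory=SimulationConfig)


def sweep_spec(
    name: str,
    base_config: Optional[SimulationConfig] = None,
    n_replicates: int = 10,
) -> SweepSpec:
    """Build the default grid for one of the canned experiments."""
    base = base_config or SimulationConfig()
    if name == "type_comparison":
        grid: List[Mapping] = [{}]
    elif name == "composition":
        grid = [
            {"focal_type": t, "proportion": p}
            for t, p in itertools.product(AGENT_TYPES, COMPOSITION_GRID)
        ]
    elif name == "diversity":
        grid = [{"pi": p} for p in PI_GRID]
    elif name == "forgetting":
        grid = [{"theta": th} for th in THETA_GRID]
    elif name == "bias":
        grid = [{"bias": b} for b in BIAS_PRESETS]
    elif name == "mood_dependence":
        grid = [{"gamma": g} for g in GAMMA_GRID]
    elif name == "sensitivity":
        grid = [{"beta_manic": b} for b in MANIC_BETA_GRID]
        grid += [{"beta_depressed": b} for b in DEPRESSED_BETA_GRID]
    else:
        raise ValueError(f"unknown sweep {name!r}; expected one of {SWEEP_NAMES}")
    return SweepSpec(name=name, grid=grid, n_replicates=n_replicates, base_config=base)


def apply_setting(config: SimulationConfig, setting: Mapping) -> SimulationConfig:
    """Return a copy of ``config`` with one grid setting applied."""
    cfg = config
    setting = dict(setting)
    if "theta" in setting:
        cfg = cfg.with_memory(forget_rate=setting.pop("theta"))
    if "gamma" in setting:
        cfg = cfg.with_memory(mood_dependence=setting.pop("gamma"))
    if "pi" in setting:
        cfg = cfg.replace(diversity=setting.pop("pi"))
    if "bias" in setting:
        cfg = cfg.with_memory(**BIAS_PRESETS[setting.pop("bias")])
    if "focal_type" in setting:
        focal = setting.pop("focal_type")
        p = setting.pop("proportion")
        rest = (1.0 - p) / 3.0
        cfg = cfg.replace(
            proportions={t: (p if t == focal else rest) for t in AGENT_TYPES}
        )
    if "beta_manic" in setting:
        override = dict(cfg.beta_override or {})
        override["manic"] = setting.pop("beta_manic")
        cfg = cfg.replace(beta_override=override)
    if "beta_depressed" in setting:
        override = dict(cfg.beta_override or {})
        override["depressed"] = setting.pop("beta_depressed")
        cfg = cfg.replace(beta_override=override)
    if setting:
        raise ValueError(f"unknown setting keys: {sorted(setting)}")
    return cfg


def run_replicates(
    config: SimulationConfig, n_replicates: int, base_seed: int = 0
) -> pd.DataFrame:
    """Run seeded replicates; one row per (replicate, agent type)."""
    rows = []
    for r in range(n_replicates):
        seed = base_seed + r
        result = run_simulation(config, seed=seed)
        means = result.type_payoffs()
        for agent_type, mean_payoff in means.items():
            rows.append(
                {
                    "replicate": r,
                    "seed": seed,
                    "agent_type": agent_type,
                    "mean_payoff": float(mean_payoff),
                }
            )
    return pd.DataFrame(rows)


def run_sweep(spec: SweepSpec, base_seed: int = 0) -> pd.DataFrame:
    """Run every grid point of a sweep; long-format summary table.

    Infeasible grid points (e.g. a diversity quota the society cannot
    supply) are skipped with a logged diagnostic and listed in
    ``df.attrs["skipped"]``.
    """
    frames = []
    skipped = []
    for setting in spec.grid:
        try:
            cfg = apply_setting(spec.base_config, setting).validate()
        except (ConfigError, ValueError) as exc:
            logger.warning("skipping infeasible grid point %s: %s", dict(setting), exc)
            skipped.append({"setting": dict(setting), "reason": str(exc)})
            continue
        df = run_replicates(cfg, spec.n_replicates, base_seed=base_seed)
        for key, value in setting.items():
            df[key] = value
        df["sweep"] = spec.name
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    out.attrs["skipped"] = skipped
    return out


def pooled_type_means(df: pd.DataFrame, by: Sequence[str] = ()) -> pd.DataFrame:
    """Mean of replicate means per agent type (optionally per grid cell)."""
    keys = list(by) + ["agent_type"]
    return df.groupby(keys, as_index=False)["mean_payoff"].mean()


def pct_vs_rational(df: pd.DataFrame, by: Sequence[str] = ()) -> pd.DataFrame:
    """Percentage difference of each type's pooled mean payoff from the
    rational-type mean of the same runs."""
    pooled = pooled_type_means(df, by=by)
    keys = list(by)

    def _with_pct(group: pd.DataFrame) -> pd.DataFrame:
        base = group.loc[group["agent_type"] == "rational", "mean_payoff"]
        group = group.copy()
        if base.empty or base.iloc[0] == 0:
            group["pct_vs_rational"] = np.nan
        else:
            group["pct_vs_rational"] = (
                (group["mean_payoff"] - base.iloc[0]) / base.iloc[0] * 100.0
            )
        return group

    if not keys:
        return _with_pct(pooled)
    return (
        pooled.groupby(keys, group_keys=False)[pooled.columns]
        .apply(_with_pct)
        .reset_index(drop=True)
    )


def bias_experiment(
    base_config: Optional[SimulationConfig] = None,
    n_replicates: int = 10,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Positive vs negative emotional encoding bias, per agent type.

    Runs one arm with every agent positively biased (k_P : k_N = 2 : 1)
    and one with every agent negatively biased (1 : 2); for each type the
    pooled two-arm mean payoff is the baseline (0) and each arm is
    reported as a signed percentage difference from it.
    """
    base = base_config or SimulationConfig()
    spec = SweepSpec(
        name="bias",
        grid=[{"bias": b} for b in BIAS_PRESETS],
        n_replicates=n_replicates,
        base_config=base,
    )
    df = run_sweep(spec, base_seed=base_seed)
    pooled = pooled_type_means(df, by=["bias"])
    rows = []
    for agent_type, group in pooled.groupby("agent_type"):
        baseline = group["mean_payoff"].mean()
        for _, row in group.iterrows():
            rows.append(
                {
                    "agent_type": agent_type,
                    "bias": row["bias"],
                    "mean_payoff": row["mean_payoff"],
                    "pct_vs_baseline": (row["mean_payoff"] - baseline) / baseline * 100.0,
                }
            )
    return pd.DataFrame(rows)


def sensitivity_correlation(df: pd.DataFrame, focal_type: str) -> float:
    """Spearman rank correlation between the swept trait sensitivity and
    the focal type's pooled mean payoff (the dose-response check)."""
    col = "beta_manic" if focal_type == "manic" else "beta_depressed"
    sub = df[df[col].notna() & (df["agent_type"] == focal_type)]
    pooled = sub.groupby(col, as_index=False)["mean_payoff"].mean()
    rho, _ = stats.spearmanr(pooled[col], pooled["mean_payoff"])
    return float(rho)


def recompute_agent_payoffs(records: pd.DataFrame, n_agents: int) -> np.ndarray:
    """Per-agent cumulative payoffs recomputed from the event log
    (conservation check against the online accumulators)."""
    totals = np.zeros(n_agents)
    np.add.at(totals, records["id_a"].to_numpy(), records["payoff_a"].to_numpy())
    np.add.at(totals, records["id_b"].to_numpy(), records["payoff_b"].to_numpy())
    return totals


def summarize(result: SimulationResult) -> pd.DataFrame:
    """Per-type metrics of one run.

    Mean/SD cumulative payoff, percentage difference vs the rational mean
    (NaN for a single-type society), activity rates, and realized degrees.
    """
    summary = result.summary()
    if summary.empty:
        raise ValueError("empty run summary")
    grouped = summary.groupby("type")
    out = pd.DataFrame(
        {
            "n_agents": grouped.size(),
            "mean_payoff": grouped["cumulative_payoff"].mean(),
            "sd_payoff": grouped["cumulative_payoff"].std(),
            "mean_activity_rate": grouped["activity_rate"].mean(),
            "mean_realized_degree": grouped["realized_degree"].mean(),
            "mean_interactions": grouped["n_interactions"].mean(),
        }
    )
    if "rational" in out.index and out.loc["rational", "mean_payoff"] > 0:
        base = out.loc["rational", "mean_payoff"]
        out["pct_vs_rational"] = (out["mean_payoff"] - base) / base * 100.0
    else:
        out["pct_vs_rational"] = np.nan
    out["mean_retrieved_per_query"] = (
        result.n_retrieved / result.n_queries if result.n_queries else np.nan
    )
    return out.reset_index(names="agent_type")


def write_report(df: pd.DataFrame, path: str | Path, title: str = "Sweep report") -> None:
    """Write a small markdown report mirroring a sweep's summary table."""
    lines = [f"# {title}", ""]
    if df.empty:
        lines.append("No feasible grid points were run.")
    else:
        lines.append(df.to_markdown(index=False, floatfmt=".4g"))
    skipped = df.attrs.get("skipped") if hasattr(df, "attrs") else None
    if skipped:
        lines += ["", "## Skipped grid points", ""]
        for item in skipped:
            lines.append(f"- `{item['setting']}`: {item['reason']}")
    Path(path).write_text("\n".join(lines) + "\n")
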