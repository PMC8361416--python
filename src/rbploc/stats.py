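"""Aggregation hierarchy, control normalization and two-group testing.

Values ascend the acquisition hierarchy by unweighted means — cells to
field, fields to well — and are normalized within each experimental repeat
to the mean of the untreated-control group. Two-group comparisons use an
unpaired two-tailed Student's t-test when both groups pass a normality
gate, and a two-sided Mann-Whitney test otherwise (exact enumeration for
small samples, normal approximation with tie correction above that).
No multiple-testing correction is applied across proteins: each protein's
comparison is reported on its own, and downstream users should correct if
they screen many targets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from math import comb
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("rbploc")

__all__ = [
    "LEVEL_KEYS",
    "ComparisonResult",
    "ReportConfig",
    "Report",
    "aggregate",
    "normalize_to_control",
    "mann_whitney_u",
    "mann_whitney_exact_p",
    "compare_groups",
    "run_pipeline_report",
    "write_report",
    "significance_stars",
]

#: Grouping keys that define each level of the acquisition hierarchy.
LEVEL_KEYS: dict[str, list[str]] = {
    "field": ["line", "condition", "repeat", "well", "field"],
    "well": ["line", "condition", "repeat", "well"],
    "line": ["line", "condition"],
}

_LEVEL_ORDER = ["cell", "field", "well", "line"]

#: Pooled samples up to this size use the exact Mann-Whitney null.
EXACT_MW_MAX_N = 12


def _infer_level(df: pd.DataFrame) -> str:
    if "cell" in df.columns:
        return "cell"
    for level in ("field", "well", "line"):
        if LEVEL_KEYS[level][-1] in df.columns:
            return level
    raise ValueError("cannot infer aggregation level from columns")


def aggregate(df: pd.DataFrame, level: str, value_col: str) -> pd.DataFrame:
    """Average a tidy value table up to the requested level.

    Each step of the hierarchy is an unweighted mean of the level below
    (cells -> field -> well -> line). Cell rows flagged invalid and
    non-finite values are excluded; groups left empty are dropped with a
    logged warning. The returned table carries the grouping keys, the
    averaged value and ``n`` (number of lower-level units averaged).
    """
    if level not in _LEVEL_ORDER:
        raise ValueError(f"unknown level {level!r}")
    current = _infer_level(df)
    if _LEVEL_ORDER.index(level) < _LEVEL_ORDER.index(current):
        raise ValueError(f"cannot aggregate {current}-level data down to {level}")
    out = df.copy()
    if current == "cell" and "valid" in out.columns:
        n_bad = int((~out["valid"]).sum())
        if n_bad:
            logger.warning("dropping %d flagged cell records", n_bad)
        out = out[out["valid"]]
    out = out[np.isfinite(out[value_col])]
    extra = [c for c in ("channel",) if c in out.columns]
    while current != level:
        nxt = _LEVEL_ORDER[_LEVEL_ORDER.index(current) + 1]
        keys = LEVEL_KEYS[nxt] + extra
        grouped = out.groupby(keys, sort=False)[value_col]
        out = grouped.mean().reset_index()
        out["n"] = grouped.size().values
        current = nxt
    return out.reset_index(drop=True)


def normalize_to_control(
    table: pd.DataFrame,
    value_col: str,
    control_condition: str,
    repeat_col: str = "repeat",
    condition_col: str = "condition",
    out_col: str | None = None,
) -> pd.DataFrame:
    """Divide every value by its repeat's mean control value.

    Within each experimental repeat the mean of the control group's
    normalized values is exactly 1. Normalizing an already-normalized
    table is a no-op (the control mean is then 1). A repeat with no
    control rows is an error naming the repeat.
    """
    out_col = out_col or f"{value_col}_norm"
    table = table.copy()
    extra = [c for c in ("channel",) if c in table.columns]
    norm = np.empty(len(table), dtype=np.float64)
    for key, idx in table.groupby([repeat_col] + extra, sort=False).groups.items():
        sub = table.loc[idx]
        ctrl = sub.loc[sub[condition_col] == control_condition, value_col]
        if ctrl.empty:
            rep = key[0] if isinstance(key, tuple) else key
            raise ValueError(f"repeat {rep!r} has no {control_condition!r} control rows")
        norm[table.index.get_indexer(idx)] = sub[value_col] / ctrl.mean()
    table[out_col] = norm
    return table


# ---------------------------------------------------------------------------
# Two-group testing
# ---------------------------------------------------------------------------


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> float:
    """U statistic of group a (midranks for ties)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    ranks = sps.rankdata(np.concatenate([a, b]))
    return float(ranks[: len(a)].sum() - len(a) * (len(a) + 1) / 2)


def mann_whitney_exact_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Exact two-sided Mann-Whitney p-value under the permutation null.

    The null distribution of U over all C(n_a+n_b, n_a) group assignments
    of the pooled (possibly tied) values is built by dynamic programming
    over doubled midranks; the two-sided p is the probability of a
    min(U, n_a*n_b - U) at least as extreme as observed. Equivalent to
    brute-force enumeration of every assignment.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    ranks2 = np.rint(2 * sps.rankdata(np.concatenate([a, b]))).astype(int)
    total = int(ranks2.sum())
    # dp[k, s] = number of k-subsets of the doubled ranks summing to s
    dp = np.zeros((n_a + 1, total + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in ranks2:
        for k in range(min(n_a, 1_000_000), 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    counts = dp[n_a]
    s_vals = np.nonzero(counts)[0]
    m2 = 2 * n_a * n_b
    u2 = s_vals - n_a * (n_a + 1)  # doubled U for each achievable rank sum
    u2_obs = int(np.rint(2 * mann_whitney_u(a, b)))
    stat = min(u2_obs, m2 - u2_obs)
    extreme = np.minimum(u2, m2 - u2) <= stat
    return float(counts[s_vals[extreme]].sum() / comb(n_a + n_b, n_a))


def significance_stars(p: float, thresholds=(0.05, 0.01, 0.001)) -> str:
    if p <= thresholds[2]:
        return "***"
    if p <= thresholds[1]:
        return "**"
    if p <= thresholds[0]:
        return "*"
    return "ns"


@dataclass
class ComparisonResult:
    """Outcome of one two-group comparison."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    normality_p_a: float | None
    normality_p_b: float | None
    test_used: str  # "t_test" | "mann_whitney"
    statistic: float
    p_value: float
    stars: str
    normalization: str = ""
    notes: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def _normality_p(x: np.ndarray, alpha: float) -> float:
    """D'Agostino-Pearson omnibus p; Shapiro-Wilk for n < 8."""
    if np.ptp(x) == 0:
        return 0.0  # a constant sample is not treated as Gaussian
    if len(x) >= 8:
        return float(sps.normaltest(x).pvalue)
    return float(sps.shapiro(x).pvalue)


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    alpha_normality: float = 0.05,
    labels: tuple[str, str] = ("a", "b"),
    force_mannwhitney: bool = False,
    welch: bool = False,
    normalization: str = "",
) -> ComparisonResult:
    """Gaussianity-gated two-group test.

    Both groups must pass the normality gate for the (two-tailed, unpaired,
    pooled-variance by default) t-test to be used; otherwise a two-sided
    Mann-Whitney test is run — exactly for pooled n <= 12, by normal
    approximation with tie correction above. Groups of fewer than 3 values
    cannot be gated, forcing Mann-Whitney (logged).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    notes = []
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        # all values identical: no evidence of any difference
        return ComparisonResult(
            *labels, len(a), len(b), a.mean(), b.mean(), 0.0, 0.0, None, None,
            "t_test", 0.0, 1.0, "ns", normalization, "degenerate: all values equal",
        )
    if len(a) < 3 or len(b) < 3:
        force_mannwhitney = True
        notes.append("group too small for normality gate; Mann-Whitney forced")
        logger.warning("compare_groups: %s", notes[-1])
    p_norm_a = p_norm_b = None
    if not force_mannwhitney:
        p_norm_a = _normality_p(a, alpha_normality)
        p_norm_b = _normality_p(b, alpha_normality)
    gaussian = (
        not force_mannwhitney
        and p_norm_a > alpha_normality
        and p_norm_b > alpha_normality
    )
    if gaussian:
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            stat, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        else:
            res = sps.ttest_ind(a, b, equal_var=not welch)
            stat, p = float(res.statistic), float(res.pvalue)
        test = "t_test"
    else:
        stat = mann_whitney_u(a, b)
        if len(a) + len(b) <= EXACT_MW_MAX_N:
            p = mann_whitney_exact_p(a, b)
        else:
            p = float(
                sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
            )
        test = "mann_whitney"
    return ComparisonResult(
        label_a=labels[0],
        label_b=labels[1],
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        normality_p_a=p_norm_a,
        normality_p_b=p_norm_b,
        test_used=test,
        statistic=stat,
        p_value=p,
        stars=significance_stars(p),
        normalization=normalization,
        notes="; ".join(notes),
    )


# ---------------------------------------------------------------------------
# Report over full pipeline outputs
# ---------------------------------------------------------------------------


@dataclass
class ReportConfig:
    """What to compare and at which level of the hierarchy.

    Defaults follow the assay's plotting conventions: N:C compared per
    well, Nu:Ne per field, both normalized per repeat to the control
    group's mean.
    """

    control: str
    comparisons: list[tuple[str, str]] | None = None  # (control-ish, other)
    nc_level: str = "well"
    nu_ne_level: str = "field"
    normalize: bool = True
    alpha: float = 0.05
    alpha_normality: float = 0.05
    welch: bool = False


@dataclass
class Report:
    comparisons: pd.DataFrame
    plotdata: dict[str, pd.DataFrame]
    log: dict


def _target_channels(fields: pd.DataFrame) -> list[str]:
    return [c for c in fields["channel"].unique() if c not in ("dapi", "tubulin")]


def run_pipeline_report(
    cells: pd.DataFrame,
    fields: pd.DataFrame,
    config: ReportConfig,
) -> Report:
    """One gated comparison per (protein channel, metric).

    N:C ratios are aggregated to ``config.nc_level`` and Nu:Ne ratios to
    ``config.nu_ne_level``; values are normalized per repeat to the control
    group before testing. Per-line means are emitted as plot overlay
    points; the tested n is the number of wells (N:C) or fields (Nu:Ne).
    """
    for lvl in (config.nc_level, config.nu_ne_level):
        if lvl not in _LEVEL_ORDER:
            raise ValueError(f"unknown level {lvl!r}")
        for key in LEVEL_KEYS.get(lvl, []):
            if key not in cells.columns or key not in fields.columns:
                raise ValueError(f"requested level {lvl!r} needs column {key!r}")
    conditions = list(dict.fromkeys(fields["condition"]))
    if config.control not in conditions:
        raise ValueError(f"control condition {config.control!r} absent from data")
    pairs = config.comparisons or [
        (config.control, c) for c in conditions if c != config.control
    ]
    rows = []
    plotdata: dict[str, pd.DataFrame] = {}
    results: list[ComparisonResult] = []
    for metric, source, value_col, level in (
        ("nc_ratio", cells, "nc_ratio", config.nc_level),
        ("nu_ne_ratio", fields, "nu_ne_ratio", config.nu_ne_level),
    ):
        if "channel" not in source.columns:
            raise ValueError("input tables must carry a 'channel' column")
        for channel in _target_channels(source):
            sub = source[source["channel"] == channel]
            agg = aggregate(sub, level, value_col)
            norm_note = ""
            col = value_col
            if config.normalize:
                agg = normalize_to_control(agg, value_col, config.control)
                col = f"{value_col}_norm"
                norm_note = (
                    f"per-repeat division by mean of {config.control!r} group"
                )
            overlay = aggregate(agg, "line", col)
            key = f"{channel}_{metric}_{level}"
            plotdata[key] = agg
            plotdata[f"{key}_line_means"] = overlay
            for cond_a, cond_b in pairs:
                va = agg.loc[agg["condition"] == cond_a, col].to_numpy()
                vb = agg.loc[agg["condition"] == cond_b, col].to_numpy()
                res = compare_groups(
                    va,
                    vb,
                    alpha_normality=config.alpha_normality,
                    labels=(cond_a, cond_b),
                    welch=config.welch,
                    normalization=norm_note,
                )
                results.append(res)
                rows.append(
                    {
                        "channel": channel,
                        "metric": metric,
                        "level": level,
                        **res.to_dict(),
                        "significant": res.p_value <= config.alpha,
                    }
                )
    log = {
        "config": asdict(config),
        "conditions": conditions,
        "n_cell_records": int(len(cells)),
        "n_field_records": int(len(fields)),
    }
    return Report(comparisons=pd.DataFrame(rows), plotdata=plotdata, log=log)


def write_report(report: Report, outdir: Path | str) -> Path:
    """Write comparisons.csv/.json, plotdata/*.csv and run.log."""
    outdir = Path(outdir)
    (outdir / "plotdata").mkdir(parents=True, exist_ok=True)
    report.comparisons.to_csv(outdir / "comparisons.csv", index=False)
    (outdir / "comparisons.json").write_text(
        json.dumps(report.comparisons.to_dict(orient="records"), indent=1, default=str)
    )
    for name, df in report.plotdata.items():
        df.to_csv(outdir / "plotdata" / f"{name}.csv", index=False)
    (outdir / "run.log").write_text(json.dumps(report.log, indent=1, default=str))
    return outdir
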