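"""Baseline standardization, condition contrasts with FDR, and RT analyses.

Per-trial metric values (5 metric types x 5 bands x 19 channels = 475
candidate hypotheses) are averaged within 5-min epochs and divided by
the same subject/condition/metric's baseline-epoch value (the epoch
immediately before fragrance onset, [25-30] min, epoch group 5).

Condition contrasts pair the two sessions within (subject, epoch) over
the analysis window (default epoch groups 6-8, i.e. [30-45] min).  A
Shapiro-Wilk test on the paired differences (alpha = 0.05) gates the
choice between the paired t-test and the Wilcoxon signed-rank test.
Benjamini-Hochberg FDR is applied per family -- the 19 channels of one
(metric, band) pair -- at alpha = 0.05.

Reaction-time epoch means are standardized piecewise: epochs in
[30-60] min by the last pre-fragrance epoch (group 5), epochs in
[0-30] min by the first epoch (group 0).  The paired RT contrast pools
subjects x window epochs (30 subjects x 3 epochs -> df = 89); the
two-way repeated-measures ANOVA crosses condition x epoch with subject
as the blocking factor.
"""

from __future__ import annotations

import importlib.resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .synthdata import CHANNELS_1020, FRONTAL_CHANNELS, PARIETAL_CHANNELS

__all__ = [
    "METRIC_NAMES",
    "BAND_NAMES",
    "load_table2",
    "trials_to_frame",
    "epoch_average",
    "standardize_baseline",
    "condition_contrast",
    "bh_fdr",
    "rt_epoch_table",
    "rt_contrast",
    "rt_anova",
    "rt_metric_correlation",
    "sact_exclusion",
    "count_significant",
]

METRIC_NAMES: tuple[str, ...] = ("ND", "NB", "NE", "CC", "PSD")
BAND_NAMES: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")
DEFAULT_WINDOW: tuple[int, ...] = (6, 7, 8)
BASELINE_EPOCH = 5

_KEY = ["subject_id", "condition", "epoch_group", "channel", "band", "metric"]


def load_table2() -> pd.DataFrame:
    """Packaged transcription of the published significant-metric table."""
    ref = importlib.resources.files("olfalert.data").joinpath(
        "table2_significant_metrics.csv"
    )
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def trials_to_frame(rows: Iterable[dict]) -> pd.DataFrame:
    """Assemble per-trial long-format metric rows into a DataFrame."""
    df = pd.DataFrame(list(rows))
    missing = set(_KEY + ["trial_index", "value"]) - set(df.columns)
    if missing:
        raise ValueError(f"metric rows lack columns {sorted(missing)}")
    return df


def epoch_average(trial_values: pd.DataFrame) -> pd.DataFrame:
    """Mean metric value per (subject, condition, epoch, channel, band, metric).

    Returns columns ``*_KEY, value_raw, n_trials``; empty epochs simply
    produce no row (the caller's grid logic treats them as missing).
    """
    grouped = trial_values.groupby(_KEY, observed=True)["value"]
    out = grouped.agg(value_raw="mean", n_trials="size").reset_index()
    return out


def standardize_baseline(
    epoch_means: pd.DataFrame,
    baseline_epoch: int = BASELINE_EPOCH,
) -> tuple[pd.DataFrame, list[str]]:
    """Divide each epoch value by the subject/condition/metric baseline value.

    The baseline row itself standardizes to 1.0.  Zero or missing
    baselines mark the affected rows as missing and are logged.
    """
    key = ["subject_id", "condition", "channel", "band", "metric"]
    base = (
        epoch_means[epoch_means["epoch_group"] == baseline_epoch]
        .set_index(key)["value_raw"]
        .rename("baseline")
    )
    df = epoch_means.join(base, on=key)
    log: list[str] = []
    bad = df["baseline"].isna() | (df["baseline"] == 0)
    if bad.any():
        for _, row in df.loc[bad, key].drop_duplicates().iterrows():
            log.append(
                "missing/zero baseline for "
                + ", ".join(f"{k}={row[k]}" for k in key)
            )
    df["value_std"] = np.where(bad, np.nan, df["value_raw"] / df["baseline"])
    return df.drop(columns="baseline"), log


def bh_fdr(p_values: Sequence[float], alpha: float = 0.05):
    """Benjamini-Hochberg step-up adjustment with monotonicity.

    Returns ``(p_adjusted, significant)`` arrays.  NaN p-values are
    passed through as NaN/not-significant.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    adj = np.full(p.shape, np.nan)
    flags = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p)
    if ok.any():
        rej, p_adj, _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
        adj[ok] = p_adj
        flags[ok] = rej
    return adj, flags


def _paired_test(diffs: np.ndarray, gate_alpha: float = 0.05) -> dict:
    """Shapiro-gated paired test on condition differences."""
    n = diffs.size
    if np.allclose(diffs, diffs[0]):
        if diffs[0] == 0:
            # Identical condition vectors: no evidence by convention.
            return {"test_used": "wilcoxon", "statistic": 0.0, "df": np.nan, "p_raw": 1.0}
        normal = True  # constant nonzero shift: Shapiro undefined, t is exact
    else:
        normal = sps.shapiro(diffs).pvalue >= gate_alpha
    if normal:
        res = sps.ttest_1samp(diffs, 0.0)
        return {
            "test_used": "paired_t",
            "statistic": float(res.statistic),
            "df": float(n - 1),
            "p_raw": float(res.pvalue),
        }
    res = sps.wilcoxon(diffs)
    return {
        "test_used": "wilcoxon",
        "statistic": float(res.statistic),
        "df": np.nan,
        "p_raw": float(res.pvalue),
    }


def condition_contrast(
    std_table: pd.DataFrame,
    window: Sequence[int] = DEFAULT_WINDOW,
    fdr_alpha: float = 0.05,
    gate_alpha: float = 0.05,
    min_pairs: int = 3,
    fdr_family: tuple[str, ...] = ("metric", "band"),
    channels: Sequence[str] = CHANNELS_1020,
    bands: Sequence[str] = BAND_NAMES,
    metrics: Sequence[str] = METRIC_NAMES,
) -> pd.DataFrame:
    """Per-(metric, band, channel) paired condition contrasts with FDR.

    Always enumerates the full candidate grid (5 metrics x 5 bands x 19
    channels = 475 hypotheses); triples with fewer than ``min_pairs``
    paired (subject, epoch) observations are reported with a skip
    reason.  FDR families default to the 19 channels of one
    (metric, band) pair.
    """
    data = std_table[std_table["epoch_group"].isin(list(window))]
    wide = data.pivot_table(
        index=["metric", "band", "channel", "subject_id", "epoch_group"],
        columns="condition",
        values="value_std",
        observed=True,
    )
    rows = []
    for metric in metrics:
        for band in bands:
            for channel in channels:
                row = {"metric": metric, "band": band, "channel": channel}
                try:
                    cell = wide.loc[(metric, band, channel)]
                except KeyError:
                    cell = None
                if (
                    cell is None
                    or "alerting" not in cell
                    or "relaxing" not in cell
                ):
                    row.update(
                        n_pairs=0, test_used=None, statistic=np.nan, df=np.nan,
                        p_raw=np.nan, reason="no paired data",
                    )
                    rows.append(row)
                    continue
                paired = cell.dropna(subset=["alerting", "relaxing"])
                diffs = (paired["alerting"] - paired["relaxing"]).to_numpy()
                if diffs.size < min_pairs:
                    row.update(
                        n_pairs=int(diffs.size), test_used=None, statistic=np.nan,
                        df=np.nan, p_raw=np.nan,
                        reason=f"only {diffs.size} pairs (< {min_pairs})",
                    )
                    rows.append(row)
                    continue
                row.update(n_pairs=int(diffs.size), reason="")
                row.update(_paired_test(diffs, gate_alpha=gate_alpha))
                rows.append(row)
    table = pd.DataFrame(rows)
    table["p_adjusted"] = np.nan
    table["significant"] = False
    for _, idx in table.groupby(list(fdr_family), observed=True).groups.items():
        adj, flags = bh_fdr(table.loc[idx, "p_raw"].to_numpy(), alpha=fdr_alpha)
        table.loc[idx, "p_adjusted"] = adj
        table.loc[idx, "significant"] = flags
    return table


# --- Reaction-time analyses -------------------------------------------------


def rt_epoch_table(events: pd.DataFrame) -> pd.DataFrame:
    """Epoch-mean RTs with piecewise baseline standardization.

    ``events`` has columns subject, condition, time_s, rt_s (the events
    CSV layout).  Epochs >= 6 ([30-60] min) are divided by epoch 5; the
    earlier epochs by epoch 0.
    """
    df = events.copy()
    df["epoch_group"] = (df["time_s"] // 300).astype(int)
    means = (
        df.groupby(["subject", "condition", "epoch_group"], observed=True)["rt_s"]
        .mean()
        .rename("rt_mean_raw")
        .reset_index()
    )
    key = ["subject", "condition"]
    for name, epoch in (("_b0", 0), ("_b5", BASELINE_EPOCH)):
        base = (
            means[means["epoch_group"] == epoch]
            .set_index(key)["rt_mean_raw"]
            .rename(name)
        )
        means = means.join(base, on=key)
    means["rt_mean_std"] = np.where(
        means["epoch_group"] > BASELINE_EPOCH,
        means["rt_mean_raw"] / means["_b5"],
        means["rt_mean_raw"] / means["_b0"],
    )
    return means.drop(columns=["_b0", "_b5"])


def rt_contrast(
    rt_table: pd.DataFrame,
    window: Sequence[int] = DEFAULT_WINDOW,
    pooling: str = "epochs",
) -> dict:
    """Paired t-test on standardized RT over the analysis window.

    ``pooling="epochs"`` (default) pools subjects x window epochs (30
    subjects x 3 epochs -> df = 89, the published layout); because every
    epoch of a subject shares that subject's baseline-epoch divisor, the
    pairs are positively correlated and the pooled test is mildly
    anticonservative under the null.  ``pooling="subjects"`` averages
    the window epochs within each subject first (df = n_subjects - 1),
    which restores exact calibration.  The statistic is negative when
    the alerting condition has shorter RTs than the relaxing condition.
    Unmatched (subject, epoch) pairs are dropped and counted.
    """
    if pooling not in ("epochs", "subjects"):
        raise ValueError(f"unknown pooling {pooling!r}")
    data = rt_table[rt_table["epoch_group"].isin(list(window))]
    if pooling == "subjects":
        data = (
            data.groupby(["subject", "condition"], observed=True)["rt_mean_std"]
            .mean()
            .reset_index()
            .assign(epoch_group=-1)
        )
    wide = data.pivot_table(
        index=["subject", "epoch_group"], columns="condition",
        values="rt_mean_std", observed=True,
    )
    for cond in ("alerting", "relaxing"):
        if cond not in wide:
            raise ValueError(f"condition {cond!r} absent from RT table")
    n_total = len(wide)
    wide = wide.dropna()
    diffs = (wide["alerting"] - wide["relaxing"]).to_numpy()
    if diffs.size < 2:
        raise ValueError("fewer than 2 paired RT observations")
    res = sps.ttest_1samp(diffs, 0.0)
    return {
        "t": float(res.statistic),
        "df": int(diffs.size - 1),
        "p": float(res.pvalue),
        "n_pairs": int(diffs.size),
        "n_dropped": int(n_total - diffs.size),
        "mean_diff": float(diffs.mean()),
    }


def rt_anova(
    rt_table: pd.DataFrame, window: Sequence[int] = tuple(range(6, 12))
) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA: condition x epoch, subject blocked.

    Requires a complete within-subject layout over the window; missing
    cells raise an error listing them.
    """
    from statsmodels.stats.anova import AnovaRM

    data = rt_table[rt_table["epoch_group"].isin(list(window))].copy()
    cells = data.groupby(
        ["subject", "condition", "epoch_group"], observed=True
    ).size()
    expected = (
        data["subject"].nunique() * data["condition"].nunique() * len(list(window))
    )
    if len(cells) != expected or (cells != 1).any():
        present = set(cells.index)
        missing = [
            (s, c, e)
            for s in data["subject"].unique()
            for c in data["condition"].unique()
            for e in window
            if (s, c, e) not in present
        ]
        raise ValueError(f"incomplete RM-ANOVA layout; missing cells: {missing[:10]}")
    if np.ptp(data["rt_mean_std"].to_numpy()) == 0:
        # Degenerate all-equal input: every effect sum of squares is zero.
        return pd.DataFrame(
            {"F": [0.0] * 3, "p": [1.0] * 3, "df1": [np.nan] * 3, "df2": [np.nan] * 3},
            index=["condition", "epoch", "condition_x_epoch"],
        )
    fit = AnovaRM(
        data, depvar="rt_mean_std", subject="subject",
        within=["condition", "epoch_group"],
    ).fit()
    table = fit.anova_table.rename(
        columns={"F Value": "F", "Pr > F": "p", "Num DF": "df1", "Den DF": "df2"}
    )
    table.index = ["condition", "epoch", "condition_x_epoch"]
    return table


def rt_metric_correlation(
    std_table: pd.DataFrame,
    rt_table: pd.DataFrame,
    band: str = "alpha",
    window: Sequence[int] = DEFAULT_WINDOW,
    metrics: Sequence[str] = METRIC_NAMES,
    fdr_alpha: float = 0.05,
    min_pairs: int = 10,
    channels: Sequence[str] = CHANNELS_1020,
) -> pd.DataFrame:
    """Pearson r between standardized RT and metric, per (channel, metric).

    Rows are pooled over subjects, conditions and window epochs; BH-FDR
    is applied across the 19 channels within each metric.  Triples with
    fewer than ``min_pairs`` matched rows are skipped.
    """
    m = std_table[
        (std_table["band"] == band)
        & std_table["epoch_group"].isin(list(window))
        & std_table["metric"].isin(list(metrics))
    ]
    rt = rt_table[rt_table["epoch_group"].isin(list(window))].rename(
        columns={"subject": "subject_id"}
    )
    merged = m.merge(
        rt[["subject_id", "condition", "epoch_group", "rt_mean_std"]],
        on=["subject_id", "condition", "epoch_group"],
    )
    rows = []
    for metric in metrics:
        for channel in channels:
            sel = merged[(merged["metric"] == metric) & (merged["channel"] == channel)]
            sel = sel.dropna(subset=["value_std", "rt_mean_std"])
            row = {"metric": metric, "band": band, "channel": channel,
                   "n": int(len(sel))}
            if len(sel) < min_pairs:
                row.update(r=np.nan, p_raw=np.nan, reason="insufficient pairs")
            else:
                res = sps.pearsonr(sel["value_std"], sel["rt_mean_std"])
                row.update(r=float(res.statistic), p_raw=float(res.pvalue), reason="")
            rows.append(row)
    table = pd.DataFrame(rows)
    table["p_adjusted"] = np.nan
    table["significant"] = False
    for _, idx in table.groupby("metric", observed=True).groups.items():
        adj, flags = bh_fdr(table.loc[idx, "p_raw"].to_numpy(), alpha=fdr_alpha)
        table.loc[idx, "p_adjusted"] = adj
        table.loc[idx, "significant"] = flags
    return table


# --- Screening and reporting -------------------------------------------------


def sact_exclusion(
    session1_counts: tuple[int, int],
    session2_counts: tuple[int, int],
    session1_rt: Sequence[float],
    session2_rt: Sequence[float],
    alpha: float = 0.05,
) -> dict:
    """Between-session baseline-attention screening.

    Fisher's exact test on the 2x2 (correct, incorrect) accuracy table
    AND a two-sample Welch t-test on the RT samples; the subject is
    dropped only when both are significant.  Degenerate tables (a zero
    margin) keep the subject and are logged.
    """
    table = np.array([list(session1_counts), list(session2_counts)], dtype=int)
    out: dict = {"log": []}
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        out["log"].append("degenerate accuracy table (zero margin); keeping subject")
        out.update(p_accuracy=np.nan, p_rt=np.nan, drop=False)
        return out
    p_acc = float(sps.fisher_exact(table).pvalue)
    p_rt = float(
        sps.ttest_ind(
            np.asarray(session1_rt, float), np.asarray(session2_rt, float),
            equal_var=False,
        ).pvalue
    )
    out.update(p_accuracy=p_acc, p_rt=p_rt, drop=(p_acc < alpha) and (p_rt < alpha))
    return out


def count_significant(significance_table: pd.DataFrame) -> dict:
    """Summary counts: candidates, significant, frontal/parietal significant.

    Accepts either a full significance table (one row per candidate,
    boolean ``significant``) or a bare list of significant triples such
    as the packaged published table, in which case the candidate count
    is the full 5 x 5 x 19 design.
    """
    if "significant" in significance_table.columns:
        sig = significance_table[significance_table["significant"].fillna(False)]
        n_candidates = int(len(significance_table))
    else:
        sig = significance_table
        n_candidates = len(METRIC_NAMES) * len(BAND_NAMES) * len(CHANNELS_1020)
    fp = set(FRONTAL_CHANNELS) | set(PARIETAL_CHANNELS)
    return {
        "n_candidates": n_candidates,
        "n_significant": int(len(sig)),
        "n_frontal_parietal": int(sig["channel"].isin(fp).sum()),
    }
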