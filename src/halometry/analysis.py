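"""Pre/post group analysis: deterioration, BrAC grouping, paired tests,
regression, and report tables.

The study design this mirrors: every subject takes the test before and
after drinking, monocularly and binocularly; breath alcohol content
(BrAC, mg ethanol per litre of exhaled air) is the exposure; the outcome
is the visual disturbance index (VDI).  Deterioration is VDI(post) -
VDI(pre), positive when discrimination worsens.  Subjects split at the
0.25 mg/l BrAC driving limit into low and high cohorts.  Tests are the
classical closed-form paired t and ordinary least squares; p-values are
reported raw by default, with optional Holm correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def vdi_deterioration(pre_vdi, post_vdi):
    """VDI(post) - VDI(pre); positive means discrimination deteriorated."""
    pre = np.asarray(pre_vdi, dtype=float)
    post = np.asarray(post_vdi, dtype=float)
    for name, v in (("pre_vdi", pre), ("post_vdi", post)):
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"{name} must lie in [0, 1]")
    out = post - pre
    return out if out.ndim else float(out)


def group_by_brac(
    records: pd.DataFrame, threshold_mg_per_l: float = 0.25
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition subject records at the BrAC threshold (boundary goes low).

    Subjects with missing BrAC are excluded with a warning.  Returns
    ``(low, high)`` frames: BrAC <= threshold and BrAC > threshold.
    """
    if "brac_mg_per_l" not in records.columns:
        raise ValueError("records need a brac_mg_per_l column")
    missing = records["brac_mg_per_l"].isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} record(s) without BrAC excluded from grouping",
            stacklevel=2,
        )
        records = records[~missing]
    low = records[records["brac_mg_per_l"] <= threshold_mg_per_l].reset_index(drop=True)
    high = records[records["brac_mg_per_l"] > threshold_mg_per_l].reset_index(drop=True)
    return low, high


@dataclass(frozen=True)
class PairedResult:
    mean_difference: float
    t_statistic: float
    p_value: float
    df: int
    degenerate: bool = False


def paired_comparison(pre_values, post_values) -> PairedResult:
    """Classical paired-sample t test on post - pre differences.

    Zero-variance differences cannot support a t statistic: identical
    vectors return t = 0, p = 1; a constant nonzero difference is flagged
    degenerate with an infinite t.
    """
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post vectors must have equal length")
    n = len(pre)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = post - pre
    mean = float(diff.mean())
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.isclose(mean, 0.0):
            return PairedResult(0.0, 0.0, 1.0, n - 1, degenerate=True)
        return PairedResult(mean, float("inf") if mean > 0 else float("-inf"),
                            0.0, n - 1, degenerate=True)
    t, p = stats.ttest_rel(post, pre)
    return PairedResult(mean, float(t), float(p), n - 1)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr: float


def deterioration_regression(deteriorations, bracs) -> RegressionResult:
    """OLS fit of VDI deterioration on BrAC, with r² and slope test."""
    y = np.asarray(deteriorations, dtype=float)
    x = np.asarray(bracs, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(x.std(), 0.0):
        raise ValueError("BrAC is constant; regression is undefined")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        stderr=float(fit.stderr),
    )


def _monocular_per_subject(records: pd.DataFrame) -> pd.DataFrame:
    """One monocular VDI per subject/condition: the mean of the two eyes."""
    mono = records[records["eye"].isin(["right", "left"])]
    return (
        mono.groupby(["subject_id", "condition"], as_index=False)
        .agg(vdi=("vdi", "mean"), brac_mg_per_l=("brac_mg_per_l", "first"),
             pupil_mm=("pupil_mm", "first"))
    )


def _mean_sd(values: pd.Series) -> str:
    if len(values) == 0:
        return "-"
    if len(values) == 1:
        return f"{values.iloc[0]:.2f} ± NA"
    return f"{values.mean():.2f} ± {values.std(ddof=1):.2f}"


def _paired_by_subject(frame: pd.DataFrame, value: str) -> tuple[np.ndarray, np.ndarray]:
    wide = frame.pivot_table(index="subject_id", columns="condition", values=value)
    wide = wide.dropna(subset=[c for c in ("pre", "post") if c in wide.columns])
    if "pre" not in wide.columns or "post" not in wide.columns:
        return np.array([]), np.array([])
    return wide["pre"].to_numpy(), wide["post"].to_numpy()


@dataclass
class Report:
    """Summary tables plus the deterioration regression."""

    summary_table: pd.DataFrame  # per-measure rows, pre/post columns, p-values
    brac_table: pd.DataFrame  # same rows split by BrAC cohort
    regression: RegressionResult | None
    eye_level_table: pd.DataFrame  # monocular summaries with eyes as rows

    def to_text(self) -> str:
        parts = ["Summary (mean ± SD)", self.summary_table.to_string(index=False),
                 "", "By BrAC cohort (mean ± SD)", self.brac_table.to_string(index=False)]
        if self.regression is not None:
            r = self.regression
            parts += ["", (f"Deterioration vs BrAC: slope={r.slope:.3f}, "
                           f"intercept={r.intercept:.3f}, r²={r.r_squared:.3f}, "
                           f"p={r.p_value:.3g}")]
        return "\n".join(parts)


def _summary_rows(records: pd.DataFrame, holm: bool = False) -> pd.DataFrame:
    mono = _monocular_per_subject(records)
    bino = records[records["eye"] == "binocular"]
    rows = []
    specs = [
        ("VDI monocular (mean of eyes)", mono, "vdi"),
        ("VDI binocular", bino, "vdi"),
        ("Pupil size (mm)", mono, "pupil_mm"),
    ]
    pvals = []
    for label, frame, col in specs:
        if frame.empty or frame[col].isna().all():
            warnings.warn(f"no data for row {label!r}; omitted", stacklevel=3)
            continue
        pre = frame[frame["condition"] == "pre"][col].dropna()
        post = frame[frame["condition"] == "post"][col].dropna()
        pre_v, post_v = _paired_by_subject(frame.dropna(subset=[col]), col)
        if len(pre_v) >= 2:
            res = paired_comparison(pre_v, post_v)
            p = res.p_value
        else:
            p = float("nan")
        rows.append({"measure": label, "pre": _mean_sd(pre), "post": _mean_sd(post),
                     "p_value": p})
        pvals.append(p)
    table = pd.DataFrame(rows)
    if holm and len(table):
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.full(m, np.nan)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * pvals[i])
            adj[i] = min(running, 1.0)
        table["p_holm"] = adj
    return table


def make_report(
    records: pd.DataFrame,
    *,
    brac_threshold_mg_per_l: float = 0.25,
    holm: bool = False,
) -> Report:
    """Build the pre/post report: summary table, BrAC-split table, regression.

    ``records`` is the tidy subjects frame (columns ``subject_id,
    condition, eye, vdi, brac_mg_per_l, pupil_mm``).  Monocular VDI is
    reported both per eye (eye-level table) and as the per-subject mean of
    the two eyes (summary rows); the deterioration regression uses
    binocular VDI.  Conditions or measures with no data are omitted with a
    warning.
    """
    required = {"subject_id", "condition", "eye", "vdi"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if "pupil_mm" not in records.columns:
        records = records.assign(pupil_mm=np.nan)
    if "brac_mg_per_l" not in records.columns:
        records = records.assign(brac_mg_per_l=np.nan)

    summary = _summary_rows(records, holm=holm)

    low, high = group_by_brac(records.dropna(subset=["brac_mg_per_l"]),
                              brac_threshold_mg_per_l) if records["brac_mg_per_l"].notna().any() else (
        records.iloc[0:0], records.iloc[0:0])
    brac_rows = []
    for cohort_label, cohort in ((f"BrAC <= {brac_threshold_mg_per_l}", low),
                                 (f"BrAC > {brac_threshold_mg_per_l}", high)):
        if cohort.empty:
            continue
        part = _summary_rows(cohort)
        part.insert(0, "cohort", cohort_label)
        part["n_subjects"] = cohort["subject_id"].nunique()
        brac_rows.append(part)
    brac_table = pd.concat(brac_rows, ignore_index=True) if brac_rows else pd.DataFrame()

    regression = None
    bino = records[records["eye"] == "binocular"].dropna(subset=["brac_mg_per_l"])
    pre_v, post_v = _paired_by_subject(bino, "vdi")
    if len(pre_v) >= 3:
        det = vdi_deterioration(pre_v, post_v)
        wide = bino.pivot_table(index="subject_id", columns="condition", values="vdi").dropna()
        bracs = bino.groupby("subject_id")["brac_mg_per_l"].first().loc[wide.index]
        try:
            regression = deterioration_regression(det, bracs.to_numpy())
        except ValueError:
            regression = None

    eye_level = (
        records[records["eye"].isin(["right", "left"])]
        .groupby(["condition", "eye"], as_index=False)
        .agg(n=("vdi", "size"), vdi_mean=("vdi", "mean"), vdi_sd=("vdi", "std"))
    )
    return Report(summary_table=summary, brac_table=brac_table,
                  regression=regression, eye_level_table=eye_level)


def plot_deterioration(records: pd.DataFrame, path=None):
    """Scatter of binocular VDI deterioration against BrAC with OLS line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bino = records[records["eye"] == "binocular"].dropna(subset=["brac_mg_per_l"])
    wide = bino.pivot_table(index="subject_id", columns="condition", values="vdi").dropna()
    bracs = bino.groupby("subject_id")["brac_mg_per_l"].first().loc[wide.index].to_numpy()
    det = vdi_deterioration(wide["pre"].to_numpy(), wide["post"].to_numpy())
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(bracs, det, color="tab:blue")
    if len(bracs) >= 3 and not np.allclose(bracs.std(), 0):
        fit = deterioration_regression(det, bracs)
        xs = np.linspace(bracs.min(), bracs.max(), 50)
        ax.plot(xs, fit.intercept + fit.slope * xs, "k-",
                label=f"r² = {fit.r_squared:.3f}, p = {fit.p_value:.3g}")
        ax.legend()
    ax.set_xlabel("BrAC (mg/l)")
    ax.set_ylabel("VDI deterioration (post − pre)")
    ax.axhline(0, color="0.7", lw=0.8)
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig
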