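"""Cohort-level statistics: paired pre/post comparisons and the
entropy-by-RRI correlation matrices.

Pre- vs post-ablation entropy is compared with a two-sided paired t-test
on per-patient values (one value per patient, phase and channel, the
mean over its analysis windows); results are reported as mean ± SD in
each group. Associations between atrial entropy and ventricular metrics
are computed per 50 s window: parametric Pearson correlation for the
variability metrics, non-parametric Spearman correlation for the
irregularity metrics (SampEn and normalized SampEn). Normality is
assessed with the D'Agostino–Pearson omnibus test for reporting;
no multiple-comparison correction is applied. Significance is starred
at p < 0.05 (*), < 0.01 (**) and < 0.001 (***).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .entropy import eligibility_filter, patient_entropy
from .records import CS_CHANNELS
from .rri import IRREGULARITY_METRICS, RRI_METRIC_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "NormalityResult",
    "PairedComparison",
    "CorrelationCell",
    "CohortTables",
    "normality_test",
    "paired_pre_post",
    "correlate",
    "significance_stars",
    "build_tables",
]

ENTROPY_PARAMS = ("shen", "sampen")
PARAM_LABELS = {"shen": "ShEn", "sampen": "SampEn"}


@dataclass(frozen=True)
class NormalityResult:
    statistic: float  # K^2 omnibus statistic
    p_value: float
    n: int
    reliable: bool    # False below the test's validity floor (n < 20)


@dataclass(frozen=True)
class PairedComparison:
    parameter: str
    channel: str
    n_pairs: int
    mean_pre: float
    sd_pre: float
    mean_post: float
    sd_post: float
    statistic: float
    p_value: float
    degenerate: bool = False  # zero-variance differences


@dataclass(frozen=True)
class CorrelationCell:
    parameter: str     # atrial entropy parameter (shen | sampen)
    channel: str
    rri_metric: str
    phase: str
    method: str        # pearson | spearman
    r: float
    p_value: float
    n: int


@dataclass
class CohortTables:
    """Paired-comparison table plus the two correlation matrices."""

    table1: pd.DataFrame
    table2: pd.DataFrame  # atrial ShEn vs RRI metrics
    table3: pd.DataFrame  # atrial SampEn vs RRI metrics
    raw: dict = field(default_factory=dict)


def normality_test(values) -> NormalityResult:
    """D'Agostino–Pearson omnibus normality test (K² against chi²₂)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 8:
        raise ValueError(f"normality test needs n >= 8, got {n}")
    k2, p = stats.normaltest(x)
    reliable = n >= 20
    if not reliable:
        logger.info("normality_test: n=%d below validity floor 20", n)
    return NormalityResult(statistic=float(k2), p_value=float(p), n=n, reliable=reliable)


def paired_pre_post(pre, post, parameter: str = "", channel: str = "") -> PairedComparison:
    """Two-sided paired t-test on matched per-patient values.

    Zero-variance differences are handled explicitly: identical pairs
    give t = 0, p = 1; a constant nonzero shift is flagged degenerate
    with p reported at the machine floor.
    """
    a = np.asarray(pre, dtype=float)
    b = np.asarray(post, dtype=float)
    if a.shape != b.shape:
        raise ValueError("pre and post must be matched (equal length)")
    if a.size < 2:
        raise ValueError(f"need >= 2 pairs, got {a.size}")
    d = a - b
    degenerate = False
    if np.std(d, ddof=1) == 0.0:
        if d[0] == 0.0:
            t, p = 0.0, 1.0
        else:
            t = np.inf if d[0] > 0 else -np.inf
            p = float(np.finfo(float).tiny)
            degenerate = True
            logger.info("paired_pre_post: zero-variance nonzero differences")
    else:
        t, p = stats.ttest_rel(a, b)
    return PairedComparison(
        parameter=parameter, channel=channel, n_pairs=int(a.size),
        mean_pre=float(a.mean()), sd_pre=float(a.std(ddof=1)),
        mean_post=float(b.mean()), sd_post=float(b.std(ddof=1)),
        statistic=float(t), p_value=float(p), degenerate=degenerate,
    )


def correlate(
    entropy_values,
    rri_values,
    rri_metric: str,
    parameter: str = "",
    channel: str = "",
    phase: str = "",
) -> CorrelationCell:
    """Window-level correlation between atrial entropy and one RRI metric.

    Spearman for the irregularity metrics (SampEn, normalized SampEn),
    Pearson for the variability metrics. Constant input on either side
    leaves r undefined (NaN).
    """
    x = np.asarray(entropy_values, dtype=float)
    y = np.asarray(rri_values, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need >= 3 paired observations, got {x.size}")
    method = "spearman" if rri_metric in IRREGULARITY_METRICS else "pearson"
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        logger.info("correlate: constant input, r undefined (%s/%s/%s)",
                    parameter, channel, rri_metric)
        r, p = float("nan"), float("nan")
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        r, p = stats.pearsonr(x, y)
    return CorrelationCell(
        parameter=parameter, channel=channel, rri_metric=rri_metric,
        phase=phase, method=method, r=float(r), p_value=float(p), n=int(x.size),
    )


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def format_p(p: float) -> str:
    """Rendered-table style: floor small p-values at '< 0.001'."""
    if not np.isfinite(p):
        return ""
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


def _patient_level(entropy_df: pd.DataFrame, param: str) -> pd.DataFrame:
    rows = []
    for (pid, phase, ch), grp in entropy_df.groupby(
        ["patient_id", "phase", "channel"], sort=True
    ):
        rows.append({
            "patient_id": pid, "phase": phase, "channel": ch,
            "value": patient_entropy(grp[param]),
        })
    return pd.DataFrame(rows)


def build_tables(
    entropy_df: pd.DataFrame,
    rri_df: pd.DataFrame | None = None,
    pvi_threshold: float = 0.70,
    channels: tuple[str, ...] = CS_CHANNELS,
) -> CohortTables:
    """Assemble the paired-comparison table and correlation matrices.

    ``entropy_df`` is the long per-window table (patient_id, phase,
    window_index, channel, shen, sampen, pvi_completion); ``rri_df``
    carries one row per (patient_id, phase, window_index) with the RRI
    metric columns. Paired comparisons use patients at or above the PVI
    completion threshold with both phases; correlations pair entropy and
    RRI values of the same 50 s window and use every available window.
    Missing cells are emitted with NaN values and a reason code.
    """
    empty_cols1 = ["parameter", "channel", "n_pairs", "mean_pre", "sd_pre",
                   "mean_post", "sd_post", "statistic", "p_value", "stars", "reason"]
    if entropy_df.empty:
        t1 = pd.DataFrame(columns=empty_cols1)
        t23 = pd.DataFrame()
        return CohortTables(table1=t1, table2=t23, table3=t23.copy(), raw={})

    meta = entropy_df[["patient_id", "phase", "pvi_completion"]].drop_duplicates()
    _, paired_ids = eligibility_filter(meta, threshold=pvi_threshold)

    rows1 = []
    raw: dict = {"paired": [], "correlations": []}
    for param in ENTROPY_PARAMS:
        plevel = _patient_level(entropy_df, param)
        for ch in channels:
            sub = plevel[(plevel["channel"] == ch)]
            pre = sub[sub["phase"] == "pre"].set_index("patient_id")["value"]
            post = sub[sub["phase"] == "post"].set_index("patient_id")["value"]
            ids = sorted(
                (paired_ids & set(pre.index) & set(post.index)),
            )
            ids = [i for i in ids if np.isfinite(pre[i]) and np.isfinite(post[i])]
            if len(ids) < 2:
                rows1.append({
                    "parameter": PARAM_LABELS[param], "channel": ch,
                    "n_pairs": len(ids), "mean_pre": np.nan, "sd_pre": np.nan,
                    "mean_post": np.nan, "sd_post": np.nan,
                    "statistic": np.nan, "p_value": np.nan, "stars": "",
                    "reason": "insufficient_pairs",
                })
                continue
            cmp_ = paired_pre_post(pre[ids], post[ids], parameter=param, channel=ch)
            raw["paired"].append(cmp_)
            rows1.append({
                "parameter": PARAM_LABELS[param], "channel": ch,
                "n_pairs": cmp_.n_pairs,
                "mean_pre": cmp_.mean_pre, "sd_pre": cmp_.sd_pre,
                "mean_post": cmp_.mean_post, "sd_post": cmp_.sd_post,
                "statistic": cmp_.statistic, "p_value": cmp_.p_value,
                "stars": significance_stars(cmp_.p_value), "reason": "",
            })
    table1 = pd.DataFrame(rows1, columns=empty_cols1)

    corr_tables = {"shen": pd.DataFrame(), "sampen": pd.DataFrame()}
    if rri_df is not None and not rri_df.empty:
        merged = entropy_df.merge(
            rri_df, on=["patient_id", "phase", "window_index"], how="inner",
            suffixes=("_atrial", "_rri"),
        )

        def col(name: str, side: str) -> str:
            return f"{name}_{side}" if f"{name}_{side}" in merged.columns else name

        for param in ENTROPY_PARAMS:
            rows = []
            for metric in RRI_METRIC_NAMES:
                for ch in channels:
                    for phase in ("pre", "post"):
                        sub = merged[(merged["channel"] == ch) & (merged["phase"] == phase)]
                        if len(sub) < 3:
                            rows.append({
                                "rri_metric": metric, "channel": ch, "phase": phase,
                                "method": "", "r": np.nan, "p_value": np.nan,
                                "n": len(sub), "stars": "", "reason": "insufficient_windows",
                            })
                            continue
                        cell = correlate(
                            sub[col(param, "atrial")], sub[col(metric, "rri")],
                            metric, parameter=param, channel=ch, phase=phase,
                        )
                        raw["correlations"].append(cell)
                        rows.append({
                            "rri_metric": metric, "channel": ch, "phase": phase,
                            "method": cell.method, "r": cell.r,
                            "p_value": cell.p_value, "n": cell.n,
                            "stars": significance_stars(cell.p_value), "reason": "",
                        })
            corr_tables[param] = pd.DataFrame(rows)

    return CohortTables(
        table1=table1,
        table2=corr_tables["shen"],
        table3=corr_tables["sampen"],
        raw=raw,
    )
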