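"""Longitudinal paired-eye statistics.

Per (measure, region, day): a two-sided paired t-test between the injected and
control eye across subjects, Benjamini-Hochberg FDR correction (default
q = 0.1, applied per measure x region family), percent-change summaries, and a
tidy results table.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import DAYS, MEASURE_NAMES


@dataclass
class ComparisonRecord:
    measure: str
    region: str
    day: int
    n: int
    mean_injected_um: float
    mean_control_um: float
    percent_change: float
    t: float
    p: float
    p_fdr: float
    significant: bool
    flagged: bool = False   # degenerate test (zero-variance differences, n < 2)


def paired_t(injected: np.ndarray, control: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test; returns (t, p).

    (nan, nan) signals a degenerate test (zero-variance differences).
    """
    injected = np.asarray(injected, float)
    control = np.asarray(control, float)
    if injected.shape != control.shape:
        raise ValueError("paired samples must have equal length")
    if len(injected) < 2:
        raise ValueError("need n >= 2 pairs")
    diffs = injected - control
    if np.allclose(diffs.std(ddof=1), 0.0):
        if np.allclose(diffs, 0.0):
            return 0.0, 1.0
        return np.nan, np.nan
    res = sps.ttest_rel(injected, control)
    return float(res.statistic), float(res.pvalue)


def fdr_correct(pvals: np.ndarray, q: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection flags at q).

    adjusted p_(i) = min_{j >= i} (m * p_(j) / j), clipped to 1.  NaN p-values
    propagate to NaN adjusted values and are never rejected.
    """
    p = np.asarray(pvals, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adj = np.full(p.shape, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    pf = p[finite]
    m = pf.size
    if m:
        order = np.argsort(pf, kind="stable")
        ranked = pf[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        ranked = np.clip(ranked, 0.0, 1.0)
        adj_f = np.empty(m)
        adj_f[order] = ranked
        rej_f = adj_f <= q
        adj[finite] = adj_f
        reject[finite] = rej_f
    return adj, reject


def percent_change(mean_injected: float, mean_control: float) -> float:
    """100 * (injected - control) / control; negative = thinning."""
    if mean_control <= 0:
        raise ValueError("control mean must be > 0")
    return 100.0 * (mean_injected - mean_control) / mean_control


def longitudinal_analysis(
    table: pd.DataFrame,
    fdr_q: float = 0.1,
    alpha: float = 0.05,
    family: str = "panel",
) -> pd.DataFrame:
    """Paired-eye comparisons from a tidy thickness table.

    ``table`` columns: subject, eye ('injected'/'control'), day, measure,
    region, mean_um.  One ComparisonRecord per (measure, region, day); the FDR
    family is every day within one measure x region panel (``family='panel'``)
    or all records at once (``family='global'``).  Subjects missing one eye at
    a day are dropped from that comparison.
    """
    required = {"subject", "eye", "day", "measure", "region", "mean_um"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"thickness table missing columns: {sorted(missing)}")
    if family not in ("panel", "global"):
        raise ValueError("family must be 'panel' or 'global'")

    wide = table.pivot_table(
        index=["measure", "region", "day", "subject"],
        columns="eye", values="mean_um", aggfunc="first",
    )
    records: list[ComparisonRecord] = []
    for (measure, region, day), grp in wide.groupby(level=[0, 1, 2]):
        paired = grp.dropna(subset=["injected", "control"])
        n = len(paired)
        if n < 2:
            continue
        inj = paired["injected"].to_numpy()
        ctl = paired["control"].to_numpy()
        t, p = paired_t(inj, ctl)
        records.append(ComparisonRecord(
            measure=measure, region=region, day=int(day), n=n,
            mean_injected_um=float(inj.mean()),
            mean_control_um=float(ctl.mean()),
            percent_change=percent_change(float(inj.mean()), float(ctl.mean())),
            t=t, p=p, p_fdr=np.nan, significant=False,
            flagged=not np.isfinite(p),
        ))

    df = pd.DataFrame([asdict(r) for r in records])
    if df.empty:
        return df
    if family == "global":
        adj, _ = fdr_correct(df["p"].to_numpy(), q=fdr_q)
        df["p_fdr"] = adj
    else:
        for _, idx in df.groupby(["measure", "region"]).groups.items():
            adj, _ = fdr_correct(df.loc[idx, "p"].to_numpy(), q=fdr_q)
            df.loc[idx, "p_fdr"] = adj
    df["significant"] = df["p_fdr"] < alpha
    order = {m: i for i, m in enumerate(MEASURE_NAMES)}
    df = df.sort_values(
        ["measure", "region", "day"],
        key=lambda s: s.map(order) if s.name == "measure" else s,
    ).reset_index(drop=True)
    return df
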