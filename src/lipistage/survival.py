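"""Kaplan–Meier product-limit estimation and the log-rank test.

The estimator is the standard product-limit form

    S(t) = Π_{tᵢ ≤ t} (1 − dᵢ / nᵢ),

over distinct event times tᵢ with dᵢ events and nᵢ subjects at risk;
censored observations reduce risk sets only.  Ties between events and
censorings at the same time are resolved events-first (the usual
convention).  Greenwood's variance accompanies each curve.

The k-sample log-rank statistic accumulates observed-minus-expected events
over shared risk sets with the hypergeometric covariance and refers
(O−E)ᵀ V⁻ (O−E) on k−1 dimensions to a chi-square with k−1 degrees of
freedom.

Endpoint horizons (disease-free survival to 5 years, overall survival to
8 years) are applied as administrative censoring before estimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .ingest import ClinicalTable

#: administrative censoring horizons, months
HORIZONS = {"DFS": 60.0, "OS": 96.0}

_ENDPOINT_COLUMNS = {"DFS": ("dfs_months", "dfs_event"),
                     "OS": ("os_months", "os_event")}


@dataclass
class SurvivalCurve:
    """Product-limit estimate at the distinct event times, with risk-set
    sizes, event counts, Greenwood variance and the censoring times."""

    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    censor_times: np.ndarray
    n_subjects: int

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous, S(t) = 1 before the first
        event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def median(self) -> float:
        """Smallest event time with S(t) ≤ 0.5 (NaN if never reached)."""
        below = self.survival <= 0.5
        return float(self.event_times[below][0]) if below.any() else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times,
            "n_at_risk": self.n_at_risk,
            "n_events": self.n_events,
            "survival": self.survival,
            "greenwood_var": self.greenwood_var,
        })


@dataclass
class LogRankResult:
    chi2: float
    df: int
    p: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {"chi2": self.chi2, "df": self.df, "p": self.p,
                "degenerate": self.degenerate}


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimate.

    ``events`` is 1 for an observed event, 0 for a censored observation.
    """
    t = np.asarray(times, dtype=float).ravel()
    e = np.asarray(events, dtype=int).ravel()
    if t.shape != e.shape:
        raise InputError("times and events differ in length")
    if t.size == 0:
        raise InputError("empty survival data")
    if (t < 0).any():
        raise InputError("negative survival times")
    if not np.isin(e, [0, 1]).all():
        raise InputError("events must be 0/1")

    event_times = np.unique(t[e == 1])
    n_at_risk = np.array([(t >= u).sum() for u in event_times], dtype=int)
    n_events = np.array([((t == u) & (e == 1)).sum() for u in event_times], dtype=int)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - n_events / n_at_risk
    survival = np.cumprod(frac)
    # Greenwood: Var[S(t)] = S(t)² Σ d/(n(n−d)); 0 once S hits 0
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = n_events / (n_at_risk * (n_at_risk - n_events).astype(float))
        greenwood = survival ** 2 * np.cumsum(inc)
    greenwood = np.where(np.isfinite(greenwood), greenwood, 0.0)
    return SurvivalCurve(
        event_times=event_times,
        n_at_risk=n_at_risk,
        n_events=n_events,
        survival=survival,
        greenwood_var=greenwood,
        censor_times=np.sort(t[e == 0]),
        n_subjects=t.size,
    )


def logrank_test(groups: Sequence[tuple]) -> LogRankResult:
    """k-sample log-rank test over shared risk sets.

    ``groups`` is a sequence of (times, events) pairs; returns the chi-square
    statistic on k−1 degrees of freedom.  With no events anywhere the result
    is degenerate (chi2 = 0, p = 1, flagged).
    """
    if len(groups) < 2:
        raise InputError("log-rank test needs at least 2 groups")
    ts, es = [], []
    for times, events in groups:
        t = np.asarray(times, dtype=float).ravel()
        e = np.asarray(events, dtype=int).ravel()
        if t.size == 0:
            raise InputError("each group needs at least one subject")
        if (t < 0).any():
            raise InputError("negative survival times")
        ts.append(t)
        es.append(e)
    k = len(ts)
    all_t = np.concatenate(ts)
    all_e = np.concatenate(es)
    labels = np.concatenate([np.full(t.size, g) for g, t in enumerate(ts)])
    event_times = np.unique(all_t[all_e == 1])
    if event_times.size == 0:
        return LogRankResult(0.0, k - 1, 1.0, degenerate=True)

    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for u in event_times:
        at_risk = all_t >= u
        n = at_risk.sum()
        d = ((all_t == u) & (all_e == 1)).sum()
        n_g = np.array([(at_risk & (labels == g)).sum() for g in range(k)], dtype=float)
        d_g = np.array([((all_t == u) & (all_e == 1) & (labels == g)).sum()
                        for g in range(k)], dtype=float)
        O += d_g
        E += d * n_g / n
        if n > 1:
            frac = n_g / n
            V += (d * (n - d) / (n - 1)) * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        chi2 = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff)
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(np.clip(stats.chi2.sf(chi2, df), np.finfo(float).tiny, 1.0))
    return LogRankResult(chi2, df, p)


# ---------------------------------------------------------------------------
# cohort-level analysis
# ---------------------------------------------------------------------------

@dataclass
class SurvivalAnalysis:
    """Per-group curves, the group comparison, and an at-risk table at
    12-month ticks."""

    endpoint: str
    curves: dict[str, SurvivalCurve]
    logrank: LogRankResult | None
    at_risk: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "groups": {g: c.n_subjects for g, c in self.curves.items()},
            "medians": {g: (None if np.isnan(c.median()) else c.median())
                        for g, c in self.curves.items()},
            "logrank": None if self.logrank is None else self.logrank.to_dict(),
        }


def _group_label(row: pd.Series) -> str:
    if row["group"] == "CRC" and pd.notna(row.get("stage")):
        return f"stage-{int(row['stage'])}"
    return str(row["group"])


def survival_by_group(
    clinical: ClinicalTable,
    endpoint: str,
    by: str = "stage",
    horizon: float | None = None,
    include_groups: Sequence[str] | None = None,
) -> SurvivalAnalysis:
    """One KM curve per patient group plus the log-rank comparison.

    ``by="stage"`` labels cancer samples by stage (mirroring per-stage
    survival plots); ``by="group"`` pools them by cohort (CFI/CRC/CLM).
    The endpoint horizon (60 months for DFS, 96 for OS by default) is
    applied as administrative censoring.  With a single group only the curve
    is returned, without a test.
    """
    if endpoint not in _ENDPOINT_COLUMNS:
        raise InputError(f"endpoint must be one of {tuple(_ENDPOINT_COLUMNS)}")
    tcol, ecol = _ENDPOINT_COLUMNS[endpoint]
    df = clinical.data
    missing = [c for c in (tcol, ecol) if c not in df.columns]
    if missing:
        raise InputError(f"clinical table lacks endpoint column(s) {missing}")
    df = df[df[tcol].notna() & df[ecol].notna()]
    if include_groups is not None:
        df = df[df["group"].isin(include_groups)]
    if df.empty:
        raise InputError(f"no samples with complete {endpoint} data")
    horizon = HORIZONS[endpoint] if horizon is None else horizon

    if by == "group":
        labels = df["group"].astype(str)
    elif by == "stage":
        labels = df.apply(_group_label, axis=1)
    else:
        raise InputError("by must be 'stage' or 'group'")

    times = df[tcol].to_numpy(dtype=float)
    events = df[ecol].to_numpy(dtype=int)
    over = times > horizon
    times = np.where(over, horizon, times)
    events = np.where(over, 0, events)

    curves: dict[str, SurvivalCurve] = {}
    group_data: list[tuple[np.ndarray, np.ndarray]] = []
    order = sorted(labels.unique())
    for g in order:
        sel = (labels == g).to_numpy()
        curves[g] = km_estimate(times[sel], events[sel])
        group_data.append((times[sel], events[sel]))

    result = logrank_test(group_data) if len(order) >= 2 else None

    tick_end = min(horizon, float(times.max())) + 1
    ticks = np.arange(0.0, tick_end, 12.0)
    at_risk = pd.DataFrame(
        {g: [int((group_data[i][0] >= tk).sum()) for tk in ticks]
         for i, g in enumerate(order)},
        index=pd.Index(ticks, name="months"),
    )
    return SurvivalAnalysis(endpoint, curves, result, at_risk)


def write_curves(analysis: SurvivalAnalysis, out_dir: str | Path) -> list[Path]:
    """Export each curve as CSV (time, n_at_risk, n_events, survival,
    greenwood_var)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for g, curve in analysis.curves.items():
        path = out / f"km_{analysis.endpoint.lower()}_{g}.csv"
        curve.to_frame().to_csv(path, index=False)
        paths.append(path)
    return paths
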