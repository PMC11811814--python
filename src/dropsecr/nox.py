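"""Droplet-level NOX activity: percent signal loss, threshold, labels.

A cell with active NADPH oxidases (NOXes) oxidizes the A647 fluorophore
in its droplet, so the droplet's whole-droplet A647 intensity decays over
the time lapse. The per-droplet statistic is the percent signal loss

    x = 100 * (signal(t1) - signal(lowest)) / signal(t1),

where ``signal(lowest)`` is the lowest intensity between the second and
the last time point. The classification threshold is median(x) + 3*SD(x)
over control droplets that contain the probe but no NOX activity; the
published operating value of that procedure is 10.3%, used as the fixed
default. Droplets with loss strictly greater than the threshold are
labeled NOX-active.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import welch_ttest, brown_forsythe_welch_anova, StatsResult

#: classification labels
NOX_POS = "NOX_drop_pos"
NOX_NEG = "NOX_drop_neg"

#: fixed default percent-loss threshold
DEFAULT_THRESHOLD_PCT = 10.3


@dataclass(frozen=True)
class SignalLossResult:
    droplet_id: str
    x_pct: float  # may be negative (signal rose); never clamped
    signal_t1: float
    signal_lowest: float


@dataclass(frozen=True)
class ThresholdModel:
    source: str  # "control_derived" | "fixed"
    threshold_pct: float
    median_pct: float | None = None
    sd_pct: float | None = None
    k: float = 3.0


def fixed_threshold(threshold_pct: float = DEFAULT_THRESHOLD_PCT) -> ThresholdModel:
    return ThresholdModel("fixed", threshold_pct)


def signal_loss(trace, droplet_id: str = "") -> SignalLossResult:
    """Percent A647 signal loss of one droplet trace (>= 2 frames).

    The minimum is taken over frames 2..T only; a rising trace yields a
    negative loss, which is retained.
    """
    y = np.asarray(trace, dtype=float)
    if y.size < 2:
        raise ValueError("signal_loss needs at least 2 frames")
    s1 = float(y[0])
    if s1 <= 0:
        raise ValueError("first-frame signal must be > 0")
    lowest = float(np.min(y[1:]))
    x = 100.0 * (s1 - lowest) / s1
    return SignalLossResult(droplet_id, x, s1, lowest)


def fit_threshold(control_losses, k: float = 3.0) -> ThresholdModel:
    """Control-derived threshold: median + k * sample SD of the control
    percent losses (k = 3). Requires >= 2 control droplets."""
    xs = np.asarray(
        [r.x_pct if isinstance(r, SignalLossResult) else float(r) for r in control_losses],
        dtype=float,
    )
    if xs.size < 2:
        raise ValueError(
            "need >= 2 control droplets to fit a threshold; "
            "use fixed_threshold() for the fixed default"
        )
    med = float(np.median(xs))
    sd = float(np.std(xs, ddof=1))
    return ThresholdModel("control_derived", med + k * sd, med, sd, k)


def classify_nox(x: SignalLossResult | float, model: ThresholdModel) -> str:
    """Label a droplet by strict comparison of its percent loss with the
    threshold; a loss exactly at the threshold is negative."""
    x_pct = x.x_pct if isinstance(x, SignalLossResult) else float(x)
    return NOX_POS if x_pct > model.threshold_pct else NOX_NEG


def classify_table(
    traces: pd.DataFrame,
    model: ThresholdModel,
    channel: str = "a647",
) -> pd.DataFrame:
    """Per-droplet signal-loss calls from a long trace table.

    ``traces`` columns: droplet_id, frame, time_s, channel, droplet_mean
    (and optionally n_cells, track_quality, condition). Returns one row
    per droplet: droplet_id, x_pct, signal_t1, signal_lowest,
    threshold_pct, label, plus carried-over metadata.
    """
    sub = traces[traces["channel"] == channel].sort_values(["droplet_id", "frame"])
    rows = []
    carry = [c for c in ("n_cells", "track_quality", "condition") if c in sub.columns]
    for did, grp in sub.groupby("droplet_id", sort=False):
        res = signal_loss(grp["droplet_mean"].to_numpy(), str(did))
        row = {
            "droplet_id": did,
            "x_pct": res.x_pct,
            "signal_t1": res.signal_t1,
            "signal_lowest": res.signal_lowest,
            "threshold_pct": model.threshold_pct,
            "label": classify_nox(res, model),
        }
        for c in carry:
            row[c] = grp[c].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def nox_frequency(calls: pd.DataFrame, by: str | list[str] | None = None) -> pd.DataFrame:
    """Percent of cell-containing, track-ok droplets labeled NOX-active.

    Droplets with ``track_quality != "ok"`` (when the column is present)
    or without cells are excluded from numerator and denominator. Zero
    denominators report NaN, not 0. ``by`` groups (e.g. by condition).
    """
    df = calls
    if "track_quality" in df.columns:
        df = df[df["track_quality"] == "ok"]
    if "n_cells" in df.columns:
        df = df[df["n_cells"] >= 1]

    def summarize(grp: pd.DataFrame) -> pd.Series:
        n = len(grp)
        pos = int((grp["label"] == NOX_POS).sum())
        return pd.Series(
            {
                "n_positive": pos,
                "n_total": n,
                "pct_positive": 100.0 * pos / n if n else float("nan"),
            }
        )

    if by is None:
        return summarize(df).to_frame().T
    out = df.groupby(by).apply(summarize, include_groups=False).reset_index()
    return out


def condition_contrast(freqs: pd.DataFrame, value: str = "pct_positive",
                       group: str = "condition") -> StatsResult | pd.DataFrame:
    """Compare replicate frequencies between conditions.

    Two groups -> Welch's t-test; more than two -> Brown-Forsythe & Welch
    ANOVA. A single replicate per group yields descriptive output only.
    """
    groups = [g[value].to_numpy(dtype=float) for _, g in freqs.groupby(group)]
    if len(groups) < 2:
        raise ValueError("need >= 2 conditions to contrast")
    if any(len(g) < 2 for g in groups):
        return (
            freqs.groupby(group)[value]
            .agg(["mean", "std", "count"])
            .reset_index()
        )
    if len(groups) == 2:
        return welch_ttest(groups[0], groups[1])
    return brown_forsythe_welch_anova(groups)
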