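"""Calibration curves and per-droplet secretion / ROS quantification.

IgG readout is *fluorescence relocation*: the ratio of the mean signal on
the nanoparticle beadline to the mean signal of the whole droplet. The
relocation-vs-concentration calibration is a saturating exponential

    R(c) = baseline + span * (1 - exp(-c / c0)),

strictly monotone on c >= 0. Lactate uses a linear intensity-vs-
concentration calibration. Concentrations are nM for IgG and uM for
lactate; amounts are converted through the droplet volume (50 pL) and
Avogadro's number into molecule counts (IgG) or attomoles (lactate).

A cell's secretion rate is the mean of the per-interval rates
(delta amount / delta time); negative per-interval rates are retained
(noise) and only the final mean is clamped at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .config import AssayConstants

# gate labels
GATE_IGG_SC = "igg_sc"
GATE_BELOW_LOD = "below_lod"
GATE_ABOVE_RANGE = "above_range"
GATE_IN_RANGE = "in_range"
GATE_EXCLUDED_MULTICELL = "excluded_multicell"
GATE_IGG_UNINTERPRETABLE = "igg_uninterpretable"


@dataclass
class CalibrationCurve:
    """Monotone readout <-> concentration map.

    kind "igg_relocation": params (baseline, span, c0), concentration nM.
    kind "lactate_linear": params (intercept, slope), concentration uM.
    """

    kind: str
    params: tuple[float, ...]
    conc_range: tuple[float, float] = (0.0, np.inf)
    fit_rss: float | None = None
    warn_nonmonotone: bool = False

    def forward(self, conc):
        c = np.asarray(conc, dtype=float)
        if self.kind == "igg_relocation":
            baseline, span, c0 = self.params
            out = baseline + span * (1.0 - np.exp(-c / c0))
        elif self.kind == "lactate_linear":
            intercept, slope = self.params
            out = intercept + slope * c
        else:
            raise ValueError(f"unknown calibration kind {self.kind!r}")
        return out if out.ndim else float(out)

    def inverse(self, readout):
        """Concentration for a readout; values below the zero-concentration
        readout clamp to 0, values beyond the forward image clamp to the
        top of the concentration range. Returns (conc, clamped_mask)."""
        r = np.atleast_1d(np.asarray(readout, dtype=float))
        clamped = np.zeros(r.shape, dtype=bool)
        if self.kind == "igg_relocation":
            baseline, span, c0 = self.params
            frac = (r - baseline) / span
            lo = frac <= 0
            hi = frac >= 1
            frac = np.clip(frac, 0.0, 1.0 - 1e-12)
            conc = -c0 * np.log1p(-frac)
            conc[lo] = 0.0
            conc[hi] = self.conc_range[1]
            clamped = lo | hi
        elif self.kind == "lactate_linear":
            intercept, slope = self.params
            conc = (r - intercept) / slope
            clamped = conc < 0
            conc = np.maximum(conc, 0.0)
        else:
            raise ValueError(f"unknown calibration kind {self.kind!r}")
        if np.isscalar(readout) or np.asarray(readout).ndim == 0:
            return float(conc[0]), bool(clamped[0])
        return conc, clamped


def default_igg_curve() -> CalibrationCurve:
    """Default relocation calibration: baseline ratio 1 (no secretion),
    ~4.4-fold relocation near the top of the quantitative range."""
    return CalibrationCurve("igg_relocation", (1.0, 4.0, 15.0), (0.0, 60.0))


def default_lactate_curve() -> CalibrationCurve:
    """Default linear lactate probe calibration (a.u. vs uM)."""
    return CalibrationCurve("lactate_linear", (50.0, 2.0), (0.0, 400.0))


def fit_igg_calibration(standards: pd.DataFrame) -> CalibrationCurve:
    """Least-squares fit of the saturating-exponential relocation model.

    ``standards`` needs columns ``concentration`` (nM) and ``readout``;
    at least 4 distinct concentrations including 0 are required.
    """
    conc = np.asarray(standards["concentration"], dtype=float)
    readout = np.asarray(standards["readout"], dtype=float)
    uniq = np.unique(conc)
    if uniq.size < 4 or 0.0 not in uniq:
        raise ValueError("need >= 4 distinct concentrations including 0")

    def model(c, baseline, span, c0):
        return baseline + span * (1.0 - np.exp(-c / c0))

    p0 = (readout[conc == 0].mean(), readout.max() - readout.min(), uniq[uniq > 0].mean())
    popt, _ = curve_fit(model, conc, readout, p0=p0, maxfev=20000)
    rss = float(np.sum((model(conc, *popt) - readout) ** 2))
    curve = CalibrationCurve(
        "igg_relocation", tuple(float(p) for p in popt), (0.0, float(uniq.max())), fit_rss=rss
    )
    # flag standards whose mean readout is non-monotone beyond noise
    means = pd.DataFrame({"c": conc, "r": readout}).groupby("c")["r"].mean()
    if np.any(np.diff(means.to_numpy()) < -3.0 * np.sqrt(rss / max(len(conc) - 3, 1))):
        curve.warn_nonmonotone = True
        warnings.warn("calibration standards are non-monotone beyond noise")
    return curve


def fit_lactate_calibration(standards: pd.DataFrame) -> CalibrationCurve:
    """Linear fit with the intercept fixed from zero-concentration standards."""
    conc = np.asarray(standards["concentration"], dtype=float)
    readout = np.asarray(standards["readout"], dtype=float)
    zero = conc == 0
    if zero.any():
        intercept = float(readout[zero].mean())
        nz = ~zero
        slope = float(np.sum((readout[nz] - intercept) * conc[nz]) / np.sum(conc[nz] ** 2))
    else:
        res = linregress(conc, readout)
        intercept, slope = float(res.intercept), float(res.slope)
    return CalibrationCurve(
        "lactate_linear", (intercept, slope), (0.0, float(conc.max() if conc.size else 0.0))
    )


# ---------------------------------------------------------------------------
# unit chain

def igg_molecules(conc_nm, constants: AssayConstants):
    """Molecule count in one droplet at an in-droplet concentration in nM."""
    return np.asarray(conc_nm, dtype=float) * 1e-9 * constants.droplet_volume * constants.avogadro


def lactate_amol(conc_um, constants: AssayConstants):
    """Attomoles in one droplet at an in-droplet concentration in uM."""
    return np.asarray(conc_um, dtype=float) * 1e-6 * constants.droplet_volume * 1e18


def igg_conc_nm_from_rate(rate_per_s, t_s, constants: AssayConstants):
    """Forward model: in-droplet IgG concentration (nM) after secreting at
    ``rate_per_s`` molecules/s for ``t_s`` seconds."""
    n = np.asarray(rate_per_s, dtype=float) * np.asarray(t_s, dtype=float)
    return n / (constants.droplet_volume * constants.avogadro) * 1e9


def lactate_conc_um_from_rate(rate_amol_s, t_s, constants: AssayConstants):
    """Forward model: in-droplet lactate concentration (uM) after secreting
    at ``rate_amol_s`` amol/s for ``t_s`` seconds."""
    amol = np.asarray(rate_amol_s, dtype=float) * np.asarray(t_s, dtype=float)
    return amol * 1e-18 / constants.droplet_volume * 1e6


# ---------------------------------------------------------------------------
# gating

def igg_gate(rate: float, constants: AssayConstants) -> str:
    """Gate label for an IgG secretion rate: secreting cells are gated at
    or above the limit of detection (>=); rates at or above the upper
    quantitative bound are additionally out of range."""
    if rate >= constants.igg_upper:
        return GATE_ABOVE_RANGE
    if rate >= constants.igg_lod:
        return GATE_IGG_SC
    return GATE_BELOW_LOD


def lactate_gate(rate: float, constants: AssayConstants) -> str:
    if rate >= constants.lactate_upper:
        return GATE_ABOVE_RANGE
    if rate < constants.lactate_lod:
        return GATE_BELOW_LOD
    return GATE_IN_RANGE


@dataclass
class SecretionEstimate:
    droplet_id: str
    assay: str  # "igg" | "lactate"
    rate: float  # molecules/s or amol/s; NaN if uninterpretable/excluded
    interval_rates: tuple[float, ...] = ()
    in_quant_range: bool = False
    gate: str = GATE_BELOW_LOD
    flags: tuple[str, ...] = ()


def _mean_interval_rate(amounts: np.ndarray, times: np.ndarray) -> tuple[float, np.ndarray]:
    rates = np.diff(amounts) / np.diff(times)
    return max(float(np.mean(rates)), 0.0), rates


def igg_secretion_rate(
    series: pd.DataFrame,
    curve: CalibrationCurve,
    constants: AssayConstants,
    nox_label: str | None = None,
) -> SecretionEstimate:
    """IgG secretion rate of one droplet from its A647 relocation trace.

    ``series`` holds one droplet's A647 channel rows with columns
    ``time_s``, ``droplet_mean``, ``beadline_mean`` sorted by time.
    Droplets classified NOX-active in the same run lose the A647 probe
    signal, so their IgG rate is not interpretable.
    """
    droplet_id = str(series["droplet_id"].iloc[0]) if "droplet_id" in series else ""
    if nox_label is not None and str(nox_label).endswith("pos"):
        return SecretionEstimate(
            droplet_id, "igg", float("nan"), gate=GATE_IGG_UNINTERPRETABLE,
            flags=("nox_signal_loss",),
        )
    times = np.asarray(series["time_s"], dtype=float)
    dmean = np.asarray(series["droplet_mean"], dtype=float)
    bmean = np.asarray(series["beadline_mean"], dtype=float)
    if np.any(dmean <= 0):
        return SecretionEstimate(
            droplet_id, "igg", float("nan"), gate=GATE_BELOW_LOD, flags=("zero_droplet_mean",)
        )
    relocation = bmean / dmean
    conc_nm, clamped = curve.inverse(relocation)
    molecules = igg_molecules(conc_nm, constants)
    rate, interval_rates = _mean_interval_rate(molecules, times)
    flags = []
    if np.any(clamped):
        flags.append("calibration_clamped")
    # automated stand-ins for manual droplet curation: fraction of
    # increasing relocation steps and total relocation change
    steps = np.diff(relocation)
    if steps.size and np.mean(steps > 0) < 0.5 and rate > 0:
        flags.append("nonmonotone_relocation")
    gate = igg_gate(rate, constants)
    return SecretionEstimate(
        droplet_id, "igg", rate, tuple(interval_rates),
        in_quant_range=constants.igg_lod <= rate < constants.igg_upper,
        gate=gate, flags=tuple(flags),
    )


def lactate_secretion_rate(
    series: pd.DataFrame,
    curve: CalibrationCurve,
    constants: AssayConstants,
    n_cells: int = 1,
) -> SecretionEstimate:
    """Lactate secretion rate (amol/s) of one single-cell droplet.

    Droplets containing more than one cell are excluded from rate
    estimation and gated ``excluded_multicell``.
    """
    droplet_id = str(series["droplet_id"].iloc[0]) if "droplet_id" in series else ""
    if n_cells != 1:
        return SecretionEstimate(
            droplet_id, "lactate", float("nan"), gate=GATE_EXCLUDED_MULTICELL
        )
    times = np.asarray(series["time_s"], dtype=float)
    dmean = np.asarray(series["droplet_mean"], dtype=float)
    if np.any(dmean <= 0):
        return SecretionEstimate(
            droplet_id, "lactate", float("nan"), gate=GATE_BELOW_LOD,
            flags=("zero_droplet_mean",),
        )
    conc_um, _ = curve.inverse(dmean)
    conc_um = np.atleast_1d(conc_um)
    amounts = lactate_amol(conc_um, constants)
    rate, interval_rates = _mean_interval_rate(amounts, times)
    return SecretionEstimate(
        droplet_id, "lactate", rate, tuple(interval_rates),
        in_quant_range=constants.lactate_lod <= rate < constants.lactate_upper,
        gate=lactate_gate(rate, constants),
    )


def ros_slope(cell_trace, times_s, constants: AssayConstants | None = None) -> float:
    """Average intracellular ROS signal increase, in a.u. per 10 min.

    Per-interval increases are averaged up to the frame at which the cell
    signal is maximal; intervals after the maximum are ignored. A maximum
    at the first frame gives slope 0.
    """
    constants = constants or AssayConstants()
    y = np.asarray(cell_trace, dtype=float)
    t = np.asarray(times_s, dtype=float)
    if y.size < 2:
        raise ValueError("need >= 2 frames")
    m = int(np.argmax(y))
    if m == 0:
        return 0.0
    rates = np.diff(y[: m + 1]) / np.diff(t[: m + 1])
    return float(np.mean(rates) * constants.ros_window_s)


def joint_phenotype_table(
    nox_calls: pd.DataFrame,
    igg_estimates: pd.DataFrame,
    lactate_estimates: pd.DataFrame,
    ros_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge per-droplet NOX calls, secretion estimates and ROS slopes.

    Inputs are keyed by ``droplet_id``; the join is the intersection of
    the supplied tables. A disjoint id set yields an empty table and a
    warning rather than an error.
    """
    out = nox_calls.set_index("droplet_id")
    for df, prefix in (
        (igg_estimates, "igg"),
        (lactate_estimates, "lactate"),
        (ros_table, "ros"),
    ):
        if df is None:
            continue
        sub = df.set_index("droplet_id").add_prefix(f"{prefix}_")
        out = out.join(sub, how="inner")
    if out.empty:
        warnings.warn("joint phenotype table: no shared droplet ids")
    return out.reset_index()
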