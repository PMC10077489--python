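"""Gaussian peak fitting, peak-to-peak distances, QC, and aggregation.

Each channel of an intensity profile is fit independently with
``amplitude * exp(-(d - center)^2 / (2 sigma^2)) + baseline``; the signed
peak-to-peak distance (membrane centre minus glycocalyx centre) is the
per-line thickness index.  Loops are summarised over their valid lines and
excluded when the per-loop SD exceeds ``sd_max`` and/or the signal-to-noise
ratio falls below ``snr_min`` (strict inequalities: values exactly at a
threshold are retained).  Hierarchical aggregation is the unweighted
mean-of-means loop -> glomerulus -> subject -> group.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .profiles import IntensityProfile

log = logging.getLogger(__name__)

__all__ = [
    "GaussianFitResult",
    "LineMeasurement",
    "QCConfig",
    "LoopSummary",
    "HierarchySummary",
    "fit_gaussian",
    "peak_to_peak",
    "measure_line",
    "compute_snr",
    "apply_qc",
    "summarize_loop",
    "aggregate",
]


@dataclass(frozen=True)
class GaussianFitResult:
    amplitude: float
    center: float  # um from line start
    sigma: float
    baseline: float
    rss: float
    converged: bool
    reason: str | None = None
    residual_sd: float = float("nan")


@dataclass(frozen=True)
class LineMeasurement:
    line_id: str
    p2p: float  # membrane center - glx center, um, signed; nan when invalid
    glx_fit: GaussianFitResult
    membrane_fit: GaussianFitResult
    valid: bool
    reason: str | None = None


@dataclass(frozen=True)
class QCConfig:
    """Loop-level exclusion thresholds.

    ``sd_unit`` documents the unit in which ``sd_max`` is meant to be
    compared with the per-loop SD of the reported peak-to-peak values; no
    silent conversion is applied.
    """

    sd_max: float = 7.5
    sd_unit: str = "report_units"
    snr_min: float = 15.0
    min_valid_lines: int = 50
    snr_channel: str = "membrane"

    def __post_init__(self) -> None:
        if not self.sd_max > 0 or not self.snr_min > 0:
            raise ValueError("sd_max and snr_min must be > 0")
        if self.snr_channel not in ("membrane", "glx"):
            raise ValueError("snr_channel must be 'membrane' or 'glx'")


@dataclass(frozen=True)
class LoopSummary:
    loop_id: str
    mean_p2p: float
    sd_p2p: float
    snr: float
    n_valid_lines: int
    excluded: bool
    reasons: tuple[str, ...] = ()
    orientation_anomaly: bool = False


@dataclass(frozen=True)
class HierarchySummary:
    """Unweighted mean-of-means tables at each hierarchy level."""

    per_glomerulus: pd.DataFrame
    per_subject: pd.DataFrame
    per_group: pd.DataFrame


def _gauss(d, amplitude, center, sigma, baseline):
    return amplitude * np.exp(-((d - center) ** 2) / (2.0 * sigma**2)) + baseline


def fit_gaussian(distances, values) -> GaussianFitResult:
    """Nonlinear least-squares Gaussian fit of one channel's profile.

    Initialised from (max - min, argmax, span/4, min) with the centre bound
    to the sampled range and sigma to [step, span].
    """
    d = np.asarray(distances, dtype=float)
    v = np.asarray(values, dtype=float)
    if d.size < 8:
        raise ValueError(f"need >= 8 samples to fit, got {d.size}")
    if np.ptp(v) == 0:
        return GaussianFitResult(
            amplitude=0.0,
            center=float("nan"),
            sigma=float("nan"),
            baseline=float(v[0]),
            rss=0.0,
            converged=False,
            reason="flat_profile",
            residual_sd=0.0,
        )
    step = float(d[1] - d[0])
    span = float(d[-1] - d[0])
    p0 = (float(v.max() - v.min()), float(d[np.argmax(v)]), span / 4.0, float(v.min()))
    bounds = ([0.0, d[0], step, -np.inf], [np.inf, d[-1], span, np.inf])
    try:
        popt, _ = curve_fit(_gauss, d, v, p0=p0, bounds=bounds, maxfev=10000)
    except Exception as exc:  # optimizer failure
        return GaussianFitResult(
            amplitude=float("nan"),
            center=float("nan"),
            sigma=float("nan"),
            baseline=float("nan"),
            rss=float("nan"),
            converged=False,
            reason=f"optimizer_failure: {exc}",
        )
    resid = v - _gauss(d, *popt)
    rss = float(np.sum(resid**2))
    return GaussianFitResult(
        amplitude=float(popt[0]),
        center=float(popt[1]),
        sigma=float(popt[2]),
        baseline=float(popt[3]),
        rss=rss,
        converged=True,
        residual_sd=float(np.std(resid)),
    )


def peak_to_peak(glx_fit: GaussianFitResult, membrane_fit: GaussianFitResult) -> float:
    """Signed distance membrane centre minus glycocalyx centre (um).

    Positive when the glycocalyx peak is luminal to the membrane peak, the
    expected ordering; the sign is preserved, never folded.
    """
    if not (glx_fit.converged and membrane_fit.converged):
        raise ValueError("peak_to_peak requires two converged fits")
    return membrane_fit.center - glx_fit.center


def measure_line(profile: IntensityProfile, line_id: str) -> LineMeasurement:
    """Fit both channels of one profile and derive the line's p2p."""
    glx_fit = fit_gaussian(profile.distances, profile.glx_values)
    mem_fit = fit_gaussian(profile.distances, profile.membrane_values)
    if glx_fit.converged and mem_fit.converged:
        return LineMeasurement(
            line_id=line_id,
            p2p=peak_to_peak(glx_fit, mem_fit),
            glx_fit=glx_fit,
            membrane_fit=mem_fit,
            valid=True,
        )
    reasons = []
    if not glx_fit.converged:
        reasons.append(f"glx:{glx_fit.reason}")
    if not mem_fit.converged:
        reasons.append(f"membrane:{mem_fit.reason}")
    return LineMeasurement(
        line_id=line_id,
        p2p=float("nan"),
        glx_fit=glx_fit,
        membrane_fit=mem_fit,
        valid=False,
        reason="; ".join(reasons),
    )


def compute_snr(measurements, channel: str = "membrane") -> float:
    """Mean over valid lines of fitted amplitude / residual SD.

    A perfect fit (zero residual SD) on any line yields +inf, which is never
    excluded by an SNR floor.
    """
    ratios = []
    for m in measurements:
        if not m.valid:
            continue
        fit = m.membrane_fit if channel == "membrane" else m.glx_fit
        if fit.residual_sd == 0:
            return float("inf")
        ratios.append(fit.amplitude / fit.residual_sd)
    if not ratios:
        raise ValueError("compute_snr requires at least one valid line")
    return float(np.mean(ratios))


def apply_qc(
    sd_p2p: float, snr: float, n_valid: int, qc: QCConfig
) -> tuple[bool, tuple[str, ...]]:
    """Evaluate the exclusion rules on precomputed loop statistics.

    Excluded iff sd > sd_max, snr < snr_min, or too few valid lines;
    boundary values (sd == sd_max, snr == snr_min) are retained.
    """
    reasons = []
    if n_valid == 0:
        return True, ("no_valid_lines",)
    if sd_p2p > qc.sd_max:
        reasons.append("sd")
    if snr < qc.snr_min:
        reasons.append("snr")
    if n_valid < qc.min_valid_lines:
        reasons.append("too_few_lines")
    return bool(reasons), tuple(reasons)


def summarize_loop(measurements, qc: QCConfig, loop_id: str = "") -> LoopSummary:
    """Summarise one loop's line measurements and apply the QC rules."""
    valid = [m for m in measurements if m.valid]
    n_valid = len(valid)
    if n_valid == 0:
        return LoopSummary(
            loop_id=loop_id,
            mean_p2p=float("nan"),
            sd_p2p=float("nan"),
            snr=float("nan"),
            n_valid_lines=0,
            excluded=True,
            reasons=("no_valid_lines",),
        )
    p2p = np.array([m.p2p for m in valid])
    mean = float(p2p.mean())
    sd = float(p2p.std(ddof=1)) if n_valid > 1 else 0.0
    snr = compute_snr(measurements, channel=qc.snr_channel)
    excluded, reasons = apply_qc(sd, snr, n_valid, qc)
    anomaly = bool(np.mean(p2p < 0) > 0.10)
    if anomaly:
        log.warning("loop %s: orientation_anomaly (>10%% negative p2p)", loop_id)
    return LoopSummary(
        loop_id=loop_id,
        mean_p2p=mean,
        sd_p2p=sd,
        snr=snr,
        n_valid_lines=n_valid,
        excluded=excluded,
        reasons=reasons,
        orientation_anomaly=anomaly,
    )


def aggregate(
    loop_table: pd.DataFrame, value_col: str = "mean_p2p"
) -> HierarchySummary:
    """Unweighted mean-of-means over loop -> glomerulus -> subject -> group.

    *loop_table* needs columns ``subject_id``, ``group``, ``glomerulus_id``
    and *value_col*, plus an optional boolean ``excluded`` column; excluded
    loops contribute nothing, and glomeruli or subjects left without any
    contributing member are omitted with a warning.
    """
    required = {"subject_id", "group", "glomerulus_id", value_col}
    missing = required - set(loop_table.columns)
    if missing:
        raise ValueError(f"loop table missing columns: {sorted(missing)}")
    df = loop_table.copy()
    if "excluded" in df.columns:
        dropped = df[df["excluded"].astype(bool)]
        for gid in dropped["glomerulus_id"].unique():
            if gid not in df.loc[~df["excluded"].astype(bool), "glomerulus_id"].values:
                log.warning("glomerulus %s: all loops excluded, omitted", gid)
        df = df[~df["excluded"].astype(bool)]
    df = df[np.isfinite(df[value_col])]
    if df.empty:
        empty = pd.DataFrame()
        return HierarchySummary(empty, empty, empty)

    for subject in loop_table["subject_id"].unique():
        if subject not in df["subject_id"].values:
            log.warning("subject %s: no contributing glomeruli, omitted", subject)

    per_glom = (
        df.groupby(["group", "subject_id", "glomerulus_id"], sort=True)[value_col]
        .agg(mean="mean", n_loops="size")
        .reset_index()
    )
    per_subject = (
        per_glom.groupby(["group", "subject_id"], sort=True)["mean"]
        .agg(mean="mean", n_glomeruli="size")
        .reset_index()
    )
    per_group = (
        per_subject.groupby("group", sort=True)["mean"]
        .agg(mean="mean", sd="std", n_subjects="size")
        .reset_index()
    )
    return HierarchySummary(
        per_glomerulus=per_glom, per_subject=per_subject, per_group=per_group
    )
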