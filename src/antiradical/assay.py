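"""DPPH radical-scavenging statistics.

Percent inhibition uses the standard colorimetric definition
100 * (A_control - A_sample) / A_control. IC50 is estimated either by
log-linear interpolation between the two observations bracketing the 50%
level (default, fewest assumptions) or by a four-parameter logistic
least-squares fit. Descriptor-activity association is the Pearson
product-moment correlation with the least-squares line and residuals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .errors import ExtrapolationError, FitError

log = logging.getLogger(__name__)

MODELS = ("loglinear_interpolation", "four_parameter_logistic")


def percent_inhibition(absorbance_control: float, absorbance_sample: float) -> float:
    """Inhibition (%) = 100 * (control - sample) / control.

    A negative result (pro-oxidant reading) is legal and logged.
    """
    if not absorbance_control > 0:
        raise ValueError(
            f"control absorbance must be positive, got {absorbance_control}"
        )
    value = 100.0 * (absorbance_control - absorbance_sample) / absorbance_control
    if value < 0:
        log.info("negative inhibition %.2f%% (pro-oxidant reading)", value)
    return value


@dataclass(frozen=True)
class DosePoint:
    concentration: float  # ppm
    inhibition: float     # %


@dataclass
class DoseResponseCurve:
    """One compound's dose-response data, stored as (ppm, % inhibition)."""

    compound_id: str
    points: List[DosePoint] = field(default_factory=list)

    def __post_init__(self):
        for p in self.points:
            if not p.concentration > 0:
                raise ValueError(
                    f"{self.compound_id}: concentrations must be positive "
                    f"(got {p.concentration})"
                )

    @classmethod
    def from_inhibition(cls, compound_id: str,
                        pairs: Sequence[Tuple[float, float]]) -> "DoseResponseCurve":
        return cls(compound_id, [DosePoint(c, i) for c, i in pairs])

    @classmethod
    def from_absorbances(cls, compound_id: str,
                         triples: Sequence[Tuple[float, float, float]]) -> "DoseResponseCurve":
        """Build from (concentration, A_sample, A_control) triples."""
        return cls(compound_id, [
            DosePoint(c, percent_inhibition(ctrl, smp))
            for c, smp, ctrl in triples
        ])

    def averaged(self) -> "DoseResponseCurve":
        """Duplicate concentrations averaged, sorted by concentration."""
        by_conc: dict = {}
        for p in self.points:
            by_conc.setdefault(p.concentration, []).append(p.inhibition)
        pts = [DosePoint(c, float(np.mean(v)))
               for c, v in sorted(by_conc.items())]
        return DoseResponseCurve(self.compound_id, pts)


@dataclass(frozen=True)
class Ic50Fit:
    ic50: float  # ppm
    model: str
    extrapolated: bool = False
    fit_diagnostics: dict = field(default_factory=dict)


def _logistic(c, bottom, top, ic50, hill):
    return bottom + (top - bottom) / (1.0 + (ic50 / c) ** hill)


def fit_ic50(curve: DoseResponseCurve, model: str = "loglinear_interpolation",
             allow_extrapolation: bool = False,
             fix_bottom: Optional[float] = 0.0,
             fix_top: Optional[float] = 100.0) -> Ic50Fit:
    """Estimate IC50 (ppm) from a dose-response curve.

    ``loglinear_interpolation`` interpolates inhibition against
    log10(concentration) between the two points bracketing 50%; it needs
    >= 3 points and raises :class:`ExtrapolationError` when the data do not
    straddle 50% (unless extrapolation is explicitly allowed, in which case
    the nearest segment is extended and the fit flagged).

    ``four_parameter_logistic`` least-squares fits
    bottom + (top - bottom) / (1 + (ic50/c)^hill); it needs >= 4 points and
    reports the inflection-scale parameter as the IC50. Percent inhibition
    is structurally anchored at 0 (no compound) and 100 (complete
    scavenging), so the asymptotes default to those values; pass
    ``fix_bottom=None`` / ``fix_top=None`` to free them.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    avg = curve.averaged()
    conc = np.array([p.concentration for p in avg.points], dtype=float)
    inh = np.array([p.inhibition for p in avg.points], dtype=float)

    min_points = 3 if model == "loglinear_interpolation" else 4
    if len(conc) < min_points:
        raise FitError(
            f"{curve.compound_id}: need >= {min_points} distinct "
            f"concentrations for {model}, got {len(conc)}"
        )
    if np.ptp(inh) == 0:
        raise FitError(f"{curve.compound_id}: constant response, cannot fit")

    if model == "loglinear_interpolation":
        return _fit_interpolation(curve.compound_id, conc, inh, allow_extrapolation)
    return _fit_logistic(curve.compound_id, conc, inh, fix_bottom, fix_top)


def _fit_interpolation(compound_id, conc, inh, allow_extrapolation) -> Ic50Fit:
    logc = np.log10(conc)
    # exact hit first
    exact = np.where(inh == 50.0)[0]
    if exact.size:
        return Ic50Fit(ic50=float(conc[exact[0]]), model="loglinear_interpolation",
                       extrapolated=False,
                       fit_diagnostics={"bracket": "exact observation"})
    # first adjacent pair straddling 50
    for i in range(len(conc) - 1):
        lo, hi = inh[i], inh[i + 1]
        if (lo - 50.0) * (hi - 50.0) < 0:
            frac = (50.0 - lo) / (hi - lo)
            ic50 = 10.0 ** (logc[i] + frac * (logc[i + 1] - logc[i]))
            return Ic50Fit(
                ic50=float(ic50), model="loglinear_interpolation",
                extrapolated=False,
                fit_diagnostics={"bracket": (float(conc[i]), float(conc[i + 1]))},
            )
    if not allow_extrapolation:
        raise ExtrapolationError(
            f"{compound_id}: observed inhibition does not bracket 50% "
            f"(range {inh.min():.1f}..{inh.max():.1f}%)"
        )
    # extend the end segment closer to the 50% level
    idx = (0, 1) if abs(inh[0] - 50) < abs(inh[-1] - 50) else (-2, -1)
    i, j = idx
    slope = (inh[j] - inh[i]) / (logc[j] - logc[i])
    if slope == 0:
        raise FitError(f"{compound_id}: flat end segment, cannot extrapolate")
    ic50 = 10.0 ** (logc[i] + (50.0 - inh[i]) / slope)
    log.warning("%s: IC50 extrapolated beyond observed range", compound_id)
    return Ic50Fit(ic50=float(ic50), model="loglinear_interpolation",
                   extrapolated=True,
                   fit_diagnostics={"segment": (float(conc[i]), float(conc[j]))})


def _fit_logistic(compound_id, conc, inh, fix_bottom, fix_top) -> Ic50Fit:
    geo_mid = float(np.exp(np.mean(np.log(conc))))
    # free parameters only; fixed asymptotes are substituted in the model
    names, p0, lo, hi = [], [], [], []
    if fix_bottom is None:
        names.append("bottom"); p0.append(min(inh.min(), 0.0))
        lo.append(-50.0); hi.append(50.0)
    if fix_top is None:
        names.append("top"); p0.append(max(inh.max(), 100.0))
        lo.append(10.0); hi.append(200.0)
    names += ["ic50", "hill"]
    p0 += [geo_mid, 1.0]
    lo += [conc.min() / 1e3, 0.05]
    hi += [conc.max() * 1e3, 20.0]

    def model_fn(c, *params):
        p = dict(zip(names, params))
        return _logistic(c,
                         p.get("bottom", fix_bottom),
                         p.get("top", fix_top),
                         p["ic50"], p["hill"])

    try:
        popt, _ = optimize.curve_fit(model_fn, conc, inh, p0=p0,
                                     bounds=(lo, hi), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"{compound_id}: logistic fit failed: {exc}") from exc
    fitted = dict(zip(names, (float(v) for v in popt)))
    bottom = fitted.get("bottom", fix_bottom)
    top = fitted.get("top", fix_top)
    ic50, hill = fitted["ic50"], fitted["hill"]
    resid = inh - _logistic(conc, bottom, top, ic50, hill)
    extrapolated = not (conc.min() <= ic50 <= conc.max())
    if extrapolated:
        log.warning("%s: fitted IC50 %.4g ppm outside observed range", compound_id, ic50)
    return Ic50Fit(
        ic50=ic50, model="four_parameter_logistic", extrapolated=extrapolated,
        fit_diagnostics={
            "bottom": bottom, "top": top, "hill": hill,
            "rmse": float(np.sqrt(np.mean(resid ** 2))),
            "max_abs_residual": float(np.max(np.abs(resid))),
        },
    )


def read_assay_table(path) -> List[DoseResponseCurve]:
    """Read dose-response CSV/TSV: either
    (compound_id, concentration_ppm, absorbance_sample, absorbance_control)
    or (compound_id, concentration_ppm, inhibition_pct). One curve per
    compound, rows kept in file order."""
    import csv
    from pathlib import Path as _Path

    path = _Path(path)
    delim = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        if "compound_id" not in header or "concentration_ppm" not in header:
            raise ValueError(
                f"{path.name}: assay table needs compound_id and "
                f"concentration_ppm columns"
            )
        has_inh = "inhibition_pct" in header
        has_abs = ("absorbance_sample" in header
                   and "absorbance_control" in header)
        if not (has_inh or has_abs):
            raise ValueError(
                f"{path.name}: need inhibition_pct or "
                f"absorbance_sample/absorbance_control columns"
            )
        curves: dict = {}
        for row in reader:
            cid = row["compound_id"].strip()
            conc = float(row["concentration_ppm"])
            if has_inh and row.get("inhibition_pct", "").strip() != "":
                inh = float(row["inhibition_pct"])
            else:
                inh = percent_inhibition(float(row["absorbance_control"]),
                                         float(row["absorbance_sample"]))
            curves.setdefault(cid, []).append(DosePoint(conc, inh))
    return [DoseResponseCurve(cid, pts) for cid, pts in curves.items()]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    slope: float
    intercept: float
    residuals: tuple  # ppm, per compound, in input order
    descriptor_used: str
    n: int


def pearson_correlation(x: Sequence[float], y: Sequence[float],
                        descriptor_used: str = "") -> CorrelationResult:
    """Pearson r between descriptor values x and IC50s y, with the
    least-squares line of y on x and per-point residuals."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise FitError("zero variance: correlation undefined")
    lin = stats.linregress(x, y)
    residuals = y - (lin.slope * x + lin.intercept)
    return CorrelationResult(
        r=float(lin.rvalue), slope=float(lin.slope),
        intercept=float(lin.intercept), residuals=tuple(float(v) for v in residuals),
        descriptor_used=descriptor_used, n=len(x),
    )
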