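"""Plate-assay calibrations.

qPCR absolute quantification from a 10-fold serial-dilution standard
curve (Cq vs log10 concentration, amplification efficiency from the
slope, detection-limit censoring), and BCECF ratiometric pH readout
coupled to OD600 growth summaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("glycoferm")


@dataclass
class StandardCurve:
    """Least-squares line Cq = intercept + slope * log10(concentration)."""

    slope: float  # Cq per log10(CFU/mL); negative for valid amplification
    intercept: float  # Cq at log10(conc) = 0
    r_squared: float
    efficiency: float  # 10^(-1/slope) - 1; 1.0 at perfect doubling
    lod: float  # CFU/mL; calls below are censored at this value


def fit_standard_curve(dilutions: list[tuple[float, float]],
                       lod_policy: str = "lowest-dilution") -> StandardCurve:
    """Fit a qPCR standard curve from (concentration CFU/mL, Cq) pairs.

    Requires >= 3 dilution points spanning >= 2 log10 units. Replicates
    at the same concentration are allowed. The default LOD policy sets
    the detection limit to the lowest dilution present in the curve (all
    of whose replicates amplified, by construction of the input).
    """
    if len(dilutions) < 3:
        raise ValueError("insufficient dilution points (need >= 3)")
    conc = np.array([c for c, _ in dilutions], dtype=float)
    cq = np.array([q for _, q in dilutions], dtype=float)
    if (conc <= 0).any():
        raise ValueError("concentrations must be positive")
    logc = np.log10(conc)
    if logc.max() - logc.min() < 2.0:
        raise ValueError("dilution series must span at least 2 log10 units")
    slope, intercept = np.polyfit(logc, cq, 1)
    if slope >= 0:
        raise ValueError("positive standard-curve slope: no valid amplification")
    pred = intercept + slope * logc
    ss_res = float(((cq - pred) ** 2).sum())
    ss_tot = float(((cq - cq.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    efficiency = 10.0 ** (-1.0 / slope) - 1.0
    if not 0.9 <= efficiency <= 1.1:
        logger.warning("amplification efficiency %.3f outside [0.9, 1.1]", efficiency)
    if not 0.0 < efficiency <= 1.2:
        raise ValueError(f"implausible amplification efficiency {efficiency:.3f}")
    if lod_policy != "lowest-dilution":
        raise ValueError(f"unknown LOD policy {lod_policy!r}")
    lod = float(conc.min())
    return StandardCurve(slope=float(slope), intercept=float(intercept),
                         r_squared=r2, efficiency=float(efficiency), lod=lod)


def quantify_absolute(cq: float, curve: StandardCurve) -> tuple[float, bool]:
    """Concentration (CFU/mL) from a Cq via the standard curve.

    Returns ``(concentration, censored)``; estimates below the detection
    limit are reported at the LOD with ``censored=True``.
    """
    if not math.isfinite(cq):
        raise ValueError("non-finite Cq")
    conc = 10.0 ** ((cq - curve.intercept) / curve.slope)
    if conc < curve.lod:
        logger.warning("estimate %.3g CFU/mL below LOD %.3g; censored", conc, curve.lod)
        return curve.lod, True
    return float(conc), False


def bcecf_ph(f405: float, f475: float,
             calib: list[tuple[float, float]]) -> tuple[float, bool]:
    """pH from the BCECF 405/475 fluorescence ratio.

    Piecewise-linear interpolation through the calibration (ratio, pH)
    points — two points give the plain linear form, more give a segmented
    calibration; beyond the outermost points the nearest segment is
    extended. The buffered fermentation design keeps the dye near-linear
    across the physiological window (pH 5.8-6.8); returns ``(pH,
    extrapolated)`` where the flag marks readouts beyond that window.
    """
    if f475 <= 0:
        raise ValueError("denominator fluorescence must be positive")
    points = sorted(calib)
    ratios = [r for r, _ in points]
    if len(set(ratios)) != len(ratios):
        raise ValueError("calibration ratios must be distinct")
    ratio = f405 / f475
    # pick the segment containing the ratio (or the nearest end segment)
    for (r1, p1), (r2, p2) in zip(points, points[1:]):
        if ratio <= r2 or (r2, p2) == points[-1]:
            break
    ph = p1 + (ratio - r1) * (p2 - p1) / (r2 - r1)
    extrapolated = not 5.8 <= ph <= 6.8
    if extrapolated:
        logger.warning("pH %.2f outside the buffered range [5.8, 6.8]", ph)
    return float(ph), extrapolated


def growth_summary(od_series: list[tuple[float, float]]) -> dict[str, float]:
    """Blank-subtracted growth summary from an OD600 time series.

    The t0 reading is the blank by default; returns final OD, max OD,
    and the net change from t0.
    """
    if len(od_series) < 2:
        raise ValueError("need at least 2 time points")
    times = np.array([t for t, _ in od_series], dtype=float)
    ods = np.array([o for _, o in od_series], dtype=float)
    if (np.diff(times) <= 0).any():
        raise ValueError("time points must be strictly increasing")
    blank = ods[0]
    net = ods - blank
    return {
        "final_od": float(net[-1]),
        "max_od": float(net.max()),
        "delta_od": float(net[-1]),
    }
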