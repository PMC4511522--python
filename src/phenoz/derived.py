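"""Closed-form derived phenotypes computed from raw measurements.

Each quantity is a pure function of one or two raw readings, applied row-wise
before any statistics.  They cover the standard transformations of a
multi-assay Arabidopsis stress screen:

* ``phi_po`` — maximum quantum yield of PSII primary photochemistry
  (Fv/Fm = (Fm - F0)/Fm) from the OJIP fast chlorophyll-fluorescence
  transient.
* ``relative_leakage`` — electrolyte leakage at a timepoint relative to total
  leakage after complete lysis; a cell-death proxy in [0, 1].
* ``conductance_response`` — fractional change of whole-rosette stomatal
  conductance 16 min after a closure stimulus; negative means closure.
* ``germination_ratio`` — germination percentage on salt medium over the
  percentage on control medium.
* ``fold_change_ddct`` — relative qPCR expression by the comparative-Ct
  (2^-ddCt) method.
* ``relative_rlu_total`` — total luminol luminescence of a line as a
  percentage of a reference total (oxidative-burst assays).
* ``water_loss_pct`` — percent fresh-weight loss of an excised rosette.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

__all__ = [
    "phi_po",
    "relative_leakage",
    "conductance_response",
    "germination_ratio",
    "fold_change_ddct",
    "relative_rlu_total",
    "water_loss_pct",
]


def phi_po(f0: float, fm: float) -> float:
    """Maximum quantum yield of primary PSII photochemistry, TR0/ABS.

    Parameters
    ----------
    f0 : minimal (dark-adapted) fluorescence, arbitrary units, > 0.
    fm : maximal fluorescence under a saturating pulse, same units.

    Returns
    -------
    (fm - f0) / fm, the standard Fv/Fm estimator, strictly in (0, 1).

    Raises
    ------
    ValueError if ``fm <= f0`` or ``f0 <= 0`` (not a valid OJIP pair).
    """
    if not (math.isfinite(f0) and math.isfinite(fm)):
        raise ValueError("OJIP fluorescence values must be finite")
    if f0 <= 0:
        raise ValueError(f"F0 must be positive, got {f0}")
    if fm <= f0:
        raise ValueError(f"Fm must exceed F0, got F0={f0}, Fm={fm}")
    return (fm - f0) / fm


def relative_leakage(value_t: float, total: float) -> float:
    """Electrolyte leakage at a timepoint as a fraction of total leakage.

    ``total`` is the conductivity after complete cell lysis (freezing or
    autoclaving); the ratio is unit-free and lies in [0, 1].
    """
    if total <= 0:
        raise ValueError(f"total leakage must be positive, got {total}")
    if value_t < 0 or value_t > total:
        raise ValueError(
            f"timepoint leakage must lie in [0, total], got {value_t} with total {total}"
        )
    return value_t / total


def conductance_response(gst0: float, gst16: float) -> float:
    """Fractional stomatal-conductance change 16 min after a stimulus.

    Computed as (gst16 - gst0)/gst0 from pre-treatment conductance ``gst0``
    and the conductance 16 min post-stimulus.  Negative values indicate
    stomatal closure.
    """
    if gst0 <= 0:
        raise ValueError(f"pre-treatment conductance must be positive, got {gst0}")
    return (gst16 - gst0) / gst0


def germination_ratio(pct_salt: float, pct_control: float) -> float:
    """Germination percentage on salt medium relative to control medium.

    Returns NaN (flagged missing) when the control percentage is zero, since
    the ratio is then undefined rather than an error of the caller.
    """
    for name, v in (("pct_salt", pct_salt), ("pct_control", pct_control)):
        if not 0 <= v <= 100:
            raise ValueError(f"{name} must be a percentage in [0, 100], got {v}")
    if pct_control == 0:
        return float("nan")
    return pct_salt / pct_control


def fold_change_ddct(
    ct_target_trt: float,
    ct_ref_trt: float | Sequence[float],
    ct_target_ctl: float,
    ct_ref_ctl: float | Sequence[float],
) -> float:
    """Relative expression by the comparative-Ct (2^-ddCt) method.

    ddCt = (Ct_target,trt - Ct_ref,trt) - (Ct_target,ctl - Ct_ref,ctl) and the
    fold change is 2^-ddCt.  With several reference genes the reference Ct is
    the arithmetic mean of their Cts, which corresponds to the geometric mean
    of the reference quantities.
    """
    ref_trt = float(np.mean(np.asarray(ct_ref_trt, dtype=float)))
    ref_ctl = float(np.mean(np.asarray(ct_ref_ctl, dtype=float)))
    for v in (ct_target_trt, ref_trt, ct_target_ctl, ref_ctl):
        if not math.isfinite(v):
            raise ValueError("all Ct values must be finite")
    ddct = (ct_target_trt - ref_trt) - (ct_target_ctl - ref_ctl)
    return float(2.0 ** (-ddct))


def relative_rlu_total(line_curve: Sequence[float], reference_total: float) -> float:
    """Total ROS-burst luminescence as a percent of a reference total.

    ``line_curve`` is the RLU time series of one sample over the recording
    window; ``reference_total`` is the mean total RLU of the reference
    genotype.  Returns 100 x sum(line_curve) / reference_total.
    """
    if reference_total <= 0:
        raise ValueError(f"reference total RLU must be positive, got {reference_total}")
    return 100.0 * float(np.sum(np.asarray(line_curve, dtype=float))) / reference_total


def water_loss_pct(w0: float, wt: float) -> float:
    """Percent fresh-weight loss of an excised rosette, 100 x (w0 - wt)/w0."""
    if w0 <= 0:
        raise ValueError(f"initial fresh weight must be positive, got {w0}")
    if wt < 0:
        raise ValueError(f"fresh weight cannot be negative, got {wt}")
    return 100.0 * (w0 - wt) / w0
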