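"""Gamma-radiation standard curve: % tail DNA -> SSBs per cell.

Ionizing radiation is the dosimetric anchor: 1 Gy of gamma rays deposits
1000 single-strand breaks per cell.  Irradiating the same cell model at a
dose ladder, scoring % tail DNA, background-correcting against the 0-Gy
condition and regressing SSBs on the induced % tail DNA gives a per-cell-
model slope (SSBs per point of delta % tail DNA).  That slope converts any
chemical treatment's background-corrected % tail DNA into an absolute SSB
estimate.  Background correction can produce small negative estimates when
there is no induced damage; those are reported as-is but flagged
``no_change`` rather than clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .model import GAMMA_SSB_PER_GY, ValidationError

__all__ = [
    "GAMMA_DOSE_DESIGN_GY",
    "InsufficientDoses",
    "DegenerateCurve",
    "StandardCurve",
    "SsbEstimate",
    "dose_to_ssb",
    "fit_standard_curve",
    "estimate_ssb",
]

#: Canonical gamma dose ladder (Gy), Cs-137 source.
GAMMA_DOSE_DESIGN_GY: List[float] = [0.0, 0.9, 1.8, 3.6, 5.4, 7.2, 9.0]


class InsufficientDoses(ValueError):
    """Fewer than three usable nonzero doses (plus the 0-Gy background)."""


class DegenerateCurve(ValueError):
    """The fitted slope is not positive (no dose response)."""


def dose_to_ssb(dose_gy: float, ssb_per_gy: float = GAMMA_SSB_PER_GY) -> float:
    """SSBs per cell deposited by ``dose_gy`` of gamma radiation."""
    if dose_gy < 0:
        raise ValidationError("dose_gy must be >= 0")
    return ssb_per_gy * dose_gy


@dataclass
class StandardCurve:
    cell_model: str
    doses_gy: np.ndarray
    mean_tail: np.ndarray  # per-dose mean % tail DNA, same order as doses
    background: float  # 0-Gy mean % tail DNA
    slope: float  # SSBs per point of delta % tail DNA
    r_squared: float
    residuals: np.ndarray
    excluded_doses: List[float] = field(default_factory=list)  # saturated
    through_origin: bool = True
    intercept: float = 0.0  # SSBs, nonzero only for the unforced variant

    def predict_ssb(self, delta_tail: float) -> float:
        return self.slope * delta_tail + self.intercept

    def to_frame(self) -> pd.DataFrame:
        delta = self.mean_tail - self.background
        return pd.DataFrame(
            {
                "cell_model": self.cell_model,
                "dose_gy": self.doses_gy,
                "mean_tail": self.mean_tail,
                "delta_tail": delta,
                "ssb": [dose_to_ssb(d) for d in self.doses_gy],
                "slope": self.slope,
                "r2": self.r_squared,
            }
        )


@dataclass
class SsbEstimate:
    cell_model: str
    delta_tail: float
    ssb: float
    no_change: bool  # negative estimate: calculation artefact, treat as none


def fit_standard_curve(
    doses_gy: Sequence[float],
    mean_tail: Sequence[float],
    cell_model: str = "",
    t_max: float = 75.0,
    saturation_margin: float = 2.0,
    through_origin: bool = True,
) -> StandardCurve:
    """Least-squares standard curve of SSBs on background-corrected % tail.

    Requires a 0-Gy condition (defines the background) and at least three
    distinct nonzero doses.  Doses whose mean % tail DNA is within
    ``saturation_margin`` points of ``t_max`` sit outside the informative
    range of the assay and are excluded from the fit (but reported).  The
    regression is forced through the origin by default, since background
    correction already removes the intercept; ``through_origin=False``
    fits an intercept as well.
    """
    doses = np.asarray(list(doses_gy), dtype=float)
    tails = np.asarray(list(mean_tail), dtype=float)
    if doses.shape != tails.shape:
        raise ValidationError("doses_gy and mean_tail must have equal length")
    zero = doses == 0
    if not zero.any():
        raise InsufficientDoses("dose design must contain the 0-Gy background")
    background = float(tails[zero].mean())

    nonzero = ~zero
    saturated = nonzero & (tails >= t_max - saturation_margin)
    usable = nonzero & ~saturated
    if len(np.unique(doses[usable])) < 3:
        raise InsufficientDoses(
            f"need >= 3 distinct usable nonzero doses, have {len(np.unique(doses[usable]))}"
        )

    delta = tails[usable] - background
    ssb = np.array([dose_to_ssb(d) for d in doses[usable]])
    if through_origin:
        denom = float((delta**2).sum())
        if denom == 0:
            raise DegenerateCurve("no induced % tail DNA at any dose")
        slope = float((delta * ssb).sum() / denom)
        intercept = 0.0
    else:
        if np.allclose(delta, delta[0]):
            raise DegenerateCurve("no spread in induced % tail DNA")
        slope, intercept = np.polyfit(delta, ssb, 1)
        slope, intercept = float(slope), float(intercept)
    if slope <= 0:
        raise DegenerateCurve(f"nonpositive slope {slope:.3g}")
    fitted = slope * delta + intercept
    resid = ssb - fitted
    ss_tot = float((ssb**2).sum()) if through_origin else float(
        ((ssb - ssb.mean()) ** 2).sum()
    )
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else float("nan")
    return StandardCurve(
        cell_model=cell_model,
        doses_gy=doses,
        mean_tail=tails,
        background=background,
        slope=slope,
        r_squared=r2,
        residuals=resid,
        excluded_doses=[float(d) for d in doses[saturated]],
        through_origin=through_origin,
        intercept=intercept,
    )


def estimate_ssb(
    curve: StandardCurve,
    treated_mean_tail: float,
    vehicle_mean_tail: float,
    cell_model: Optional[str] = None,
) -> SsbEstimate:
    """Convert a treated-vs-vehicle % tail difference into SSBs per cell.

    The raw (possibly negative) estimate is always reported; a negative
    value sets ``no_change`` because it reflects background correction
    noise, not a real reduction in strand breaks.
    """
    if cell_model is not None and curve.cell_model and cell_model != curve.cell_model:
        raise ValidationError(
            f"curve was fitted on {curve.cell_model!r}, summaries are {cell_model!r}"
        )
    delta = float(treated_mean_tail - vehicle_mean_tail)
    ssb = curve.predict_ssb(delta)
    return SsbEstimate(
        cell_model=curve.cell_model,
        delta_tail=delta,
        ssb=ssb,
        no_change=ssb < 0,
    )
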