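"""DNA-combing length calibration.

Combed lambda-DNA standards of known genomic length (HindIII fragments of
4.36, 9.41 and 23.13 kbp) calibrate the stretching rate s (kb per um of
combed fiber); labeled comet lengths then convert to kilobase pairs as
kbp = s * length.  A consistency helper multiplies fork count, fork speed
and pulse duration into the expected replicated yield.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd


@dataclass
class FiberMeasurements:
    """Measured fiber lengths (um); standards also carry their known kbp."""

    data: pd.DataFrame    # columns: length_um, known_kbp (NaN for unknowns), label

    def __post_init__(self):
        if "length_um" not in self.data.columns:
            raise ValueError("need a length_um column")
        if (self.data["length_um"] <= 0).any():
            raise ValueError("fiber lengths must be > 0")


@dataclass
class CalibrationFit:
    rate_kb_per_um: float
    intercept_kbp: float
    rate_se: float
    residual_sd_kbp: float
    n_per_class: Dict[float, int]

    def __post_init__(self):
        if self.rate_kb_per_um <= 0:
            raise ValueError("stretching rate must be > 0")


def fit_stretching_rate(standards: FiberMeasurements,
                        through_origin: bool = True) -> CalibrationFit:
    """Least-squares fit of genomic length (kbp) on combed length (um).

    The slope is the stretching rate s (kb/um); its uncertainty comes from
    the fit residuals.  Fitting through the origin (default) encodes that
    zero physical length means zero genomic length; a free intercept is
    available since combing protocols can leave small offsets.
    """
    d = standards.data.dropna(subset=["known_kbp"])
    classes = d["known_kbp"].unique()
    if len(classes) < 2:
        raise ValueError("degenerate fit: need >= 2 distinct standard lengths")
    x = d["length_um"].to_numpy(dtype=float)
    y = d["known_kbp"].to_numpy(dtype=float)
    n = len(x)
    if through_origin:
        s = float(x @ y / (x @ x))
        intercept = 0.0
        resid = y - s * x
        dof = max(n - 1, 1)
        se = float(np.sqrt((resid @ resid) / dof / (x @ x)))
    elif n > 2:
        (s, intercept), cov = np.polyfit(x, y, 1, cov=True)
        resid = y - (s * x + intercept)
        dof = max(n - 2, 1)
        se = float(np.sqrt(cov[0, 0]))
    else:   # exact interpolation through two points
        s, intercept = np.polyfit(x, y, 1)
        resid = y - (s * x + intercept)
        dof = 1
        se = 0.0
    resid_sd = float(np.sqrt((resid @ resid) / dof))
    counts = {float(c): int((d["known_kbp"] == c).sum()) for c in classes}
    return CalibrationFit(float(s), float(intercept), se, resid_sd, counts)


def comet_length_to_kbp(length_um: float, fit: CalibrationFit
                        ) -> Tuple[float, float]:
    """Convert a comet length to kbp with propagated uncertainty.

    kbp = s * length (+ intercept when fitted); the uncertainty combines
    the rate standard error scaled by the length with the calibration
    residual scatter, in quadrature.
    """
    if length_um < 0:
        raise ValueError("length must be >= 0")
    kbp = fit.rate_kb_per_um * length_um + fit.intercept_kbp
    err = float(np.hypot(length_um * fit.rate_se, fit.residual_sd_kbp))
    return float(kbp), err


def replication_yield(n_forks: float, fork_speed_kb_per_min: float,
                      duration_min: float) -> float:
    """Replicated DNA (kb) = forks x speed x duration.

    Four forks at 2 kb/min for the 60 min an RD takes to replicate give
    480 kb — of the order of one RD's genomic span (~500 kbp).
    """
    if min(n_forks, fork_speed_kb_per_min, duration_min) < 0:
        raise ValueError("all inputs must be >= 0")
    return float(n_forks * fork_speed_kb_per_min * duration_min)
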