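"""Solution behavior: viscosity-concentration fits and opalescence.

The concentration dependence of viscosity above the crowding onset is modeled
as eta(c) = a exp(b c).  The fit is ordinary least squares of ln(eta) on c
(multiplicative-noise model), which makes the 95% prediction band a standard
linear-regression interval on the log scale, exponentiated back.  Opalescence
is the blank-subtracted mean optical density over 340-360 nm at 5 nm steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ValidationError

OD_GRID_NM = (340, 345, 350, 355, 360)


@dataclass
class ExpFit:
    a_cp: float            # pre-exponential, cP
    b_ml_mg: float         # growth rate, mL/mg
    residual_sd_log: float
    n: int
    c_mean: float
    sxx: float

    def predict(self, c0: float) -> float:
        return self.a_cp * math.exp(self.b_ml_mg * c0)


@dataclass
class OpalescenceResult:
    mean_od: float
    per_replicate: tuple[float, ...]


def fit_exponential(concentration_mg_ml, viscosity_cp) -> ExpFit:
    """Fit eta = a exp(b c) by OLS on the log scale."""
    c = np.asarray(list(concentration_mg_ml), dtype=float)
    eta = np.asarray(list(viscosity_cp), dtype=float)
    if len(c) != len(eta):
        raise ValidationError("concentration/viscosity lengths differ")
    if (eta <= 0).any():
        raise ValidationError("viscosities must be positive")
    if len(np.unique(c)) < 3:
        raise ValidationError("need at least 3 distinct concentrations")
    y = np.log(eta)
    slope, intercept = np.polyfit(c, y, 1)
    resid = y - (intercept + slope * c)
    dof = len(c) - 2
    s = math.sqrt(float(resid @ resid) / dof) if dof > 0 else float("nan")
    c_mean = float(c.mean())
    sxx = float(np.sum((c - c_mean) ** 2))
    return ExpFit(float(math.exp(intercept)), float(slope), s, len(c), c_mean, sxx)


def predict_viscosity(fit: ExpFit, c0: float,
                      level: float = 0.95) -> tuple[float, float, float]:
    """Point prediction and prediction interval at concentration ``c0``.

    The interval is the exponentiated log-scale prediction interval
    ln(point) +/- t_{n-2} * s * sqrt(1 + 1/n + (c0 - c_mean)^2 / Sxx).
    """
    if fit.n <= 2:
        raise ValidationError("prediction interval needs n > 2")
    point = fit.predict(c0)
    tq = scipy.stats.t.ppf(0.5 + level / 2.0, fit.n - 2)
    half = tq * fit.residual_sd_log * math.sqrt(
        1.0 + 1.0 / fit.n + (c0 - fit.c_mean) ** 2 / fit.sxx)
    return point, point * math.exp(-half), point * math.exp(half)


def opalescence_mean_od(readings: pd.DataFrame,
                        blank: pd.DataFrame) -> OpalescenceResult:
    """Blank-subtracted mean OD over the 340-360 nm grid.

    ``readings`` needs wavelength_nm and od columns (plus optional replicate);
    ``blank`` maps the same five wavelengths to blank OD.  Both must cover
    the exact grid {340, 345, 350, 355, 360}.
    """
    for frame, name in ((readings, "readings"), (blank, "blank")):
        got = set(int(w) for w in frame["wavelength_nm"].unique())
        if got != set(OD_GRID_NM):
            raise ValidationError(
                f"{name} wavelength grid {sorted(got)} != {list(OD_GRID_NM)}")
    blank_map = blank.groupby("wavelength_nm")["od"].mean()
    work = readings.copy()
    work["od_corr"] = work["od"] - work["wavelength_nm"].map(blank_map)
    if "replicate" in work.columns:
        per_rep = tuple(float(v) for v in work.groupby("replicate")["od_corr"].mean())
    else:
        per_rep = (float(work["od_corr"].mean()),)
    return OpalescenceResult(float(np.mean(per_rep)), per_rep)
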