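"""Dynamic light scattering analysis: cumulant fits, diffusion coefficients,
the diffusion interaction parameter kD, and sensitivity diagnostics.

kD is the slope/intercept ratio of the linear model D(c) = D0 (1 + kD c),
reported in mL/g (concentrations are handled in mg/mL internally, hence the
factor of 1000).  Positive kD indicates net intermolecular repulsion (good
colloidal behavior); negative kD indicates attraction / self-association.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from .errors import FitError, NoDecayError, ValidationError
from .physics import water_viscosity_cp
from .tableio import read_table, write_table


@dataclass(frozen=True)
class OpticsConfig:
    """Instrument optics used to convert decay rates to diffusion."""

    wavelength_nm: float = 825.0
    angle_deg: float = 150.0
    refractive_index: float = 1.33

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValidationError("wavelength must be positive")
        if not 0 < self.angle_deg < 180:
            raise ValidationError("scattering angle must lie in (0, 180)")

    @property
    def q_cm(self) -> float:
        """Scattering vector magnitude q = 4 pi n sin(theta/2) / lambda, in 1/cm."""
        lam_cm = self.wavelength_nm * 1e-7
        theta = math.radians(self.angle_deg)
        return 4.0 * math.pi * self.refractive_index * math.sin(theta / 2.0) / lam_cm


@dataclass
class CumulantResult:
    gamma: float       # decay rate, 1/s
    mu2: float         # second cumulant, 1/s^2 (as fitted; may be negative)
    beta: float        # intercept amplitude
    baseline: float
    mu2_clipped: bool = False

    @property
    def pdi(self) -> float:
        """Polydispersity index mu2/gamma^2, clipped at zero."""
        return max(self.mu2, 0.0) / self.gamma**2


@dataclass
class DlsSeries:
    """Collection of DLS measurements.

    ``table`` rows: concentration_mg_ml, temperature_c, replicate, d_cm2_s.
    Optional ``g2`` long table: the same keys plus tau_s and g2 columns.
    """

    table: pd.DataFrame
    g2: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"concentration_mg_ml", "temperature_c", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"DLS table missing columns: {sorted(missing)}")
        if (self.table["concentration_mg_ml"] <= 0).any():
            raise ValidationError("concentrations must be positive")
        if "d_cm2_s" in self.table.columns and (self.table["d_cm2_s"] <= 0).any():
            raise ValidationError("diffusion coefficients must be positive")

    def at_temperature(self, temp_c: float, atol: float = 1e-9) -> "DlsSeries":
        mask = np.isclose(self.table["temperature_c"], temp_c, atol=atol)
        return DlsSeries(self.table[mask].reset_index(drop=True), meta=dict(self.meta))

    def temperatures(self) -> np.ndarray:
        return np.unique(self.table["temperature_c"].to_numpy(float))

    def write(self, path) -> None:
        if self.g2 is not None:
            write_table(path, self.g2, {**self.meta, "format": "g2"})
        else:
            write_table(path, self.table, {**self.meta, "format": "d"})

    @classmethod
    def read(cls, path) -> "DlsSeries":
        frame, meta = read_table(path)
        fmt = meta.pop("format", "d")
        if fmt == "g2":
            keys = ["concentration_mg_ml", "temperature_c", "replicate"]
            table = frame[keys].drop_duplicates().reset_index(drop=True)
            return cls(table=table, g2=frame, meta=meta)
        return cls(table=frame, meta=meta)


@dataclass
class KdResult:
    kd_ml_g: float
    slope: float          # cm^2 s^-1 per mg mL^-1
    intercept: float      # D0, cm^2/s
    se_slope: float
    se_intercept: float
    kd_se: float
    ci_low: float
    ci_high: float
    r_squared: float
    n: int
    _ols: object = field(default=None, repr=False, compare=False)

    @property
    def ci_width(self) -> float:
        return self.ci_high - self.ci_low

    def prediction_band(self, concentrations, level: float = 0.95) -> pd.DataFrame:
        """Pointwise prediction interval of D at new concentrations."""
        c = np.asarray(concentrations, dtype=float)
        pred = self._ols.get_prediction(sm.add_constant(c, has_constant="add"))
        frame = pred.summary_frame(alpha=1.0 - level)
        return pd.DataFrame({
            "concentration_mg_ml": c,
            "d_cm2_s": frame["mean"].to_numpy(),
            "lower": frame["obs_ci_lower"].to_numpy(),
            "upper": frame["obs_ci_upper"].to_numpy(),
        })


@dataclass
class SensitivityReport:
    per_temp_step: float      # mean |dD| per adjacent temperature step, cm^2/s
    per_conc_step: float      # mean |dD| per adjacent concentration step, cm^2/s
    temp_step_c: float
    conc_step_mg_ml: float
    by_concentration: pd.DataFrame
    by_temperature: pd.DataFrame


# ---------------------------------------------------------------------------
# cumulant analysis
# ---------------------------------------------------------------------------

def _g2_model(tau, baseline, beta, gamma, mu2):
    g1 = np.exp(-gamma * tau) * (1.0 + 0.5 * mu2 * tau**2)
    return baseline + beta * g1**2


def cumulant_fit(tau_s, g2, order: int = 2) -> CumulantResult:
    """Fit the second-order cumulant model to an intensity autocorrelation.

    g2(tau) = baseline + beta [exp(-Gamma tau)(1 + mu2/2 tau^2)]^2.  Initial
    values come from a log-linear fit of ln(g2 - baseline)/2; ``order=1``
    fixes mu2 = 0.
    """
    tau = np.asarray(tau_s, dtype=float)
    y = np.asarray(g2, dtype=float)
    if len(tau) < 10:
        raise ValidationError("need at least 10 correlation points")
    if not np.all(np.diff(tau) > 0):
        raise ValidationError("tau must be strictly increasing")

    tail = max(3, len(y) // 10)
    base0 = float(np.median(y[-tail:]))
    amp = y - base0
    if np.nanmax(amp) < 5e-4:
        raise NoDecayError("g2 shows no decay above baseline")

    use = amp > max(np.nanmax(amp) * 1e-3, 1e-12)
    half_log = 0.5 * np.log(amp[use])
    slope, icept = np.polyfit(tau[use], half_log, 1)
    gamma0 = max(-slope, 1e-6)
    beta0 = float(np.clip(np.exp(2.0 * icept), 1e-3, 1.2))

    if order == 1:
        def model(t, baseline, beta, gamma):
            return _g2_model(t, baseline, beta, gamma, 0.0)
        p0 = [base0, beta0, gamma0]
        bounds = ([0.0, 1e-6, 1e-9], [2.0, 1.2, np.inf])
    elif order == 2:
        model = _g2_model
        p0 = [base0, beta0, gamma0, 0.0]
        bounds = ([0.0, 1e-6, 1e-9, -np.inf], [2.0, 1.2, np.inf, np.inf])
    else:
        raise ValidationError("order must be 1 or 2")

    last_err = None
    for attempt in range(3):
        try:
            popt, _ = scipy.optimize.curve_fit(
                model, tau, y, p0=p0, bounds=bounds, maxfev=20000)
            break
        except RuntimeError as err:  # pragma: no cover - rare restart path
            last_err = err
            p0 = list(p0)
            p0[2] *= 10.0 ** (attempt + 1 - 1.5)
    else:  # pragma: no cover
        raise FitError(f"cumulant fit failed to converge: {last_err}")

    if order == 1:
        baseline, beta, gamma = popt
        mu2 = 0.0
    else:
        baseline, beta, gamma, mu2 = popt
    clipped = mu2 < 0
    return CumulantResult(float(gamma), float(mu2), float(beta), float(baseline),
                          mu2_clipped=bool(clipped))


def diffusion_from_gamma(result: CumulantResult, optics: OpticsConfig | None = None) -> float:
    """D = Gamma / q^2, in cm^2/s."""
    optics = optics or OpticsConfig()
    return result.gamma / optics.q_cm**2


def reduce_g2_series(series: DlsSeries, optics: OpticsConfig | None = None,
                     order: int = 2) -> DlsSeries:
    """Cumulant-fit every stored g2 curve, producing a D-valued series."""
    if series.g2 is None:
        raise ValidationError("series carries no g2 curves")
    optics = optics or OpticsConfig()
    keys = ["concentration_mg_ml", "temperature_c", "replicate"]
    rows = []
    for key, grp in series.g2.groupby(keys, sort=True):
        res = cumulant_fit(grp["tau_s"].to_numpy(), grp["g2"].to_numpy(), order=order)
        rows.append(dict(zip(keys, key)) | {"d_cm2_s": diffusion_from_gamma(res, optics)})
    return DlsSeries(pd.DataFrame(rows), meta=dict(series.meta))


# ---------------------------------------------------------------------------
# kD estimation
# ---------------------------------------------------------------------------

def fit_kd(series: DlsSeries, temperature_c: float | None = None,
           mode: str = "pooled", level: float = 0.95) -> KdResult:
    """Estimate kD = 1000 * slope/intercept from D vs concentration.

    ``mode="pooled"`` (default) regresses every replicate point jointly,
    preserving the leverage structure used for prediction bands;
    ``mode="per_replicate"`` fits each replicate separately and pools the
    per-replicate kD values (se then reflects between-run scatter).
    """
    table = series.table
    if "d_cm2_s" not in table.columns:
        raise ValidationError("series has no diffusion values; reduce g2 curves first")
    if temperature_c is not None:
        table = series.at_temperature(temperature_c).table
    elif len(series.temperatures()) > 1:
        raise ValidationError("multiple temperatures present; pass temperature_c")
    if table["concentration_mg_ml"].nunique() < 3:
        raise ValidationError("kD fit needs at least 3 distinct concentrations")

    if mode == "per_replicate":
        kds = []
        for _, grp in table.groupby("replicate"):
            sub = DlsSeries(grp.reset_index(drop=True))
            kds.append(fit_kd(sub, mode="pooled", level=level).kd_ml_g)
        kds = np.asarray(kds)
        pooled = fit_kd(DlsSeries(table.reset_index(drop=True)), mode="pooled", level=level)
        se = float(np.std(kds, ddof=1) / math.sqrt(len(kds))) if len(kds) > 1 else float("nan")
        tq = scipy.stats.t.ppf(0.5 + level / 2.0, max(len(kds) - 1, 1))
        mean_kd = float(np.mean(kds))
        return KdResult(mean_kd, pooled.slope, pooled.intercept, pooled.se_slope,
                        pooled.se_intercept, se, mean_kd - tq * se, mean_kd + tq * se,
                        pooled.r_squared, len(kds), _ols=pooled._ols)
    if mode != "pooled":
        raise ValidationError("mode must be 'pooled' or 'per_replicate'")

    c = table["concentration_mg_ml"].to_numpy(float)
    d = table["d_cm2_s"].to_numpy(float)
    ols = sm.OLS(d, sm.add_constant(c)).fit()
    intercept, slope = ols.params
    if intercept <= 0:
        raise ValidationError("non-positive fitted D0; kD undefined")
    kd = 1000.0 * slope / intercept
    cov = ols.cov_params()
    var_i, var_s = cov[0, 0], cov[1, 1]
    cov_si = cov[0, 1]
    # delta method on g(s, i) = 1000 s / i
    grad_s = 1000.0 / intercept
    grad_i = -1000.0 * slope / intercept**2
    kd_var = grad_s**2 * var_s + grad_i**2 * var_i + 2.0 * grad_s * grad_i * cov_si
    kd_se = math.sqrt(max(kd_var, 0.0))
    tq = scipy.stats.t.ppf(0.5 + level / 2.0, len(c) - 2)
    return KdResult(float(kd), float(slope), float(intercept),
                    float(math.sqrt(var_s)), float(math.sqrt(var_i)), float(kd_se),
                    float(kd - tq * kd_se), float(kd + tq * kd_se),
                    float(ols.rsquared), len(c), _ols=ols)


def write_kd_result(result: KdResult, path, meta: dict | None = None) -> None:
    frame = pd.DataFrame([{
        "kd_ml_g": result.kd_ml_g, "kd_se": result.kd_se,
        "ci_low": result.ci_low, "ci_high": result.ci_high,
        "slope": result.slope, "intercept_d0": result.intercept,
        "r_squared": result.r_squared, "n": result.n,
    }])
    write_table(path, frame, meta or {})


# ---------------------------------------------------------------------------
# temperature / concentration sensitivity
# ---------------------------------------------------------------------------

def temperature_sensitivity(series: DlsSeries) -> SensitivityReport:
    """Mean |dD| over adjacent temperature and concentration steps.

    Requires a full temperature x concentration grid.  For each
    concentration, adjacent-temperature |differences| of the replicate-mean D
    are averaged, then averaged across concentrations; the concentration-step
    sensitivity is computed analogously at fixed temperature.
    """
    table = series.table
    if "d_cm2_s" not in table.columns:
        raise ValidationError("series has no diffusion values")
    grid = (table.groupby(["concentration_mg_ml", "temperature_c"])["d_cm2_s"]
            .mean().unstack("temperature_c"))
    if grid.isna().any().any():
        raise ValidationError("ragged grid: every (c, T) cell must be populated")
    if grid.shape[0] < 2 or grid.shape[1] < 2:
        raise ValidationError("need at least 2 temperatures and 2 concentrations")

    temps = grid.columns.to_numpy(float)
    concs = grid.index.to_numpy(float)
    d = grid.to_numpy(float)

    dT = np.abs(np.diff(d, axis=1))          # per temperature step, each conc
    dC = np.abs(np.diff(d, axis=0))          # per concentration step, each temp
    by_conc = pd.DataFrame({"concentration_mg_ml": concs,
                            "mean_abs_dD_per_T_step": dT.mean(axis=1)})
    by_temp = pd.DataFrame({"temperature_c": temps,
                            "mean_abs_dD_per_c_step": dC.mean(axis=0)})
    return SensitivityReport(
        per_temp_step=float(dT.mean()),
        per_conc_step=float(dC.mean()),
        temp_step_c=float(np.mean(np.diff(temps))),
        conc_step_mg_ml=float(np.mean(np.diff(concs))),
        by_concentration=by_conc,
        by_temperature=by_temp,
    )


def solvent_viscosity_cp(temp_c: float) -> float:
    """Water viscosity in cP; re-exported for optics configuration."""
    return water_viscosity_cp(temp_c)
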