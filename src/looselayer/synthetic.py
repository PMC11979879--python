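"""Synthetic-data generators with known ground truth.

Emulated input families:

* QCM-D traces — two-compartment Langmuir adsorption (irreversible base
  layer + reversible loose layer gated by base coverage) integrated with
  fixed-step RK4, rendered through the Sauerbrey relation per overtone with
  drift, buffer-change offsets, and Gaussian noise.
* DLS series — D(c, T) = D0(T) (1 + kD c/1000) with Stokes-Einstein/Vogel
  temperature scaling, optionally emitted as second-order-cumulant g2 curves;
  polystyrene-bead spiking via intensity-weighted harmonic mixing.
* Viscosity and opalescence tables — exponential eta(c) and flat OD(340-360).

Identical (scenario, schedule, seed) always produce bit-identical output.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .dls import DlsSeries, OpticsConfig
from .errors import StabilityError, ValidationError
from .physics import d0_at_temperature, stokes_einstein_d
from .scenario import FlowSchedule, FlowSegment, SyntheticScenario, three_phase_schedule
from .trace import OVERTONES, OvertoneTrace, QcmdExperiment

OD_WAVELENGTHS_NM = (340, 345, 350, 355, 360)


# ---------------------------------------------------------------------------
# QCM-D trace generation
# ---------------------------------------------------------------------------

def _kinetics_rhs(gamma, c, gmax2_eff, s: SyntheticScenario):
    g1, g2 = gamma
    dg1 = s.ka1 * c * (s.gmax1 - g1)
    occupancy = g1 / s.gmax1 if s.gmax1 > 0 else 0.0
    dg2 = s.ka2 * c * occupancy * (gmax2_eff - g2) - s.kd2 * g2
    return np.array([dg1, dg2])


def simulate_qcmd(scenario: SyntheticScenario, schedule: FlowSchedule,
                  dt: float = 1.0) -> QcmdExperiment:
    """Simulate a multi-segment QCM-D run.

    Surface kinetics are integrated with fixed-step RK4 at step ``dt``;
    concentration and buffer are piecewise constant per segment.  Each
    overtone receives the same overtone-normalized deterministic signal
    (rigid Sauerbrey film) plus independent Gaussian noise.  The returned
    experiment carries the true phase boundaries and the Gamma1/Gamma2
    trajectories as ground truth.
    """
    if not dt > 0:
        raise ValidationError("dt must be positive")
    for name in ("ka1", "ka2", "kd2", "gmax1", "gmax2", "drift_rate_hz_h"):
        if not math.isfinite(getattr(scenario, name)):
            raise ValidationError(f"non-finite scenario parameter {name}")

    # refuse steps coarser than the fastest kinetic timescale 1/(ka*c + kd)
    fastest = 0.0
    for seg in schedule.segments:
        c = seg.concentration_mg_ml
        fastest = max(fastest, scenario.ka1 * c, scenario.ka2 * c + scenario.kd2)
    if fastest > 0 and dt > 1.0 / fastest:
        raise StabilityError(
            f"dt={dt} s exceeds the fastest kinetic timescale {1.0 / fastest:.3g} s")

    n_steps = int(round(schedule.duration_s / dt))
    time = np.arange(n_steps + 1) * dt
    gamma = np.zeros((n_steps + 1, 2))
    state = np.zeros(2)

    def seg_at(t):
        return schedule.segment_at(min(t, schedule.duration_s - 1e-9))

    for i in range(n_steps):
        # concentration is piecewise constant; treat the step as wholly inside
        # the segment containing its midpoint so grid-aligned boundaries stay
        # exact
        seg = seg_at(time[i] + dt / 2.0)
        c = seg.concentration_mg_ml
        gmax2_eff = scenario.effective_gmax2(seg.buffer)
        k1 = _kinetics_rhs(state, c, gmax2_eff, scenario)
        k2 = _kinetics_rhs(state + 0.5 * dt * k1, c, gmax2_eff, scenario)
        k3 = _kinetics_rhs(state + 0.5 * dt * k2, c, gmax2_eff, scenario)
        k4 = _kinetics_rhs(state + dt * k3, c, gmax2_eff, scenario)
        state = state + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        state = np.clip(state, 0.0, None)
        gamma[i + 1] = state

    g1, g2 = gamma[:, 0], gamma[:, 1]
    offsets = np.array([
        scenario.buffer_offsets.get(seg_at(t).buffer, 0.0) for t in time
    ])
    drift = scenario.drift_rate_hz_h / 3600.0 * time
    f_clean = -(g1 + g2) / scenario.c_sauerbrey + drift + offsets
    d_clean = scenario.alpha1 * g1 + scenario.alpha2 * g2

    rng = np.random.default_rng(scenario.seed)
    traces = {}
    for n in OVERTONES:
        f = f_clean + rng.normal(0.0, scenario.noise_sd_f, size=f_clean.shape) \
            if scenario.noise_sd_f > 0 else f_clean.copy()
        d = d_clean + rng.normal(0.0, scenario.noise_sd_d, size=d_clean.shape) \
            if scenario.noise_sd_d > 0 else d_clean.copy()
        traces[n] = OvertoneTrace(n, time, f, d, normalized=True)

    metadata = {
        "temperature_c": 20.0,
        "flow_rate_ul_min": schedule.segments[0].flow_rate_ul_min,
        "seed": scenario.seed,
    }
    ground_truth = {
        "gamma1": g1, "gamma2": g2, "time_s": time,
        "scenario": scenario, "schedule": schedule,
    }
    return QcmdExperiment(traces=traces, schedule=schedule,
                          metadata=metadata, ground_truth=ground_truth)


def add_irreversible_offset(experiment: QcmdExperiment, offset_hz: float,
                            from_time_s: float = None) -> QcmdExperiment:
    """Apply a constant frequency offset from ``from_time_s`` onward.

    Models irreversibly bound particulates (e.g. spiked beads) that add mass
    before and after the rinse alike; the loose-layer metric is insensitive
    to this by construction.  Defaults to the first sample onset.
    """
    if from_time_s is None:
        if experiment.schedule is None:
            raise ValidationError("no schedule; pass from_time_s explicitly")
        t = 0.0
        for seg in experiment.schedule.segments:
            if seg.label == "sample":
                from_time_s = t
                break
            t += seg.duration_s
        else:
            raise ValidationError("schedule has no sample segment")
    traces = {}
    for n, tr in experiment.traces.items():
        f = tr.delta_f.copy()
        f[tr.time_s >= from_time_s] += offset_hz
        traces[n] = OvertoneTrace(n, tr.time_s.copy(), f, tr.delta_d.copy(), tr.normalized)
    return QcmdExperiment(traces=traces, schedule=experiment.schedule,
                          metadata=dict(experiment.metadata),
                          ground_truth=experiment.ground_truth)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

# Eight-mAb validation panel: consensus loose-layer shift (Hz, mean +/- SD at
# 10 mg/mL) and kD (mL/g, mean +/- SD), three runs each.
MAB_PANEL = {
    "trastuzumab":  {"qcmd_mean": -23.9, "qcmd_sd": 2.7, "kd_mean": 51.7, "kd_sd": 2.5},
    "tocilizumab":  {"qcmd_mean": -31.7, "qcmd_sd": 2.1, "kd_mean": 64.9, "kd_sd": 7.3},
    "evolocumab":   {"qcmd_mean": -36.9, "qcmd_sd": 5.0, "kd_mean": 22.8, "kd_sd": 8.0},
    "anrukinzumab": {"qcmd_mean": -40.5, "qcmd_sd": 2.1, "kd_mean": 7.5, "kd_sd": 4.0},
    "fremanezumab": {"qcmd_mean": -47.6, "qcmd_sd": 4.3, "kd_mean": 36.8, "kd_sd": 13.6},
    "cetuximab":    {"qcmd_mean": -79.4, "qcmd_sd": 9.4, "kd_mean": -42.4, "kd_sd": 6.3},
    "omalizumab":   {"qcmd_mean": -82.4, "qcmd_sd": 15.5, "kd_mean": -22.9, "kd_sd": 1.8},
    "dupilumab":    {"qcmd_mean": -112.4, "qcmd_sd": 4.4, "kd_mean": 3.0, "kd_sd": 13.1},
}

PANEL_CONCENTRATION_MG_ML = 10.0


def mab_panel_preset(name: str, seed: int = 0) -> tuple[SyntheticScenario, FlowSchedule]:
    """Scenario + schedule calibrated to one of the eight panel mAbs.

    The loose-layer capacity is chosen analytically so the noiseless
    steady-state loose coverage at 10 mg/mL renders exactly the panel's mean
    delta_f3_loose through the Sauerbrey relation; kd_true equals the panel
    kD mean.
    """
    key = name.lower()
    if key not in MAB_PANEL:
        raise ValidationError(
            f"unknown panel molecule {name!r}; valid: {sorted(MAB_PANEL)}")
    entry = MAB_PANEL[key]
    base = SyntheticScenario()
    c = PANEL_CONCENTRATION_MG_ML
    frac = base.ka2 * c / (base.ka2 * c + base.kd2)
    gamma2_target = abs(entry["qcmd_mean"]) * base.c_sauerbrey
    scenario = base.replace(
        gmax2=gamma2_target / frac,
        kd_true=entry["kd_mean"],
        seed=seed,
    )
    schedule = three_phase_schedule(concentration_mg_ml=c, buffer="histidine")
    return scenario, schedule


BSA_LOOSE_TARGETS_HZ = {"acetate": -60.0, "histidine": -53.9, "phosphate": -47.6}
BSA_CONCENTRATION_MG_ML = 20.0


def bsa_buffer_preset(seed: int = 0) -> tuple[SyntheticScenario, FlowSchedule]:
    """Sequential BSA run across acetate, histidine, and phosphate buffers.

    One experiment, three sample/rinse cycles separated by buffer swaps;
    the per-buffer loose-layer capacities are calibrated so the noiseless
    loose shifts are -60, -53.9 and -47.6 Hz (acetate > histidine >
    phosphate in magnitude), and buffer-change swelling offsets shift the
    irreversible-layer frequency between cycles.
    """
    c = BSA_CONCENTRATION_MG_ML
    base = SyntheticScenario(gmax1=400.0, kd_true=0.0)
    frac = base.ka2 * c / (base.ka2 * c + base.kd2)
    capacities = {
        buf: abs(target) * base.c_sauerbrey / frac
        for buf, target in BSA_LOOSE_TARGETS_HZ.items()
    }
    scenario = base.replace(
        loose_capacity_by_buffer=capacities,
        buffer_offsets={"acetate": 0.0, "histidine": 6.0, "phosphate": 11.0},
        seed=seed,
    )
    flow = 150.0
    segs = [FlowSegment("baseline", "acetate", 0.0, 900.0, flow)]
    for buf in ("acetate", "histidine", "phosphate"):
        if buf != "acetate":
            segs.append(FlowSegment("baseline", buf, 0.0, 600.0, flow))
        segs.append(FlowSegment("sample", buf, c, 1200.0, flow))
        segs.append(FlowSegment("rinse", buf, 0.0, 2400.0, flow))
    return scenario, FlowSchedule(tuple(segs))


# ---------------------------------------------------------------------------
# DLS generation
# ---------------------------------------------------------------------------

def true_diffusion(scenario: SyntheticScenario, concentration_mg_ml: float,
                   temp_c: float) -> float:
    """Noiseless D(c, T) = D0(T) (1 + kD c / 1000), cm^2/s."""
    d0 = d0_at_temperature(scenario.d0_ref, temp_c, scenario.ref_temp_c)
    factor = 1.0 + scenario.kd_true * concentration_mg_ml / 1000.0
    if factor <= 0:
        raise ValidationError(
            "kd_true * c/1000 <= -1 gives a nonphysical negative D")
    return d0 * factor


def default_impurity_d(scenario: SyntheticScenario, temp_c: float = 20.0) -> float:
    """Bead diffusion coefficient; Stokes-Einstein for Rh = 500 nm (1 um bead)."""
    if scenario.d_impurity is not None:
        return scenario.d_impurity
    return stokes_einstein_d(500.0, temp_c)


def simulate_dls_series(
    scenario: SyntheticScenario,
    concentrations,
    temperatures=(20.0,),
    replicates: int = 3,
    emit_g2: bool = False,
    optics: OpticsConfig | None = None,
    tau_s: np.ndarray | None = None,
) -> DlsSeries:
    """Generate a DLS measurement series over a c x T grid.

    Replicate D values receive additive Gaussian noise with standard
    deviation ``dls_noise_frac * D0(T)``.  With ``emit_g2``, second-order
    cumulant curves g2(tau) = 1 + beta [exp(-q^2 D tau)]^2 (mu2 = 0) are
    emitted with small additive measurement noise instead.
    """
    concentrations = [float(c) for c in concentrations]
    temperatures = [float(t) for t in temperatures]
    if any(c <= 0 for c in concentrations):
        raise ValidationError("concentrations must be positive")
    if any(not 0.0 <= t <= 40.0 for t in temperatures):
        raise ValidationError("temperatures must lie within 0-40 degC")
    optics = optics or OpticsConfig()
    rng = np.random.default_rng(scenario.seed)

    rows, g2_rows = [], []
    if tau_s is None:
        tau_s = np.logspace(-6.5, -2.5, 120)
    beta = 0.9
    for temp in temperatures:
        d0 = d0_at_temperature(scenario.d0_ref, temp, scenario.ref_temp_c)
        for c in concentrations:
            d_true = true_diffusion(scenario, c, temp)
            for rep in range(1, replicates + 1):
                if emit_g2:
                    gamma = optics.q_cm**2 * d_true
                    g2 = 1.0 + beta * np.exp(-2.0 * gamma * tau_s)
                    g2 = g2 + rng.normal(0.0, 1e-3, size=g2.shape)
                    for tv, gv in zip(tau_s, g2):
                        g2_rows.append({
                            "concentration_mg_ml": c, "temperature_c": temp,
                            "replicate": rep, "tau_s": tv, "g2": gv,
                        })
                    rows.append({"concentration_mg_ml": c, "temperature_c": temp,
                                 "replicate": rep, "d_true_cm2_s": d_true})
                else:
                    noise = rng.normal(0.0, scenario.dls_noise_frac * d0) \
                        if scenario.dls_noise_frac > 0 else 0.0
                    rows.append({
                        "concentration_mg_ml": c, "temperature_c": temp,
                        "replicate": rep, "d_cm2_s": d_true + noise,
                        "d_true_cm2_s": d_true,
                    })
    meta = {"kd_true": scenario.kd_true, "d0_ref": scenario.d0_ref,
            "seed": scenario.seed}
    return DlsSeries(pd.DataFrame(rows),
                     g2=pd.DataFrame(g2_rows) if emit_g2 else None, meta=meta)


def spike_impurities(series: DlsSeries, scenario: SyntheticScenario) -> DlsSeries:
    """Contaminate a series with slow-diffusing beads at intensity weight phi.

    D-valued rows are replaced by the intensity-weighted harmonic (z-average)
    combination D_app = 1/((1-phi)/D + phi/D_imp) with replicate noise
    inflated by ``impurity_noise_inflation``; stored g2 curves gain a second
    exponential component with rate q^2 D_imp and weight phi.
    """
    phi = scenario.impurity_intensity_fraction
    if not 0.0 <= phi < 1.0:
        raise ValidationError("impurity_intensity_fraction must lie in [0, 1)")
    if phi == 0.0:
        return series
    d_imp = default_impurity_d(scenario)
    rng = np.random.default_rng(scenario.seed + 104729)

    table = series.table.copy()
    g2_out = None
    if series.g2 is not None:
        optics = OpticsConfig()
        beta = 0.9
        parts = []
        keys = ["concentration_mg_ml", "temperature_c", "replicate"]
        merged = series.g2.merge(series.table, on=keys, how="left")
        d_col = "d_true_cm2_s" if "d_true_cm2_s" in merged.columns else "d_cm2_s"
        gamma_p = optics.q_cm**2 * merged[d_col].to_numpy(float)
        gamma_i = optics.q_cm**2 * d_imp
        tau = merged["tau_s"].to_numpy(float)
        g1 = (1.0 - phi) * np.exp(-gamma_p * tau) + phi * np.exp(-gamma_i * tau)
        g2_vals = 1.0 + beta * g1**2 + rng.normal(0.0, 1e-3, size=len(tau))
        g2_out = series.g2.copy()
        g2_out["g2"] = g2_vals
        parts.append(g2_out)
    if "d_cm2_s" in table.columns:
        d_base = table["d_true_cm2_s"].to_numpy(float) \
            if "d_true_cm2_s" in table.columns else table["d_cm2_s"].to_numpy(float)
        d_app = 1.0 / ((1.0 - phi) / d_base + phi / d_imp)
        sd = scenario.impurity_noise_inflation * scenario.dls_noise_frac * d_app
        table["d_cm2_s"] = d_app + rng.normal(0.0, 1.0, size=len(d_app)) * sd
        table["d_true_cm2_s"] = d_app

    meta = dict(series.meta)
    meta.update({"impurity_intensity_fraction": phi, "d_impurity": d_imp})
    return DlsSeries(table, g2=g2_out, meta=meta)


# ---------------------------------------------------------------------------
# viscosity and opalescence
# ---------------------------------------------------------------------------

def simulate_viscosity(scenario: SyntheticScenario, concentrations,
                       replicates: int = 1,
                       noise_frac: float = 0.0) -> pd.DataFrame:
    """Exponential concentration dependence eta(c) = eta0 exp(b c) (1 + eps)."""
    concs = np.asarray(list(concentrations), dtype=float)
    if (concs < 0).any():
        raise ValidationError("concentrations must be non-negative")
    rng = np.random.default_rng(scenario.seed + 7919)
    rows = []
    for rep in range(1, replicates + 1):
        eta = scenario.eta0_cp * np.exp(scenario.b_visc * concs)
        if noise_frac > 0:
            eta = eta * (1.0 + rng.normal(0.0, noise_frac, size=eta.shape))
        for c, e in zip(concs, eta):
            rows.append({"concentration_mg_ml": c, "viscosity_cp": e,
                         "replicate": rep})
    return pd.DataFrame(rows)


def simulate_opalescence(scenario: SyntheticScenario, concentrations,
                         replicates: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flat OD(340-360 nm) proportional to concentration, plus a blank.

    Returns (readings, blank) frames on the exact 5-point wavelength grid.
    """
    concs = np.asarray(list(concentrations), dtype=float)
    if (concs < 0).any():
        raise ValidationError("concentrations must be non-negative")
    rng = np.random.default_rng(scenario.seed + 15485863)
    blank_level = 0.04
    rows = []
    for c in concs:
        for rep in range(1, replicates + 1):
            for wl in OD_WAVELENGTHS_NM:
                od = blank_level + scenario.od_per_mg_ml * c
                if scenario.od_noise_sd > 0:
                    od += rng.normal(0.0, scenario.od_noise_sd)
                rows.append({"concentration_mg_ml": c, "replicate": rep,
                             "wavelength_nm": wl, "od": od})
    blank = pd.DataFrame({"wavelength_nm": list(OD_WAVELENGTHS_NM),
                          "od": [blank_level] * len(OD_WAVELENGTHS_NM)})
    return pd.DataFrame(rows), blank
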