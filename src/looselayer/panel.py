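"""Panel-level comparison of the QCM-D loose-layer metric and kD-DLS.

Produces the validation-panel summary: per-molecule means +/- SD, relative
errors, behavior ranks under each metric, and the rank-order correlation
between the two metrics with an exact permutation p-value (all n!
permutations enumerated for small panels) alongside the Student-t
approximation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ValidationError
from .tableio import read_table, write_table

EXACT_ENUMERATION_LIMIT = 10


@dataclass(frozen=True)
class PanelEntry:
    molecule: str
    qcmd_mean: float     # delta_f3_loose, Hz
    qcmd_sd: float
    kd_mean: float       # mL/g
    kd_sd: float
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.qcmd_sd < 0 or self.kd_sd < 0:
            raise ValidationError("standard deviations must be >= 0")
        if self.n_replicates < 2 and (self.qcmd_sd > 0 or self.kd_sd > 0):
            raise ValidationError("SD requires at least 2 replicates")


# Reference validation panel: eight therapeutic mAbs spanning good to poor
# solution behavior, with consensus loose-layer shifts (10 mg/mL) and kD.
REFERENCE_PANEL: tuple[PanelEntry, ...] = (
    PanelEntry("Trastuzumab", -23.9, 2.7, 51.7, 2.5),
    PanelEntry("Tocilizumab", -31.7, 2.1, 64.9, 7.3),
    PanelEntry("Evolocumab", -36.9, 5.0, 22.8, 8.0),
    PanelEntry("Anrukinzumab", -40.5, 2.1, 7.5, 4.0),
    PanelEntry("Fremanezumab", -47.6, 4.3, 36.8, 13.6),
    PanelEntry("Cetuximab", -79.4, 9.4, -42.4, 6.3),
    PanelEntry("Omalizumab", -82.4, 15.5, -22.9, 1.8),
    PanelEntry("Dupilumab", -112.4, 4.4, 3.0, 13.1),
)


@dataclass
class RankCorrelationResult:
    rho: float
    p_exact: float | None
    p_t_approx: float
    ranks_x: np.ndarray
    ranks_y: np.ndarray
    sum_d2: float


@dataclass
class ComparisonReport:
    entries: tuple[PanelEntry, ...]
    qcmd_rel_err_pct: tuple[float, ...]
    kd_rel_err_pct: tuple[float, ...]
    qcmd_ranks: tuple[float, ...]
    kd_ranks: tuple[float, ...]
    rank_correlation: RankCorrelationResult
    pearson_r: float


def relative_error(mean: float, sd: float) -> float:
    """Relative error as a percentage, 100 * sd / |mean|."""
    if mean == 0:
        raise ValidationError("relative error undefined for mean = 0")
    if sd < 0:
        raise ValidationError("sd must be >= 0")
    return 100.0 * sd / abs(mean)


def rank_by_behavior(values, higher_is_better: bool = True) -> np.ndarray:
    """Behavior ranks: rank 1 = best behaved; ties get average ranks.

    For the loose-layer shift the least-negative (largest) value is best;
    for kD the largest value is best — both are ``higher_is_better``.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValidationError("cannot rank an empty sequence")
    return scipy.stats.rankdata(-v if higher_is_better else v)


def pearson(x, y) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("pearson needs equal-length inputs, n >= 3")
    xc, yc = x - x.mean(), y - y.mean()
    sx, sy = math.sqrt(float(xc @ xc)), math.sqrt(float(yc @ yc))
    if sx == 0 or sy == 0:
        raise ValidationError("zero variance in x or y")
    return float(xc @ yc) / (sx * sy)


def _t_approx_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 2.0 / math.factorial(n)  # degenerate; bounded away from 0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * scipy.stats.t.sf(abs(t), n - 2))


def spearman(x, y, p_method: str = "exact") -> RankCorrelationResult:
    """Spearman rank correlation with exact or t-approximate inference.

    rho is the Pearson correlation of the rank vectors (average ranks for
    ties).  The exact two-sided p-value enumerates all n! permutations of the
    y ranks and counts those with |rho_perm| >= |rho_obs| - 1e-12; for
    n > 10 the enumeration is refused and the t approximation must be used.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n = len(x)
    if len(y) != n or n < 3:
        raise ValidationError("spearman needs equal-length inputs, n >= 3")
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rho = pearson(rx, ry)
    sum_d2 = float(np.sum((rx - ry) ** 2))
    p_t = _t_approx_p(rho, n)

    p_exact = None
    if p_method == "exact":
        if n > EXACT_ENUMERATION_LIMIT:
            raise ValidationError(
                f"exact enumeration refused for n={n} > {EXACT_ENUMERATION_LIMIT}; "
                "use p_method='t_approx'")
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt(float(rxc @ rxc)) * math.sqrt(float(ryc @ ryc))
        perms = np.array(list(itertools.permutations(ryc)))
        rhos = perms @ rxc / denom
        p_exact = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    elif p_method != "t_approx":
        raise ValidationError("p_method must be 'exact' or 't_approx'")
    return RankCorrelationResult(rho, p_exact, p_t, rx, ry, sum_d2)


def comparison_report(entries: Sequence[PanelEntry]) -> ComparisonReport:
    """Assemble the panel summary (sorted by loose-layer rank)."""
    entries = list(entries)
    if len(entries) < 3:
        raise ValidationError("panel comparison needs at least 3 molecules")
    names = [e.molecule for e in entries]
    if len(set(n.lower() for n in names)) != len(names):
        raise ValidationError("duplicate molecule names in panel")

    qcmd = [e.qcmd_mean for e in entries]
    kd = [e.kd_mean for e in entries]
    qcmd_ranks = rank_by_behavior(qcmd)
    order = np.argsort(qcmd_ranks, kind="stable")
    entries = [entries[i] for i in order]
    qcmd = [e.qcmd_mean for e in entries]
    kd = [e.kd_mean for e in entries]
    qcmd_ranks = rank_by_behavior(qcmd)
    kd_ranks = rank_by_behavior(kd)

    corr = spearman(qcmd, kd, p_method="exact" if len(entries) <= EXACT_ENUMERATION_LIMIT
                    else "t_approx")
    return ComparisonReport(
        entries=tuple(entries),
        qcmd_rel_err_pct=tuple(relative_error(e.qcmd_mean, e.qcmd_sd) for e in entries),
        kd_rel_err_pct=tuple(relative_error(e.kd_mean, e.kd_sd) for e in entries),
        qcmd_ranks=tuple(float(r) for r in qcmd_ranks),
        kd_ranks=tuple(float(r) for r in kd_ranks),
        rank_correlation=corr,
        pearson_r=pearson(qcmd, kd),
    )


def report_frame(report: ComparisonReport) -> pd.DataFrame:
    rows = []
    for i, e in enumerate(report.entries):
        rows.append({
            "molecule": e.molecule,
            "qcmd_mean_hz": e.qcmd_mean, "qcmd_sd_hz": e.qcmd_sd,
            "qcmd_rel_err_pct": report.qcmd_rel_err_pct[i],
            "kd_mean_ml_g": e.kd_mean, "kd_sd_ml_g": e.kd_sd,
            "kd_rel_err_pct": report.kd_rel_err_pct[i],
            "rank_qcmd": report.qcmd_ranks[i], "rank_kd": report.kd_ranks[i],
            "n_replicates": e.n_replicates,
        })
    return pd.DataFrame(rows)


def write_report(report: ComparisonReport, path, meta: dict | None = None) -> None:
    corr = report.rank_correlation
    all_meta = dict(meta or {})
    all_meta.update({
        "spearman_rho": corr.rho,
        "spearman_p_exact": corr.p_exact,
        "spearman_p_t_approx": corr.p_t_approx,
        "spearman_sum_d2": corr.sum_d2,
        "pearson_r": report.pearson_r,
    })
    write_table(path, report_frame(report), all_meta)


def read_panel_table(path) -> list[PanelEntry]:
    """Read a panel table (molecule, qcmd_mean/sd, kd_mean/sd[, n])."""
    frame, _ = read_table(path)
    entries = []
    for _, row in frame.iterrows():
        entries.append(PanelEntry(
            molecule=str(row["molecule"]),
            qcmd_mean=float(row["qcmd_mean_hz"]), qcmd_sd=float(row["qcmd_sd_hz"]),
            kd_mean=float(row["kd_mean_ml_g"]), kd_sd=float(row["kd_sd_ml_g"]),
            n_replicates=int(row.get("n_replicates", 3)),
        ))
    return entries


def write_panel_table(entries: Sequence[PanelEntry], path,
                      meta: dict | None = None) -> None:
    frame = pd.DataFrame([{
        "molecule": e.molecule,
        "qcmd_mean_hz": e.qcmd_mean, "qcmd_sd_hz": e.qcmd_sd,
        "kd_mean_ml_g": e.kd_mean, "kd_sd_ml_g": e.kd_sd,
        "n_replicates": e.n_replicates,
    } for e in entries])
    write_table(path, frame, meta or {})
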