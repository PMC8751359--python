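"""Headline analyses: oscillation-region scans, stoichiometric-condition and
ratio analyses, and repression-function sensitivity curves."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import spearmanr

from . import param_sampling, simulate
from .models import (
    NeurosporaParams,
    StoichCondition,
    effective_constants,
    neurospora_f,
)

__all__ = [
    "kd_sweep_core",
    "stoich_condition_check",
    "ttfl_vs_ptr",
    "phospho_strength_sweep",
    "sensitivity_curve",
    "steady_state_repressor",
    "stoich_ratio_distribution",
    "SensitivityCurve",
]

KD_GRID_14 = np.logspace(-4, -1, 14)
PHOSPHO_KD_GRID = (1e-4, 1e-3, 1e-2, 1e-1, 1.0)

#: simulation windows for the FFT scans (hours); long enough for >= 10
#: circadian cycles after the 30% transient cut.
CORE_T_END = 480.0
CORE_DT = 0.25
TTFL_T_END = 600.0
TTFL_DT = 0.25


def _binomial_se(frac: float, n: int) -> float:
    return float(np.sqrt(max(frac * (1.0 - frac), 0.0) / n)) if n else np.nan


# ---------------------------------------------------------------------------
# three-phosphoform model scans
# ---------------------------------------------------------------------------


def classify_core_table(table: pd.DataFrame) -> pd.DataFrame:
    """Attach FFT oscillation verdicts to a core parameter table."""
    cols = ["k1", "k2", "k3", "k4", "Kd", "A_T", "C_T"]
    rows = table[cols].to_numpy(dtype=float)
    y0 = np.zeros((len(rows), 3))
    osc, periods = simulate.batch_classify_fft(
        "core", rows, y0, CORE_T_END, CORE_DT, component=2)
    out = table.copy()
    out["oscillating"] = osc
    out["period"] = periods
    out["ratio_CT_AT"] = out["C_T"] / out["A_T"]
    return out


def kd_sweep_core(kd_grid: Optional[Sequence[float]] = None, n: int = 100_000,
                  seed: int = 0, ranges: Optional[dict] = None) -> dict:
    """Oscillating fraction of random parameter sets per Kd value.

    Returns a dict with the per-Kd fraction table (with binomial standard
    errors), the concatenated per-row scan, and a Spearman trend test of
    fraction against Kd.
    """
    if kd_grid is None:
        kd_grid = KD_GRID_14
    kd_grid = np.asarray(kd_grid, dtype=float)
    if np.any((kd_grid < 1e-4 - 1e-12) | (kd_grid > 1e-1 + 1e-12)):
        raise ValueError("kd_grid must lie within [1e-4, 1e-1]")
    records = []
    scans = []
    for Kd in kd_grid:
        table = param_sampling.sample_core(Kd, n, seed, ranges=ranges)
        scan = classify_core_table(table)
        frac = float(scan["oscillating"].mean())
        records.append({"Kd": Kd, "n": n, "n_osc": int(scan["oscillating"].sum()),
                        "fraction": frac, "se": _binomial_se(frac, n)})
        scans.append(scan)
    fractions = pd.DataFrame.from_records(records)
    rho, pvalue = spearmanr(fractions["Kd"], fractions["fraction"])
    return {
        "fractions": fractions,
        "scan": pd.concat(scans, ignore_index=True),
        "trend": {"spearman_rho": float(rho), "pvalue": float(pvalue)},
    }


def stoich_condition_check(scan: pd.DataFrame,
                           condition: StoichCondition = StoichCondition()
                           ) -> dict:
    """Compliance of oscillating rows with C_T > (1 + r) A_T (strict).

    Returns the compliant fraction among oscillating rows plus the violator
    rows with their margins (C_T - (1+r) A_T, negative or zero = violation).
    """
    osc = scan[scan["oscillating"]].copy()
    threshold = (1.0 + condition.r_const) * osc["A_T"] + condition.epsilon
    osc["margin"] = osc["C_T"] - threshold
    compliant = osc["C_T"] > threshold
    return {
        "n_oscillating": int(len(osc)),
        "n_compliant": int(compliant.sum()),
        "fraction_compliant": float(compliant.mean()) if len(osc) else np.nan,
        "violators": osc.loc[~compliant],
    }


# ---------------------------------------------------------------------------
# transcription-coupled comparison
# ---------------------------------------------------------------------------


def _classify_ttfl_table(table: pd.DataFrame, mode: str):
    cols = ["k1", "k2", "k3", "k4", "Kd", "A_T", "V_trsp", "V_m", "K_s",
            "K_0", "V_d"]
    rows = table[cols].to_numpy(dtype=float)
    mode_col = np.full((len(rows), 1), 1.0 if mode == "ttfl" else 0.0)
    rows = np.hstack([rows, mode_col])
    y0 = np.zeros((len(rows), 5))
    return simulate.batch_classify_fft("ttfl", rows, y0, TTFL_T_END, TTFL_DT,
                                       component=4)


def ttfl_vs_ptr(n: int = 22_500, seed: int = 0,
                ranges: Optional[dict] = None) -> dict:
    """Paired oscillating fractions for the two transcription modes.

    The identical parameter table drives both modes; per-row paired verdicts
    are retained in the returned scan table.
    """
    table = param_sampling.sample_ttfl(n=n, seed=seed, ranges=ranges)
    osc_t, per_t = _classify_ttfl_table(table, "ttfl")
    osc_p, per_p = _classify_ttfl_table(table, "ptr")
    scan = table.copy()
    scan["oscillating_ttfl"] = osc_t
    scan["period_ttfl"] = per_t
    scan["oscillating_ptr"] = osc_p
    scan["period_ptr"] = per_p
    frac_t, frac_p = float(osc_t.mean()), float(osc_p.mean())
    return {
        "fraction_ttfl": frac_t,
        "fraction_ptr": frac_p,
        "se_ttfl": _binomial_se(frac_t, n),
        "se_ptr": _binomial_se(frac_p, n),
        "scan": scan,
    }


# ---------------------------------------------------------------------------
# phospholock robustness surface
# ---------------------------------------------------------------------------


def phospho_strength_sweep(kd_grid: Sequence[float] = PHOSPHO_KD_GRID,
                           multiplier_grid: Sequence[float] = param_sampling.PHOSPHO_MULTIPLIERS,
                           n: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Oscillating percentage per (Kd, k2r/k2f multiplier) cell.

    Smaller multipliers mean stronger phosphorylation of the locked
    complex.  Verdicts use the event-location procedure with random initial
    conditions drawn from the run's substream.
    """
    from .models import PhospholockParams, chain_param_vector

    records = []
    for Kd in kd_grid:
        base = param_sampling.sample_phospholock(n=n, seed=seed, Kd=Kd)
        rng = param_sampling.substream(seed, f"phospho-sweep-init-kd={Kd:.6g}")
        y0 = rng.uniform(0.0, 10.0, size=(n, 3))
        for mult in multiplier_grid:
            table = param_sampling.apply_phospho_multiplier(base, mult)
            rows = np.empty((n, 11))
            for i, rec in enumerate(table.itertuples(index=False)):
                p = PhospholockParams(
                    alpha1=rec.alpha1, alpha2=rec.alpha2, alpha3=rec.alpha3,
                    beta1=rec.beta1, beta2=rec.beta2, beta3=rec.beta3,
                    A_T=rec.A_T, k1f=rec.k1f, k1r=rec.k1r, k2f=rec.k2f,
                    k2r=rec.k2r, k3=rec.k3)
                rows[i] = chain_param_vector(p)
            osc, _ = simulate.batch_classify_events("chain", rows, y0)
            frac = float(osc.mean())
            records.append({"Kd": Kd, "multiplier": mult, "n": n,
                            "fraction": frac, "percent": 100.0 * frac,
                            "se": _binomial_se(frac, n)})
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# sensitivity curves
# ---------------------------------------------------------------------------


@dataclass
class SensitivityCurve:
    """Log-log sensitivity d log f / d log x on a log-spaced grid."""

    x: np.ndarray
    f: np.ndarray
    sensitivity: np.ndarray

    @property
    def peak_magnitude(self) -> float:
        return float(np.max(np.abs(self.sensitivity)))

    @property
    def peak_location(self) -> float:
        return float(self.x[int(np.argmax(np.abs(self.sensitivity)))])


def sensitivity_curve(f: Callable, grid) -> SensitivityCurve:
    """Centered log-log finite-difference sensitivity of a positive function.

    Grid points where f <= 0 truncate the domain (with a warning) since the
    logarithmic derivative is undefined there.
    """
    import warnings

    x = np.asarray(grid, dtype=float)
    if np.any(x <= 0):
        raise ValueError("grid must be positive for a log-log derivative")
    fx = np.asarray([float(f(xi)) for xi in x])
    positive = fx > 0
    if not positive.all():
        warnings.warn("f <= 0 on part of the grid; domain truncated")
        keep = np.flatnonzero(positive)
        x, fx = x[keep], fx[keep]
    if x.size < 3:
        raise ValueError("need >= 3 grid points with f > 0")
    lx, lf = np.log(x), np.log(fx)
    sens = np.gradient(lf, lx)
    return SensitivityCurve(x=x, f=fx, sensitivity=sens)


# ---------------------------------------------------------------------------
# steady-state stoichiometric ratio
# ---------------------------------------------------------------------------


def steady_state_repressor(p: NeurosporaParams):
    """Steady-state total repressor R* of the activator-phosphorylation
    chain, and the stoichiometric ratio S = R*/A_T.

    R* solves  f(R) = (beta1 beta2 beta3 / (alpha1 alpha2 alpha3)) R,
    where the left side is the repression function written through the
    bound-complex radical; the bracket [0, A_T prod(alpha)/prod(beta) + 1]
    guarantees a sign change (left side bounded by A_T, right side linear).
    """
    K1, K2, K3 = effective_constants(p)
    k4 = p.k4
    ratio = (p.beta1 * p.beta2 * p.beta3) / (p.alpha1 * p.alpha2 * p.alpha3)

    def bound_complex(R):
        c = K2 * (1.0 + k4)
        s = K1 * p.A_T + K3 * R + c
        disc = max(s * s - 4.0 * K1 * K3 * p.A_T * R, 0.0)
        return (s - np.sqrt(disc)) / (2.0 * K1 * K3)

    def residual(R):
        lhs = (p.A_T - K3 * bound_complex(R)) / (1.0 + k4)
        return lhs - ratio * R

    hi = p.A_T / ratio + 1.0
    lo = 0.0
    if residual(lo) <= 0:
        raise ValueError("no sign change at R = 0 (degenerate parameters)")
    if residual(hi) >= 0:
        raise ValueError("bracketing failure: residual positive at upper end")
    R_star = brentq(residual, lo, hi, xtol=1e-300, rtol=8.9e-16)
    scale = max(p.A_T, ratio * R_star, 1e-300)
    if abs(residual(R_star)) > 1e-8 * scale:
        raise RuntimeError(f"root residual too large: {residual(R_star):.3e}")
    return float(R_star), float(R_star / p.A_T)


def _ratio_for_row(rec, k3_value: float) -> float:
    p = NeurosporaParams(
        alpha1=rec.alpha1, alpha2=rec.alpha2, alpha3=rec.alpha3,
        beta1=rec.beta1, beta2=rec.beta2, beta3=rec.beta3,
        A_T=rec.A_T, k1f=rec.k1f, k1r=rec.k1r, k2f=rec.k2f, k2r=rec.k2r,
        k3=k3_value, k4f=rec.k4f, k4r=rec.k4r)
    return steady_state_repressor(p)[1]


def stoich_ratio_distribution(k3_grid: Sequence[float] = (0.0, 0.5, 1.0, 2.0),
                              target: int = 100, seed: int = 0,
                              max_draws: int = 200_000) -> dict:
    """Distribution of steady-state repressor:activator ratios from
    oscillating parameter sets, per k3 value.

    Returns per-k3 tables of oscillating sets with their ratios, plus a
    summary (min, max, range) per k3.
    """
    tables = {}
    summary = []
    for k3v in k3_grid:
        table = param_sampling.sample_until_oscillating(
            target=target, k3_value=k3v, seed=seed, max_draws=max_draws)
        ratios = np.array([
            _ratio_for_row(rec, k3v) for rec in table.itertuples(index=False)
        ])
        table = table.copy()
        table["stoich_ratio"] = ratios
        tables[k3v] = table
        summary.append({
            "k3": k3v, "n": len(table),
            "min_ratio": float(ratios.min()),
            "max_ratio": float(ratios.max()),
            "range": float(ratios.max() - ratios.min()),
            "draws": table.attrs.get("draws"),
        })
    return {"tables": tables, "summary": pd.DataFrame.from_records(summary)}
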