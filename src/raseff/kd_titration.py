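"""Dissociation constants from fluorescence-polarization titrations.

A fixed concentration R_t of fluorescently labeled, GTP-analog-loaded RAS is
titrated with increasing total effector E_t; polarization rises as the small
labeled species is incorporated into the slower-tumbling complex. Because
R_t (1 μM in the assay design) is comparable to the K_d of the tightest
effectors, ligand depletion is not negligible and the hyperbolic isotherm is
wrong there; the exact 1:1 mass-action solution is the physical root of

    x² − (R_t + E_t + K_d)·x + R_t·E_t = 0,

so the bound fraction is x/R_t with

    x = [(R_t + E_t + K_d) − sqrt((R_t + E_t + K_d)² − 4·R_t·E_t)] / 2,

the quadratic (tight-binding) ligand-binding equation. The measured signal
is assumed linear in the bound fraction, giving three fit parameters:
K_d, the free-state signal P_free and the saturated signal P_bound. K_d is
kept positive through a log parameterization. Units are μM end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from raseff.errors import DegenerateDataError, InsufficientDataError

MIN_POINTS = 5


@dataclass
class TitrationCurve:
    """One titration series: fixed receptor, increasing ligand, signals."""

    receptor_total: float  # μM, the labeled RAS·mGppNHp species
    ligand_totals: np.ndarray  # μM, titrated effector, strictly increasing
    signals: np.ndarray | None = None  # polarization, arbitrary units
    meta: tuple[str, str] = ("", "")  # (RAS name, effector name)

    def __post_init__(self) -> None:
        self.ligand_totals = np.asarray(self.ligand_totals, dtype=float)
        if self.receptor_total <= 0:
            raise ValueError("receptor_total must be positive")
        if np.any(self.ligand_totals < 0):
            raise ValueError("ligand totals must be non-negative")
        if np.any(np.diff(self.ligand_totals) <= 0):
            raise ValueError("ligand totals must be strictly increasing")
        if self.signals is not None:
            self.signals = np.asarray(self.signals, dtype=float)
            if self.signals.shape != self.ligand_totals.shape:
                raise ValueError("signals and ligand_totals must have equal length")


@dataclass
class BindingFit:
    """Fitted (K_d, P_free, P_bound) with diagnostics."""

    kd: float  # μM
    p_free: float
    p_bound: float
    residual_norm: float  # sum of squared residuals
    stderr_kd: float  # asymptotic standard error of K_d
    converged: bool

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("fitted kd must be positive")
        if self.residual_norm < 0:
            raise ValueError("residual_norm must be non-negative")


def fraction_bound(receptor_total, ligand_total, kd):
    """Bound receptor fraction x/R_t from the quadratic isotherm.

    Vectorized over `ligand_total`. The discriminant is clamped at zero to
    absorb floating-point negatives near stoichiometric (K_d → 0) binding,
    where the two roots coalesce.
    """
    rt = float(receptor_total)
    et = np.asarray(ligand_total, dtype=float)
    kd = float(kd)
    if rt <= 0:
        raise ValueError("receptor_total must be positive")
    if kd < 0 or np.any(et < 0):
        raise ValueError("ligand_total and kd must be non-negative")
    b = rt + et + kd
    disc = np.maximum(b * b - 4.0 * rt * et, 0.0)
    x = 0.5 * (b - np.sqrt(disc))
    frac = x / rt
    if frac.ndim == 0:
        return float(frac)
    return frac


def model_signal(curve: TitrationCurve, kd: float, p_free: float, p_bound: float):
    """Predicted polarization: P_free + (P_bound − P_free)·fraction_bound."""
    frac = fraction_bound(curve.receptor_total, curve.ligand_totals, kd)
    return p_free + (p_bound - p_free) * np.asarray(frac)


def _initial_kd(curve: TitrationCurve) -> float:
    """E_t at half-signal, linearly interpolated (a serviceable K_d guess)."""
    s = curve.signals
    half = 0.5 * (s[0] + s[-1])
    e = curve.ligand_totals
    rising = s[-1] >= s[0]
    for k in range(1, len(s)):
        lo, hi = (s[k - 1], s[k]) if rising else (s[k], s[k - 1])
        if lo <= half <= hi and s[k] != s[k - 1]:
            t = (half - s[k - 1]) / (s[k] - s[k - 1])
            guess = e[k - 1] + t * (e[k] - e[k - 1])
            return max(guess, 1e-6)
    return max(float(np.median(e)), 1e-6)


def fit_titration(curve: TitrationCurve, max_nfev: int = 1000) -> BindingFit:
    """Least-squares fit of (K_d, P_free, P_bound) to one titration.

    Unit weights; initialization P_free = first signal, P_bound = last
    signal, K_d = interpolated half-signal concentration; K_d constrained
    positive by fitting log K_d. The standard error of K_d comes from the
    Jacobian at the optimum (delta method through the log parameter).
    """
    if curve.signals is None or len(curve.signals) < MIN_POINTS:
        raise InsufficientDataError(
            f"need at least {MIN_POINTS} titration points, got "
            f"{0 if curve.signals is None else len(curve.signals)}"
        )
    s = curve.signals
    if np.ptp(s) == 0:
        raise DegenerateDataError("signals are constant; nothing to fit")

    theta0 = np.array([np.log(_initial_kd(curve)), s[0], s[-1]])

    def residuals(theta):
        return model_signal(curve, np.exp(theta[0]), theta[1], theta[2]) - s

    result = least_squares(residuals, theta0, method="lm", max_nfev=max_nfev)
    log_kd, p_free, p_bound = result.x
    kd = float(np.exp(log_kd))
    ssr = float(np.sum(result.fun**2))

    # asymptotic covariance: s² (JᵀJ)⁻¹, then Var(kd) = kd²·Var(log kd)
    dof = max(len(s) - 3, 1)
    jtj = result.jac.T @ result.jac
    try:
        cov = np.linalg.inv(jtj) * (ssr / dof)
        stderr_kd = float(kd * np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        stderr_kd = float("nan")

    return BindingFit(
        kd=kd,
        p_free=float(p_free),
        p_bound=float(p_bound),
        residual_norm=ssr,
        stderr_kd=stderr_kd,
        converged=bool(result.status > 0 and result.nfev < max_nfev),
    )


def replicate_summary(fits: list[BindingFit]) -> tuple[float, float]:
    """Mean K_d and standard error of the mean over replicate fits."""
    if len(fits) < 2:
        raise InsufficientDataError("replicate summary needs at least 2 fits")
    kds = np.array([f.kd for f in fits], dtype=float)
    sem = float(np.std(kds, ddof=1) / np.sqrt(len(kds)))
    return float(np.mean(kds)), sem


def read_titration_tsv(
    path, receptor_total: float, meta: tuple[str, str] = ("", "")
) -> TitrationCurve:
    """Read a (ligand_total_uM, polarization) TSV into a TitrationCurve."""
    import pandas as pd

    table = pd.read_csv(path, sep="\t")
    required = {"ligand_total_uM", "polarization"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return TitrationCurve(
        receptor_total=receptor_total,
        ligand_totals=table["ligand_total_uM"].to_numpy(),
        signals=table["polarization"].to_numpy(),
        meta=meta,
    )
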