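"""Equilibrium single-site binding fits and reporter-repair normalization.

Two isotherms are supported:

* ``hyperbolic``  R(L) = offset + Bmax * L / (Kd + L)        (free-ligand)
* ``depletion``   R(L) = offset + Bmax * f(T, L, Kd)          (quadratic)

where ``f = ((T + L + Kd) - sqrt((T + L + Kd)^2 - 4 T L)) / (2 T)`` is the
bound fraction of the fixed labelled partner at total concentration T.  The
depletion form is the default for thermophoresis-style designs where T is
comparable to the affinity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateDataError, ValidationError

MODELS = ("hyperbolic", "depletion")


@dataclass
class BindingCurve:
    """Concentration-response pairs from one titration (nM, signal units)."""

    concentrations: np.ndarray
    responses: np.ndarray
    target_conc: float = 0.0  # fixed labelled-partner concentration, nM
    replicate: int = 0

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValidationError("concentrations and responses differ in length")
        if np.any(self.concentrations < 0):
            raise ValidationError("concentrations must be >= 0")
        if np.unique(self.concentrations).size < 4:
            raise ValidationError("need >= 4 distinct concentrations to fit")


@dataclass
class FitResult:
    kd: float
    rmax: float
    offset: float
    kd_se: float
    rmax_se: float
    offset_se: float
    model: str
    converged: bool
    rss: float
    n_points: int = 0
    extras: dict = field(default_factory=dict)


def bound_fraction(target: float, ligand, kd: float):
    """Exact bound fraction of the fixed partner under ligand depletion."""
    L = np.asarray(ligand, dtype=float)
    s = target + L + kd
    disc = np.maximum(s**2 - 4.0 * target * L, 0.0)
    return (s - np.sqrt(disc)) / (2.0 * target)


def hyperbolic_fraction(ligand, kd: float):
    L = np.asarray(ligand, dtype=float)
    return L / (kd + L)


def _model_response(params, L, model, target):
    kd, rmax, offset = params
    if model == "depletion":
        return offset + rmax * bound_fraction(target, L, kd)
    return offset + rmax * hyperbolic_fraction(L, kd)


def fit_single_site(curve: BindingCurve, model: str = "hyperbolic") -> FitResult:
    """Least-squares fit of Kd, Bmax and offset with multi-start initialization.

    Kd starting values span the sampled concentration range on a log grid;
    the best converged solution wins.  Standard errors come from the Jacobian
    at the optimum.
    """
    if model not in MODELS:
        raise ValidationError(f"model must be one of {MODELS}")
    if model == "depletion" and curve.target_conc <= 0:
        raise ValidationError("depletion model requires target_conc > 0")

    L = curve.concentrations
    R = curve.responses
    if np.ptp(R) == 0:
        raise DegenerateDataError("responses are constant; nothing to fit")

    pos = L[L > 0]
    lo, hi = pos.min(), pos.max()
    kd_grid = np.geomspace(lo / 10.0, hi * 10.0, 12)
    span = float(R.max() - R.min())
    target = curve.target_conc

    def residuals(p):
        return _model_response(p, L, model, target) - R

    best = None
    for kd0 in kd_grid:
        p0 = np.array([kd0, span, float(R.min())])
        try:
            sol = least_squares(
                residuals, p0,
                bounds=([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        raise DegenerateDataError("all fit starts failed")

    rss, sol = best
    kd, rmax, offset = sol.x
    dof = max(L.size - 3, 1)
    s2 = rss / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        ses = np.full(3, np.nan)
    converged = bool(sol.success)
    if not converged:
        warnings.warn("binding fit did not converge; reporting best-found parameters")
    return FitResult(
        kd=float(kd), rmax=float(rmax), offset=float(offset),
        kd_se=float(ses[0]), rmax_se=float(ses[1]), offset_se=float(ses[2]),
        model=model, converged=converged, rss=rss, n_points=int(L.size),
    )


def fit_replicates(curves: list[BindingCurve], model: str = "hyperbolic") -> FitResult:
    """Pool replicate curves into one global fit (shared parameters)."""
    L = np.concatenate([c.concentrations for c in curves])
    R = np.concatenate([c.responses for c in curves])
    target = curves[0].target_conc
    pooled = BindingCurve(L, R, target_conc=target)
    return fit_single_site(pooled, model=model)


def normalize_repair(gfp_pos_pct, transfection_eff_pct):
    """Repair frequency normalized to the parallel transfection-efficiency
    control: gfp% / (efficiency% / 100).  Accepts scalars or paired vectors."""
    g = np.asarray(gfp_pos_pct, dtype=float)
    t = np.asarray(transfection_eff_pct, dtype=float)
    if g.shape != t.shape:
        raise ValidationError("GFP and efficiency vectors differ in length")
    if np.any(t <= 0):
        raise ValidationError("transfection efficiency must be > 0")
    out = g / (t / 100.0)
    return float(out) if out.ndim == 0 else out
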