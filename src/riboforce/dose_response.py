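"""Saturation-curve fitting for bulk assays and force-response data.

Three named models, all hyperbolic in ligand concentration x:

- ``mfs_saturation``  y = (u + b*x/K_D) / (1 + x/K_D)
    Force-spectroscopy dose response: u is the response at x=0, b the
    response at saturation, K_D the half-saturation concentration.
- ``one_site_total``  y = B_max*x/(K_D + x) + ns_slope*x + background
    One-site total binding (fluorescence-intensity / thermophoresis
    titrations); the linear term absorbs nonspecific binding and can be
    constrained to zero.
- ``termination``     y = e_min + (e_max - e_min)*x/(T_50 + x)
    Transcription-termination efficiency versus ligand; T_50 is the
    concentration of half-maximal effect.

All fitters use multistart nonlinear least squares (a decade grid over the
half-saturation constant) with standard errors from the Jacobian at the
optimum; ``fit_t50`` additionally reports a seeded residual-bootstrap SE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .trace_model import DoseResponseFit

__all__ = [
    "GelQuantification",
    "FitConvergenceError",
    "mfs_saturation_curve",
    "one_site_total_curve",
    "termination_curve",
    "CURVES",
    "fit_saturation",
    "fit_one_site_total",
    "termination_efficiency",
    "fit_t50",
]


class FitConvergenceError(RuntimeError):
    """No multistart converged; carries the best residual norm found."""

    def __init__(self, message: str, best_residual: float = np.nan):
        super().__init__(message)
        self.best_residual = best_residual


@dataclass(frozen=True)
class GelQuantification:
    """Band intensities from one lane of a termination gel."""

    concentration: float
    terminated_intensity: float
    readthrough_intensity: float

    def __post_init__(self) -> None:
        if self.terminated_intensity < 0 or self.readthrough_intensity < 0:
            raise ValueError("band intensities must be >= 0")
        if self.terminated_intensity == 0 and self.readthrough_intensity == 0:
            raise ValueError("terminated and readthrough intensities both zero")


def mfs_saturation_curve(x, u, b, K_D):
    x = np.asarray(x, dtype=float)
    return (u + b * x / K_D) / (1.0 + x / K_D)


def one_site_total_curve(x, B_max, K_D, ns_slope, background):
    x = np.asarray(x, dtype=float)
    return B_max * x / (K_D + x) + ns_slope * x + background


def termination_curve(x, e_min, e_max, T_50):
    x = np.asarray(x, dtype=float)
    return e_min + (e_max - e_min) * x / (T_50 + x)


CURVES = {
    "mfs_saturation": mfs_saturation_curve,
    "one_site_total": one_site_total_curve,
    "termination": termination_curve,
}


def _kd_grid(x: np.ndarray) -> np.ndarray:
    """Candidate half-saturation constants: decade grid spanning the data."""
    pos = x[x > 0]
    if pos.size == 0:
        return np.array([1.0])
    lo, hi = np.log10(pos.min()), np.log10(pos.max())
    return 10.0 ** np.arange(np.floor(lo) - 1, np.ceil(hi) + 2)


def _multistart_ls(residual_fn, starts, bounds, n_obs):
    """Run least_squares from each start; return best solution + covariance."""
    best = None
    best_res = np.inf
    for p0 in starts:
        try:
            sol = least_squares(residual_fn, p0, bounds=bounds, method="trf")
        except ValueError:
            continue
        if sol.cost < best_res:
            best_res, best = sol.cost, sol
    if best is None or not best.success:
        raise FitConvergenceError(
            "no multistart converged",
            best_residual=np.sqrt(2 * best_res) if np.isfinite(best_res) else np.nan,
        )
    # covariance from the Jacobian at the optimum
    n_par = best.x.size
    dof = max(n_obs - n_par, 1)
    s2 = 2 * best.cost / dof
    JTJ = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(JTJ) * s2
    except np.linalg.LinAlgError:
        cov = np.full((n_par, n_par), np.nan)
    return best, cov


def fit_saturation(
    x, y, init: dict[str, float] | None = None, sigma=None
) -> DoseResponseFit:
    """Fit y = (u + b*x/K_D)/(1 + x/K_D) by multistart least squares.

    Requires >= 4 distinct concentrations including one at or near zero.
    ``sigma`` (optional per-point standard errors) turns the fit into
    weighted least squares — useful when the zero-concentration response is
    pinned by construction (self-normalization) and should anchor u.
    The fit is flagged ``non_identifiable`` when |b - u| < 2*SE(b - u):
    a flat curve carries no information about K_D.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 4:
        raise ValueError("need >= 4 distinct concentrations")
    if x.min() > 0.05 * x.max():
        raise ValueError("need a concentration at or near zero to anchor u")
    if sigma is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(sigma, dtype=float)
        if w.shape != y.shape or np.any(w <= 0):
            raise ValueError("sigma must be positive and match y in shape")

    u0 = float(y[np.argmin(x)])
    b0 = float(y[np.argmax(x)])
    scale = max(abs(u0), abs(b0), 1e-12)
    starts = [(u0, b0, K) for K in _kd_grid(x)]
    if init is not None:
        starts.insert(0, (init.get("u", u0), init.get("b", b0), init.get("K_D", np.median(_kd_grid(x)))))
    bounds = ([-np.inf, -np.inf, 1e-300], [np.inf, np.inf, np.inf])

    def resid(p):
        return (mfs_saturation_curve(x, *p) - y) / w

    best, cov = _multistart_ls(resid, starts, bounds, x.size)
    u, b, K = best.x
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    flags: list[str] = []
    se_diff = np.sqrt(max(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1], 0.0))
    if abs(b - u) < 2 * se_diff or abs(b - u) < 1e-9 * scale:
        flags.append("non_identifiable")
    return DoseResponseFit(
        model="mfs_saturation",
        params={"u": float(u), "b": float(b), "K_D": float(K)},
        std_errors={"u": float(se[0]), "b": float(se[1]), "K_D": float(se[2])},
        concentrations=x,
        residual_norm=float(np.sqrt(2 * best.cost)),
        flags=tuple(flags),
    )


def fit_one_site_total(
    table: pd.DataFrame,
    fix_ns_slope: bool = False,
) -> DoseResponseFit:
    """Fit a one-site total binding curve to a titration table.

    ``table`` needs columns ``concentration_molar`` and ``signal`` (replicates
    pooled).  With ``fix_ns_slope`` the nonspecific linear term is pinned to
    zero (specific-only variant).
    """
    x = table["concentration_molar"].to_numpy(dtype=float)
    y = table["signal"].to_numpy(dtype=float)
    if np.unique(x).size < 5:
        raise ValueError("need >= 5 distinct concentrations")

    bg0 = float(np.median(y[x <= np.quantile(x, 0.2)]))
    amp0 = float(y.max() - y.min()) or 1.0
    kd_grid = _kd_grid(x)

    if fix_ns_slope:
        starts = [(amp0, K, bg0) for K in kd_grid]
        bounds = ([0, 1e-300, -np.inf], [np.inf, np.inf, np.inf])

        def resid(p):
            return one_site_total_curve(x, p[0], p[1], 0.0, p[2]) - y

        best, cov = _multistart_ls(resid, starts, bounds, x.size)
        B, K, bg = best.x
        ns, se_ns = 0.0, 0.0
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        se_B, se_K, se_bg = se
    else:
        starts = [(amp0, K, 0.0, bg0) for K in kd_grid]
        bounds = ([0, 1e-300, -np.inf, -np.inf], [np.inf, np.inf, np.inf, np.inf])

        def resid(p):
            return one_site_total_curve(x, *p) - y

        best, cov = _multistart_ls(resid, starts, bounds, x.size)
        B, K, ns, bg = best.x
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        se_B, se_K, se_ns, se_bg = se

    flags: list[str] = []
    if K > x.max():
        flags.append("not_saturated")
    return DoseResponseFit(
        model="one_site_total",
        params={
            "B_max": float(B),
            "K_D": float(K),
            "ns_slope": float(ns),
            "background": float(bg),
        },
        std_errors={
            "B_max": float(se_B),
            "K_D": float(se_K),
            "ns_slope": float(se_ns),
            "background": float(se_bg),
        },
        concentrations=x,
        residual_norm=float(np.sqrt(2 * best.cost)),
        flags=tuple(flags),
    )


def termination_efficiency(gel: GelQuantification) -> float:
    """Terminated band over total RNA: T / (T + RT), in [0, 1]."""
    total = gel.terminated_intensity + gel.readthrough_intensity
    return gel.terminated_intensity / total


def fit_t50(
    concentrations,
    efficiencies,
    n_boot: int = 1000,
    rng=None,
) -> DoseResponseFit:
    """Fit termination efficiency vs concentration; T_50 = half-effect conc.

    Replicate measurements are fitted pooled; ``std_errors`` carries the
    Jacobian-based SEs plus a seeded residual-bootstrap SE for T_50 under the
    key ``T_50_bootstrap``.  Flagged ``not_saturated`` when the fitted T_50
    exceeds the tested concentration range.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(efficiencies, dtype=float)
    if np.unique(x).size < 5:
        raise ValueError("need >= 5 distinct concentrations")
    if np.any((y < -1e-9) | (y > 1 + 1e-9)):
        raise ValueError("efficiencies must lie in [0, 1]")

    e_min0 = float(y[np.argmin(x)])
    e_max0 = float(y[np.argmax(x)])
    starts = [(e_min0, e_max0, K) for K in _kd_grid(x)]
    bounds = ([-np.inf, -np.inf, 1e-300], [np.inf, np.inf, np.inf])

    def resid_for(yy):
        def resid(p):
            return termination_curve(x, *p) - yy

        return resid

    best, cov = _multistart_ls(resid_for(y), starts, bounds, x.size)
    e_min, e_max, t50 = best.x
    se = np.sqrt(np.clip(np.diag(cov), 0, None))

    std_errors = {"e_min": float(se[0]), "e_max": float(se[1]), "T_50": float(se[2])}
    if n_boot > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        res = termination_curve(x, e_min, e_max, t50) - y
        t50_bs = []
        for _ in range(n_boot):
            yb = termination_curve(x, e_min, e_max, t50) + gen.choice(res, size=res.size)
            try:
                bb, _ = _multistart_ls(
                    resid_for(yb), [(e_min, e_max, t50)], bounds, x.size
                )
                t50_bs.append(bb.x[2])
            except FitConvergenceError:
                continue
        if len(t50_bs) >= 10:
            std_errors["T_50_bootstrap"] = float(np.std(t50_bs, ddof=1))

    flags: list[str] = []
    if t50 > x.max():
        flags.append("not_saturated")
    return DoseResponseFit(
        model="termination",
        params={"e_min": float(e_min), "e_max": float(e_max), "T_50": float(t50)},
        std_errors=std_errors,
        concentrations=x,
        residual_norm=float(np.sqrt(2 * best.cost)),
        flags=tuple(flags),
    )
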