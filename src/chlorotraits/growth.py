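"""Growth-rate prediction and measurement for lytic viruses.

A lytic virus growing on a constant host population multiplies in
discrete infection cycles: a free virion adsorbs (rate ``k*H`` at host
density ``H``), completes infection with probability ``s`` (specific
infectivity), waits a lysis delay ``mu_l``, and releases ``b_r`` progeny.
The long-run exponential growth rate ``lambda`` of the virus population
is the root of the Euler-Lotka characteristic equation

    1 = s * b_r * (k*H / (k*H + lambda)) * exp(-lambda * mu_l)

where the middle factor is the Laplace transform of the exponential
adsorption-waiting-time distribution and the last factor accounts for
the fixed lysis delay. The left side is per-capita lifetime reproduction
discounted at rate ``lambda``; the equation has a unique root
``lambda > -k*H`` whenever ``s*b_r > 0``, equal to zero exactly when
``s*b_r = 1``.

Observed growth rates come from log-linear fits to growth-assay titer
time series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

logger = logging.getLogger("chlorotraits.growth")

__all__ = [
    "GrowthPrediction",
    "ObservedGrowth",
    "characteristic_residual",
    "predict_growth_rate",
    "fit_observed_growth",
]


@dataclass
class GrowthPrediction:
    """Predicted exponential growth rate at a stated host density."""

    strain_id: str | None
    lambda_pred: float
    host_density: float
    inputs_used: dict
    converged: bool
    bracket: tuple[float, float] | None
    residual: float
    flags: list[str] = field(default_factory=list)


@dataclass
class ObservedGrowth:
    """Growth rate measured by log-linear regression on a growth assay."""

    strain_id: str | None
    lambda_obs: float
    ci_low: float
    ci_high: float
    n_points: int
    flags: list[str] = field(default_factory=list)


def characteristic_residual(lam, s, k, mu_l, b_r, host_density):
    """Residual f(lambda) of the characteristic equation (zero at the root)."""
    kH = k * host_density
    return s * b_r * kH / (kH + lam) * np.exp(-lam * mu_l) - 1.0


def _log_residual(lam, log_R0, kH, mu_l):
    # g = ln(s b_r) + ln(kH) - ln(kH + lam) - lam*mu; same root as f,
    # better conditioned because |f| = |expm1(g)| ~ |g| near the root.
    return log_R0 + np.log(kH) - np.log(kH + lam) - lam * mu_l


def predict_growth_rate(
    s: float,
    k: float,
    mu_l: float,
    b_r: float,
    host_density: float = 1e7,
    strain_id: str | None = None,
    residual_tol: float = 1e-9,
) -> GrowthPrediction:
    """Solve the Euler-Lotka characteristic equation for the growth rate.

    Parameters
    ----------
    s : specific infectivity, probability in [0, 1].
    k : adsorption constant, mL/h.
    mu_l : mean lysis time, h.
    b_r : burst size per releasing cell.
    host_density : host cells per mL at which growth is predicted.

    Returns
    -------
    GrowthPrediction with ``lambda_pred`` in 1/h. Negative rates
    (declining populations, ``s*b_r < 1``) are valid and bounded below
    by ``-k*host_density``. When no root exists (``s*b_r == 0`` or
    ``k == 0``) the prediction is flagged non-converged and the rate is
    NaN rather than a number.
    """
    if not (0.0 <= s <= 1.0):
        raise ValueError(f"specific infectivity s must be in [0, 1], got {s}")
    if k < 0 or b_r < 0:
        raise ValueError("k and b_r must be non-negative")
    if mu_l <= 0:
        raise ValueError(f"mean lysis time mu_l must be positive, got {mu_l}")
    if host_density <= 0:
        raise ValueError(f"host density must be positive, got {host_density}")

    inputs = {"s": s, "k": k, "mu_l": mu_l, "b_r": b_r}
    kH = k * host_density
    R0 = s * b_r
    if R0 <= 0 or kH <= 0:
        reason = "s*b_r=0" if R0 <= 0 else "k*H=0"
        return GrowthPrediction(
            strain_id, float("nan"), host_density, inputs, False, None,
            float("nan"), flags=[f"no_growth_solution:{reason}"],
        )
    if R0 == 1.0:
        return GrowthPrediction(
            strain_id, 0.0, host_density, inputs, True, (0.0, 0.0), 0.0
        )

    log_R0 = np.log(R0)
    g = lambda lam: _log_residual(lam, log_R0, kH, mu_l)

    if R0 > 1.0:
        # g(0) = ln R0 > 0; at the infinite-host limit ln(R0)/mu the
        # adsorption factor makes g negative, so this brackets the root.
        lo, hi = 0.0, log_R0 / mu_l
    else:
        # Declining population: root in (-kH, 0). Walk the lower edge
        # toward -kH until the residual turns positive.
        hi = 0.0
        eps = 0.5
        lo = -kH * (1.0 - eps)
        while g(lo) <= 0.0:
            eps *= 0.1
            lo = -kH * (1.0 - eps)
            if eps < 1e-300:  # pragma: no cover - unreachable for valid inputs
                break

    root = brentq(g, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)

    # Newton polish on g until the linear-scale residual meets tolerance.
    resid = np.expm1(g(root))
    for _ in range(100):
        if abs(resid) <= residual_tol:
            break
        gprime = -1.0 / (kH + root) - mu_l
        root = root - g(root) / gprime
        resid = np.expm1(g(root))

    converged = bool(abs(resid) <= residual_tol) and np.isfinite(root)
    return GrowthPrediction(
        strain_id, float(root), host_density, inputs, converged,
        (float(lo), float(hi)), float(resid),
    )


def fit_observed_growth(
    growth: pd.DataFrame,
    window: tuple[float, float] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    strain_id: str | None = None,
) -> ObservedGrowth:
    """Estimate the observed growth rate from a growth-assay time series.

    Fits ln(titer) ~ time by ordinary least squares over the configured
    exponential window (default: the full series) and attaches a
    percentile bootstrap CI obtained by resampling whole replicates.
    Non-positive titers inside the window are dropped with a flag; fewer
    than three usable distinct time points is an estimation failure.
    """
    flags: list[str] = []
    df = growth
    if window is not None:
        t0, t1 = window
        df = df[(df["time_h"] >= t0) & (df["time_h"] <= t1)]
    pos = df["pfu_per_ml"] > 0
    if (~pos).any():
        flags.append("nonpositive_titers_dropped")
    df = df[pos]
    n_points = int(len(df))
    if df["time_h"].nunique() < 3:
        flags.append("failed:insufficient_points")
        nan = float("nan")
        return ObservedGrowth(strain_id, nan, nan, nan, n_points, flags)

    t = df["time_h"].to_numpy(float)
    y = np.log(df["pfu_per_ml"].to_numpy(float))
    slope = _ols_slope(t, y)

    reps = df["replicate"].to_numpy()
    rep_ids = np.unique(reps)
    if n_boot > 0 and len(rep_ids) > 1:
        rng = np.random.default_rng(seed)
        groups = [(t[reps == rid], y[reps == rid]) for rid in rep_ids]
        samples = np.empty(n_boot)
        n_rep = len(groups)
        for b in range(n_boot):
            take = rng.integers(0, n_rep, n_rep)
            tb = np.concatenate([groups[i][0] for i in take])
            yb = np.concatenate([groups[i][1] for i in take])
            if np.unique(tb).size < 2:
                samples[b] = np.nan
                continue
            samples[b] = _ols_slope(tb, yb)
        ok = samples[np.isfinite(samples)]
        if ok.size >= max(10, 0.8 * n_boot):
            from .estimation import percentile_ci
            lo, hi = percentile_ci(ok, n_rep)
            lo, hi = min(lo, slope), max(hi, slope)
        else:
            flags.append("ci_unreliable")
            lo = hi = slope
    else:
        if n_boot > 0:
            flags.append("single_replicate_no_ci")
        lo = hi = slope
    return ObservedGrowth(strain_id, float(slope), float(lo), float(hi), n_points, flags)


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    tm = t - t.mean()
    return float(tm @ (y - y.mean()) / (tm @ tm))
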