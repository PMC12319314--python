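"""Life-history trait estimation from replicate-level assay data.

Estimates the nine traits of a lytic virus strain, each with a 95%
bootstrap confidence interval:

========  ==========================================  ==================
trait     meaning                                     source assay
========  ==========================================  ==================
a         attaching fraction of virions               adsorption
k         adsorption constant (mL/h)                  adsorption
d         depolarization probability                  depolarization
r         release probability                         one-step
mu_l      mean lysis time (h)                         one-step
sigma_l   SD of lysis time (h)                        one-step
b_d       burst size per depolarized cell             one-step
b_r       burst size per releasing cell (b_d / r)     one-step
s         specific infectivity (a * d * r)            composed
m         mortality rate (1/h)                        decay
p         persistent fraction                         decay
========  ==========================================  ==================

Confidence intervals are nonparametric percentile bootstrap intervals
obtained by resampling whole replicates, which respects the assays'
error structure; composite traits (s, b_r) are propagated through joint
bootstrap replicates rather than by interval arithmetic. Traits whose
interval is uninformative (spanning more than two orders of magnitude
for positive-scale traits, or more than 0.8 for probabilities) or whose
bootstrap refits mostly fail are flagged poorly resolved, so downstream
comparative analyses can exclude them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression, least_squares
from scipy.stats import norm, t as t_dist

from .synthetic import AssayDataset, lysis_cdf

logger = logging.getLogger("chlorotraits.estimation")

__all__ = [
    "TraitEstimate",
    "LifeHistoryProfile",
    "fit_adsorption",
    "estimate_depolarization",
    "fit_lysis_curve",
    "estimate_burst_sizes",
    "estimate_specific_infectivity",
    "fit_decay",
    "bootstrap_ci",
    "percentile_ci",
    "estimate_profile",
    "profiles_to_frame",
]

PROBABILITY_TRAITS = frozenset({"a", "d", "r", "s", "p"})
POSITIVE_TRAITS = frozenset({"k", "mu_l", "sigma_l", "b_d", "b_r", "m"})
TRAIT_NAMES = ("a", "k", "d", "r", "mu_l", "sigma_l", "b_d", "b_r", "s", "m", "p")

#: Poorly-resolved thresholds: CI spanning more than this ratio (positive
#: traits) or absolute width (probabilities) flags the trait.
CI_SPAN_RATIO = 100.0
CI_SPAN_PROB = 0.8
MAX_FAIL_FRAC = 0.2


@dataclass
class TraitEstimate:
    """Point estimate with a 95% CI for one life-history trait."""

    trait_name: str
    estimate: float
    ci_low: float
    ci_high: float
    n_boot: int = 0
    flags: list[str] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._clamp()

    def _clamp(self) -> None:
        if not np.isfinite(self.estimate):
            return
        lo, hi = (0.0, 1.0) if self.trait_name in PROBABILITY_TRAITS else (0.0, np.inf)
        self.estimate = float(np.clip(self.estimate, lo, hi))
        if np.isfinite(self.ci_low):
            self.ci_low = float(np.clip(min(self.ci_low, self.estimate), lo, hi))
        if np.isfinite(self.ci_high):
            self.ci_high = float(np.clip(max(self.ci_high, self.estimate), lo, hi))

    @property
    def poorly_resolved(self) -> bool:
        return any(f.startswith(("poorly_resolved", "missing", "failed")) for f in self.flags)


@dataclass
class LifeHistoryProfile:
    """All trait estimates for one strain, with poorly-resolved flags."""

    strain_id: str
    traits: dict[str, TraitEstimate]

    def __getitem__(self, name: str) -> TraitEstimate:
        return self.traits[name]

    @property
    def flagged_traits(self) -> list[str]:
        return [t for t, e in self.traits.items() if e.poorly_resolved]


def percentile_ci(samples: np.ndarray, n_units: int | None = None,
                  level: float = 0.95) -> tuple[float, float]:
    """Bootstrap percentile interval with a small-sample expansion.

    With few resampling units (replicates), raw percentile intervals are
    systematically narrow: the resampling distribution understates the
    sampling SD by about sqrt((n-1)/n), and normal-theory 2.5/97.5
    quantiles ignore the Student-t tail. Following the standard expanded
    percentile correction, the quantile levels are set from the t(n-1)
    critical value scaled by sqrt(n/(n-1)); for large n this reduces to
    the ordinary percentile interval.
    """
    alpha = 1.0 - level
    if n_units is not None and n_units > 1:
        z = t_dist.ppf(alpha / 2.0, n_units - 1) * np.sqrt(n_units / (n_units - 1.0))
        alpha = 2.0 * norm.cdf(z)
    lo, hi = np.percentile(samples, [100 * alpha / 2.0, 100 * (1.0 - alpha / 2.0)])
    return float(lo), float(hi)


def _point_only(name, value, flags=None, diagnostics=None) -> TraitEstimate:
    v = float(value)
    return TraitEstimate(name, v, v, v, n_boot=0, flags=list(flags or []),
                         diagnostics=dict(diagnostics or {}))


# ---------------------------------------------------------------------------
# Replicate-array extraction (fast path shared by point fits and bootstrap)

def _by_replicate(df: pd.DataFrame, cols: list[str]) -> list[tuple[np.ndarray, ...]]:
    out = []
    for _, g in df.groupby("replicate", sort=True):
        g = g.sort_values("time_h") if "time_h" in g.columns else g
        out.append(tuple(g[c].to_numpy(float) for c in cols))
    return out


def _pool(groups: list[tuple[np.ndarray, ...]]) -> tuple[np.ndarray, ...]:
    return tuple(np.concatenate(a) for a in zip(*groups))


def _resample(groups: list, rng: np.random.Generator) -> list:
    idx = rng.integers(0, len(groups), len(groups))
    return [groups[i] for i in idx]


# ---------------------------------------------------------------------------
# Adsorption: V(t) = v0 * [(1-a) + a*exp(-kappa*t)], kappa = k*H

def _log_or_weighted_resid(model_fn):
    """Residual builder: log-scale when all observations are positive,
    Poisson-weighted linear scale otherwise (no pseudocounts)."""

    def build(t, v):
        if np.all(v > 0):
            logv = np.log(v)

            def resid(theta):
                mu = np.maximum(model_fn(theta, t), 1e-300)
                return np.log(mu) - logv
        else:
            scale = max(float(np.mean(v)), 1.0)

            def resid(theta):
                mu = model_fn(theta, t)
                return (mu - v) / np.sqrt(np.maximum(mu, 1e-6 * scale))
        return resid

    return build


def _adsorption_model(theta, t):
    lnv0, a, kappa = theta
    return np.exp(lnv0) * ((1.0 - a) + a * np.exp(-kappa * t))


_adsorption_resid = _log_or_weighted_resid(_adsorption_model)


def _fit_adsorption_core(groups, H, x0=None):
    t, v = _pool(groups)
    vbar = float(np.mean(v))
    if vbar <= 0:
        raise RuntimeError("all-zero adsorption counts")
    if np.ptp(v) <= 1e-12 * vbar:
        # constant titers: no adsorption signal; a unidentifiable
        return {"k": 0.0, "a": np.nan, "lnv0": np.log(vbar),
                "theta": None, "flags": ["no_adsorption", "a_unidentifiable"]}
    if x0 is None:
        order = np.argsort(t)
        ts, vs = t[order], v[order]
        v00 = max(float(np.mean(vs[ts == ts[0]])), 1e-12)
        vend = max(float(np.mean(vs[ts == ts[-1]])), 1e-12)
        a0 = float(np.clip(1.0 - vend / v00, 1e-3, 1.0 - 1e-6))
        mid = ts[0] + 0.25 * (ts[-1] - ts[0])
        vmid = max(float(np.mean(vs[ts <= mid][-1:])), 1e-12)
        kappa0 = max(np.log(v00 / vmid) / max(mid - ts[0], 1e-6), 1e-3)
        x0 = np.array([np.log(v00), a0, kappa0])
    res = least_squares(
        _adsorption_resid(t, v), x0,
        bounds=([-np.inf, 0.0, 0.0], [np.inf, 1.0, np.inf]),
        method="trf", x_scale="jac",
    )
    lnv0, a, kappa = res.x
    return {"k": kappa / H, "a": float(a), "lnv0": float(lnv0),
            "theta": res.x, "flags": [] if res.success else ["fit_not_converged"],
            "residual_scale": float(np.sqrt(np.mean(res.fun ** 2)))}


def fit_adsorption(adsorption: pd.DataFrame) -> tuple[TraitEstimate, TraitEstimate]:
    """Fit the adsorption curve; returns estimates for k (mL/h) and a.

    Nonlinear least squares of ``V(t) = v0*[(1-a) + a*exp(-k*H*t)]`` on
    the log scale (Poisson-weighted linear scale when zero counts are
    present). When the data are a pure exponential the fitted a sits at
    1 and the model reduces to log-linear decay with slope -k*H.
    """
    if adsorption["time_h"].nunique() < 3:
        raise ValueError("adsorption fit needs >= 3 distinct time points")
    H = float(adsorption["host_density"].iloc[0])
    if H <= 0:
        raise ValueError("host density must be positive")
    groups = _by_replicate(adsorption, ["time_h", "free_pfu_per_ml"])
    try:
        fit = _fit_adsorption_core(groups, H)
    except RuntimeError as e:
        nan = float("nan")
        k = TraitEstimate("k", nan, nan, nan, flags=[f"failed:{e}"])
        a = TraitEstimate("a", nan, nan, nan, flags=[f"failed:{e}"])
        return k, a
    diag = {"residual_scale": fit.get("residual_scale", 0.0)}
    k = _point_only("k", fit["k"], fit["flags"], diag)
    a_flags = list(fit["flags"])
    if np.isnan(fit["a"]):
        a = TraitEstimate("a", float("nan"), float("nan"), float("nan"),
                          flags=a_flags + ["poorly_resolved"], diagnostics=diag)
    else:
        a = _point_only("a", fit["a"], a_flags, diag)
    return k, a


# ---------------------------------------------------------------------------
# Depolarization: Poisson MOI statistics

def _depolarization_core(totals, deps, moi):
    F = float(np.sum(deps)) / float(np.sum(totals))
    flags = []
    if F >= 1.0:
        d = 1.0
        flags.append("saturated")  # cannot invert 1 - exp(-d*MOI) at F = 1
    elif F <= 0.0:
        d = 0.0
    else:
        d = -np.log1p(-F) / moi
        if d > 1.0:
            flags.append("clamped")
    return {"d": float(np.clip(d, 0.0, 1.0)), "F": F, "flags": flags}


def estimate_depolarization(depolarization: pd.DataFrame) -> TraitEstimate:
    """Depolarization probability from pooled counts.

    Inverts the Poisson infection model ``F = 1 - exp(-d*MOI)`` at the
    pooled depolarized fraction; pooling is preferred over per-replicate
    means because counts may be small.
    """
    if (depolarization["cells_depolarized"] > depolarization["cells_total"]).any():
        raise ValueError("cells_depolarized exceeds cells_total")
    moi = float(depolarization["adsorbed_moi"].iloc[0])
    if moi <= 0:
        raise ValueError("adsorbed_moi must be positive")
    res = _depolarization_core(
        depolarization["cells_total"].to_numpy(float),
        depolarization["cells_depolarized"].to_numpy(float), moi)
    return _point_only("d", res["d"], res["flags"], {"pooled_fraction": res["F"]})


# ---------------------------------------------------------------------------
# One-step curve: cumulative release C(t) = r * Phi((t - mu_l) / sigma_l)

def _release_curves(groups):
    """Per-replicate cumulative release fraction and depolarized density.

    C(t) = (IC(t0) - IC(t)) / D, with infectious centers IC counting
    cells that have not yet lysed and D the measured depolarized-cell
    density (averaged over the replicate's time points).
    """
    ts, cs, Ds = [], [], []
    for t, ic, dep in groups:
        D = float(np.mean(dep))
        if D <= 0:
            continue
        ts.append(t)
        cs.append((ic[0] - ic) / D)
        Ds.append(D)
    if not ts:
        raise RuntimeError("no usable one-step replicates (zero depolarized density)")
    return np.concatenate(ts), np.concatenate(cs), float(np.mean(Ds))


def _fit_lysis_core(groups, x0=None, sigma_floor=None):
    t, c, D = _release_curves(groups)
    tu = np.unique(t)
    if sigma_floor is None:
        sigma_floor = 0.5 * float(np.median(np.diff(tu)))
    cbar = np.array([c[t == u].mean() for u in tu])
    iso = isotonic_regression(cbar).x
    r_iso = float(iso[-1])
    flags = []
    if r_iso <= 1e-3:
        return {"r": max(r_iso, 0.0), "mu_l": np.nan, "sigma_l": np.nan, "D": D,
                "theta": None, "flags": ["no_release", "mu_sigma_unidentifiable"]}
    if x0 is None:
        r0 = float(np.clip(r_iso, 1e-3, 1.0))
        half = iso >= 0.5 * r_iso
        mu0 = float(tu[half][0]) if half.any() else float(tu[-1])
        q25 = tu[iso >= 0.25 * r_iso]
        q75 = tu[iso >= 0.75 * r_iso]
        sig0 = (float(q75[0]) - float(q25[0])) / 1.349 if len(q25) and len(q75) else 1.0
        sig0 = float(np.clip(sig0, sigma_floor, tu[-1]))
        x0 = np.array([r0, mu0, sig0])

    def resid(theta):
        r, mu, sig = theta
        return r * lysis_cdf(t, mu, sig) - c

    res = least_squares(
        resid, x0,
        bounds=([0.0, 1e-6, sigma_floor], [1.0, 2.0 * tu[-1], tu[-1]]),
        method="trf", x_scale="jac",
    )
    r, mu, sig = res.x
    if lysis_cdf(np.array([tu[-1]]), mu, sig)[0] < 0.9:
        flags.append("truncated_curve")
    if not res.success:
        flags.append("fit_not_converged")
    return {"r": float(r), "mu_l": float(mu), "sigma_l": float(sig), "D": D,
            "theta": res.x, "flags": flags,
            "residual_scale": float(np.sqrt(np.mean(res.fun ** 2)))}


def fit_lysis_curve(
    onestep: pd.DataFrame,
) -> tuple[TraitEstimate, TraitEstimate, TraitEstimate]:
    """Fit the cumulative release curve; returns (mu_l, sigma_l, r).

    The plateau of the depolarized-cell-normalized release curve is the
    release probability r, its midpoint the mean lysis time and its
    spread the lysis-time SD. A monotone (isotonic) smooth of the pooled
    curve provides starting values and the plateau check, so noisy
    non-monotone curves cannot derail initialization; the fit itself
    runs on the raw replicate-level data. sigma_l is bounded below by
    half the median sampling interval to prevent degenerate zero-SD
    fits on coarse grids. The releasing-cell density r*D is reported in
    the diagnostics.
    """
    groups = _by_replicate(
        onestep, ["time_h", "infectious_centers_per_ml", "depolarized_cells_per_ml"])
    fit = _fit_lysis_core(groups)
    diag = {"depolarized_density": fit["D"],
            "releasing_density": fit["r"] * fit["D"] if np.isfinite(fit["r"]) else np.nan,
            "residual_scale": fit.get("residual_scale", np.nan)}
    r = _point_only("r", fit["r"], [f for f in fit["flags"] if f != "mu_sigma_unidentifiable"], diag)
    if np.isnan(fit["mu_l"]):
        nan = float("nan")
        mu = TraitEstimate("mu_l", nan, nan, nan, flags=["poorly_resolved", "no_release"])
        sig = TraitEstimate("sigma_l", nan, nan, nan, flags=["poorly_resolved", "no_release"])
    else:
        mu = _point_only("mu_l", fit["mu_l"], fit["flags"], diag)
        sig = _point_only("sigma_l", fit["sigma_l"], fit["flags"], diag)
    return mu, sig, r


# ---------------------------------------------------------------------------
# Burst sizes

def _burst_core(groups, r_hat):
    yields, Ds = [], []
    for t, free, dep in groups:
        D = float(np.mean(dep))
        if D <= 0:
            continue
        yields.append(free[-1] - free[0])  # final yield minus residual inoculum
        Ds.append(D)
    if not Ds:
        raise RuntimeError("no usable one-step replicates for burst size")
    num = float(np.mean(yields))
    flags = []
    if num < 0:
        num, flags = 0.0, ["negative_yield_clamped"]
    b_d = num / float(np.mean(Ds))
    if r_hat is None or not np.isfinite(r_hat) or r_hat <= 0:
        return {"b_d": b_d, "b_r": np.nan, "flags": flags + ["b_r_undefined_r_zero"]}
    return {"b_d": b_d, "b_r": b_d / r_hat, "flags": flags}


def estimate_burst_sizes(
    onestep: pd.DataFrame, r: TraitEstimate,
) -> tuple[TraitEstimate, TraitEstimate]:
    """Burst sizes from the final free-progeny yield.

    b_d = (final yield - residual inoculum) / depolarized-cell density,
    averaged over replicates; b_r = b_d / r. Requires the release curve
    to have plateaued by the final time point.
    """
    groups = _by_replicate(
        onestep, ["time_h", "free_pfu_per_ml", "depolarized_cells_per_ml"])
    res = _burst_core(groups, r.estimate)
    b_d = _point_only("b_d", res["b_d"], [f for f in res["flags"] if not f.startswith("b_r")])
    if np.isnan(res["b_r"]):
        b_r = TraitEstimate("b_r", float("nan"), float("nan"), float("nan"),
                            flags=res["flags"])
    else:
        b_r = _point_only("b_r", res["b_r"], res["flags"])
    return b_d, b_r


# ---------------------------------------------------------------------------
# Specific infectivity

def estimate_specific_infectivity(
    a: TraitEstimate, d: TraitEstimate, r: TraitEstimate,
) -> TraitEstimate:
    """Specific infectivity s = a*d*r.

    When joint bootstrap samples of the components are available in the
    diagnostics (as produced by estimate_profile), the CI is the
    percentile interval of the per-replicate products; naive endpoint
    multiplication is never used.
    """
    flags = []
    for comp in (a, d, r):
        if comp.poorly_resolved:
            flags.append(f"component_{comp.trait_name}_poorly_resolved")
    est = a.estimate * d.estimate * r.estimate
    samples = [comp.diagnostics.get("boot_samples") for comp in (a, d, r)]
    if all(s is not None for s in samples):
        prod = samples[0] * samples[1] * samples[2]
        ok = prod[np.isfinite(prod)]
        if ok.size:
            units = [comp.diagnostics.get("n_units") for comp in (a, d, r)]
            n_units = min(u for u in units if u) if all(units) else None
            lo, hi = percentile_ci(ok, n_units)
            return TraitEstimate("s", est, min(lo, est), max(hi, est),
                                 n_boot=int(ok.size), flags=flags)
    return _point_only("s", est, flags)


# ---------------------------------------------------------------------------
# Decay: S(t) = S0 * [p + (1-p)*exp(-m*t)]

def _decay_model(theta, t):
    lnS0, m, p = theta
    return np.exp(lnS0) * (p + (1.0 - p) * np.exp(-m * t))


_decay_resid = _log_or_weighted_resid(_decay_model)


def _loglinear_slope(t, v):
    pos = v > 0
    t, lv = t[pos], np.log(v[pos])
    if np.unique(t).size < 2:
        return 0.0
    tm = t - t.mean()
    return float(tm @ (lv - lv.mean()) / (tm @ tm))


def _fit_decay_core(groups, fix_p=None, x0=None):
    t, v = _pool(groups)
    vbar = float(np.mean(v))
    if vbar <= 0:
        raise RuntimeError("all-zero decay titers")
    if np.ptp(v) <= 1e-12 * vbar:
        # constant titers: no decay detected; convention (m, p) = (0, 1)
        return {"m": 0.0, "p": 1.0, "theta": None, "flags": ["no_decay_detected"]}
    if fix_p == 0.0:
        # single-exponential: exactly the log-linear regression solution
        slope = _loglinear_slope(t, v)
        return {"m": max(-slope, 0.0), "p": 0.0, "theta": None,
                "flags": ["p_fixed_zero"]}

    order = np.argsort(t)
    ts, vs = t[order], v[order]
    early = ts <= np.median(ts)
    m_fast = max(-_loglinear_slope(ts[early], vs[early]), 1e-6)
    first = max(float(np.mean(vs[ts == ts[0]])), 1e-12)
    last = float(np.mean(vs[ts == ts[-1]]))
    p_tail = float(np.clip(last / first, 0.0, 1.0))
    lnS0 = np.log(first)

    if fix_p is not None:
        pf = float(fix_p)

        def resid(theta):
            return _decay_resid(t, v)(np.array([theta[0], theta[1], pf]))

        starts = [np.array([lnS0, m_fast]), np.array([lnS0, 10 * m_fast])]
        best = None
        for s0 in starts:
            res = least_squares(resid, s0, bounds=([-np.inf, 0.0], [np.inf, np.inf]),
                                method="trf", x_scale="jac")
            if best is None or res.cost < best.cost - 1e-12 * best.cost:
                best = res
        return {"m": float(best.x[1]), "p": pf, "theta": None,
                "flags": [] if best.success else ["fit_not_converged"]}

    resid = _decay_resid(t, v)
    if x0 is not None:
        starts = [np.asarray(x0)]
    else:
        # biphasic least squares is multimodal: multi-start over
        # {fast slope, 10x} x {p = 0, p = tail ratio}, best SSE wins,
        # ties broken by smaller m
        starts = [np.array([lnS0, mm, pp])
                  for mm in (m_fast, 10.0 * m_fast) for pp in (0.0, p_tail)]
    best = None
    for s0 in starts:
        res = least_squares(resid, s0,
                            bounds=([-np.inf, 0.0, 0.0], [np.inf, np.inf, 1.0]),
                            method="trf", x_scale="jac")
        if best is None:
            best = res
        elif res.cost < best.cost * (1 - 1e-12):
            best = res
        elif abs(res.cost - best.cost) <= 1e-12 * max(best.cost, 1e-300) \
                and res.x[1] < best.x[1]:
            best = res
    lnS0, m, p = best.x
    return {"m": float(m), "p": float(p), "theta": best.x,
            "flags": [] if best.success else ["fit_not_converged"],
            "residual_scale": float(np.sqrt(np.mean(best.fun ** 2)))}


def fit_decay(
    decay: pd.DataFrame, fix_p: float | None = None,
) -> tuple[TraitEstimate, TraitEstimate]:
    """Fit biphasic decay; returns (m, p).

    Nonlinear least squares on log titer of
    ``S(t) = S0*[p + (1-p)*exp(-m*t)]`` with multi-start initialization.
    Constant titers return (m, p) = (0, 1) flagged "no decay detected".
    With ``fix_p=0`` the model is a single exponential and the solution
    is exactly the log-linear regression slope.
    """
    if decay["time_h"].nunique() < 4:
        raise ValueError("decay fit needs >= 4 distinct time points")
    groups = _by_replicate(decay, ["time_h", "pfu_per_ml"])
    try:
        fit = _fit_decay_core(groups, fix_p=fix_p)
    except RuntimeError as e:
        nan = float("nan")
        return (TraitEstimate("m", nan, nan, nan, flags=[f"failed:{e}"]),
                TraitEstimate("p", nan, nan, nan, flags=[f"failed:{e}"]))
    diag = {"residual_scale": fit.get("residual_scale", np.nan)}
    return (_point_only("m", fit["m"], fit["flags"], diag),
            _point_only("p", fit["p"], fit["flags"], diag))


# ---------------------------------------------------------------------------
# Bootstrap

def bootstrap_ci(
    fit, rows: pd.DataFrame, n_boot: int = 1000, seed: int = 0,
) -> tuple[float, float, dict]:
    """Percentile 95% CI by resampling whole replicates.

    ``fit`` maps a data frame (same schema as ``rows``) to a scalar.
    Returns ``(ci_low, ci_high, diagnostics)``; diagnostics carry the
    bootstrap samples, the failure fraction, and whether the interval
    had to be widened to contain the original point estimate.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    estimate = float(fit(rows))
    rep_ids = rows["replicate"].unique()
    blocks = {rid: rows[rows["replicate"] == rid] for rid in rep_ids}
    rng = np.random.default_rng(seed)
    samples = np.full(n_boot, np.nan)
    for b in range(n_boot):
        take = rng.choice(rep_ids, size=len(rep_ids), replace=True)
        parts = []
        for j, rid in enumerate(take):
            blk = blocks[rid].copy()
            blk["replicate"] = j  # relabel so duplicated blocks stay distinct
            parts.append(blk)
        try:
            samples[b] = float(fit(pd.concat(parts, ignore_index=True)))
        except Exception:
            pass
    ok = samples[np.isfinite(samples)]
    fail_frac = 1.0 - ok.size / n_boot
    diag = {"boot_samples": samples, "fail_frac": fail_frac, "widened": False,
            "n_units": len(rep_ids)}
    flags = []
    if fail_frac > MAX_FAIL_FRAC or ok.size == 0:
        flags.append("ci_unreliable")
    if ok.size == 0:
        return estimate, estimate, {**diag, "flags": flags}
    lo, hi = percentile_ci(ok, len(rep_ids))
    if estimate < lo or estimate > hi:
        diag["widened"] = True
        flags.append("interval_widened_to_contain_estimate")
        lo, hi = min(lo, estimate), max(hi, estimate)
    diag["flags"] = flags
    return float(lo), float(hi), diag


# ---------------------------------------------------------------------------
# Full-profile orchestration

def _safe(core, *args, **kwargs):
    try:
        return core(*args, **kwargs)
    except Exception:
        return None


def estimate_profile(
    dataset: AssayDataset, n_boot: int = 1000, seed: int = 0,
) -> LifeHistoryProfile:
    """Estimate all traits of one strain, with joint bootstrap CIs.

    Runs every estimator on the available assays, then resamples whole
    replicates (independently per assay) ``n_boot`` times and refits,
    warm-starting each refit at the original solution. Composite traits
    (s = a*d*r, b_r = b_d/r) are recomputed inside each bootstrap
    replicate, so their intervals reflect the joint uncertainty.
    Per-trait failures never abort the profile; they flag the trait.
    """
    nan = float("nan")
    point: dict[str, float] = {name: nan for name in TRAIT_NAMES}
    flags: dict[str, list[str]] = {name: [] for name in TRAIT_NAMES}
    diags: dict[str, dict] = {name: {} for name in TRAIT_NAMES}

    def missing(names, why):
        for nm in names:
            flags[nm].append(f"missing:{why}")

    # --- point estimates ---------------------------------------------------
    ads = dataset.adsorption
    ads_groups, H = None, None
    if ads is None or len(ads) == 0:
        missing(("a", "k"), "no_adsorption_data")
    else:
        H = float(ads["host_density"].iloc[0])
        ads_groups = _by_replicate(ads, ["time_h", "free_pfu_per_ml"])
        fit = _safe(_fit_adsorption_core, ads_groups, H)
        if fit is None:
            missing(("a", "k"), "adsorption_fit_failed")
        else:
            point["k"], point["a"] = fit["k"], fit["a"]
            flags["k"] += fit["flags"]
            flags["a"] += fit["flags"]
            if np.isnan(fit["a"]):
                flags["a"].append("poorly_resolved")
            diags["k"]["theta"] = diags["a"]["theta"] = fit["theta"]

    dep = dataset.depolarization
    moi = None
    if dep is None or len(dep) == 0:
        missing(("d",), "no_depolarization_data")
        dep_groups = None
    else:
        moi = float(dep["adsorbed_moi"].iloc[0])
        dep_groups = [(np.atleast_1d(t), np.atleast_1d(c)) for t, c in _by_replicate(
            dep, ["cells_total", "cells_depolarized"])]
        res = _depolarization_core(
            np.concatenate([g[0] for g in dep_groups]),
            np.concatenate([g[1] for g in dep_groups]), moi)
        point["d"] = res["d"]
        flags["d"] += res["flags"]

    one = dataset.onestep
    lys_groups = burst_groups = None
    if one is None or len(one) == 0:
        missing(("r", "mu_l", "sigma_l", "b_d", "b_r"), "no_onestep_data")
    else:
        lys_groups = _by_replicate(
            one, ["time_h", "infectious_centers_per_ml", "depolarized_cells_per_ml"])
        burst_groups = _by_replicate(
            one, ["time_h", "free_pfu_per_ml", "depolarized_cells_per_ml"])
        lfit = _safe(_fit_lysis_core, lys_groups)
        if lfit is None:
            missing(("r", "mu_l", "sigma_l"), "lysis_fit_failed")
        else:
            point["r"], point["mu_l"], point["sigma_l"] = lfit["r"], lfit["mu_l"], lfit["sigma_l"]
            for nm in ("r", "mu_l", "sigma_l"):
                flags[nm] += [f for f in lfit["flags"] if f != "mu_sigma_unidentifiable"]
            if np.isnan(lfit["mu_l"]):
                flags["mu_l"].append("poorly_resolved")
                flags["sigma_l"].append("poorly_resolved")
            diags["mu_l"]["theta"] = lfit["theta"]
            diags["r"]["releasing_density"] = lfit["r"] * lfit["D"]
        bfit = _safe(_burst_core, burst_groups, point["r"])
        if bfit is None:
            missing(("b_d", "b_r"), "burst_fit_failed")
        else:
            point["b_d"], point["b_r"] = bfit["b_d"], bfit["b_r"]
            flags["b_d"] += [f for f in bfit["flags"] if not f.startswith("b_r")]
            flags["b_r"] += bfit["flags"]

    if np.isnan(point["a"]) or np.isnan(point["d"]) or np.isnan(point["r"]):
        flags["s"].append("missing:component_unavailable")
    else:
        point["s"] = point["a"] * point["d"] * point["r"]

    dec = dataset.decay
    dec_groups = None
    if dec is None or len(dec) == 0:
        missing(("m", "p"), "no_decay_data")
    else:
        dec_groups = _by_replicate(dec, ["time_h", "pfu_per_ml"])
        dfit = _safe(_fit_decay_core, dec_groups)
        if dfit is None:
            missing(("m", "p"), "decay_fit_failed")
        else:
            point["m"], point["p"] = dfit["m"], dfit["p"]
            flags["m"] += dfit["flags"]
            flags["p"] += dfit["flags"]
            diags["m"]["theta"] = dfit["theta"]

    # --- bootstrap ---------------------------------------------------------
    samples = {name: np.full(n_boot, np.nan) for name in TRAIT_NAMES}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        ads_x0 = diags["k"].get("theta")
        lys_x0 = diags["mu_l"].get("theta")
        dec_x0 = diags["m"].get("theta")
        for b in range(n_boot):
            if ads_groups is not None:
                fit = _safe(_fit_adsorption_core, _resample(ads_groups, rng), H,
                            x0=ads_x0)
                if fit is not None:
                    samples["k"][b] = fit["k"]
                    samples["a"][b] = fit["a"]
            if dep_groups is not None:
                g = _resample(dep_groups, rng)
                res = _depolarization_core(
                    np.concatenate([x[0] for x in g]),
                    np.concatenate([x[1] for x in g]), moi)
                samples["d"][b] = res["d"]
            if lys_groups is not None:
                idx = rng.integers(0, len(lys_groups), len(lys_groups))
                lfit = _safe(_fit_lysis_core, [lys_groups[i] for i in idx], x0=lys_x0)
                if lfit is not None:
                    samples["r"][b] = lfit["r"]
                    samples["mu_l"][b] = lfit["mu_l"]
                    samples["sigma_l"][b] = lfit["sigma_l"]
                    bfit = _safe(_burst_core, [burst_groups[i] for i in idx], lfit["r"])
                    if bfit is not None:
                        samples["b_d"][b] = bfit["b_d"]
                        samples["b_r"][b] = bfit["b_r"]
            if dec_groups is not None:
                dfit = _safe(_fit_decay_core, _resample(dec_groups, rng), x0=dec_x0)
                if dfit is not None:
                    samples["m"][b] = dfit["m"]
                    samples["p"][b] = dfit["p"]
        samples["s"] = samples["a"] * samples["d"] * samples["r"]

    # --- assemble ----------------------------------------------------------
    unit_counts = {
        "a": ads_groups, "k": ads_groups, "d": dep_groups,
        "r": lys_groups, "mu_l": lys_groups, "sigma_l": lys_groups,
        "b_d": lys_groups, "b_r": lys_groups, "m": dec_groups, "p": dec_groups,
    }
    n_units = {name: (len(g) if g is not None else None)
               for name, g in unit_counts.items()}
    s_units = [n_units[c] for c in ("a", "d", "r")]
    n_units["s"] = min(u for u in s_units if u) if all(s_units) else None

    traits: dict[str, TraitEstimate] = {}
    for name in TRAIT_NAMES:
        est = point[name]
        fl = list(flags[name])
        sm = samples[name]
        ok = sm[np.isfinite(sm)]
        if not np.isfinite(est):
            traits[name] = TraitEstimate(name, nan, nan, nan, n_boot=n_boot,
                                         flags=fl or ["missing"], diagnostics=diags[name])
            continue
        if n_boot > 0 and ok.size > 0:
            fail_frac = 1.0 - ok.size / n_boot
            lo, hi = percentile_ci(ok, n_units[name])
            if est < lo or est > hi:
                fl.append("interval_widened_to_contain_estimate")
                lo, hi = min(lo, est), max(hi, est)
            if fail_frac > MAX_FAIL_FRAC:
                fl.append("poorly_resolved:refit_failures")
            if name in PROBABILITY_TRAITS:
                if (min(hi, 1.0) - max(lo, 0.0)) > CI_SPAN_PROB:
                    fl.append("poorly_resolved:wide_ci")
            elif hi > 0 and hi / max(lo, hi * 1e-6) > CI_SPAN_RATIO:
                # covers lo <= 0: an interval reaching 0 spans unbounded ratio
                fl.append("poorly_resolved:wide_ci")
            d = dict(diags[name])
            d["boot_samples"] = sm
            d["fail_frac"] = fail_frac
            d["n_units"] = n_units[name]
            traits[name] = TraitEstimate(name, est, float(lo), float(hi),
                                         n_boot=n_boot, flags=fl, diagnostics=d)
        else:
            traits[name] = TraitEstimate(name, est, est, est, n_boot=0,
                                         flags=fl, diagnostics=diags[name])
    return LifeHistoryProfile(strain_id=dataset.strain_id, traits=traits)


def profiles_to_frame(
    profiles: list[LifeHistoryProfile], drop_flagged: bool = False,
) -> pd.DataFrame:
    """Wide table of trait estimates and CI bounds, one row per strain.

    With ``drop_flagged`` poorly resolved estimates become NaN, matching
    the convention of excluding them from comparative analyses.
    """
    rows = []
    for prof in profiles:
        row: dict = {"strain_id": prof.strain_id}
        for name, est in prof.traits.items():
            value = est.estimate
            if drop_flagged and est.poorly_resolved:
                value = np.nan
            row[name] = value
            row[f"{name}_lo"] = est.ci_low
            row[f"{name}_hi"] = est.ci_high
            row[f"{name}_flags"] = ";".join(est.flags)
        rows.append(row)
    return pd.DataFrame(rows)
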