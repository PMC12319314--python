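"""Comparative statistics across a panel of virus strains.

Implements the panel-level analyses run on estimated life-history
profiles: fold-ranges of trait variation, partitioning of trait variance
by type host (permutation-tested R-squared), rank correlation of
predicted versus observed growth rates, all-subsets OLS regression with
an AIC consensus, and CI-breadth-weighted trait correlations used to
test life-history trade-off hypotheses within species.

Uncertainty enters these analyses only through weights (inverse CI
breadth); point estimates feed the statistics, and poorly resolved
estimates are expected to arrive as NaN and are dropped pairwise.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("chlorotraits.stats")

__all__ = [
    "VariancePartition",
    "WeightedCorrelation",
    "ModelSelectionTable",
    "fold_range",
    "host_variance_partition",
    "correlate_predicted_observed",
    "aic_subset_selection",
    "weighted_correlation",
    "tradeoff_tests",
]

#: Trait pairs probed by the trade-off tests: faster growth may trade
#: against survival, larger bursts against later lysis, and burst size
#: may scale with genome size.
TRADEOFF_PAIRS = (
    ("growth_rate", "m"),
    ("b_r", "mu_l"),
    ("b_r", "genome_size"),
)

#: Variables log-transformed before correlation (rates and sizes span
#: orders of magnitude; probabilities and signed growth rates do not).
LOG_SCALE_VARS = frozenset({"k", "m", "b_d", "b_r", "mu_l", "sigma_l", "genome_size"})

MIN_CORRELATION_N = 5  # trade-off correlations are only tested at n >= 5


@dataclass
class VariancePartition:
    """Share of between-strain trait variance explained by a grouping."""

    trait_name: str
    r_squared: float
    p_value: float
    groups: int
    n: int
    flags: list[str] = field(default_factory=list)


@dataclass
class WeightedCorrelation:
    """CI-breadth-weighted Pearson correlation between two traits."""

    trait_x: str
    trait_y: str
    r_weighted: float
    p_value: float
    weights: np.ndarray
    species: str | None
    n: int
    tested: bool = True
    note: str = ""


@dataclass
class ModelSelectionTable:
    """All-subsets OLS fits with AIC and the delta-AIC <= 2 consensus."""

    table: pd.DataFrame
    consensus_predictors: set[str]
    n_strains: int


# ---------------------------------------------------------------------------

def fold_range(estimates) -> float:
    """Max/min fold-range of a trait across strains (NaNs dropped)."""
    x = np.asarray(estimates, float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("fold_range needs >= 2 non-missing values")
    if np.any(x <= 0):
        raise ValueError("fold_range undefined for non-positive values")
    return float(x.max() / x.min())


# ---------------------------------------------------------------------------

def _r_squared_between(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    grand = values.mean()
    sst = float(((values - grand) ** 2).sum())
    counts = np.bincount(codes, minlength=n_groups)
    sums = np.bincount(codes, weights=values, minlength=n_groups)
    nz = counts > 0
    ssb = float((counts[nz] * (sums[nz] / counts[nz] - grand) ** 2).sum())
    return ssb / sst


def host_variance_partition(
    profiles: pd.DataFrame,
    trait_name: str,
    grouping: dict | pd.Series | None = None,
    n_perm: int = 9999,
    seed: int = 0,
) -> VariancePartition:
    """Partition trait variance by type host (or any categorical factor).

    R-squared is the between-group over total sum of squares of the
    trait point estimates; the P-value is a permutation test shuffling
    group labels, ``P = (#{permuted R2 >= observed} + 1)/(n_perm + 1)``.

    ``profiles`` is a wide per-strain table (see ``profiles_to_frame``);
    ``grouping`` maps strain_id to group, defaulting to the table's
    ``type_host`` column.
    """
    df = profiles
    if grouping is None:
        if "type_host" not in df.columns:
            raise ValueError("no grouping given and no 'type_host' column present")
        labels = df["type_host"]
    else:
        labels = df["strain_id"].map(dict(grouping) if not isinstance(grouping, dict) else grouping)
    values = df[trait_name].to_numpy(float)
    keep = np.isfinite(values) & labels.notna().to_numpy()
    values, labels = values[keep], labels[keep]
    codes, uniques = pd.factorize(labels)
    n_groups = len(uniques)
    if n_groups < 2:
        raise ValueError("variance partition needs >= 2 groups")
    if len(values) < 3:
        raise ValueError("variance partition needs >= 3 strains")
    if np.ptp(values) == 0:
        return VariancePartition(trait_name, float("nan"), float("nan"),
                                 n_groups, len(values), flags=["zero_total_variance"])
    r2 = _r_squared_between(values, codes, n_groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _r_squared_between(values, perm, n_groups) >= r2 - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return VariancePartition(trait_name, float(r2), float(p), n_groups, len(values))


# ---------------------------------------------------------------------------

def correlate_predicted_observed(predicted, observed) -> tuple[float, float]:
    """Spearman rank correlation between predicted and observed growth.

    Ties get average ranks. The two-sided P-value is exact (full
    enumeration of pairings) for n <= 10 and the asymptotic
    t-approximation otherwise.
    """
    x = np.asarray(predicted, float)
    y = np.asarray(observed, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 5:
        raise ValueError("correlate_predicted_observed needs >= 5 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 10:
        p = _exact_pairing_pvalue(rx, ry, rho)
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return rho, p


def _exact_pairing_pvalue(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided P by enumerating all n! pairings of the ranks.

    The permutation statistic rho is an affine function of the dot
    product sum(rx[perm]*ry), so only dot products are enumerated.
    """
    n = len(rx)
    sx = rx.std()
    sy = ry.std()
    mean_term = n * rx.mean() * ry.mean()
    denom = n * sx * sy
    thresh = abs(rho_obs) - 1e-12
    count = 0
    total = 0
    it = itertools.permutations(range(n))
    while True:
        chunk = np.array(list(itertools.islice(it, 20000)), dtype=np.intp)
        if chunk.size == 0:
            break
        dots = rx[chunk] @ ry
        rhos = (dots - mean_term) / denom
        count += int((np.abs(rhos) >= thresh).sum())
        total += len(chunk)
    return count / total


# ---------------------------------------------------------------------------

def aic_subset_selection(
    lambda_obs, predictors: pd.DataFrame, delta_threshold: float = 2.0,
) -> ModelSelectionTable:
    """All-subsets OLS of observed growth on trait predictors, with AIC.

    Every subset of the predictor columns (2^p models including the
    intercept-only model) is fit by OLS on complete cases;
    ``AIC = n*ln(RSS/n) + 2K`` with K counting the coefficients
    (intercept included) plus one for the error variance. The consensus
    set is the intersection of predictors over all models within
    ``delta_threshold`` AIC units of the best; rank-deficient subsets
    are flagged and excluded from the consensus.
    """
    y = np.asarray(lambda_obs, float)
    X = predictors.astype(float)
    keep = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
    y, X = y[keep], X.loc[keep]
    n = len(y)
    names = list(X.columns)
    max_k = len(names) + 2
    if n < max_k + 2:
        raise ValueError(
            f"aic_subset_selection needs n >= {max_k + 2} complete cases, got {n}")

    rows = []
    for size in range(len(names) + 1):
        for subset in itertools.combinations(names, size):
            M = np.column_stack([np.ones(n)] + [X[c].to_numpy() for c in subset])
            flagged = np.linalg.matrix_rank(M) < M.shape[1]
            if flagged:
                coef = np.full(M.shape[1], np.nan)
                rss = aic = np.nan
                logger.warning("collinear predictor subset %s excluded from consensus",
                               subset)
            else:
                coef, _, _, _ = np.linalg.lstsq(M, y, rcond=None)
                resid = y - M @ coef
                rss = float(resid @ resid)
                K = M.shape[1] + 1
                with np.errstate(divide="ignore"):
                    aic = n * np.log(rss / n) + 2 * K
            rows.append({
                "predictors": subset,
                "coefficients": coef,
                "rss": rss,
                "aic": aic,
                "flagged_collinear": flagged,
            })
    table = pd.DataFrame(rows)
    best = table.loc[~table["flagged_collinear"], "aic"].min()
    table["delta_aic"] = table["aic"] - best
    in_band = table[(~table["flagged_collinear"]) & (table["delta_aic"] <= delta_threshold)]
    consensus: set[str] = set(names)
    for subset in in_band["predictors"]:
        consensus &= set(subset)
    return ModelSelectionTable(table=table, consensus_predictors=consensus, n_strains=n)


# ---------------------------------------------------------------------------

def _weighted_pearson(x, y, w) -> float:
    w = w / w.sum()
    mx = float(w @ x)
    my = float(w @ y)
    cxy = float(w @ ((x - mx) * (y - my)))
    cx = float(w @ ((x - mx) ** 2))
    cy = float(w @ ((y - my) ** 2))
    return cxy / np.sqrt(cx * cy)


def weighted_correlation(
    x, y, ci_breadth_x, ci_breadth_y,
    species: str | None = None,
    trait_x: str = "x", trait_y: str = "y",
    n_perm: int = 9999, seed: int = 0,
    rule: str = "product",
) -> WeightedCorrelation:
    """Pearson correlation weighted by 95% CI breadth.

    Each point's weight is the inverse of the product of its two CI
    breadths (``rule="product"``, default) or of their sum
    (``rule="sum"``), normalized to sum to one, so strains uncertain in
    either coordinate are down-weighted. The two-sided P-value is a
    weight-preserving permutation test: y values travel with their own
    breadths while x values keep theirs, and weights are recomputed for
    each pairing. Refuses n < 5 (correlations are only tested within
    species where n >= 5).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    bx = np.asarray(ci_breadth_x, float)
    by = np.asarray(ci_breadth_y, float)
    keep = np.isfinite(x) & np.isfinite(y) & np.isfinite(bx) & np.isfinite(by)
    x, y, bx, by = x[keep], y[keep], bx[keep], by[keep]
    n = x.size
    if n < MIN_CORRELATION_N:
        raise ValueError(
            f"weighted_correlation requires n >= {MIN_CORRELATION_N} "
            f"(correlations are only tested where n >= 5); got n = {n}")
    if np.any(bx <= 0) or np.any(by <= 0):
        raise ValueError("CI breadths must be strictly positive")
    if rule not in ("product", "sum"):
        raise ValueError(f"unknown weight rule '{rule}'")

    def weights(bx_, by_):
        w = 1.0 / (bx_ * by_) if rule == "product" else 1.0 / (bx_ + by_)
        return w / w.sum()

    w = weights(bx, by)
    r_obs = _weighted_pearson(x, y, w)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = _weighted_pearson(x, y[perm], weights(bx, by[perm]))
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return WeightedCorrelation(trait_x, trait_y, float(r_obs), float(p),
                               w, species, n)


# ---------------------------------------------------------------------------

def _maybe_log(values, lo, hi, name):
    """Log-transform a rate/size variable and its CI bounds; breadth follows."""
    if name not in LOG_SCALE_VARS:
        return values, np.maximum(hi - lo, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.log(values)
        breadth = np.log(hi) - np.log(lo)
    v[~np.isfinite(v)] = np.nan
    return v, breadth


def tradeoff_tests(
    profiles: pd.DataFrame,
    genome_sizes: pd.Series | dict | None = None,
    species_labels: pd.Series | dict | None = None,
    growth_rates: pd.DataFrame | None = None,
    n_perm: int = 9999,
    seed: int = 0,
    rule: str = "product",
) -> list[WeightedCorrelation]:
    """Test the hypothesized life-history trade-offs within each species.

    Runs CI-breadth-weighted correlations for growth rate vs mortality,
    burst size vs lysis time, and burst size vs genome size, within
    every species with n >= 5 complete cases for the pair; smaller
    species are reported as not tested. Rates and sizes are correlated
    on the log scale (their CI breadths become log-ratio breadths);
    genome sizes carry no CI and get unit breadth, and signed growth
    rates stay on the natural scale.

    ``profiles`` is the wide per-strain table; ``growth_rates`` is an
    optional frame with columns strain_id, lambda_obs, lambda_lo,
    lambda_hi (without it the growth-vs-mortality pair is skipped).
    """
    df = profiles.copy()
    if species_labels is not None:
        mapping = species_labels if isinstance(species_labels, dict) else dict(species_labels)
        df["species"] = df["strain_id"].map(mapping)
    if "species" not in df.columns:
        raise ValueError("species labels are required for within-species tests")
    if genome_sizes is not None:
        mapping = genome_sizes if isinstance(genome_sizes, dict) else dict(genome_sizes)
        df["genome_size"] = df["strain_id"].map(mapping)
    if growth_rates is not None:
        g = growth_rates.set_index("strain_id")
        df["growth_rate"] = df["strain_id"].map(g["lambda_obs"])
        df["growth_rate_lo"] = df["strain_id"].map(g["lambda_lo"])
        df["growth_rate_hi"] = df["strain_id"].map(g["lambda_hi"])

    def column(sub: pd.DataFrame, name: str):
        if name not in sub.columns:
            return None, None
        vals = sub[name].to_numpy(float)
        if f"{name}_lo" in sub.columns:
            lo = sub[f"{name}_lo"].to_numpy(float)
            hi = sub[f"{name}_hi"].to_numpy(float)
        else:  # no CI available (e.g. genome size): unit breadth
            lo = vals
            hi = vals + 1.0 if name not in LOG_SCALE_VARS else vals * np.e
        v, breadth = _maybe_log(vals, lo, hi, name)
        # degenerate (zero) breadths would produce infinite weights
        pos = breadth[np.isfinite(breadth) & (breadth > 0)]
        floor = 1e-6 * (np.median(pos) if pos.size else 1.0) + 1e-12
        return v, np.maximum(breadth, floor)

    results: list[WeightedCorrelation] = []
    rng = np.random.default_rng(seed)
    for species, sub in df.groupby("species", sort=True):
        for trait_x, trait_y in TRADEOFF_PAIRS:
            vx, bx = column(sub, trait_x)
            vy, by = column(sub, trait_y)
            if vx is None or vy is None:
                results.append(WeightedCorrelation(
                    trait_x, trait_y, float("nan"), float("nan"), np.array([]),
                    species, 0, tested=False, note="variable unavailable"))
                continue
            keep = np.isfinite(vx) & np.isfinite(vy)
            if keep.sum() < MIN_CORRELATION_N:
                results.append(WeightedCorrelation(
                    trait_x, trait_y, float("nan"), float("nan"), np.array([]),
                    species, int(keep.sum()), tested=False,
                    note=f"n < {MIN_CORRELATION_N}"))
                continue
            res = weighted_correlation(
                vx[keep], vy[keep], bx[keep], by[keep], species=species,
                trait_x=trait_x, trait_y=trait_y, n_perm=n_perm,
                seed=int(rng.integers(0, 2**31 - 1)), rule=rule)
            results.append(res)
    return results
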