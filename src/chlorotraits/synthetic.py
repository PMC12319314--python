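"""Synthetic assay-panel generator with known ground-truth life histories.

Emulates the five assay types used to measure lytic-virus life-history
traits, so the estimation pipeline can be validated against known truth:

* adsorption assay - free-virus titer decays exponentially toward a
  non-adsorbing plateau: ``V(t) = v0 * [(1-a) + a*exp(-k*H*t)]``;
* depolarization assay - depolarized cells out of total, with Poisson
  multiplicity-of-infection statistics: fraction ``1 - exp(-d*MOI)``;
* one-step growth assay - infectious centers decline and free progeny
  accumulate as releasing cells lyse, lysis times normal
  ``(mu_l, sigma_l)``, a fraction ``r`` of depolarized cells release
  ``b_r`` progeny each;
* decay (survival) assay - biphasic decay with a persistent fraction:
  ``S(t) = v0 * [p + (1-p)*exp(-m*t)]``;
* growth assay - exponential titer growth at a supplied rate.

Counting noise follows plaque-assay practice: each observation is scored
at the dilution giving roughly ``count_target`` plaques (or cells), so
counts are Poisson with that mean and the reported titer has relative
error ``1/sqrt(count_target)``. Titers in the growth assay carry
multiplicative lognormal noise instead, centered on the log scale so
log-linear fits are unbiased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger("chlorotraits.synthetic")

__all__ = [
    "TrueTraits",
    "AssayDesign",
    "AssayDataset",
    "DEFAULT_TRAIT_RANGES",
    "lysis_cdf",
    "draw_true_traits",
    "simulate_adsorption_assay",
    "simulate_one_step_assay",
    "simulate_decay_assay",
    "simulate_growth_assay",
    "build_panel",
]

#: Trait names drawn log-uniformly (rates and burst sizes span orders of
#: magnitude between strains); all others are drawn uniformly.
LOG_UNIFORM_TRAITS = frozenset({"k", "b_r", "m"})
PROBABILITY_TRAITS = frozenset({"a", "d", "r", "p"})

#: Default per-trait (low, high) bounds for synthetic panels. Chosen to
#: span trait variation of the scale reported for chlorovirus panels
#: (up to 77-fold for burst size, narrower for lysis time and decay)
#: while keeping every trait identifiable from the default assay design.
DEFAULT_TRAIT_RANGES: dict[str, tuple[float, float]] = {
    "a": (0.60, 0.95),
    "k": (5e-9, 7.7e-8),      # mL/h
    "d": (0.20, 0.90),
    "r": (0.20, 0.90),
    "mu_l": (6.0, 16.0),      # h
    "sigma_l": (1.0, 3.0),    # h
    "b_r": (10.0, 770.0),     # virions per releasing cell
    "m": (0.005, 0.05),       # 1/h
    "p": (0.02, 0.20),
}

_TRAIT_ORDER = ("a", "k", "d", "r", "mu_l", "sigma_l", "b_r", "m", "p")


@dataclass
class TrueTraits:
    """Ground-truth life-history traits of one simulated strain.

    ``b_d`` (burst per depolarized cell) and ``s`` (specific
    infectivity) are derived: ``b_d = r*b_r`` and ``s = a*d*r``.
    """

    strain_id: str
    a: float        # fraction of virions capable of attaching
    k: float        # adsorption constant, mL/h
    d: float        # depolarization probability
    r: float        # release probability
    mu_l: float     # mean lysis time, h
    sigma_l: float  # SD of lysis time, h
    b_r: float      # burst size per releasing cell
    m: float        # mortality rate, 1/h
    p: float        # persistent fraction

    def __post_init__(self) -> None:
        for name in PROBABILITY_TRAITS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"trait {name} must be in [0, 1], got {v}")
        if self.k < 0 or self.m < 0 or self.b_r < 0:
            raise ValueError("k, m and b_r must be non-negative")
        if self.mu_l <= 0:
            raise ValueError(f"mu_l must be positive, got {self.mu_l}")
        if self.sigma_l < 0:
            raise ValueError(f"sigma_l must be non-negative, got {self.sigma_l}")

    @property
    def b_d(self) -> float:
        return self.r * self.b_r

    @property
    def s(self) -> float:
        return self.a * self.d * self.r

    def as_dict(self) -> dict[str, float]:
        out = {name: getattr(self, name) for name in _TRAIT_ORDER}
        out["b_d"] = self.b_d
        out["s"] = self.s
        return out


@dataclass
class AssayDesign:
    """Experimental design shared by the five simulated assays."""

    host_density: float = 1e7            # cells/mL (one-step & growth context)
    adsorption_host_density: float = 1e8  # cells/mL (adsorption assay runs denser)
    v0: float = 1e6                      # initial titer, adsorption & decay assays
    v0_growth: float = 1e4               # growth-assay inoculum
    adsorbed_moi: float = 3.0            # adsorbed virions per cell
    cells_total: int = 200               # cells scored per depolarization replicate
    time_grids: dict[str, np.ndarray] = field(default_factory=lambda: {
        "adsorption": np.array([0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0]),
        "onestep": np.arange(0.0, 28.01, 1.0),
        "decay": np.array([0.0, 12.0, 24.0, 48.0, 96.0, 168.0, 240.0, 360.0, 480.0, 600.0]),
        "growth": np.array([0.0, 12.0, 24.0, 36.0, 48.0, 60.0, 72.0]),
    })
    n_replicates: int = 10
    count_noise: bool = True
    titer_cv: float = 0.15               # lognormal CV of growth-assay titers
    count_target: int = 100              # plaques/cells scored per observation
    residual_fraction: float = 0.02      # unadsorbed inoculum carried into one-step
    seed: int = 0

    def __post_init__(self) -> None:
        if self.host_density <= 0 or self.adsorption_host_density <= 0:
            raise ValueError("host densities must be positive")
        if self.v0 <= 0 or self.v0_growth <= 0:
            raise ValueError("initial titers must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.titer_cv < 0:
            raise ValueError("titer_cv must be non-negative")
        if self.count_target < 1:
            raise ValueError("count_target must be >= 1")
        for name, grid in self.time_grids.items():
            grid = np.asarray(grid, float)
            if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
                raise ValueError(f"time grid '{name}' must be strictly increasing")
            if grid[0] < 0:
                raise ValueError(f"time grid '{name}' has negative times")
            self.time_grids[name] = grid


@dataclass
class AssayDataset:
    """Replicate-level measurements for one strain's five assays."""

    strain_id: str
    adsorption: pd.DataFrame | None = None
    depolarization: pd.DataFrame | None = None
    onestep: pd.DataFrame | None = None
    decay: pd.DataFrame | None = None
    growth: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Trait sampling

def _validate_ranges(ranges: dict[str, tuple[float, float]]) -> None:
    for name in _TRAIT_ORDER:
        if name not in ranges:
            raise ValueError(f"trait_ranges missing trait '{name}'")
        lo, hi = ranges[name]
        if lo > hi:
            raise ValueError(f"trait '{name}': lower bound {lo} > upper bound {hi}")
        if name in PROBABILITY_TRAITS and not (0.0 <= lo and hi <= 1.0):
            raise ValueError(
                f"trait '{name}' is a probability; bounds [{lo}, {hi}] outside [0, 1]"
            )
        if name in LOG_UNIFORM_TRAITS and lo < 0:
            raise ValueError(f"trait '{name}' must be non-negative, got lower bound {lo}")
        if name == "mu_l" and lo <= 0:
            raise ValueError(f"mu_l bounds must be positive, got lower bound {lo}")
        if name == "sigma_l" and lo < 0:
            raise ValueError(f"sigma_l bounds must be non-negative, got lower bound {lo}")


def draw_true_traits(
    n_strains: int,
    trait_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> list[TrueTraits]:
    """Draw ground-truth traits for a panel of strains.

    Rates and burst sizes (``k``, ``b_r``, ``m``) are log-uniform within
    their bounds; probabilities and lysis-time parameters are uniform.
    Reproducible for a fixed seed.
    """
    if n_strains < 1:
        raise ValueError(f"n_strains must be >= 1, got {n_strains}")
    ranges = dict(DEFAULT_TRAIT_RANGES)
    if trait_ranges:
        ranges.update(trait_ranges)
    _validate_ranges(ranges)
    rng = np.random.default_rng(seed)
    draws: dict[str, np.ndarray] = {}
    for name in _TRAIT_ORDER:
        lo, hi = ranges[name]
        if lo == hi:
            draws[name] = np.full(n_strains, float(lo))
        elif name in LOG_UNIFORM_TRAITS:
            if lo <= 0:
                raise ValueError(f"trait '{name}' needs a positive lower bound "
                                 f"for log-uniform sampling, got {lo}")
            draws[name] = np.exp(rng.uniform(np.log(lo), np.log(hi), n_strains))
        else:
            draws[name] = rng.uniform(lo, hi, n_strains)
    return [
        TrueTraits(strain_id=f"S{i + 1:03d}",
                   **{name: float(draws[name][i]) for name in _TRAIT_ORDER})
        for i in range(n_strains)
    ]


# ---------------------------------------------------------------------------
# Counting / noise helpers

def _counted(expected: np.ndarray, rng: np.random.Generator | None,
             design: AssayDesign) -> np.ndarray:
    """Plaque/cell counting at the countable dilution.

    Each observation is scored in the volume giving ``count_target``
    expected events, so the reported value is Poisson-distributed with
    mean equal to the true expectation (unbiased) and CV
    ``1/sqrt(count_target)``. Zero expectations stay exactly zero.
    """
    expected = np.asarray(expected, float)
    if rng is None or not design.count_noise:
        return expected.copy()
    out = np.zeros_like(expected)
    pos = expected > 0
    n = design.count_target
    counts = rng.poisson(n, size=int(pos.sum()))
    out[pos] = counts * expected[pos] / n
    return out


def _lognormal_factor(n: int, cv: float, rng: np.random.Generator | None) -> np.ndarray:
    if rng is None or cv <= 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(0.0, sigma, n))


def _rng_for(design: AssayDesign, rng: np.random.Generator | None):
    if not design.count_noise and design.titer_cv == 0:
        return None
    return rng if rng is not None else np.random.default_rng(design.seed)


# ---------------------------------------------------------------------------
# Assay simulators

def adsorption_expectation(traits: TrueTraits, design: AssayDesign,
                           t: np.ndarray) -> np.ndarray:
    """Expected free titer: v0 * [(1-a) + a*exp(-k*H*t)]."""
    kH = traits.k * design.adsorption_host_density
    return design.v0 * ((1.0 - traits.a) + traits.a * np.exp(-kH * np.asarray(t, float)))


def simulate_adsorption_assay(
    traits: TrueTraits, design: AssayDesign,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    rng = _rng_for(design, rng)
    t = design.time_grids["adsorption"]
    rows = []
    for rep in range(1, design.n_replicates + 1):
        v = _counted(adsorption_expectation(traits, design, t), rng, design)
        rows.append(pd.DataFrame({
            "replicate": rep, "time_h": t, "free_pfu_per_ml": v,
            "host_density": design.adsorption_host_density,
        }))
    return pd.concat(rows, ignore_index=True)


def lysis_cdf(t, mu_l: float, sigma_l: float) -> np.ndarray:
    """Cumulative lysis-time distribution: normal (mu_l, sigma_l) truncated at 0."""
    t = np.asarray(t, float)
    if sigma_l <= 0:
        return (t >= mu_l).astype(float)
    lo = norm.cdf(-mu_l / sigma_l)
    return np.clip((norm.cdf((t - mu_l) / sigma_l) - lo) / (1.0 - lo), 0.0, 1.0)


def onestep_expectations(traits: TrueTraits, design: AssayDesign, t: np.ndarray):
    """Expected one-step curves: (infectious centers, free virus, depolarized density).

    Depolarized density D = H*(1 - exp(-d*MOI)); a fraction r of those
    cells will release. Infectious centers are releasing cells that have
    not yet lysed; free virus is the residual inoculum plus b_r progeny
    per lysed cell. Lysis times are normal (mu_l, sigma_l) truncated at 0.
    """
    t = np.asarray(t, float)
    H = design.host_density
    D = H * (1.0 - np.exp(-traits.d * design.adsorbed_moi))
    phi = lysis_cdf(t, traits.mu_l, traits.sigma_l)
    releasing = traits.r * D
    ic = releasing * (1.0 - phi)
    residual = design.residual_fraction * design.adsorbed_moi * H
    free = residual + traits.b_r * releasing * phi
    return ic, free, D


def simulate_one_step_assay(
    traits: TrueTraits, design: AssayDesign,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the one-step growth and depolarization assays.

    Returns ``(onestep, depolarization)`` data frames. If the time grid
    ends before the lysis curve plateaus (mu_l + 3*sigma_l), the
    truncation is recorded in ``onestep.attrs['truncated']`` and logged.
    """
    rng = _rng_for(design, rng)
    t = design.time_grids["onestep"]
    truncated = t[-1] < traits.mu_l + 3.0 * traits.sigma_l
    if truncated:
        logger.warning(
            "strain %s: one-step grid ends at %.1f h, before lysis plateau %.1f h",
            traits.strain_id, t[-1], traits.mu_l + 3.0 * traits.sigma_l)

    ic, free, D = onestep_expectations(traits, design, t)
    rows = []
    for rep in range(1, design.n_replicates + 1):
        rows.append(pd.DataFrame({
            "replicate": rep, "time_h": t,
            "infectious_centers_per_ml": _counted(ic, rng, design),
            "free_pfu_per_ml": _counted(free, rng, design),
            "depolarized_cells_per_ml": _counted(np.full_like(t, D), rng, design),
        }))
    onestep = pd.concat(rows, ignore_index=True)
    onestep.attrs["truncated"] = bool(truncated)

    frac = 1.0 - np.exp(-traits.d * design.adsorbed_moi)
    dep_rows = []
    for rep in range(1, design.n_replicates + 1):
        if rng is not None:
            n_dep = float(rng.binomial(design.cells_total, frac))
        else:
            n_dep = frac * design.cells_total
        dep_rows.append({
            "replicate": rep, "cells_total": design.cells_total,
            "cells_depolarized": n_dep, "adsorbed_moi": design.adsorbed_moi,
        })
    return onestep, pd.DataFrame(dep_rows)


def decay_expectation(traits: TrueTraits, design: AssayDesign,
                      t: np.ndarray) -> np.ndarray:
    """Expected surviving titer: v0 * [p + (1-p)*exp(-m*t)]."""
    t = np.asarray(t, float)
    return design.v0 * (traits.p + (1.0 - traits.p) * np.exp(-traits.m * t))


def simulate_decay_assay(
    traits: TrueTraits, design: AssayDesign,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    rng = _rng_for(design, rng)
    t = design.time_grids["decay"]
    rows = []
    for rep in range(1, design.n_replicates + 1):
        v = _counted(decay_expectation(traits, design, t), rng, design)
        rows.append(pd.DataFrame({"replicate": rep, "time_h": t, "pfu_per_ml": v}))
    return pd.concat(rows, ignore_index=True)


def simulate_growth_assay(
    traits: TrueTraits, design: AssayDesign, growth_rate: float,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a growth assay at the given exponential rate (1/h)."""
    if not np.isfinite(growth_rate):
        raise ValueError(f"growth_rate must be finite, got {growth_rate}")
    rng = _rng_for(design, rng)
    t = design.time_grids["growth"]
    expected = design.v0_growth * np.exp(growth_rate * t)
    rows = []
    for rep in range(1, design.n_replicates + 1):
        noise = _lognormal_factor(len(t), design.titer_cv if rng is not None else 0.0, rng)
        rows.append(pd.DataFrame({
            "replicate": rep, "time_h": t, "pfu_per_ml": expected * noise,
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Panel assembly

_SPECIES_GENOME_KB = {0: 305.0, 1: 330.0, 2: 360.0}


def _assign_species(n_strains: int, group_sizes: tuple[int, ...]) -> np.ndarray:
    """Assign strains to species groups, scaling the group-size pattern to n."""
    total = sum(group_sizes)
    counts = [max(1, round(n_strains * g / total)) for g in group_sizes]
    while sum(counts) > n_strains:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < n_strains:
        counts[int(np.argmin(counts))] += 1
    return np.repeat(np.arange(len(group_sizes)), counts)[:n_strains]


def build_panel(
    n_strains: int = 34,
    trait_ranges: dict[str, tuple[float, float]] | None = None,
    design: AssayDesign | None = None,
    seed: int = 0,
    outdir=None,
    group_sizes: tuple[int, ...] = (12, 12, 10),
    truths: list[TrueTraits] | None = None,
):
    """Build a complete synthetic panel: assays, truth table, metadata.

    Each strain's growth assay is simulated at the growth rate predicted
    from its own true traits, so predicted-vs-observed comparisons have a
    known answer. Species/type-host groups follow ``group_sizes``
    (scaled to ``n_strains``); species and type host are assigned 1:1,
    mirroring the type-host confounding of real panels.

    Returns ``(datasets, truth_table, strains)``; if ``outdir`` is given
    the panel is also written as CSV files (deterministic bytes for a
    fixed seed).
    """
    from .growth import predict_growth_rate  # local import avoids a cycle

    design = design if design is not None else AssayDesign()
    if truths is None:
        truths = draw_true_traits(n_strains, trait_ranges, seed=seed)
    else:
        n_strains = len(truths)
    species_idx = _assign_species(n_strains, group_sizes)
    root = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in root.spawn(n_strains + 1)]
    meta_rng = streams[-1]

    datasets: dict[str, AssayDataset] = {}
    strain_rows = []
    truth_rows = []
    for i, tt in enumerate(truths):
        rng = streams[i] if (design.count_noise or design.titer_cv > 0) else None
        onestep, depol = simulate_one_step_assay(tt, design, rng)
        lam = predict_growth_rate(tt.s, tt.k, tt.mu_l, tt.b_r, design.host_density)
        datasets[tt.strain_id] = AssayDataset(
            strain_id=tt.strain_id,
            adsorption=simulate_adsorption_assay(tt, design, rng),
            depolarization=depol,
            onestep=onestep,
            decay=simulate_decay_assay(tt, design, rng),
            growth=simulate_growth_assay(tt, design, lam.lambda_pred, rng),
        )
        sp = int(species_idx[i])
        genome = _SPECIES_GENOME_KB[sp % 3] + meta_rng.uniform(-15.0, 15.0)
        strain_rows.append({
            "strain_id": tt.strain_id,
            "species": f"species_{sp + 1}",
            "type_host": f"host_{chr(ord('A') + sp)}",
            "genome_size_kb": round(float(genome), 1),
        })
        row = {"strain_id": tt.strain_id}
        row.update(tt.as_dict())
        row["lambda_true"] = lam.lambda_pred
        truth_rows.append(row)

    truth_table = pd.DataFrame(truth_rows)
    strains = pd.DataFrame(strain_rows)
    if outdir is not None:
        from .io import write_panel
        write_panel(datasets, strains, outdir, truth=truth_table)
    return datasets, truth_table, strains
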