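"""Trait-dependent sampling designs and inverse-probability weights.

Six designs over a cohort of n individuals with residual trait Y_i:

=====  ======================================================================
D1     entire cohort (100%)
D2     50% simple random sample
D3     all observations in each 25% tail of the trait distribution
D4     all observations in each 20% tail plus the central 10%
D5_1   probability sampling, p_i increasing linearly in d_i/d_max
D5_2   as D5_1 with a squared distance, favoring extremes more strongly
=====  ======================================================================

D3/D4 are systematic (no randomness).  D5 draws each individual independently
(Poisson sampling) with probability p_i proportional to (floor + d_i/d_max)^k,
calibrated so the expected sample size equals the target fraction of the
cohort; every individual retains a nonzero probability.
Sampled individuals carry the IPW weight w_i = 1/p_i, making weighted
estimators unbiased for cohort quantities (Horvitz-Thompson).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trait_prep import ResidualTrait

__all__ = [
    "DESIGN_IDS",
    "DesignSpec",
    "DesignSelection",
    "select_srs",
    "select_extreme",
    "sampling_probabilities",
    "select_bernoulli",
    "make_selection",
]

DESIGN_IDS = ("D1", "D2", "D3", "D4", "D5_1", "D5_2")


def _rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of one sampling design.

    ``floor`` is the additive offset inside the distance score for D5
    variants; it keeps every probability positive and the IPW weights
    bounded.  ``exponent`` is the power on (floor + d_i/d_max)
    (1 for D5_1, 2 for D5_2).
    """

    design_id: str
    target_fraction: float = 0.5
    tail_fracs: tuple[float, float] = (0.25, 0.25)
    center_frac: float = 0.0
    exponent: float = 1.0
    floor: float = 0.1

    def __post_init__(self):
        if not (0.0 < self.target_fraction <= 1.0):
            raise ValueError("target_fraction must be in (0, 1]")
        if self.design_id.startswith("D5") and self.floor <= 0:
            raise ValueError("floor must be > 0 for probability designs")


@dataclass
class DesignSelection:
    """Per-individual inclusion probability, inclusion flag, and IPW weight."""

    design_id: str
    p: np.ndarray
    included: np.ndarray  # boolean
    w: np.ndarray  # 1/p where included; NaN elsewhere

    @property
    def n_sampled(self) -> int:
        return int(self.included.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.included)

    @property
    def weights(self) -> np.ndarray:
        """IPW weights of the sampled individuals, in cohort order."""
        return self.w[self.included]


def _selection(design_id, p, included):
    w = np.full(p.shape, np.nan)
    w[included] = 1.0 / p[included]
    return DesignSelection(design_id=design_id, p=p, included=included, w=w)


def select_srs(n: int, fraction: float, seed) -> DesignSelection:
    """Fixed-size simple random sample of round(fraction*n) individuals."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    m = round(fraction * n)
    idx = _rng(seed).choice(n, size=m, replace=False)
    included = np.zeros(n, dtype=bool)
    included[idx] = True
    return _selection("D2", np.full(n, fraction), included)


def select_extreme(
    residual: ResidualTrait,
    tail_fracs: tuple[float, float] = (0.25, 0.25),
    center_frac: float = 0.0,
) -> DesignSelection:
    """Deterministic extreme-phenotype selection (designs D3/D4).

    Takes the lowest round(tail_fracs[0]*n) and highest round(tail_fracs[1]*n)
    residuals and, optionally, the round(center_frac*n) individuals nearest
    the median by rank.  Rounding is round-half-to-even; ties in the residual
    are broken by original order (stable sort).
    """
    lo_f, hi_f = tail_fracs
    if lo_f < 0 or hi_f < 0 or center_frac < 0:
        raise ValueError("fractions must be nonnegative")
    if lo_f + hi_f + center_frac > 1.0 + 1e-12:
        raise ValueError("tail and center fractions must sum to at most 1")
    n = residual.n
    n_lo, n_hi, n_c = round(lo_f * n), round(hi_f * n), round(center_frac * n)
    order = np.argsort(residual.y, kind="stable")
    included = np.zeros(n, dtype=bool)
    if n_lo:
        included[order[:n_lo]] = True
    if n_hi:
        included[order[n - n_hi:]] = True
    if n_c:
        ranks = np.empty(n, dtype=float)
        ranks[order] = np.arange(n)
        centrality = np.abs(ranks - (n - 1) / 2.0)
        central = np.lexsort((np.arange(n), centrality))[:n_c]
        included[central] = True
    design_id = "D4" if center_frac > 0 else "D3"
    p = included.astype(float)  # systematic: analyzed unweighted
    return _selection(design_id, p, included)


def sampling_probabilities(residual: ResidualTrait, spec: DesignSpec) -> np.ndarray:
    """Calibrated inclusion probabilities for the D5 family.

    The raw score is s_i = (floor + d_i/d_max)^exponent; probabilities are
    p_i = min(1, c*s_i) with c found by bisection so that sum(p_i) equals
    target_fraction * n after capping at 1 (tolerance 1e-10).  All p_i lie in
    (0, 1], so every individual can be sampled and weights stay bounded.

    Raising the exponent reallocates probability toward the extremes: the
    ratio of exponent-2 to exponent-1 probabilities increases with d_i, and
    because both calibrations share one expected sample size, the exponent-2
    design must assign strictly less probability near the median and at least
    as much at the maximum distance.
    """
    if residual.d_max <= 0:
        raise ValueError("design undefined: all residuals equal (d_max = 0)")
    if spec.exponent < 1:
        raise ValueError("exponent must be >= 1")
    n = residual.n
    target = spec.target_fraction * n
    if target > n:
        raise ValueError("infeasible target sample size")
    s = (spec.floor + residual.d / residual.d_max) ** spec.exponent

    def capped_sum(c):
        return np.minimum(1.0, c * s).sum()

    lo, hi = 0.0, 1.0
    while capped_sum(hi) < target - 1e-10:
        hi *= 2.0
        if hi > 1e16:  # target == n and floating slack
            return np.ones(n)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if capped_sum(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-16 * max(hi, 1.0):
            break
    c = hi
    p = np.minimum(1.0, c * s)
    if abs(p.sum() - target) > 1e-6:
        raise RuntimeError("probability calibration failed to converge")
    return p


def select_bernoulli(p: np.ndarray, seed, design_id: str = "D5_1") -> DesignSelection:
    """Independent Bernoulli (Poisson) sampling with per-individual p_i.

    Sample size is random with expectation sum(p_i); each sampled individual
    gets IPW weight w_i = 1/p_i.
    """
    p = np.asarray(p, dtype=float)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("all probabilities must lie in (0, 1]")
    included = _rng(seed).random(p.size) < p
    return _selection(design_id, p, included)


def make_selection(
    design_id: str,
    residual: ResidualTrait,
    seed=None,
    fraction: float = 0.5,
    floor: float = 0.1,
) -> DesignSelection:
    """Dispatch to the design named by ``design_id`` (see DESIGN_IDS)."""
    n = residual.n
    if design_id == "D1":
        return _selection("D1", np.ones(n), np.ones(n, dtype=bool))
    if design_id == "D2":
        return select_srs(n, fraction, seed)
    if design_id == "D3":
        half = fraction / 2.0
        return select_extreme(residual, tail_fracs=(half, half))
    if design_id == "D4":
        tail = 0.4 * fraction
        return select_extreme(residual, tail_fracs=(tail, tail),
                              center_frac=0.2 * fraction)
    if design_id in ("D5_1", "D5_2"):
        k = 1.0 if design_id == "D5_1" else 2.0
        spec = DesignSpec(design_id=design_id, target_fraction=fraction,
                          exponent=k, floor=floor)
        p = sampling_probabilities(residual, spec)
        return select_bernoulli(p, seed, design_id=design_id)
    raise ValueError(f"unknown design {design_id!r}")
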