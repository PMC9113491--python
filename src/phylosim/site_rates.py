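"""Per-site rate multipliers: invariant sites, Gamma and free-rate models.

All rate models have mean rate exactly one so that branch lengths remain
expected substitutions per site.  With an invariant proportion ``p_inv``,
variable sites are rescaled by ``1 / (1 - p_inv)``.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "RateKind",
    "RateModel",
    "SiteRateVector",
    "discrete_gamma_rates",
    "sample_site_rates",
    "parse_rate_components",
]


class RateKind(enum.Enum):
    CONSTANT = "constant"
    GAMMA_DISCRETE = "gamma_discrete"
    GAMMA_CONTINUOUS = "gamma_continuous"
    FREE = "free"


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean-per-category discrete Gamma rates (k equal-probability bins).

    The Gamma distribution has shape ``alpha`` and mean one; each category
    rate is the conditional mean of the density over its quantile interval.
    The returned rates are renormalized to mean exactly one.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be > 0")
    k = int(k)
    if k < 1:
        raise ValueError("number of categories must be >= 1")
    if k == 1:
        return np.ones(1)
    # X ~ Gamma(alpha, scale=1/alpha); E[X | bin] via the Gamma(alpha+1) CDF:
    # E[X 1{a<X<b}] = F_{alpha+1}(b) - F_{alpha+1}(a)  (mean-one scaling)
    edges = _gamma_dist.ppf(np.arange(k + 1) / k, a=alpha, scale=1.0 / alpha)
    upper = _gamma_dist.cdf(edges, a=alpha + 1, scale=1.0 / alpha)
    rates = k * np.diff(upper)
    rates /= rates.mean()
    return rates


@dataclass(frozen=True)
class RateModel:
    """Site-rate heterogeneity specification (mean rate one).

    Exactly one variable-rate component (none, discrete Gamma, continuous
    Gamma or free rates) combined with an optional invariant proportion.
    """

    kind: RateKind = RateKind.CONSTANT
    p_inv: float = 0.0
    alpha: float | None = None
    n_categories: int | None = None
    weights: np.ndarray | None = None
    rates: np.ndarray | None = None
    _category_rates: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_inv < 1.0):
            raise ValueError("p_inv must lie in [0, 1)")
        if self.kind in (RateKind.GAMMA_DISCRETE, RateKind.GAMMA_CONTINUOUS):
            if self.alpha is None or self.alpha <= 0:
                raise ValueError("gamma shape must be > 0")
        if self.kind is RateKind.GAMMA_DISCRETE:
            if self.n_categories is None or self.n_categories < 1:
                raise ValueError("discrete gamma needs >= 1 categories")
            object.__setattr__(self, "_category_rates",
                               discrete_gamma_rates(self.alpha, self.n_categories))
        if self.kind is RateKind.FREE:
            w = np.asarray(self.weights, dtype=float)
            r = np.asarray(self.rates, dtype=float)
            if w.shape != r.shape or w.ndim != 1 or len(w) < 1:
                raise ValueError("free-rate weights and rates must be matching "
                                 "1-d vectors")
            if np.any(w <= 0) or np.any(r < 0):
                raise ValueError("free-rate weights must be positive and rates "
                                 "non-negative")
            if abs(w.sum() - 1.0) > 1e-8:
                warnings.warn("free-rate weights renormalized to sum to 1")
                w = w / w.sum()
            mean = float(w @ r)
            if abs(mean - 1.0) > 1e-8:
                warnings.warn("free rates renormalized to mean 1")
                r = r / mean
            object.__setattr__(self, "weights", w)
            object.__setattr__(self, "rates", r)
            object.__setattr__(self, "n_categories", len(w))
            object.__setattr__(self, "_category_rates", r)

    # -- constructors ---------------------------------------------------
    @classmethod
    def constant(cls, p_inv: float = 0.0) -> "RateModel":
        return cls(kind=RateKind.CONSTANT, p_inv=p_inv)

    @classmethod
    def invariant(cls, p_inv: float) -> "RateModel":
        return cls(kind=RateKind.CONSTANT, p_inv=p_inv)

    @classmethod
    def discrete_gamma(cls, alpha: float, k: int = 4,
                       p_inv: float = 0.0) -> "RateModel":
        return cls(kind=RateKind.GAMMA_DISCRETE, p_inv=p_inv, alpha=alpha,
                   n_categories=int(k))

    @classmethod
    def continuous_gamma(cls, alpha: float, p_inv: float = 0.0) -> "RateModel":
        return cls(kind=RateKind.GAMMA_CONTINUOUS, p_inv=p_inv, alpha=alpha)

    @classmethod
    def free_rates(cls, pairs, p_inv: float = 0.0) -> "RateModel":
        w = [p[0] for p in pairs]
        r = [p[1] for p in pairs]
        return cls(kind=RateKind.FREE, p_inv=p_inv, weights=np.asarray(w),
                   rates=np.asarray(r))

    # -- properties -----------------------------------------------------
    @property
    def is_continuous(self) -> bool:
        return self.kind is RateKind.GAMMA_CONTINUOUS

    @property
    def category_rates(self) -> np.ndarray | None:
        """Rates of the variable-part categories (before p_inv scaling)."""
        if self.kind is RateKind.CONSTANT:
            return np.ones(1)
        return self._category_rates

    @property
    def mean_rate(self) -> float:
        """Analytic mean rate over the full model (always one).

        Variable sites are scaled by 1/(1-p_inv) and occur with probability
        (1-p_inv), so the scaling cancels and the mean equals the variable
        component's mean.
        """
        if self.kind is RateKind.GAMMA_CONTINUOUS:
            return 1.0
        if self.kind is RateKind.FREE:
            return float(self.weights @ self.rates)
        return float(np.mean(self.category_rates))


@dataclass
class SiteRateVector:
    """Length-L vector of site rates with optional category assignments.

    Invariant sites carry rate exactly zero and category ``-1``.
    """

    rates: np.ndarray
    categories: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.rates < 0):
            raise ValueError("site rates must be non-negative")
        if self.categories is not None:
            self.categories = np.asarray(self.categories, dtype=np.int32)
            if self.categories.shape != self.rates.shape:
                raise ValueError("categories and rates must align")

    def __len__(self) -> int:
        return len(self.rates)


def sample_site_rates(model: RateModel, L: int,
                      rng: np.random.Generator) -> SiteRateVector:
    """Draw ``L`` independent site rates under ``model``.

    Each site is invariant (rate 0) with probability ``p_inv``; otherwise a
    draw from the variable component scaled by ``1/(1-p_inv)`` keeps the
    overall mean rate at one.
    """
    L = int(L)
    if L < 1:
        raise ValueError("number of sites must be >= 1")
    scale = 1.0 / (1.0 - model.p_inv)

    if model.kind is RateKind.GAMMA_CONTINUOUS:
        invariant = rng.random(L) < model.p_inv if model.p_inv > 0 else \
            np.zeros(L, dtype=bool)
        rates = rng.gamma(model.alpha, 1.0 / model.alpha, size=L) * scale
        rates[invariant] = 0.0
        cats = None
        if model.p_inv > 0:
            cats = np.where(invariant, -1, 0).astype(np.int32)
        return SiteRateVector(rates=rates, categories=cats)

    if model.kind is RateKind.CONSTANT:
        cat_rates = np.ones(1)
        invariant = rng.random(L) < model.p_inv if model.p_inv > 0 else \
            np.zeros(L, dtype=bool)
        cats = np.zeros(L, dtype=np.int32)
    elif model.kind is RateKind.GAMMA_DISCRETE:
        cat_rates = model.category_rates
        invariant = rng.random(L) < model.p_inv if model.p_inv > 0 else \
            np.zeros(L, dtype=bool)
        cats = rng.integers(model.n_categories, size=L).astype(np.int32)
    else:  # FREE
        cat_rates = model.rates
        invariant = rng.random(L) < model.p_inv if model.p_inv > 0 else \
            np.zeros(L, dtype=bool)
        cum = np.cumsum(model.weights)
        cats = np.searchsorted(cum, rng.random(L), side="right")
        cats = np.minimum(cats, len(cum) - 1).astype(np.int32)

    rates = cat_rates[cats] * scale
    rates[invariant] = 0.0
    cats[invariant] = -1
    return SiteRateVector(rates=rates, categories=cats)


# ----------------------------------------------------------------------
def parse_rate_components(tokens: list[str]) -> RateModel:
    """Build a RateModel from grammar tokens such as I{0.2}, G4{0.5}, GC{0.5},
    R3{w1,r1,w2,r2,w3,r3}."""
    from .models import split_braces  # local import: tiny helper, no cycle risk

    p_inv = 0.0
    variable: RateModel | None = None

    def set_variable(rm):
        nonlocal variable
        if variable is not None:
            raise ValueError("only one variable-rate component is allowed")
        variable = rm

    for tok in tokens:
        head, body = split_braces(tok)
        head = head.upper()
        vals = [float(x) for x in body.split(",")] if body else []
        if head == "I":
            if len(vals) != 1:
                raise ValueError(f"+I takes one value, got {tok!r}")
            p_inv = vals[0]
        elif head == "GC":
            if len(vals) != 1:
                raise ValueError(f"+GC takes one value, got {tok!r}")
            set_variable(("GC", vals[0]))
        elif head.startswith("G"):
            k = int(head[1:]) if len(head) > 1 else 4
            if len(vals) != 1:
                raise ValueError(f"+G takes one value, got {tok!r}")
            set_variable(("G", vals[0], k))
        elif head.startswith("R"):
            k = int(head[1:]) if len(head) > 1 else None
            if k is None or len(vals) != 2 * k:
                raise ValueError(f"+R{{k}} needs k weight,rate pairs: {tok!r}")
            pairs = list(zip(vals[0::2], vals[1::2]))
            set_variable(("R", pairs))
        else:
            raise ValueError(f"unknown rate component {tok!r}")

    if variable is None:
        return RateModel.constant(p_inv=p_inv)
    if variable[0] == "GC":
        return RateModel.continuous_gamma(variable[1], p_inv=p_inv)
    if variable[0] == "G":
        return RateModel.discrete_gamma(variable[1], k=variable[2], p_inv=p_inv)
    return RateModel.free_rates(variable[1], p_inv=p_inv)
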