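"""Maximum-entropy circle models for ego-network tie strength.

An ego invests a finite social resource (here: grooming) across its L
partners.  Maximum-entropy arguments yield, in the discrete case, layer
membership probabilities ``p_k ∝ exp(-mu_hat * s_k)`` over r cost categories
and cumulative circle sizes ``chi_k = (e^{k mu} - 1)/(e^{r mu} - 1)``; in the
continuum limit, a single stratification parameter ``eta`` with cumulative
tie fraction ``chi(t) = (e^{eta t} - 1)/(e^eta - 1)`` over the normalized
cost distance ``t in [0, 1]`` (t = 0 strongest tie, t = 1 weakest).

``eta`` is estimated per ego by maximum likelihood, which reduces to solving
the implicit equation ``g(eta) = t_bar`` where ``g`` is the model mean of t
(:func:`mean_distance_curve`) and ``t_bar`` the empirical mean normalized
distance.  ``eta > 0`` is the normal regime (few intense ties, many weak
ones); ``eta < 0`` the inverted regime (most ties in the innermost circle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import chi2

__all__ = [
    "TieWeights",
    "NormalizedDistances",
    "CircleFitContinuous",
    "LayerModelDiscrete",
    "Regime",
    "DegenerateWeightsError",
    "normalize_distances",
    "mean_distance_curve",
    "solve_eta",
    "chi_continuous",
    "log_derivative_chi",
    "log_likelihood",
    "eta_confidence_interval",
    "fit_ego",
    "discrete_layer_probs",
    "chi_discrete",
    "eta_from_mu",
]

#: below this |eta| (or |t_bar - 1/2|) the series expansion around the
#: removable singularity at eta = 0 is used
SERIES_CUTOFF = 1e-4
#: default accuracy of the implicit-equation solver
SOLVER_TOL = 1e-8
#: confidence-interval endpoint search never leaves [eta_hat - CI_BRACKET,
#: eta_hat + CI_BRACKET]
CI_BRACKET = 100.0


class DegenerateWeightsError(ValueError):
    """All tie weights equal: the normalized distance is undefined."""


class Regime(str, Enum):
    """Sign regime of the stratification parameter."""

    NORMAL = "normal"
    INVERTED = "inverted"
    BOUNDARY = "boundary"


@dataclass(frozen=True)
class TieWeights:
    """One ego's outgoing tie weights (grooming investment per partner).

    Weights are strictly positive; a partner with zero recorded weight is
    not a tie.  ``L`` is the ego-network size.
    """

    ego_id: str
    weights: tuple[float, ...]
    L: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        object.__setattr__(self, "L", len(self.weights))
        if any(w <= 0 for w in self.weights):
            raise ValueError(f"ego {self.ego_id!r}: tie weights must be positive")


@dataclass(frozen=True)
class NormalizedDistances:
    """Normalized cost distances t_i = (s_max - s_i)/(s_max - s_min)."""

    ego_id: str
    t_values: tuple[float, ...]
    t_bar: float
    s_max: float
    s_min: float
    sigma: float

    @property
    def L(self) -> int:
        return len(self.t_values)


@dataclass(frozen=True)
class CircleFitContinuous:
    """Fitted continuous circle model for one ego."""

    ego_id: str
    eta: float
    ci_low: float
    ci_high: float
    delta: float
    regime: Regime


@dataclass(frozen=True)
class LayerModelDiscrete:
    """Discrete r-layer model: costs, layer probabilities, circle sizes."""

    r: int
    costs: tuple[float, ...]
    mu_hat: float
    mu: float
    probs: tuple[float, ...]
    circle_sizes: tuple[float, ...]


def normalize_distances(tw: TieWeights) -> NormalizedDistances:
    """Map raw tie weights to normalized distances on [0, 1].

    The bounds s_max, s_min are taken per ego from the observed weights, so
    every ego has at least one tie at t = 0 and one at t = 1.  ``sigma`` is
    the arithmetic mean tie cost.

    Raises
    ------
    DegenerateWeightsError
        If all weights are equal (s_max = s_min), in which case the ego
        carries no distributional information and must be excluded.
    """
    if tw.L < 2:
        raise ValueError(f"ego {tw.ego_id!r}: need at least 2 ties, got {tw.L}")
    w = np.asarray(tw.weights, dtype=float)
    s_max, s_min = float(w.max()), float(w.min())
    if s_max == s_min:
        raise DegenerateWeightsError(
            f"ego {tw.ego_id!r}: all {tw.L} tie weights equal ({s_max})"
        )
    t = (s_max - w) / (s_max - s_min)
    return NormalizedDistances(
        ego_id=tw.ego_id,
        t_values=tuple(float(x) for x in t),
        t_bar=float(t.mean()),
        s_max=s_max,
        s_min=s_min,
        sigma=float(w.mean()),
    )


def mean_distance_curve(eta: float) -> float:
    """Model mean normalized distance g(eta) = e^eta/(e^eta - 1) - 1/eta.

    Evaluated in overflow-safe form; the removable singularity at eta = 0
    (value 1/2) is handled by a series expansion.  g is strictly increasing
    from 0 to 1 and satisfies g(-eta) = 1 - g(eta).
    """
    if not math.isfinite(eta):
        raise ValueError("eta must be finite")
    if abs(eta) < SERIES_CUTOFF:
        return 0.5 + eta / 12.0 - eta**3 / 720.0
    if eta > 0:
        return 1.0 / (-math.expm1(-eta)) - 1.0 / eta
    return 1.0 - mean_distance_curve(-eta)


def solve_eta(t_bar: float, tol: float = SOLVER_TOL) -> float:
    """Invert the mean-distance equation: find eta with g(eta) = t_bar.

    This is the maximum-likelihood estimate of eta given the empirical mean
    normalized distance.  Monotone bisection (Brent) on an overflow-safe
    evaluation of g; near t_bar = 1/2 the linearization eta = 12(t_bar - 1/2)
    avoids the removable singularity.  Solved for max(t_bar, 1 - t_bar) and
    reflected, so the antisymmetry solve_eta(1 - t) = -solve_eta(t) holds
    exactly.
    """
    if not 0.0 < t_bar < 1.0:
        raise ValueError(f"t_bar must lie strictly in (0, 1), got {t_bar}")
    if abs(t_bar - 0.5) < 1e-6:
        return 12.0 * (t_bar - 0.5)
    sign = 1.0 if t_bar > 0.5 else -1.0
    t = max(t_bar, 1.0 - t_bar)
    # g(eta) ~ 1 - 1/eta for large eta, so the root is below ~2/(1-t) + 2
    hi = max(50.0, 2.0 / (1.0 - t) + 2.0)
    root = brentq(lambda e: mean_distance_curve(e) - t, 0.0, hi, xtol=tol)
    return sign * float(root)


def chi_continuous(t: float, eta: float) -> float:
    """Cumulative tie fraction chi(t) = (e^{eta t} - 1)/(e^eta - 1).

    Fraction of relationships with normalized cost distance <= t; the curve
    the circle model predicts for the empirical cumulative distribution.
    At eta = 0 the uniform limit chi(t) = t is returned.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"t must lie in [0, 1], got {t}")
    if abs(eta) < SERIES_CUTOFF:
        # first-order correction keeps continuity through eta = 0
        return t + eta * t * (t - 1.0) / 2.0
    if eta > 0:
        # rescale by e^{-eta} to avoid overflow for large eta
        return math.exp(eta * (t - 1.0)) * (-math.expm1(-eta * t)) / (-math.expm1(-eta))
    return math.expm1(eta * t) / math.expm1(eta)


def log_derivative_chi(t: float, eta: float) -> float:
    """Logarithmic derivative chi'(t)/chi(t) = eta e^{eta t}/(e^{eta t} - 1).

    For large positive eta this tends to eta — the continuum analogue of the
    circle scaling ratio; for eta -> -inf it tends to 0.  Singular at t = 0.
    """
    if t <= 0.0 or t > 1.0:
        raise ValueError(f"t must lie in (0, 1], got {t}")
    if not math.isfinite(eta):
        raise ValueError("eta must be finite")
    x = eta * t
    if abs(x) < SERIES_CUTOFF:
        # eta/(1 - e^{-x}) -> 1/t as x -> 0
        return (1.0 / t) * (1.0 + x / 2.0 + x * x / 12.0)
    return eta / (-math.expm1(-x))


def log_likelihood(nd: NormalizedDistances, eta: float) -> float:
    """Log-likelihood of eta under the circle density f(t) = eta e^{eta t}/(e^eta - 1).

    ell(eta) = L ln|eta| + eta sum(t_i) - L ln|e^eta - 1|; at eta = 0 the
    density is uniform and ell = 0.  Its stationary point is exactly the
    solution of the mean-distance equation, so maximizing ell and
    :func:`solve_eta` agree.
    """
    L = nd.L
    sum_t = L * nd.t_bar
    if eta == 0.0:
        return 0.0
    a = abs(eta)
    if a < SERIES_CUTOFF:
        # ln|e^eta - 1| = ln|eta| + eta/2 + O(eta^2)
        return eta * (sum_t - L / 2.0)
    # ln|e^eta - 1| = max(eta, 0) + log(1 - e^{-|eta|})
    log_em1 = max(eta, 0.0) + math.log(-math.expm1(-a))
    return L * math.log(a) + eta * sum_t - L * log_em1


def eta_confidence_interval(
    nd: NormalizedDistances, eta_hat: float, delta: float = 0.025
) -> tuple[float, float]:
    """1 - 2*delta confidence interval for eta by likelihood-ratio inversion.

    Endpoints solve 2(ell(eta_hat) - ell(eta)) = chi2_{1}(1 - 2 delta); the
    interval contains eta_hat, nests monotonically in delta, and shrinks as
    O(L^{-1/2}).

    Raises
    ------
    RuntimeError
        If an endpoint is not bracketed within eta_hat +/- 100.
    """
    if not 0.0 < delta < 0.5:
        raise ValueError(f"delta must lie in (0, 0.5), got {delta}")
    drop = chi2.ppf(1.0 - 2.0 * delta, df=1) / 2.0
    ell_hat = log_likelihood(nd, eta_hat)

    def deficit(e: float) -> float:
        return (ell_hat - log_likelihood(nd, e)) - drop

    def endpoint(direction: float) -> float:
        step = 0.25
        lo = eta_hat
        while step <= CI_BRACKET:
            hi = eta_hat + direction * step
            if deficit(hi) > 0.0:
                return float(brentq(deficit, min(lo, hi), max(lo, hi), xtol=1e-9))
            lo = hi
            step *= 2.0
        raise RuntimeError(
            f"CI endpoint not bracketed within {CI_BRACKET} of eta_hat={eta_hat}"
        )

    return endpoint(-1.0), endpoint(+1.0)


def fit_ego(tw: TieWeights, delta: float = 0.025, tol: float = SOLVER_TOL) -> CircleFitContinuous:
    """Full per-ego fit: normalize, solve for eta, attach CI and regime label."""
    nd = normalize_distances(tw)
    eta = solve_eta(nd.t_bar, tol=tol)
    lo, hi = eta_confidence_interval(nd, eta, delta)
    if eta > 0:
        regime = Regime.NORMAL
    elif eta < 0:
        regime = Regime.INVERTED
    else:
        regime = Regime.BOUNDARY
    return CircleFitContinuous(
        ego_id=tw.ego_id, eta=eta, ci_low=lo, ci_high=hi, delta=delta, regime=regime
    )


def discrete_layer_probs(costs: Sequence[float], mu_hat: float) -> LayerModelDiscrete:
    """Discrete max-entropy layer model: p_k = e^{-mu_hat s_k} / Z_r.

    ``costs`` must be strictly decreasing (s_1 = s_max down to s_r = s_min).
    Also populates mu = mu_hat (s_max - s_min)/(r - 1) and the cumulative
    circle sizes chi_k.
    """
    c = np.asarray(costs, dtype=float)
    r = len(c)
    if r < 2:
        raise ValueError("need at least 2 cost categories")
    if not np.all(np.diff(c) < 0):
        raise ValueError("costs must be strictly decreasing")
    logits = -mu_hat * c
    logits -= logits.max()  # overflow guard; normalization absorbs the shift
    p = np.exp(logits)
    p /= p.sum()
    mu = mu_hat * (c[0] - c[-1]) / (r - 1)
    chis = tuple(chi_discrete(k, r, mu) for k in range(1, r + 1))
    return LayerModelDiscrete(
        r=r,
        costs=tuple(float(x) for x in c),
        mu_hat=float(mu_hat),
        mu=float(mu),
        probs=tuple(float(x) for x in p),
        circle_sizes=chis,
    )


def chi_discrete(k: int, r: int, mu: float) -> float:
    """Expected cumulative tie fraction in circles 1..k: (e^{k mu} - 1)/(e^{r mu} - 1).

    chi_r = 1; at mu = 0 the uniform limit k/r; consecutive ratios approach
    e^mu for large mu (the circle scaling ratio).
    """
    if not 1 <= k <= r:
        raise IndexError(f"k must lie in [1, {r}], got {k}")
    if abs(mu) < SERIES_CUTOFF:
        return k / r + mu * k * (k - r) / (2.0 * r)
    if mu > 0:
        # rescale to avoid overflow at large r*mu
        return math.exp((k - r) * mu) * (-math.expm1(-k * mu)) / (-math.expm1(-r * mu))
    return math.expm1(k * mu) / math.expm1(r * mu)


def eta_from_mu(mu: float, r: int) -> float:
    """Map the discrete-model scaling exponent to the continuum parameter.

    eta = (r - 1)(e^mu - 1); with r = 4 layers and scaling ratio e^mu = 3
    this gives the canonical eta = 6.
    """
    if r < 2:
        raise ValueError("need r >= 2 layers")
    return (r - 1) * math.expm1(mu)
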