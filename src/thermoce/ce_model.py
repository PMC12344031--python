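"""Two-state continuous-time Markov colonisation-extinction model.

Each species at a site is modelled as an independent two-state Markov
process: an absent species colonises at rate ``c`` (per year) and a present
species goes locally extinct at rate ``e`` (per year).  Under species
equivalence the site's whole presence/absence matrix shares one (c, e)
pair, and the likelihood factorises over consecutive survey pairs, which
makes the per-``dt`` transition counts a sufficient statistic.  Surveys may
be irregularly spaced; a missing year simply lengthens the interval.

The stationary occupancy probability is ``c / (c + e)``; ``1/c`` is the mean
waiting time to colonisation and ``1/e`` ("persistence") the mean time to
local extinction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "OccupancySeries",
    "TransitionCounts",
    "RatePair",
    "CovariateRateModel",
    "transition_matrix",
    "count_transitions",
    "negative_log_likelihood",
    "closed_form_rates",
    "fit_site_rates",
    "fit_covariate_model",
    "BoundaryRateWarning",
]

#: Hard bounds for rates (1/year); optima pinned here get a boundary flag.
RATE_MIN = 1e-6
RATE_MAX = 1e3


class BoundaryRateWarning(UserWarning):
    """A fitted rate was pinned at the allowed boundary."""


@dataclass
class OccupancySeries:
    """A site's species x survey presence/absence matrix.

    Parameters
    ----------
    site_id
        Site identifier.
    survey_times
        Strictly increasing real-valued survey years (length >= 2).
    states
        ``(n_species, n_surveys)`` matrix of 0/1 detections.
    species
        Optional species labels matching the rows of ``states``.
    group
        Optional thermal-group label when the series is a group subset.
    """

    site_id: str
    survey_times: np.ndarray
    states: np.ndarray
    species: list[str] | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        self.survey_times = np.asarray(self.survey_times, dtype=float)
        self.states = np.asarray(self.states)
        if self.survey_times.ndim != 1 or self.survey_times.size < 2:
            raise ValueError("need at least 2 survey times")
        if np.any(np.diff(self.survey_times) <= 0):
            raise ValueError("survey_times must be strictly increasing")
        if self.states.ndim != 2:
            raise ValueError("states must be a 2-D species x survey matrix")
        if self.states.shape[1] != self.survey_times.size:
            raise ValueError("states columns must match survey_times")
        if self.states.shape[0] < 1:
            raise ValueError("states must contain at least one species row")
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("states must be binary (0/1)")
        if self.species is not None and len(self.species) != self.states.shape[0]:
            raise ValueError("species labels must match states rows")

    @property
    def n_species(self) -> int:
        return self.states.shape[0]

    @property
    def n_surveys(self) -> int:
        return self.states.shape[1]


class TransitionCounts:
    """Per-interval transition counts, the likelihood's sufficient statistic.

    Maps each observed between-survey gap ``dt`` (years) to the four counts
    ``(N00, N01, N10, N11)`` of consecutive-pair transitions pooled over
    species, where ``Nab`` counts pairs going from state ``a`` to ``b``.
    """

    def __init__(self, buckets: dict[float, np.ndarray] | None = None):
        self._buckets: dict[float, np.ndarray] = {}
        if buckets:
            for dt, counts in buckets.items():
                self.add(dt, counts)

    def add(self, dt: float, counts) -> None:
        dt = float(dt)
        counts = np.asarray(counts, dtype=float)
        if dt <= 0:
            raise ValueError("dt must be positive")
        if counts.shape != (4,) or np.any(counts < 0):
            raise ValueError("counts must be 4 non-negative numbers")
        if dt in self._buckets:
            self._buckets[dt] = self._buckets[dt] + counts
        else:
            self._buckets[dt] = counts

    def items(self):
        return sorted(self._buckets.items())

    @property
    def dts(self) -> np.ndarray:
        return np.array(sorted(self._buckets))

    def counts(self, dt: float) -> np.ndarray:
        return self._buckets[float(dt)]

    @property
    def n_transitions(self) -> float:
        return float(sum(c.sum() for c in self._buckets.values()))

    def totals(self) -> np.ndarray:
        """Counts summed over all dt buckets, as (N00, N01, N10, N11)."""
        return np.sum([c for _, c in self.items()], axis=0)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (dts, counts) with counts of shape (n_buckets, 4)."""
        items = self.items()
        dts = np.array([dt for dt, _ in items])
        mat = np.array([c for _, c in items])
        return dts, mat

    def __len__(self) -> int:
        return len(self._buckets)

    def __repr__(self) -> str:  # pragma: no cover
        return f"TransitionCounts({dict(self.items())!r})"


@dataclass
class RatePair:
    """A fitted (colonisation, extinction) rate pair with diagnostics."""

    c: float
    e: float
    nll: float
    n_transitions: float
    boundary_flag: str | None = None
    se_log_c: float = float("nan")
    se_log_e: float = float("nan")

    @property
    def persistence(self) -> float:
        """Mean time to local extinction, 1/e (years)."""
        return 1.0 / self.e

    @property
    def colonisation_time(self) -> float:
        """Mean waiting time to colonisation, 1/c (years)."""
        return 1.0 / self.c


@dataclass
class CovariateRateModel:
    """Exponential-link model rate = exp(beta0 + beta1 * X) shared across sites.

    ``beta[0:2]`` act on colonisation, ``beta[2:4]`` on extinction; standard
    errors come from the observed information (finite-difference Hessian of
    the summed negative log-likelihood) at the optimum.
    """

    beta0_c: float
    beta1_c: float
    beta0_e: float
    beta1_e: float
    se: np.ndarray
    vcov: np.ndarray
    nll: float
    covariate_name: str
    x: np.ndarray
    per_group: str | None = None
    converged: bool = True

    @property
    def params(self) -> np.ndarray:
        return np.array([self.beta0_c, self.beta1_c, self.beta0_e, self.beta1_e])

    def rates_at(self, x) -> tuple[np.ndarray, np.ndarray]:
        """Fitted (c, e) at covariate value(s) x."""
        x = np.asarray(x, dtype=float)
        c = np.exp(self.beta0_c + self.beta1_c * x)
        e = np.exp(self.beta0_e + self.beta1_e * x)
        return c, e

    def confint(self, level: float = 0.95) -> np.ndarray:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        p = self.params
        return np.column_stack([p - z * self.se, p + z * self.se])


def transition_matrix(c: float, e: float, dt: float) -> np.ndarray:
    """Row-stochastic 2x2 transition matrix over an interval of ``dt`` years.

    Closed-form solution of the generator ``[[-c, c], [e, -e]]``:

        P(0->1) = c/(c+e) * (1 - E),   P(1->1) = (c + e*E)/(c+e),

    with ``E = exp(-(c+e) dt)``.  State 0 is absent, state 1 present.
    """
    if c <= 0 or e <= 0:
        raise ValueError("rates must be positive")
    if dt < 0:
        raise ValueError("dt must be non-negative")
    s = c + e
    E = np.exp(-s * dt)
    p01 = c / s * (1.0 - E)
    p11 = (c + e * E) / s
    return np.array([[1.0 - p01, p01], [1.0 - p11, p11]])


def count_transitions(series: OccupancySeries) -> TransitionCounts:
    """Pool consecutive-pair transitions of a series into per-dt buckets."""
    t = series.survey_times
    S = series.states
    counts = TransitionCounts()
    dts = np.diff(t)
    a = S[:, :-1]
    b = S[:, 1:]
    for dt in np.unique(dts):
        cols = np.isclose(dts, dt)
        aa = a[:, cols]
        bb = b[:, cols]
        n11 = int(((aa == 1) & (bb == 1)).sum())
        n10 = int(((aa == 1) & (bb == 0)).sum())
        n01 = int(((aa == 0) & (bb == 1)).sum())
        n00 = int(((aa == 0) & (bb == 0)).sum())
        counts.add(float(dt), (n00, n01, n10, n11))
    return counts


def _bucket_nll(counts4: np.ndarray, c, e, dt) -> np.ndarray:
    """NLL contribution of one dt bucket for (broadcastable) rates."""
    s = c + e
    E = np.exp(-s * dt)
    p01 = c / s * (1.0 - E)
    p11 = (c + e * E) / s
    probs = np.stack(
        [1.0 - p01, p01, 1.0 - p11, p11], axis=-1
    )  # order N00, N01, N10, N11
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.log(probs)
        bad = (counts4 > 0) & ~np.isfinite(logp)
        terms = np.where(counts4 > 0, -counts4 * logp, 0.0)
    out = terms.sum(axis=-1)
    return np.where(bad.any(axis=-1), np.inf, out)


def negative_log_likelihood(counts: TransitionCounts, c: float, e: float) -> float:
    """Negative log-likelihood of (c, e) given pooled transition counts.

    Conditions on each species' first observed state: the likelihood is the
    product over consecutive observation pairs of the matching
    ``transition_matrix`` entry, so no stationary initial term appears.
    A transition observed with probability zero yields ``+inf``.
    """
    if c <= 0 or e <= 0:
        raise ValueError("rates must be positive")
    total = 0.0
    for dt, n in counts.items():
        total += float(_bucket_nll(n, float(c), float(e), dt))
        if not np.isfinite(total):
            return float("inf")
    return total


def closed_form_rates(counts: TransitionCounts) -> RatePair:
    """Analytic ML rates for regular sampling (a single dt bucket).

    With empirical transition frequencies ``T01 = N01/(N00+N01)`` and
    ``T10 = N10/(N10+N11)``, the continuous-time rates satisfy

        c + e = -ln(1 - T01 - T10) / dt,   c = (c+e) * T01/(T01+T10).

    Raises if either frequency sits at a boundary (no colonisations or no
    extinctions observed) or if ``T01 + T10 >= 1`` (no embeddable
    continuous-time chain).
    """
    if len(counts) != 1:
        raise ValueError("closed form requires exactly one dt bucket")
    (dt, (n00, n01, n10, n11)), = counts.items()
    if n00 + n01 <= 0 or n10 + n11 <= 0:
        raise ValueError("need observations from both occupancy states")
    t01 = n01 / (n00 + n01)
    t10 = n10 / (n10 + n11)
    if t01 <= 0 or t10 <= 0:
        raise ValueError(
            "no colonisations observed" if t01 <= 0 else "no extinctions observed"
        )
    if t01 + t10 >= 1:
        raise ValueError("T01 + T10 >= 1: no valid continuous-time rates")
    s = -np.log(1.0 - t01 - t10) / dt
    c = s * t01 / (t01 + t10)
    e = s - c
    nll = negative_log_likelihood(counts, c, e)
    return RatePair(c=float(c), e=float(e), nll=nll, n_transitions=counts.n_transitions)


def _pooled_start(counts: TransitionCounts) -> np.ndarray:
    """Moment-style starting point on the log-rate scale."""
    n00, n01, n10, n11 = counts.totals()
    dts, mat = counts.as_arrays()
    mean_dt = float(np.average(dts, weights=mat.sum(axis=1)))
    t01 = (n01 + 0.5) / (n00 + n01 + 1.0)
    t10 = (n10 + 0.5) / (n10 + n11 + 1.0)
    if t01 + t10 < 1:
        s = -np.log(1.0 - t01 - t10) / mean_dt
    else:
        s = 1.0 / mean_dt
    c = max(s * t01 / (t01 + t10), RATE_MIN)
    e = max(s - c, RATE_MIN)
    return np.log([c, e])


def _minimise_multistart(fun, x0, bounds, n_starts, seed, jitter=0.5):
    rng = np.random.default_rng(seed)
    best = None
    starts = [np.asarray(x0, dtype=float)]
    starts += [x0 + rng.normal(0.0, jitter, size=len(x0)) for _ in range(n_starts - 1)]
    for start in starts:
        if bounds is not None:
            start = np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(
            fun,
            start,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    return best


def _numerical_hessian(fun, x, eps=1e-4) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = eps
            ej[j] = eps
            f_pp = fun(x + ei + ej)
            f_pm = fun(x + ei - ej)
            f_mp = fun(x - ei + ej)
            f_mm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (f_pp - f_pm - f_mp + f_mm) / (4.0 * eps * eps)
    return H


def fit_site_rates(
    series: OccupancySeries | TransitionCounts,
    rate_min: float = RATE_MIN,
    rate_max: float = RATE_MAX,
    n_starts: int = 5,
    seed: int = 2023,
) -> RatePair:
    """Maximum-likelihood (c, e) for one site (or one site x group subset).

    Optimisation runs on the log-rate scale with multi-start quasi-Newton
    jittered around an analytic starting point.  If the data contain no
    colonisation (0->1) or no extinction (1->0) events the affected rate is
    pinned at ``rate_min`` with a boundary flag and a warning; the other
    rate is still profiled out.
    """
    counts = series if isinstance(series, TransitionCounts) else count_transitions(series)
    n00, n01, n10, n11 = counts.totals()
    if n01 + n11 == 0:
        raise ValueError("all species absent throughout: rates unidentifiable")
    if n00 + n10 == 0:
        raise ValueError("all species present throughout: rates unidentifiable")

    log_bounds = (np.log(rate_min), np.log(rate_max))

    def nll_log(theta):
        return negative_log_likelihood(counts, np.exp(theta[0]), np.exp(theta[1]))

    flag = None
    if n01 == 0 or n10 == 0:
        # One transition type never observed: the matching rate's MLE sits
        # at 0, so pin it at rate_min and profile the other rate.
        flag = "no_colonisations" if n01 == 0 else "no_extinctions"
        warnings.warn(
            f"{flag} observed; rate pinned at {rate_min}", BoundaryRateWarning
        )
        fixed_idx = 0 if n01 == 0 else 1
        free_idx = 1 - fixed_idx

        def nll_1d(theta1):
            theta = np.empty(2)
            theta[fixed_idx] = log_bounds[0]
            theta[free_idx] = theta1[0]
            return nll_log(theta)

        res = _minimise_multistart(
            nll_1d, _pooled_start(counts)[[free_idx]], [log_bounds], n_starts, seed
        )
        theta = np.empty(2)
        theta[fixed_idx] = log_bounds[0]
        theta[free_idx] = res.x[0]
    else:
        x0 = _pooled_start(counts)
        res = _minimise_multistart(nll_log, x0, [log_bounds] * 2, n_starts, seed)
        theta = res.x
        at_bound = np.isclose(theta, log_bounds[0], atol=1e-6) | np.isclose(
            theta, log_bounds[1], atol=1e-6
        )
        if at_bound.any():
            which = "c" if at_bound[0] else "e"
            flag = f"rate_{which}_at_bound"
            warnings.warn(f"fitted {which} at boundary", BoundaryRateWarning)

    c, e = np.exp(theta)
    se = np.full(2, np.nan)
    if flag is None:
        H = _numerical_hessian(nll_log, theta)
        try:
            cov = np.linalg.inv(H)
            if np.all(np.diag(cov) > 0):
                se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            pass
    return RatePair(
        c=float(c),
        e=float(e),
        nll=float(res.fun),
        n_transitions=counts.n_transitions,
        boundary_flag=flag,
        se_log_c=float(se[0]),
        se_log_e=float(se[1]),
    )


def _joint_nll_factory(counts_list: list[TransitionCounts], x: np.ndarray):
    """Vectorised summed NLL over sites for the exponential-link model."""
    site_idx = []
    dts = []
    cmat = []
    for j, counts in enumerate(counts_list):
        for dt, n in counts.items():
            site_idx.append(j)
            dts.append(dt)
            cmat.append(n)
    site_idx = np.array(site_idx)
    dts = np.array(dts)
    cmat = np.array(cmat, dtype=float)
    xb = x[site_idx]

    def nll(beta):
        c = np.exp(beta[0] + beta[1] * xb)
        e = np.exp(beta[2] + beta[3] * xb)
        vals = _bucket_nll(cmat, c, e, dts)
        total = vals.sum()
        return total if np.isfinite(total) else 1e12

    return nll


def fit_covariate_model(
    series_list: list[OccupancySeries | TransitionCounts],
    x,
    covariate_name: str = "x",
    per_group: str | None = None,
    n_starts: int = 5,
    seed: int = 2023,
) -> CovariateRateModel:
    """Jointly fit c_j = exp(b0c + b1c x_j), e_j = exp(b0e + b1e x_j).

    Minimises the per-site negative log-likelihoods summed across sites.
    Standard errors are observed-information (finite-difference Hessian at
    the optimum).  Separate models should be fitted per explanatory
    variable; this function takes exactly one covariate.
    """
    if len(series_list) < 3:
        raise ValueError("need at least 3 sites")
    x = np.asarray(x, dtype=float)
    if x.size != len(series_list):
        raise ValueError("one covariate value per site required")
    if np.ptp(x) == 0:
        raise ValueError(f"covariate {covariate_name!r} is constant: slope unidentifiable")

    counts_list = [
        s if isinstance(s, TransitionCounts) else count_transitions(s)
        for s in series_list
    ]
    nll = _joint_nll_factory(counts_list, x)

    # Start from a regression of pooled per-site log-rates on x.
    log_c0, log_e0 = [], []
    for counts in counts_list:
        lc, le = _pooled_start(counts)
        log_c0.append(lc)
        log_e0.append(le)
    X = np.column_stack([np.ones_like(x), x])
    bc, *_ = np.linalg.lstsq(X, np.array(log_c0), rcond=None)
    be, *_ = np.linalg.lstsq(X, np.array(log_e0), rcond=None)
    x0 = np.concatenate([bc, be])

    res = _minimise_multistart(nll, x0, None, n_starts, seed, jitter=0.3)
    converged = bool(res.success) and np.isfinite(res.fun)
    if not converged:
        raise RuntimeError(
            f"covariate model for {covariate_name!r} failed to converge: {res.message}"
        )

    H = _numerical_hessian(nll, res.x)
    try:
        vcov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
    except np.linalg.LinAlgError:
        vcov = np.full((4, 4), np.nan)
        se = np.full(4, np.nan)

    b = res.x
    return CovariateRateModel(
        beta0_c=float(b[0]),
        beta1_c=float(b[1]),
        beta0_e=float(b[2]),
        beta1_e=float(b[3]),
        se=se,
        vcov=vcov,
        nll=float(res.fun),
        covariate_name=covariate_name,
        x=x,
        per_group=per_group,
        converged=converged,
    )
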