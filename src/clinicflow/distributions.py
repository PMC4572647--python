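"""Location-shifted service-time distributions, samplers, and fitting.

Service times in the clinic model follow a small family of location-shifted
("three-parameter") laws as reported by distribution-fitting software: a
non-negative location (minimum) plus a positive parametric variate.  Raw
parameters may be expressed in seconds, in which case the whole variate is
divided by 60 to yield minutes (``time_divisor = 60``).

Parameter conventions (first element is always the location/minimum):

========== =============================== =========================================
family      params                          variate
========== =============================== =========================================
triangular  (min, mode, max)                triangular on [min, max]
weibull3    (min, shape, scale)             min + Weibull(shape, scale)
gamma3      (min, shape, scale)             min + Gamma(shape, scale)
erlang3     (min, k, scale)                 min + Erlang(k, scale), integer k
lognormal3  (min, mu, sigma)                min + exp(Normal(mu, sigma))
loglogistic3 (min, shape, scale)            min + scale * (U/(1-U))**(1/shape)
pearson6_4  (min, beta, p, q)               min + beta * BetaPrime(p, q)
beta4       (min, max, p, q)                min + (max-min) * Beta(p, q)
========== =============================== =========================================

Maximum-likelihood fitting profiles the location on a grid strictly below the
sample minimum (location at or above the minimum has zero likelihood, and the
boundary is a well-known pathology for shifted laws).  Goodness-of-fit
p-values (Kolmogorov-Smirnov and Anderson-Darling) are computed with the
fitted parameters treated as known — a screening approximation that inflates
p-values slightly; ranking of candidate families is by the average of the two
p-values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import (
    ConfigurationError,
    DegenerateDataError,
    MomentUndefinedError,
    SampleSizeError,
)

__all__ = [
    "FAMILIES",
    "DistributionSpec",
    "FitResult",
    "fit",
    "rank_fits",
    "load_default_table",
]

FAMILIES = (
    "triangular",
    "weibull3",
    "gamma3",
    "erlang3",
    "lognormal3",
    "loglogistic3",
    "pearson6_4",
    "beta4",
)

_N_PARAMS = {f: 4 if f in ("pearson6_4", "beta4") else 3 for f in FAMILIES}

MIN_FIT_SAMPLES = 30


@dataclass(frozen=True)
class DistributionSpec:
    """A location-shifted service-time law.

    Parameters are on the *raw* scale (e.g. seconds); sampled values and
    moments are divided by ``time_divisor`` to yield minutes.
    """

    family: str
    params: tuple[float, ...]
    time_divisor: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"unknown distribution family {self.family!r}; "
                f"expected one of {FAMILIES}"
            )
        if len(self.params) != _N_PARAMS[self.family]:
            raise ConfigurationError(
                f"{self.family} takes {_N_PARAMS[self.family]} parameters, "
                f"got params={self.params}"
            )
        if self.time_divisor not in (1, 1.0, 60, 60.0):
            raise ConfigurationError(
                f"time_divisor must be 1 or 60, got {self.time_divisor}"
            )
        p = self.params
        if self.family == "triangular":
            a, m, b = p
            if not (a <= m <= b):
                raise ConfigurationError(
                    f"triangular requires min <= mode <= max, got params={p}"
                )
        elif self.family == "beta4":
            lo, hi, a, b = p
            if hi <= lo:
                raise ConfigurationError(f"beta4 requires max > min, got params={p}")
            if a <= 0 or b <= 0:
                raise ConfigurationError(
                    f"beta4 shape parameters must be > 0, got params={p}"
                )
        else:
            for i, v in enumerate(p[1:], start=1):
                if v <= 0:
                    raise ConfigurationError(
                        f"{self.family} parameter {i} (shape/scale) must be > 0, "
                        f"got params={p}"
                    )
            if self.family == "erlang3":
                k = p[1]
                if abs(k - round(k)) > 1e-9 or k < 1:
                    raise ConfigurationError(
                        f"erlang3 shape must be a positive integer, got {k}"
                    )

    # -- internals ---------------------------------------------------------

    @property
    def location(self) -> float:
        """Lower support bound on the raw scale."""
        return self.params[0]

    @property
    def _degenerate(self) -> bool:
        return self.family == "triangular" and self.params[0] == self.params[2]

    def _frozen(self):
        """Frozen scipy distribution on the raw (undivided) scale (cached:
        freezing a scipy distribution is expensive relative to sampling)."""
        fz = self.__dict__.get("_fz")
        if fz is None:
            fz = self._build_frozen()
            object.__setattr__(self, "_fz", fz)
        return fz

    def _build_frozen(self):
        f, p = self.family, self.params
        if f == "triangular":
            a, m, b = p
            return stats.triang((m - a) / (b - a), loc=a, scale=b - a)
        if f == "weibull3":
            return stats.weibull_min(p[1], loc=p[0], scale=p[2])
        if f in ("gamma3", "erlang3"):
            return stats.gamma(p[1], loc=p[0], scale=p[2])
        if f == "lognormal3":
            return stats.lognorm(p[2], loc=p[0], scale=math.exp(p[1]))
        if f == "loglogistic3":
            return stats.fisk(p[1], loc=p[0], scale=p[2])
        if f == "pearson6_4":
            return stats.betaprime(p[2], p[3], loc=p[0], scale=p[1])
        if f == "beta4":
            return stats.beta(p[2], p[3], loc=p[0], scale=p[1] - p[0])
        raise AssertionError(f)

    # -- public API --------------------------------------------------------

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw durations in minutes.  Reproducible given the generator state."""
        if self._degenerate:
            v = self.params[0]
            out = v if size is None else np.full(size, float(v))
            return out / self.time_divisor if self.time_divisor != 1 else out
        v = self._frozen().rvs(size=size, random_state=rng)
        return v / self.time_divisor

    def mean(self) -> float:
        """Closed-form mean in minutes; raises if the moment does not exist."""
        self._check_moment(order=1)
        if self._degenerate:
            return self.params[0] / self.time_divisor
        return float(self._frozen().mean()) / self.time_divisor

    def var(self) -> float:
        """Closed-form variance in minutes^2; raises if undefined."""
        self._check_moment(order=2)
        if self._degenerate:
            return 0.0
        return float(self._frozen().var()) / self.time_divisor**2

    def cdf(self, x) -> float:
        """CDF evaluated at ``x`` minutes (non-decreasing, 0 at location/divisor)."""
        if self._degenerate:
            return np.where(np.asarray(x) >= self.params[0] / self.time_divisor, 1.0, 0.0)
        return self._frozen().cdf(np.asarray(x) * self.time_divisor)

    def ppf(self, q) -> float:
        """Quantile function in minutes."""
        if self._degenerate:
            return self.params[0] / self.time_divisor
        return self._frozen().ppf(q) / self.time_divisor

    def pdf(self, x):
        """Density at ``x`` minutes."""
        if self._degenerate:
            raise MomentUndefinedError("degenerate law has no density")
        return self._frozen().pdf(np.asarray(x) * self.time_divisor) * self.time_divisor

    def _check_moment(self, order: int) -> None:
        f, p = self.family, self.params
        if f == "loglogistic3" and p[1] <= order:
            raise MomentUndefinedError(
                f"loglogistic3 moment of order {order} undefined for shape "
                f"{p[1]} <= {order}"
            )
        if f == "pearson6_4" and p[3] <= order:
            raise MomentUndefinedError(
                f"pearson6_4 moment of order {order} undefined for q "
                f"{p[3]} <= {order}"
            )

    def scaled(self, divisor: float) -> "DistributionSpec":
        return replace(self, time_divisor=divisor)


@dataclass
class FitResult:
    """One fitted family with goodness-of-fit summaries."""

    spec: DistributionSpec
    ks_p: float
    ad_p: float
    log_likelihood: float
    rank: int = 1
    converged: bool = True
    message: str = ""


# ---------------------------------------------------------------------------
# Anderson-Darling p-value, parameters-known case (Marsaglia & Marsaglia 2004
# short-series approximation of the asymptotic distribution).
# ---------------------------------------------------------------------------


def _ad_cdf(z: float) -> float:
    if z <= 0:
        return 0.0
    if z < 2.0:
        return (
            math.exp(-1.2337141 / z)
            / math.sqrt(z)
            * (2.00012 + (0.247105 - (0.0649821 - (0.0347962 - (0.011672 - 0.00168691 * z) * z) * z) * z) * z)
        )
    return math.exp(
        -math.exp(1.0776 - (2.30695 - (0.43424 - (0.082433 - (0.008056 - 0.0003146 * z) * z) * z) * z) * z)
    )


def _anderson_darling_p(x: np.ndarray, spec: DistributionSpec) -> float:
    n = len(x)
    u = np.clip(spec.cdf(np.sort(x)), 1e-12, 1 - 1e-12)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(u) + np.log1p(-u[::-1])))
    return 1.0 - _ad_cdf(float(a2))


def _ks_p(x: np.ndarray, spec: DistributionSpec) -> float:
    return float(stats.kstest(x, spec.cdf).pvalue)


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting with the location profiled on a grid
# ---------------------------------------------------------------------------


def _loc_grid(x: np.ndarray, n_grid: int) -> np.ndarray:
    """Candidate locations strictly below min(x), clamped at zero.

    The grid spans downward by twice the lower decile gap — wide enough to
    reach the true location of heavy-tailed shifted laws whose sample minimum
    sits well above it.
    """
    xmin = float(np.min(x))
    d = float(np.percentile(x, 10)) - xmin
    if d <= 0:
        d = max((float(np.max(x)) - xmin) / max(len(x), 2), 1e-6 * max(abs(xmin), 1.0))
    lo = max(0.0, xmin - 2.0 * d)
    hi = xmin - 1e-4 * d
    if hi <= lo:
        hi = xmin * (1 - 1e-9) if xmin > 0 else xmin - 1e-9
    return np.linspace(lo, hi, n_grid)


def _fit_tail(y: np.ndarray, family: str) -> tuple[tuple[float, ...], float]:
    """MLE of the non-location parameters for shifted data ``y = x - loc > 0``.

    Returns (tail params in spec order after the location, log-likelihood).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == "weibull3":
            c, _, s = stats.weibull_min.fit(y, floc=0)
            ll = float(np.sum(stats.weibull_min.logpdf(y, c, scale=s)))
            return (c, s), ll
        if family == "gamma3":
            a, _, s = stats.gamma.fit(y, floc=0)
            ll = float(np.sum(stats.gamma.logpdf(y, a, scale=s)))
            return (a, s), ll
        if family == "erlang3":
            a, _, _ = stats.gamma.fit(y, floc=0)
            k = max(1, int(round(a)))
            s = float(np.mean(y)) / k  # scale MLE given integer shape
            ll = float(np.sum(stats.gamma.logpdf(y, k, scale=s)))
            return (float(k), s), ll
        if family == "lognormal3":
            ly = np.log(y)
            mu, sigma = float(np.mean(ly)), float(np.std(ly))
            sigma = max(sigma, 1e-12)
            ll = float(np.sum(stats.lognorm.logpdf(y, sigma, scale=math.exp(mu))))
            return (mu, sigma), ll
        if family == "loglogistic3":
            c, _, s = stats.fisk.fit(y, floc=0)
            ll = float(np.sum(stats.fisk.logpdf(y, c, scale=s)))
            return (c, s), ll
        if family == "pearson6_4":
            p, q, _, s = stats.betaprime.fit(y, floc=0)
            ll = float(np.sum(stats.betaprime.logpdf(y, p, q, scale=s)))
            # spec order: (min, beta, p, q) — beta is the scale
            return (s, p, q), ll
        if family == "beta4":
            a, b, _, s = stats.beta.fit(y, floc=0)
            ll = float(np.sum(stats.beta.logpdf(y, a, b, scale=s)))
            # spec order: (min, max, p, q); max = loc + scale, filled by caller
            return (s, a, b), ll
    raise AssertionError(family)


def _assemble(family: str, loc: float, tail: tuple[float, ...]) -> DistributionSpec:
    if family == "beta4":
        scale, a, b = tail
        return DistributionSpec("beta4", (loc, loc + scale, a, b))
    return DistributionSpec(family, (loc, *tail))


def _fit_triangular(x: np.ndarray) -> tuple[DistributionSpec, float]:
    """Triangular MLE: endpoints from extreme-spacing extrapolation, mode by grid."""
    xs = np.sort(x)
    a = float(xs[0] - (xs[1] - xs[0]))
    b = float(xs[-1] + (xs[-1] - xs[-2]))
    modes = np.linspace(a + 1e-9, b - 1e-9, 201)
    c = (modes - a) / (b - a)
    ll = stats.triang.logpdf(x[:, None], c[None, :], loc=a, scale=b - a).sum(axis=0)
    best = int(np.argmax(ll))
    m = float(modes[best])
    return DistributionSpec("triangular", (a, m, b)), float(ll[best])


def fit(
    samples: Sequence[float],
    family: str,
    n_loc_grid: int = 16,
    refine: bool = True,
) -> FitResult:
    """Fit one family to positive durations by (profile) maximum likelihood.

    The location is profiled over a grid below the sample minimum; at each
    candidate the remaining parameters are estimated by MLE on the shifted
    data.  KS and AD p-values treat the fitted parameters as known.
    """
    x = np.asarray(samples, dtype=float)
    if family not in FAMILIES:
        raise ConfigurationError(f"unknown family {family!r}")
    if len(x) < MIN_FIT_SAMPLES:
        raise SampleSizeError(
            f"need at least {MIN_FIT_SAMPLES} samples to fit, got {len(x)}"
        )
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ConfigurationError("samples must be positive finite durations")
    if float(np.std(x)) == 0.0:
        raise DegenerateDataError("samples have zero variance; nothing to fit")

    if family == "triangular":
        spec, ll = _fit_triangular(x)
        return FitResult(spec, _ks_p(x, spec), _anderson_darling_p(x, spec), ll)

    def profile(locs: Iterable[float]):
        out = []
        for loc in locs:
            y = x - loc
            if np.any(y <= 0):
                continue
            try:
                tail, ll = _fit_tail(y, family)
            except Exception as exc:  # scipy optimizer failure at this location
                out.append((loc, None, -np.inf, str(exc)))
                continue
            if not np.isfinite(ll):
                continue
            out.append((loc, tail, ll, ""))
        return out

    results = profile(_loc_grid(x, n_loc_grid))
    ok = [r for r in results if r[1] is not None]
    if not ok:
        msg = "; ".join({r[3] for r in results if r[3]}) or "no admissible location"
        return FitResult(
            spec=_fallback_spec(family, x),
            ks_p=0.0,
            ad_p=0.0,
            log_likelihood=-np.inf,
            converged=False,
            message=f"fit did not converge: {msg}",
        )
    ok.sort(key=lambda r: r[2])
    loc, tail, ll, _ = ok[-1]
    if refine and len(ok) > 1:
        # one refinement pass between the best location's grid neighbours
        grid = sorted(r[0] for r in ok)
        i = grid.index(loc)
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        extra = [r for r in profile(np.linspace(lo, hi, 8)[1:-1]) if r[1] is not None]
        for r in extra:
            if r[2] > ll:
                loc, tail, ll, _ = r
    spec = _assemble(family, float(loc), tail)
    return FitResult(spec, _ks_p(x, spec), _anderson_darling_p(x, spec), ll)


def _fallback_spec(family: str, x: np.ndarray) -> DistributionSpec:
    """Placeholder spec carried by a non-converged FitResult (diagnostics only)."""
    lo, hi = float(np.min(x)), float(np.max(x))
    if family == "triangular":
        return DistributionSpec("triangular", (lo, (lo + hi) / 2, hi))
    if family == "beta4":
        return DistributionSpec("beta4", (0.0, hi, 1.0, 1.0))
    if family == "pearson6_4":
        return DistributionSpec("pearson6_4", (0.0, 1.0, 1.0, 3.0))
    if family == "erlang3":
        return DistributionSpec("erlang3", (0.0, 1.0, max(hi, 1.0)))
    if family == "lognormal3":
        return DistributionSpec("lognormal3", (0.0, math.log(max(hi, 1.0)), 1.0))
    return DistributionSpec(family, (0.0, 1.0, max(hi, 1.0)))


def rank_fits(samples: Sequence[float], families: Sequence[str]) -> list[FitResult]:
    """Fit each candidate family and rank by descending mean of (KS, AD) p-values.

    Failed or non-converged families are skipped with a warning.  Ties are
    broken by log-likelihood.  Returns fits with ``rank`` set to 1..k (rank 1
    is the best); an empty list if every candidate failed.
    """
    if len(families) < 1:
        raise ConfigurationError("need at least one candidate family")
    fits: list[FitResult] = []
    for fam in families:
        try:
            res = fit(samples, fam)
        except Exception as exc:
            warnings.warn(f"family {fam!r} failed to fit: {exc}", stacklevel=2)
            continue
        if not res.converged:
            warnings.warn(f"family {fam!r} did not converge: {res.message}", stacklevel=2)
            continue
        fits.append(res)
    if not fits:
        warnings.warn("all candidate families failed; empty ranking", stacklevel=2)
        return []
    fits.sort(key=lambda r: (-(r.ks_p + r.ad_p) / 2.0, -r.log_likelihood))
    for i, r in enumerate(fits, start=1):
        r.rank = i
    return fits


# ---------------------------------------------------------------------------
# Packaged default service-time table
# ---------------------------------------------------------------------------


def load_default_table() -> dict[tuple[str, str], DistributionSpec]:
    """Load the packaged (staff role, patient kind) -> law table.

    Keys are ``(role, kind)`` with kind in {"new", "return"}; roles are
    us_tech, check_in, nurse, provider_A..provider_E, lab, check_out.
    """
    text = (
        resources.files("clinicflow")
        .joinpath("data/service_time_distributions.csv")
        .read_text(encoding="utf-8")
    )
    return parse_table(text)


def parse_table(text: str) -> dict[tuple[str, str], DistributionSpec]:
    table: dict[tuple[str, str], DistributionSpec] = {}
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    header = [c.strip() for c in lines[0].split(",")]
    expected = ["role", "kind", "family", "params", "time_divisor"]
    if header[: len(expected)] != expected:
        raise ConfigurationError(
            f"distribution table header must start with {expected}, got {header}"
        )
    for ln in lines[1:]:
        role, kind, family, params, divisor = _split_table_row(ln)
        spec = DistributionSpec(
            family,
            tuple(float(v) for v in params.split(";")),
            time_divisor=float(divisor),
        )
        table[(role, kind)] = spec
    return table


def _split_table_row(ln: str) -> tuple[str, str, str, str, str]:
    parts = [c.strip() for c in ln.split(",")]
    if len(parts) != 5:
        raise ConfigurationError(f"malformed distribution table row: {ln!r}")
    return tuple(parts)  # type: ignore[return-value]


def format_table(table: dict[tuple[str, str], DistributionSpec]) -> str:
    rows = ["role,kind,family,params,time_divisor"]
    for (role, kind), spec in table.items():
        params = ";".join(repr(p) for p in spec.params)
        rows.append(f"{role},{kind},{spec.family},{params},{spec.time_divisor:g}")
    return "\n".join(rows) + "\n"
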