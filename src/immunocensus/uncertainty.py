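"""Lognormal multiplicative-error arithmetic.

The census treats every uncertain quantity as lognormally distributed and
summarises its uncertainty as a *multiplicative error factor* ``ferror``:
one sigma of the distribution spans ``value / ferror`` to ``value * ferror``.
The shape parameter of the underlying lognormal is ``s = ln(ferror)``.

This module provides the four primitives the rest of the pipeline is built
from: fitting a lognormal to a normally-described measurement (moment
matching), propagating error through products, combining independent
estimates by inverse-variance weighting in log space, and propagating error
through sums by parametric bootstrap with optional perfectly-correlated
error groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "LognormalEstimate",
    "BootstrapEstimate",
    "CorrelationGroup",
    "fit_lognormal_from_normal",
    "propagate_product",
    "bootstrap_sum",
    "inverse_variance_combine",
    "ci95",
    "one_sigma",
    "geometric_mean_estimate",
]

#: z value for the 95% analytic interval on the log scale.
Z95 = 1.96

#: Maximum coefficient of variation accepted by the normal-to-lognormal fit.
MAX_CV = 3.0

#: Relative tolerance under which two "exact" (ferror == 1) estimates are
#: considered consistent when combined.
EXACT_RTOL = 1e-9


@dataclass(frozen=True)
class LognormalEstimate:
    """A point value with multiplicative uncertainty.

    Parameters
    ----------
    value
        Geometric-scale point estimate (the median of the lognormal), in the
        units of the quantity.  ``value == 0`` is allowed only as an exact
        zero sentinel (``ferror == 1``), used e.g. for cell types absent from
        a tissue.
    ferror
        Multiplicative error factor, >= 1.  ``ferror == 1`` means the
        estimate is exact.
    """

    value: float
    ferror: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.value) or self.value < 0:
            raise ValueError(f"value must be finite and >= 0, got {self.value}")
        if not math.isfinite(self.ferror) or self.ferror < 1.0:
            raise ValueError(f"ferror must be finite and >= 1, got {self.ferror}")
        if self.value == 0 and self.ferror != 1.0:
            raise ValueError("a zero estimate must be exact (ferror == 1)")

    @property
    def s(self) -> float:
        """Shape parameter of the lognormal, ``ln(ferror)``."""
        return math.log(self.ferror)

    @property
    def is_exact(self) -> bool:
        return self.ferror == 1.0

    @property
    def mean(self) -> float:
        """Arithmetic mean of the fitted lognormal."""
        return self.value * math.exp(self.s**2 / 2)

    @property
    def sd(self) -> float:
        """Arithmetic standard deviation of the fitted lognormal."""
        s2 = self.s**2
        return self.mean * math.sqrt(math.expm1(s2))

    def scaled(self, c: float) -> "LognormalEstimate":
        """Multiply by an exact positive constant."""
        if c < 0:
            raise ValueError("scale factor must be >= 0")
        if c == 0 or self.value == 0:
            return LognormalEstimate(0.0)
        return LognormalEstimate(self.value * c, self.ferror)

    def widened(self, factor: float) -> "LognormalEstimate":
        """Inflate the error factor by an extra multiplicative penalty."""
        if factor < 1:
            raise ValueError("penalty factor must be >= 1")
        if self.value == 0:
            return self
        return LognormalEstimate(self.value, self.ferror * factor)


@dataclass(frozen=True)
class BootstrapEstimate(LognormalEstimate):
    """A lognormal estimate with percentile bootstrap summaries attached."""

    ci_low: float = 0.0
    ci_median: float = 0.0
    ci_high: float = 0.0
    n_draws: int = 0


@dataclass(frozen=True)
class CorrelationGroup:
    """Estimates whose errors are resampled with one shared deviate.

    Used for extrapolated densities that were filled from the same evidence
    source: their errors are treated as perfectly correlated, which widens
    the uncertainty of any sum they enter.
    """

    group_id: str
    member_ids: frozenset[str]

    def __init__(self, group_id: str, member_ids: Iterable[str]):
        members = frozenset(member_ids)
        if not members:
            raise ValueError("a correlation group needs at least one member")
        object.__setattr__(self, "group_id", group_id)
        object.__setattr__(self, "member_ids", members)


def fit_lognormal_from_normal(mean: float, se: float) -> LognormalEstimate:
    """Fit a lognormal to a normally-described measurement by moment matching.

    The fitted lognormal has the same arithmetic mean and variance as the
    normal ``N(mean, se^2)``:  ``s^2 = ln(1 + (se/mean)^2)`` and the reported
    point value is the median ``mean * exp(-s^2 / 2)``.

    Raises
    ------
    ValueError
        If ``mean <= 0``, ``se < 0``, or the coefficient of variation
        ``se/mean`` exceeds 3 (the normal is then too poorly matched by any
        lognormal for the fit to be meaningful).
    """
    if mean <= 0:
        raise ValueError(f"mean must be positive, got {mean}")
    if se < 0:
        raise ValueError(f"se must be >= 0, got {se}")
    cv = se / mean
    if cv > MAX_CV:
        raise ValueError(f"coefficient of variation {cv:.3g} > {MAX_CV}: ill-posed fit")
    s2 = math.log1p(cv**2)
    return LognormalEstimate(mean * math.exp(-s2 / 2), math.exp(math.sqrt(s2)))


def propagate_product(a: LognormalEstimate, b: LognormalEstimate) -> LognormalEstimate:
    """Product of two lognormal quantities.

    The product of two lognormals is lognormal with shape parameter equal to
    the root-sum-of-squares of the inputs' shape parameters:
    ``f = exp(sqrt(ln^2 f_a + ln^2 f_b))``.
    """
    value = a.value * b.value
    if value == 0:
        return LognormalEstimate(0.0)
    s = math.hypot(a.s, b.s)
    return LognormalEstimate(value, math.exp(s))


def ci95(e: LognormalEstimate) -> tuple[float, float]:
    """Analytic 95% interval, ``(value * f^-1.96, value * f^+1.96)``."""
    return (e.value * e.ferror**-Z95, e.value * e.ferror**Z95)


def one_sigma(e: LognormalEstimate) -> tuple[float, float]:
    """One-sigma interval, ``(value / ferror, value * ferror)``."""
    return (e.value / e.ferror, e.value * e.ferror)


def _correlation_units(
    ids: Sequence[str], groups: Sequence[CorrelationGroup]
) -> list[int]:
    """Map each estimate to a resampling unit; grouped members share a unit.

    Units are numbered by first appearance so that a single estimate and a
    fully-correlated group of estimates draw identical deviate streams.
    """
    group_of: dict[str, str] = {}
    for g in groups:
        for m in g.member_ids:
            if m in group_of and group_of[m] != g.group_id:
                raise ValueError(f"estimate {m!r} belongs to more than one group")
            group_of[m] = g.group_id
    unit_index: dict[str, int] = {}
    units: list[int] = []
    for i in ids:
        key = group_of.get(i, f"__solo__{i}")
        if key not in unit_index:
            unit_index[key] = len(unit_index)
        units.append(unit_index[key])
    return units


def bootstrap_sum(
    estimates: Sequence[LognormalEstimate],
    groups: Sequence[CorrelationGroup] = (),
    n_draws: int = 1000,
    seed: int | None = None,
    ids: Sequence[str] | None = None,
) -> BootstrapEstimate:
    """Sum of lognormal quantities with bootstrap uncertainty.

    The point value is the sum of the member point values.  Uncertainty comes
    from ``n_draws`` parametric resamples in which every estimate is drawn
    from its own lognormal; members of one :class:`CorrelationGroup` share a
    single standard-normal deviate per draw (perfect correlation).  The
    reported interval is the 2.5/97.5 percentile spread of the draws, and a
    representative ``ferror`` is fitted as ``exp(sd(ln draws))``.

    ``seed`` is required: there is no implicit global randomness.
    """
    if len(estimates) == 0:
        raise ValueError("bootstrap_sum needs at least one estimate")
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    if seed is None:
        raise ValueError("an explicit seed is required")
    if ids is None:
        ids = [str(i) for i in range(len(estimates))]
    if len(ids) != len(estimates):
        raise ValueError("ids and estimates must have equal length")

    point = float(sum(e.value for e in estimates))
    units = _correlation_units(ids, groups)
    n_units = max(units) + 1

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, n_units))
    values = np.array([e.value for e in estimates])
    shapes = np.array([e.s for e in estimates])
    draws = np.zeros(n_draws)
    for j, (v, s) in enumerate(zip(values, shapes)):
        if v == 0:
            continue
        draws += v * np.exp(s * z[:, units[j]])

    lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
    positive = draws[draws > 0]
    if point > 0 and positive.size > 1:
        s_fit = float(np.std(np.log(positive), ddof=1))
    else:
        s_fit = 0.0
    return BootstrapEstimate(
        value=point,
        ferror=math.exp(s_fit),
        ci_low=float(lo),
        ci_median=float(med),
        ci_high=float(hi),
        n_draws=n_draws,
    )


def inverse_variance_combine(
    estimates: Sequence[LognormalEstimate],
    weight_multipliers: Sequence[float] | None = None,
) -> LognormalEstimate:
    """Fixed-effect combination of estimates in log space.

    Weights are ``w_i = m_i / ln^2(f_i)`` (``m_i`` an optional positive
    multiplier, default 1); the combined value is the weighted geometric
    mean and the combined shape parameter is ``sqrt(1 / sum w)``.

    An exact estimate (``ferror == 1``) has infinite weight and dominates
    absolutely; two disagreeing exact estimates raise ``ValueError``.
    """
    if len(estimates) == 0:
        raise ValueError("need at least one estimate")
    if weight_multipliers is None:
        weight_multipliers = [1.0] * len(estimates)
    if len(weight_multipliers) != len(estimates):
        raise ValueError("weight_multipliers length mismatch")
    if any(m <= 0 for m in weight_multipliers):
        raise ValueError("weight multipliers must be positive")
    if any(e.value <= 0 for e in estimates):
        raise ValueError("inverse-variance combination requires positive values")

    exact = [e for e in estimates if e.is_exact]
    if exact:
        ref = exact[0].value
        for e in exact[1:]:
            if abs(e.value - ref) > EXACT_RTOL * ref:
                raise ValueError(
                    f"conflicting exact estimates: {ref} vs {e.value}"
                )
        return LognormalEstimate(ref, 1.0)

    if len(estimates) == 1:
        return estimates[0]

    w = np.array([m / e.s**2 for e, m in zip(estimates, weight_multipliers)])
    logs = np.array([math.log(e.value) for e in estimates])
    total = w.sum()
    value = math.exp(float(np.dot(w, logs) / total))
    s = math.sqrt(1.0 / total)
    return LognormalEstimate(value, math.exp(s))


def geometric_mean_estimate(
    estimates: Sequence[LognormalEstimate],
    se_floor: float = 0.0,
) -> LognormalEstimate:
    """Unweighted geometric mean of estimates with spread folded into ferror.

    The combined shape parameter pools the mean per-record shape variance
    (shrunk by n, as for an average) with the between-record log variance
    contribution to the standard error of the geometric mean:
    ``s^2 = mean(s_i^2)/n + var(ln v)/n``.  ``se_floor`` imposes a minimum
    on the combined shape parameter.

    Zero-valued members are rejected: a geometric mean over zeros is not
    defined, and callers are expected to filter sentinels first.
    """
    if len(estimates) == 0:
        raise ValueError("need at least one estimate")
    if any(e.value <= 0 for e in estimates):
        raise ValueError("geometric mean requires positive values")
    n = len(estimates)
    logs = np.array([math.log(e.value) for e in estimates])
    value = math.exp(float(logs.mean()))
    within = float(np.mean([e.s**2 for e in estimates])) / n
    between = float(np.var(logs, ddof=1)) / n if n > 1 else 0.0
    s = max(math.sqrt(within + between), se_floor)
    return LognormalEstimate(value, math.exp(s))
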