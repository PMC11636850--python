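"""Krippendorff's alpha from the rates-by-units tally.

The coefficient is ``alpha = 1 - Do/De`` where ``Do`` is the disagreement
observed among the ratings and ``De`` the disagreement expected were the
same ratings assigned to units at random.  Both are computed from the
rates-by-units matrix: ``n_uc`` counts how many raters assigned category
``c`` to unit ``u``; units carrying fewer than two ratings contribute no
pairable information and are excluded from the marginals ``n_c`` and the
grand total ``n``.  With ``D`` the metric-specific matrix of squared
category differences,

    Do = (n - 1) * sum_u  [ sum_{c<k} n_uc n_uk D_ck ] / (n_u - 1)
    De = sum_{c<k} n_c n_k D_ck

where the outer sums run over units with ``n_u >= 2``.  The four metrics
differ only in ``D``: nominal (0/1 mismatch), ordinal (squared sum of
marginals between the two ranks), interval (squared value difference),
and ratio (squared relative difference, requiring non-negative rates).

``pairwise_alpha_oracle`` recomputes alpha by brute-force enumeration of
rating pairs and exists for cross-validation in test suites; it shares
no code with :func:`compute_alpha` beyond the category-difference
definitions written out longhand.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import DegenerateDataError, MetricDomainError, UndefinedAlphaError
from .io import DataSummary, ReliabilityMatrix, summarize_matrix

#: The four admissible measurement scales.
METRICS = ("nominal", "ordinal", "interval", "ratio")


@dataclass(frozen=True)
class CategorySet:
    """Distinct pairable rate values, sorted ascending.

    The ordinal metric ranks categories by this numeric order; the
    interval and ratio metrics use the values themselves.
    """

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise DegenerateDataError("category set is empty")
        if any(b <= a for a, b in zip(self.values, self.values[1:])):
            raise ValueError("categories must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    def index(self, value: float) -> int:
        return self.values.index(value)

    @classmethod
    def from_values(cls, values: Iterable[float]) -> "CategorySet":
        return cls(tuple(sorted(set(values))))


@dataclass(frozen=True)
class RatesByUnits:
    """Tally of rate assignments per unit and the pairable marginals.

    ``n_uc[u, c]`` counts raters assigning category ``c`` to unit ``u``
    (all units, pairable or not); ``n_u[u]`` is the row total.  The
    category marginals ``n_c`` and grand total ``n_total`` pool only
    units with at least two ratings.
    """

    categories: CategorySet
    n_uc: np.ndarray
    n_u: np.ndarray
    n_c: np.ndarray
    n_total: int

    def __post_init__(self) -> None:
        if not np.array_equal(self.n_uc.sum(axis=1), self.n_u):
            raise ValueError("unit totals do not match the tally rows")
        valid = self.n_u >= 2
        if not np.array_equal(self.n_uc[valid].sum(axis=0), self.n_c):
            raise ValueError("marginals do not match the tally of valid units")
        if self.n_c.sum() != self.n_total:
            raise ValueError("grand total does not match the marginals")


@dataclass(frozen=True)
class AlphaResult:
    """The coefficient together with its disagreement terms.

    ``alpha`` is kept at full precision; user-facing layers round to
    three decimals.  ``do_term / de_term`` reproduce ``1 - alpha``
    exactly, and ``de_term`` is strictly positive (degenerate inputs are
    rejected with a typed error before this object is built).
    """

    alpha: float
    metric: str
    do_term: float
    de_term: float
    summary: DataSummary
    rates_by_units: RatesByUnits


def extract_categories(m: ReliabilityMatrix) -> CategorySet:
    """Distinct rate values among pairable ratings, sorted ascending.

    Ratings in units with fewer than two ratings are unpairable and do
    not define categories.
    """
    pairable: list[float] = []
    for row in m.cells:
        present = [v for v in row if v is not None]
        if len(present) >= 2:
            pairable.extend(present)
    if not pairable:
        raise DegenerateDataError(
            "no pairable ratings: every unit has fewer than two ratings"
        )
    return CategorySet.from_values(pairable)


def build_rates_by_units(m: ReliabilityMatrix, cats: CategorySet) -> RatesByUnits:
    """Tally the reliability matrix into per-unit category counts."""
    index = {v: i for i, v in enumerate(cats.values)}
    n_uc = np.zeros((m.n_items, len(cats)), dtype=np.int64)
    for u, row in enumerate(m.cells):
        for v in row:
            if v is None:
                continue
            i = index.get(v)
            if i is None:
                if sum(x is not None for x in row) >= 2:
                    raise ValueError(f"rate {v!r} not covered by the category set")
                continue  # unpairable rating outside the category universe
            n_uc[u, i] += 1
    n_u = n_uc.sum(axis=1)
    valid = n_u >= 2
    n_c = n_uc[valid].sum(axis=0)
    return RatesByUnits(
        categories=cats,
        n_uc=n_uc,
        n_u=n_u,
        n_c=n_c,
        n_total=int(n_c.sum()),
    )


def delta_squared(metric: str, c: float, k: float, marginals: RatesByUnits | None = None) -> float:
    """Squared difference between categories ``c`` and ``k`` under a metric.

    The ordinal metric needs the pairable marginals (the squared
    difference is the count of ratings lying between the two ranks); the
    other metrics ignore them.  Symmetric in ``(c, k)`` and zero on the
    diagonal for every metric.
    """
    _check_metric(metric)
    if metric == "nominal":
        return 0.0 if c == k else 1.0
    if metric == "interval":
        return float((c - k) ** 2)
    if metric == "ratio":
        if c < 0 or k < 0:
            raise MetricDomainError(
                "ratio metric requires non-negative rates (a true zero point)"
            )
        if c == k:
            return 0.0
        return float(((c - k) / (c + k)) ** 2)
    # ordinal
    if marginals is None:
        raise ValueError("ordinal difference requires the pairable marginals")
    cats = marginals.categories
    ci, ki = cats.index(c), cats.index(k)
    lo, hi = min(ci, ki), max(ci, ki)
    between = float(marginals.n_c[lo : hi + 1].sum())
    return (between - (marginals.n_c[ci] + marginals.n_c[ki]) / 2.0) ** 2


def compute_alpha(m: ReliabilityMatrix, metric: str) -> AlphaResult:
    """Compute Krippendorff's alpha for a reliability matrix.

    Raises :class:`DegenerateDataError` when no unit carries two
    ratings, and :class:`UndefinedAlphaError` when the expected
    disagreement is zero (all pairable ratings identical), since
    ``1 - Do/De`` is then an indeterminate form rather than evidence of
    agreement.
    """
    _check_metric(metric)
    summary = summarize_matrix(m)
    cats = extract_categories(m)
    rbu = build_rates_by_units(m, cats)
    dmat = _delta_matrix(metric, rbu)

    valid = rbu.n_u >= 2
    nuc = rbu.n_uc[valid].astype(np.float64)
    n_u = rbu.n_u[valid].astype(np.float64)
    n_c = rbu.n_c.astype(np.float64)
    n_total = float(rbu.n_total)

    # sum_{c<k} x_c x_k D_ck == x' D x / 2 because D is symmetric with
    # zero diagonal.
    unit_pairs = np.einsum("uc,ck,uk->u", nuc, dmat, nuc) / 2.0
    do_term = (n_total - 1.0) * float(np.sum(unit_pairs / (n_u - 1.0)))
    de_term = float(n_c @ dmat @ n_c) / 2.0

    if de_term == 0.0:
        uniform = do_term == 0.0
        msg = (
            "alpha is indeterminate: every pairable rating is the single "
            "category {0!r} (perfect uniformity, no expected disagreement)"
            .format(cats.values[0])
            if uniform
            else "alpha is indeterminate: expected disagreement is zero"
        )
        raise UndefinedAlphaError(msg, summary=summary, uniform=uniform)

    alpha = 1.0 - do_term / de_term
    return AlphaResult(
        alpha=alpha,
        metric=metric,
        do_term=do_term,
        de_term=de_term,
        summary=summary,
        rates_by_units=rbu,
    )


def pairwise_alpha_oracle(m: ReliabilityMatrix, metric: str) -> float:
    """Alpha by explicit enumeration of rating pairs (test oracle).

    Observed disagreement averages the squared difference over all
    ordered pairs of ratings within each pairable unit, weighting each
    unit by its rating count; expected disagreement averages over all
    ordered pairs of pairable ratings pooled across units.  Everything
    is enumerated longhand -- no tally matrices -- so agreement with
    :func:`compute_alpha` is a genuine cross-check.
    """
    _check_metric(metric)
    units = []
    for row in m.cells:
        present = [v for v in row if v is not None]
        if len(present) >= 2:
            units.append(present)
    if not units:
        raise DegenerateDataError(
            "no pairable ratings: every unit has fewer than two ratings"
        )
    pooled = [v for unit in units for v in unit]
    n = len(pooled)
    counts = Counter(pooled)

    def d2(a: float, b: float) -> float:
        if metric == "nominal":
            return 0.0 if a == b else 1.0
        if metric == "interval":
            return float((a - b) ** 2)
        if metric == "ratio":
            if a < 0 or b < 0:
                raise MetricDomainError(
                    "ratio metric requires non-negative rates (a true zero point)"
                )
            return 0.0 if a == b else float(((a - b) / (a + b)) ** 2)
        lo, hi = min(a, b), max(a, b)
        between = sum(cnt for v, cnt in counts.items() if lo <= v <= hi)
        return (between - (counts[a] + counts[b]) / 2.0) ** 2

    do = 0.0
    for unit in units:
        nu = len(unit)
        pair_sum = sum(
            d2(unit[i], unit[j])
            for i in range(nu)
            for j in range(nu)
            if i != j
        )
        do += nu * (pair_sum / (nu * (nu - 1)))
    do /= n

    de = sum(
        d2(pooled[i], pooled[j])
        for i in range(n)
        for j in range(n)
        if i != j
    ) / (n * (n - 1.0))

    if de == 0.0:
        raise UndefinedAlphaError(
            "alpha is indeterminate: expected disagreement is zero",
            uniform=(do == 0.0),
        )
    return 1.0 - do / de


def _delta_matrix(metric: str, rbu: RatesByUnits) -> np.ndarray:
    """The full K x K matrix of squared category differences."""
    vals = np.asarray(rbu.categories.values, dtype=np.float64)
    k = len(vals)
    if metric == "nominal":
        return 1.0 - np.eye(k)
    if metric == "interval":
        return (vals[:, None] - vals[None, :]) ** 2
    if metric == "ratio":
        if np.any(vals < 0):
            raise MetricDomainError(
                "ratio metric requires non-negative rates (a true zero point)"
            )
        diff = vals[:, None] - vals[None, :]
        tot = vals[:, None] + vals[None, :]
        out = np.zeros((k, k))
        off = ~np.eye(k, dtype=bool)
        out[off] = (diff[off] / tot[off]) ** 2
        return out
    # ordinal: cumulative marginal sums between the two ranks
    n_c = rbu.n_c.astype(np.float64)
    cum = np.concatenate(([0.0], np.cumsum(n_c)))
    i = np.arange(k)
    lo = np.minimum(i[:, None], i[None, :])
    hi = np.maximum(i[:, None], i[None, :])
    between = cum[hi + 1] - cum[lo]
    return (between - (n_c[:, None] + n_c[None, :]) / 2.0) ** 2


def _check_metric(metric: str) -> None:
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
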