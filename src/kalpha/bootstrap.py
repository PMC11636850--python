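"""Bootstrap confidence intervals for alpha by resampling units.

Replicate matrices are formed by drawing whole item rows (with their
missing-value pattern) uniformly with replacement, keeping the original
number of rows; raters are never resampled.  Alpha is recomputed on each
replicate with that replicate's own observed categories and marginals,
and the interval is the pair of equal-tail empirical quantiles of the
replicate distribution (linear interpolation between order statistics,
so bounds are bit-reproducible for a given seed).

A replicate can be degenerate: a resample made entirely of
identically-rated rows has zero expected disagreement, and a resample of
rows carrying fewer than two ratings has no pairable data at all.  Such
replicates are maximal-agreement evidence and are scored alpha = 1;
they are counted in ``n_degenerate`` so callers can judge how often the
tail was touched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import compute_alpha
from .errors import CIUndefinedError, DegenerateDataError, UndefinedAlphaError
from .io import ReliabilityMatrix

#: Confidence levels offered by the point-and-click interface.
UI_LEVELS = (0.90, 0.95, 0.99)
#: Bootstrap population sizes offered by the point-and-click interface.
UI_BOOT_SIZES = (200, 400, 600, 1000)


@dataclass(frozen=True)
class ConfidenceInterval:
    """Equal-tail percentile bootstrap interval for alpha.

    ``lower`` and ``upper`` are the (1-level)/2 and 1-(1-level)/2
    empirical quantiles of ``replicates``; the same seed always yields
    the same bounds.
    """

    level: float
    n_boot: int
    lower: float
    upper: float
    seed: int
    n_degenerate: int
    replicates: np.ndarray = field(repr=False, compare=False)


def bootstrap_alpha(
    m: ReliabilityMatrix,
    metric: str,
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
) -> ConfidenceInterval:
    """Percentile bootstrap CI for alpha, resampling item rows.

    ``level`` and ``n_boot`` may take any admissible value; a warning is
    emitted when they fall outside the menus of the interactive tool
    (levels 90/95/99 %, sizes 200/400/600/1000) as a nudge towards
    comparable reporting.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")
    if not any(abs(level - ui) < 1e-12 for ui in UI_LEVELS):
        warnings.warn(
            f"confidence level {level} is outside the conventional menu "
            f"{UI_LEVELS}", stacklevel=2,
        )
    if n_boot not in UI_BOOT_SIZES:
        warnings.warn(
            f"bootstrap size {n_boot} is outside the conventional menu "
            f"{UI_BOOT_SIZES}", stacklevel=2,
        )

    compute_alpha(m, metric)  # validate the original input up front
    rows = m.cells
    n_items = m.n_items
    rng = np.random.default_rng(seed)

    alphas = np.empty(n_boot)
    n_degenerate = 0
    for b in range(n_boot):
        idx = rng.integers(0, n_items, size=n_items)
        replicate = ReliabilityMatrix(tuple(rows[i] for i in idx))
        try:
            alphas[b] = compute_alpha(replicate, metric).alpha
        except UndefinedAlphaError as err:
            if not err.uniform:
                raise  # unreachable for the implemented metrics
            alphas[b] = 1.0
            n_degenerate += 1
        except DegenerateDataError:
            alphas[b] = 1.0
            n_degenerate += 1

    if n_degenerate == n_boot:
        raise CIUndefinedError(
            "every bootstrap replicate was degenerate; no interval exists"
        )

    tail = (1.0 - level) / 2.0
    lower, upper = np.quantile(alphas, [tail, 1.0 - tail])
    return ConfidenceInterval(
        level=level,
        n_boot=n_boot,
        lower=float(lower),
        upper=float(upper),
        seed=seed,
        n_degenerate=n_degenerate,
        replicates=alphas,
    )
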