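"""Synthetic rating panels with controlled agreement and missingness.

The generator follows a latent-truth copy model: each item carries a
latent true category drawn uniformly; each rater independently reports
that category with probability ``agreement`` and otherwise an
independent uniform draw over the categories; finally each cell is
masked missing with probability ``missing_rate``, independently of
everything else (missingness completely at random).  The model gives a
monotone link between ``agreement`` and expected alpha — chance-level
raters (``agreement = 0``) yield alpha near zero, perfect copyists
(``agreement = 1``) yield alpha = 1 — which is exactly what reliability
tests need.  It deliberately omits rater-specific bias, ordinal-adjacent
confusion, and informative missingness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CategorySet
from .io import ReliabilityMatrix, write_matrix


@dataclass(frozen=True)
class PanelSpec:
    """Parameters of a synthetic rater panel.

    ``agreement`` is the probability a rater reports the item's latent
    true category; ``missing_rate`` is the per-cell masking probability.
    """

    n_items: int
    n_raters: int
    categories: CategorySet
    agreement: float
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ValueError("n_items must be >= 1")
        if self.n_raters < 2:
            raise ValueError("n_raters must be >= 2")
        if len(self.categories) < 2:
            raise ValueError("need at least 2 categories")
        if not 0.0 <= self.agreement <= 1.0:
            raise ValueError("agreement must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


def generate_ratings(spec: PanelSpec) -> ReliabilityMatrix:
    """Draw one rating panel from the latent-truth copy model.

    Identical spec (including seed) always yields the identical matrix.
    """
    rng = np.random.default_rng(spec.seed)
    cats = np.asarray(spec.categories.values)
    shape = (spec.n_items, spec.n_raters)

    latent = rng.integers(0, len(cats), size=spec.n_items)
    copy_truth = rng.random(shape) < spec.agreement
    noise = rng.integers(0, len(cats), size=shape)
    idx = np.where(copy_truth, latent[:, None], noise)
    missing = rng.random(shape) < spec.missing_rate

    rows = []
    for u in range(spec.n_items):
        rows.append(tuple(
            None if missing[u, r] else cats[idx[u, r]].item()
            for r in range(spec.n_raters)
        ))
    return ReliabilityMatrix(tuple(rows))


def write_fixture(m: ReliabilityMatrix, delimiter: str = ",") -> str:
    """Serialize a matrix in the standard input format (``NA`` tokens)."""
    return write_matrix(m, delimiter)


#: 12-item, 4-rater nominal worked example adapted from the reliability
#: data illustrations in Krippendorff's *Content Analysis* (4th ed.);
#: 7 missing cells, 5 categories, nominal alpha 0.743.
WORKED_EXAMPLE_CSV = """\
1,1,NA,1
2,2,3,2
3,3,3,3
3,3,3,3
2,2,2,2
1,2,3,4
4,4,4,4
1,1,2,1
2,2,2,2
NA,5,5,5
NA,NA,1,1
NA,3,NA,NA
"""


def worked_example() -> ReliabilityMatrix:
    """The bundled 12 x 4 nominal worked example (alpha = 0.743)."""
    from .io import parse_reliability_csv

    return parse_reliability_csv(WORKED_EXAMPLE_CSV)
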