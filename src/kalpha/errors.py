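"""Typed exception hierarchy.

Lexical problems with an input file raise :class:`FormatError`; semantic
problems with the data (nothing pairable, an indeterminate coefficient, a
metric applied outside its domain) raise the dedicated subclasses of
:class:`KAlphaError` so callers can distinguish "fix your file" from
"your data cannot support this statistic".
"""

from __future__ import annotations


class KAlphaError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(KAlphaError, ValueError):
    """The input text violates the reliability-data file contract."""


class DegenerateDataError(KAlphaError, ValueError):
    """No pairable ratings: every unit has fewer than two ratings."""


class UndefinedAlphaError(KAlphaError, ArithmeticError):
    """Expected disagreement is zero, so alpha = 1 - Do/De is indeterminate.

    Carries the data summary and a flag saying whether observed
    disagreement is also zero (perfect uniformity: every pairable rating
    is the same single category).
    """

    def __init__(self, message: str, summary=None, uniform: bool = False):
        super().__init__(message)
        self.summary = summary
        self.uniform = uniform


class MetricDomainError(KAlphaError, ValueError):
    """The category values lie outside the chosen metric's domain."""


class CIUndefinedError(KAlphaError, ArithmeticError):
    """Every bootstrap replicate was degenerate; no interval exists."""
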