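"""Exception hierarchy.

Schema problems (malformed input files, bad values) and degenerate-data
problems (e.g. a training cohort missing a FISH class) are kept distinct so
the command-line layer can map them to different exit codes.
"""

from __future__ import annotations


class MetgateError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MetgateError):
    """Malformed input: bad header, non-numeric cell, out-of-range value.

    Messages carry row/column coordinates where applicable.
    """


class MissingGeneError(MetgateError):
    """A gene required by a gate model is absent from a copy-number profile."""

    def __init__(self, genes):
        self.genes = tuple(genes)
        super().__init__(f"profile is missing required gene(s): {', '.join(self.genes)}")


class UndefinedRatioError(MetgateError):
    """A copy-number or signal-count ratio has a non-positive denominator."""


class DegenerateLabelsError(MetgateError):
    """A label vector needed for threshold fitting contains only one class."""


class UndefinedMetric(float):
    """Sentinel for a metric whose denominator is zero (carries NaN value).

    It is a float (NaN) so downstream arithmetic propagates naturally, but it
    can be recognised with ``isinstance`` and is falsy in boolean context.
    """

    def __new__(cls):
        return super().__new__(cls, float("nan"))

    def __bool__(self) -> bool:
        return False

    def __repr__(self) -> str:
        return "UndefinedMetric()"
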