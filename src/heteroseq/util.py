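"""Shared helpers: error types, decimal rounding, percentage formatting."""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal

logger = logging.getLogger("heteroseq")


class HeteroseqError(Exception):
    """Base class for package errors."""


class ConfigError(HeteroseqError):
    """Invalid configuration value."""


class DataError(HeteroseqError):
    """Input data violates a structural precondition."""


class ParseError(HeteroseqError):
    """A file could not be parsed; message carries the offending row."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` half-up to ``ndigits`` decimals.

    Published tables round 0.5 away from zero, so Python's banker's
    rounding cannot be used to reproduce them.  The value is passed
    through ``repr`` so that a number printed as e.g. 2.915 behaves as
    the decimal 2.915 rather than its binary approximation.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(k: float, n: float, ndigits: int = 1) -> float:
    """``100 * k / n`` rounded half-up, as printed in summary sentences."""
    if n == 0:
        raise DataError("percentage undefined for zero denominator")
    return round_half_up(100.0 * k / n, ndigits)
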