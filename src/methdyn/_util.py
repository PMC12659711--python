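"""Shared helpers: errors, logging, coordinate conventions.

Internal coordinates are 0-based half-open throughout the package; every
on-disk 1-based format (CX reports, GFF3) is converted at the I/O boundary.
BED output is natively 0-based half-open.
"""

from __future__ import annotations

import logging

logger = logging.getLogger("methdyn")

CONTEXTS = ("CpG", "CHG", "CHH")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class MethdynError(Exception):
    """Base class for package errors."""


class ValidationError(MethdynError):
    """Raised when an input file or table violates its contract."""


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]
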