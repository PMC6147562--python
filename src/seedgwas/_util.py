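"""Shared plumbing: logging, seeded substreams, half-up rounding, errors."""

from __future__ import annotations

import decimal
import logging
import zlib

import numpy as np

logger = logging.getLogger("seedgwas")


class UserInputError(ValueError):
    """Bad user input (missing file, empty result, invalid parameter)."""


class PipelineError(RuntimeError):
    """Internal failure of a pipeline stage."""


def substream(seed: int, label: str) -> np.random.Generator:
    """Return an independent RNG stream derived from a global seed.

    Each pipeline stage draws from its own named substream so stages can be
    regenerated independently without replaying earlier draws. The stream key
    is a CRC32 of the label, so it is stable across runs and platforms.
    """
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero (printed-table convention).

    numpy/python round half to even; region lengths and effect sizes are
    reported the way printed tables round, so ties go up.
    """
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))
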