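"""Binary up/down symbolisation of time series and Hamming similarity weights.

A signal is encoded one symbol per adjacent sample pair: UP when the signal
locally increases, DOWN otherwise.  Two symbol strings of equal length are
compared with the Hamming distance; the symbolic weight is the linear
complement of the normalised distance, ranging from 0 (minimal similarity,
every local movement disagrees) to 1 (maximal similarity, the two signals
rise and fall in lockstep).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = ["UP", "DOWN", "SymbolicWeight", "symbolic_transform", "symbolic_weight"]

UP: int = 1
DOWN: int = 0


@dataclass(frozen=True)
class SymbolicWeight:
    """Hamming similarity between two equal-length symbol strings.

    ``value`` is ``1 - hamming_distance / string_length`` and lies in [0, 1].
    """

    value: float
    hamming_distance: int
    string_length: int


def _validate_series(values: ArrayLike) -> NDArray[np.float64]:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < 3:
        raise ValueError(f"time series must have length >= 3, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("time series contains non-finite values")
    return arr


def symbolic_transform(values: ArrayLike, *, tie: str = "down") -> NDArray[np.uint8]:
    """Encode a time series as a binary up/down symbol string.

    Symbol ``i`` is UP (1) iff ``values[i+1] > values[i]`` and DOWN (0)
    otherwise, so a series of length n yields n - 1 symbols.  Equal adjacent
    samples carry no local increase; by default they encode DOWN.  Ties are
    measure-zero for continuous signals, but the rule is configurable
    (``tie="up"``) for discretised inputs.
    """
    arr = _validate_series(values)
    diff = np.diff(arr)
    if tie == "down":
        symbols = diff > 0
    elif tie == "up":
        symbols = diff >= 0
    else:
        raise ValueError(f"tie must be 'down' or 'up', got {tie!r}")
    return symbols.astype(np.uint8)


def symbolic_weight(a: ArrayLike, b: ArrayLike) -> SymbolicWeight:
    """Hamming similarity weight between two symbol strings of equal length.

    The Hamming distance counts positionwise mismatches, which is only
    defined for strings of the same length; unequal lengths raise
    ``ValueError``.  The weight is symmetric in its arguments.
    """
    sa = np.asarray(a, dtype=np.uint8).ravel()
    sb = np.asarray(b, dtype=np.uint8).ravel()
    if sa.size != sb.size:
        raise ValueError(
            f"symbol strings must have equal length, got {sa.size} and {sb.size}"
        )
    if sa.size == 0:
        raise ValueError("symbol strings must be non-empty")
    d = int(np.count_nonzero(sa != sb))
    return SymbolicWeight(value=1.0 - d / sa.size, hamming_distance=d, string_length=int(sa.size))
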