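"""Validated ordinal response matrices.

An :class:`OrdinalMatrix` holds an ``n x m`` integer matrix of questionnaire
responses, each entry on the ordinal scale ``{1, ..., q}``.  Both observed
(possibly distorted) data and reconstructed/true data are carried by the same
type; direction of distortion is a property of the operations, not the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["OrdinalMatrix"]


@dataclass(frozen=True)
class OrdinalMatrix:
    """An ``n x m`` matrix of integer responses on ``{1, ..., q}``.

    Parameters
    ----------
    values : array-like of int, shape (n, m)
        Response matrix; one row per respondent, one column per item.
    q : int
        Number of ordinal categories (>= 2).  Every entry must lie in
        ``{1, ..., q}``; missing entries are rejected.
    """

    values: np.ndarray = field()
    q: int = field()

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise ValueError(f"expected a 2-D matrix, got ndim={arr.ndim}")
        if arr.size == 0:
            raise ValueError("empty response matrix")
        if not np.issubdtype(arr.dtype, np.integer):
            if np.issubdtype(arr.dtype, np.floating):
                if np.isnan(arr).any():
                    i, j = np.argwhere(np.isnan(arr))[0]
                    raise ValueError(f"missing entry at row {i}, column {j}")
                if not np.array_equal(arr, np.round(arr)):
                    i, j = np.argwhere(arr != np.round(arr))[0]
                    raise ValueError(
                        f"non-integer entry {arr[i, j]!r} at row {i}, column {j}"
                    )
                arr = arr.astype(np.int64)
            else:
                raise TypeError(f"non-numeric matrix dtype {arr.dtype}")
        else:
            arr = arr.astype(np.int64)
        if int(self.q) < 2:
            raise ValueError(f"q must be >= 2, got {self.q}")
        object.__setattr__(self, "q", int(self.q))
        bad = (arr < 1) | (arr > self.q)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"entry {arr[i, j]} at row {i}, column {j} outside 1..{self.q}"
            )
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        """Number of respondents (rows)."""
        return self.values.shape[0]

    @property
    def m(self) -> int:
        """Number of items (columns)."""
        return self.values.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OrdinalMatrix):
            return NotImplemented
        return self.q == other.q and np.array_equal(self.values, other.values)

    def __hash__(self) -> int:
        return hash((self.q, self.values.tobytes(), self.values.shape))
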