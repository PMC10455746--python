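"""Mean ± sample-SD group summaries shared by all analysis modules."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive summary of one group of measurements.

    ``sd`` is the sample standard deviation (n−1 denominator), matching
    the convention used for all reported mean ± SD values.
    """

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("GroupSummary requires n >= 2 (sd undefined for n < 2)")
        if not self.sd >= 0:
            raise ValueError("sd must be non-negative")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.mean:.2f} ± {self.sd:.2f} (n={self.n})"


def summarize(values: Iterable[float]) -> GroupSummary:
    """Mean and sample SD of a collection of at least two values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError(f"need >= 2 values for a group summary, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in group")
    return GroupSummary(n=int(arr.size), mean=float(arr.mean()), sd=float(arr.std(ddof=1)))
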