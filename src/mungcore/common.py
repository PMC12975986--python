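"""Small shared result containers."""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class TestResult:
    """Outcome of one statistical test.

    ``df`` may be a single number, a pair (e.g. Welch), or ``None`` for
    permutation/non-parametric tests. ``p`` is ``None`` for pure distance
    measures (e.g. Kullback-Leibler) and ``nan`` when the test is undefined
    on the given input (the ``note`` field says why).
    """

    label: str
    statistic: float
    p: float | None = None
    df: object = None
    note: str = ""

    @property
    def defined(self) -> bool:
        return self.p is None or not math.isnan(self.p)

    def significant(self, alpha: float = 0.05) -> bool:
        if self.p is None or math.isnan(self.p):
            return False
        return self.p < alpha
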