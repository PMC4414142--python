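"""Small statistical helpers shared across analysis stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["fisher_exact_2x2", "ContingencyResult", "ttest_rows"]


def fisher_exact_2x2(a: int, b: int, c: int, d: int, alternative: str = "two-sided") -> float:
    """Fisher's exact test probability for the 2x2 table [[a, b], [c, d]]."""
    return float(sps.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])


@dataclass
class ContingencyResult:
    """A (count_1, count_2) pair with its ratio and a Fisher probability
    against a reference pair.

    The count semantics follow the analysis that produced it: I/D for
    methylation loci (increase/decrease), D/I for genes (down/up).
    """

    n1: int
    n2: int
    ref1: int
    ref2: int
    p: float

    @property
    def ratio(self) -> float:
        return self.n1 / self.n2 if self.n2 else float("inf")

    @property
    def ref_ratio(self) -> float:
        return self.ref1 / self.ref2 if self.ref2 else float("inf")


def contingency_vs_reference(n1: int, n2: int, ref1: int, ref2: int) -> ContingencyResult:
    p = fisher_exact_2x2(n1, n2, ref1, ref2)
    return ContingencyResult(int(n1), int(n2), int(ref1), int(ref2), p)


def ttest_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise two-sided independent t-test p-values.

    ``x`` and ``y`` are 2-D arrays (rows = items, columns = replicates);
    NaN replicate cells are ignored.  Rows where the test is undefined
    (fewer than two finite values on a side, or zero pooled variance)
    return NaN.
    """
    import warnings

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # rows with (near-)constant replicate values trigger a precision
        # warning and yield NaN/1.0, which is the documented behaviour
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(x, y, axis=1, nan_policy="omit")
        p = np.asarray(res.pvalue, dtype=float)
    return p
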