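"""Method-agreement statistics: paired regression and Bland-Altman analysis.

Used to compare automated pipeline counts against manual annotation or a
second automated counter. The Bland-Altman convention here is
``difference = method_A - method_B`` with A the automated method, so a
negative bias reads as "the automated method undercounts". Limits of
agreement are bias +/- multiplier * SD of the differences (sample SD, n-1);
the multiplier defaults to 1.96 (95% limits) and is exposed so other
coverages (e.g. 2.054 for 96%) are reachable.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import ZeroVarianceError


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    n: int


@dataclass
class AgreementResult:
    n_pairs: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    multiplier: float
    outlier_ids: Tuple[int, ...] = ()


def paired_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x plus Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0.0:
        raise ZeroVarianceError("regression undefined for constant x")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        r_squared=float(res.rvalue) ** 2,
        n=int(x.size),
    )


def bland_altman(
    a: Sequence[float], b: Sequence[float], multiplier: float = 1.96
) -> AgreementResult:
    """Bias and limits of agreement for paired measurements a (automated)
    vs b (reference)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired inputs must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo = bias - multiplier * sd
    hi = bias + multiplier * sd
    outliers = tuple(int(i) for i in np.flatnonzero((d < lo) | (d > hi)))
    return AgreementResult(
        n_pairs=int(a.size),
        bias=bias,
        sd_diff=sd,
        loa_low=lo,
        loa_high=hi,
        multiplier=multiplier,
        outlier_ids=outliers,
    )


def stratified_agreement(
    a: Sequence[float],
    b: Sequence[float],
    strata_edges: Sequence[float],
    multiplier: float = 1.96,
) -> List[Optional[AgreementResult]]:
    """Bland-Altman per stratum of the pair means.

    Pairs are binned by ``(a+b)/2`` against sorted ``strata_edges`` using
    half-open bins [lo, hi): a mean exactly on an edge joins the upper
    stratum. Strata with fewer than 2 pairs are reported as None.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired inputs must have equal length")
    edges = list(strata_edges)
    if sorted(edges) != edges:
        raise ValueError("strata_edges must be sorted ascending")
    means = (a + b) / 2.0
    idx = np.searchsorted(np.asarray(edges, dtype=float), means, side="right")
    out: List[Optional[AgreementResult]] = []
    for s in range(len(edges) + 1):
        m = idx == s
        if m.sum() < 2:
            out.append(None)
        else:
            out.append(bland_altman(a[m], b[m], multiplier))
    return out
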