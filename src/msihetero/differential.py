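"""Pixel-wise differential metabolites per subpopulation.

Each channel is tested with the Mann-Whitney U test (subpopulation pixels
vs all other pixels pooled), p-values are Benjamini-Hochberg adjusted
within the subpopulation's channel family, and calls require both the
adjusted p and a fold-change filter. Pixel-level testing is
pseudoreplicated across pixels of the same patient; a patient-level
aggregation mode is available via ``aggregate="patient_median"``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "mannwhitney_u",
    "bh_adjust",
    "differential_metabolites",
    "direction_counts",
    "fligner_killeen",
]


def mannwhitney_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact p by enumeration of the U null distribution when
    ``min(n_x, n_y) <= 8`` and the pooled data is tie-free; otherwise the
    normal approximation with tie and continuity corrections. Returns
    ``(U, p)`` with U counted for ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least 2 observations")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def differential_metabolites(
    intensities: np.ndarray,
    labels: np.ndarray,
    subpop: int,
    channels: np.ndarray | None = None,
    patient_ids: Sequence[str] | None = None,
    aggregate: str = "pixel",
    alpha: float = 0.05,
    fc_threshold: float = 1.5,
    min_pixels: int = 10,
) -> pd.DataFrame:
    """Test every channel of subpopulation ``subpop`` against the pooled rest.

    Returns one row per channel: ``U``, ``p``, ``q`` (BH within this
    subpopulation's family), ``fold_change`` (ratio of means), and
    ``direction``: "increased" iff q < alpha and FC >= fc_threshold,
    "decreased" iff q < alpha and FC <= 1/fc_threshold, "untestable" when a
    group mean is zero, else "ns".
    """
    X = np.asarray(intensities, dtype=float)
    labels = np.asarray(labels, dtype=int)
    in_pop = labels == subpop
    if aggregate == "patient_median":
        if patient_ids is None:
            raise ValueError("patient_ids required for patient-level aggregation")
        pids = np.asarray(patient_ids)
        rows_in, rows_out = [], []
        for pid in np.unique(pids):
            sel_in = in_pop & (pids == pid)
            sel_out = ~in_pop & (pids == pid)
            if sel_in.any():
                rows_in.append(np.median(X[sel_in], axis=0))
            if sel_out.any():
                rows_out.append(np.median(X[sel_out], axis=0))
        Xi = np.array(rows_in)
        Xo = np.array(rows_out)
        min_units = 2
    elif aggregate == "pixel":
        Xi, Xo = X[in_pop], X[~in_pop]
        min_units = min_pixels
    else:
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    if Xi.shape[0] < min_units or Xo.shape[0] < min_units:
        raise ValueError(
            f"subpopulation {subpop} has {Xi.shape[0]} units vs {Xo.shape[0]} "
            f"in the rest; need at least {min_units} each"
        )

    n_ch = X.shape[1]
    U = np.full(n_ch, np.nan)
    p = np.full(n_ch, np.nan)
    fc = np.full(n_ch, np.nan)
    testable = np.ones(n_ch, dtype=bool)
    for c in range(n_ch):
        mi, mo = Xi[:, c].mean(), Xo[:, c].mean()
        if mi <= 0 or mo <= 0:
            testable[c] = False
            continue
        fc[c] = mi / mo
        U[c], p[c] = mannwhitney_u(Xi[:, c], Xo[:, c])
    q = np.full(n_ch, np.nan)
    if testable.any():
        q[testable] = bh_adjust(p[testable])

    direction = np.full(n_ch, "ns", dtype=object)
    direction[~testable] = "untestable"
    sig = testable & (q < alpha)
    direction[sig & (fc >= fc_threshold)] = "increased"
    direction[sig & (fc <= 1.0 / fc_threshold)] = "decreased"

    return pd.DataFrame(
        {
            "subpop": subpop,
            "channel": channels if channels is not None else np.arange(n_ch),
            "U": U,
            "p": p,
            "q": q,
            "fold_change": fc,
            "direction": direction,
        }
    )


def direction_counts(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Counts of increased/decreased channels per subpopulation."""
    rows = []
    for tab in tables:
        sp = int(tab["subpop"].iloc[0])
        rows.append(
            (
                sp,
                int((tab["direction"] == "increased").sum()),
                int((tab["direction"] == "decreased").sum()),
            )
        )
    return pd.DataFrame(rows, columns=["subpop", "n_increased", "n_decreased"])


def fligner_killeen(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Fligner-Killeen test of equal variances across >= 2 groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    stat, p = stats.fligner(*groups)
    return float(stat), float(p)
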