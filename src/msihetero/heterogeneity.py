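"""Simpson's diversity of cluster composition and the cutoff-optimised
high/low heterogeneity split.

The split cutoff minimises the two-group log-rank p-value over candidate
cutoffs (midpoints of consecutive distinct diversity values with both
groups large enough). Because the cutoff is selected to minimise p, the
reported p-value is optimistically biased; every split carries an explicit
``selection_bias_caveat`` flag and no multiplicity correction is applied.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from msihetero.survival import logrank_test
from msihetero.types import ClusterComposition, DiversityScore, DiversitySplit, SurvivalRecord

__all__ = ["simpson_index", "simpson_from_labels", "optimize_diversity_cutoff"]


def simpson_index(comp: ClusterComposition) -> DiversityScore:
    """D = 1 - sum(p_i^2); 0 for a one-hot composition, at most 1 - 1/K."""
    D = 1.0 - float(np.sum(comp.shares**2))
    return DiversityScore(patient_id=comp.patient_id, D=D, k_used=comp.k)


def simpson_from_labels(labels: np.ndarray, k: int, patient_id: str = "") -> DiversityScore:
    """Same index computed directly from per-pixel labels (1-based)."""
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels - 1, minlength=k)
    p = counts / labels.size
    return DiversityScore(patient_id=patient_id, D=1.0 - float(np.sum(p**2)), k_used=k)


def optimize_diversity_cutoff(
    scores: Sequence[DiversityScore],
    surv: Sequence[SurvivalRecord],
    min_group_frac: float = 0.1,
    alpha: float = 0.05,
) -> DiversitySplit:
    """Choose the diversity cutoff minimising the log-rank p-value.

    Candidates are midpoints between consecutive sorted distinct D values
    for which both groups hold at least ``min_group_frac`` of patients and
    at least one event each. Ties in p break toward the more balanced
    split. Robustness passes iff every adjacent candidate cutoff also
    reaches p < ``alpha``.
    """
    scores = sorted(scores, key=lambda s: s.patient_id)
    surv = sorted(surv, key=lambda r: r.patient_id)
    if [s.patient_id for s in scores] != [r.patient_id for r in surv]:
        raise ValueError("scores and survival records must cover the same patients")
    n = len(scores)
    if n < 10:
        raise ValueError(f"need at least 10 patients, got {n}")
    D = np.array([s.D for s in scores])
    times = np.array([r.time for r in surv])
    events = np.array([r.event for r in surv])
    min_size = max(1, int(np.ceil(min_group_frac * n)))

    distinct = np.unique(D)
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    admissible, pvals, balance = [], [], []
    for c in candidates:
        high = D > c
        if high.sum() < min_size or (~high).sum() < min_size:
            continue
        if events[high].sum() < 1 or events[~high].sum() < 1:
            continue
        _, p = logrank_test(times[high], events[high], times[~high], events[~high])
        admissible.append(c)
        pvals.append(p)
        balance.append(abs(int(high.sum()) - int((~high).sum())))
    if not admissible:
        raise ValueError("no admissible cutoff candidate")
    pvals = np.asarray(pvals)
    balance = np.asarray(balance)
    # minimal p; ties toward the more balanced split, then the smaller cutoff
    order = np.lexsort((admissible, balance, np.round(pvals, 12)))
    best = order[0]
    cutoff = float(admissible[best])
    p_best = float(pvals[best])
    neighbours = [i for i in (best - 1, best + 1) if 0 <= i < len(admissible)]
    robust = all(pvals[i] < alpha for i in neighbours) and p_best < alpha
    groups = {s.patient_id: ("high" if s.D > cutoff else "low") for s in scores}
    return DiversitySplit(
        cutoff=cutoff,
        groups=groups,
        p_logrank=p_best,
        robustness=robust,
        metadata={
            "selection_bias_caveat": True,
            "note": "cutoff chosen to minimise the log-rank p; the reported p "
            "is not adjusted for this selection",
            "n_candidates": len(admissible),
            "neighbour_p": [float(pvals[i]) for i in neighbours],
            "min_group_frac": min_group_frac,
        },
    )
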