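"""Negative-mode adduct annotation, pathway over-representation and
within-subpopulation correlation networks."""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from msihetero.differential import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "AdductRule",
    "ADDUCT_RULES",
    "monoisotopic_mass",
    "adduct_mz",
    "annotate_peaks",
    "enrich_pathways",
    "correlation_network",
    "load_demo_mass_table",
    "load_demo_pathways",
]

# monoisotopic atomic masses (Da)
ATOMIC_MASS = {
    "H": 1.00782503,
    "C": 12.0,
    "N": 14.0030740,
    "O": 15.99491462,
    "P": 30.97376200,
    "S": 31.97207117,
    "Na": 22.98976928,
    "K": 38.96370649,
    "Cl": 34.96885268,
}
ELECTRON_MASS = 0.00054858

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass of a molecular formula such as ``C6H12O6``."""
    pos = 0
    mass = 0.0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        element, count = m.group(1), m.group(2)
        if element not in ATOMIC_MASS:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        mass += ATOMIC_MASS[element] * (int(count) if count else 1)
    if pos != len(formula) or mass == 0.0:
        raise ValueError(f"cannot parse formula {formula!r}")
    return mass


@dataclass(frozen=True)
class AdductRule:
    """A singly charged negative-mode adduct: observed m/z = M + mass_shift."""

    name: str
    mass_shift: float
    charge: int = -1


def _computed_shift(name: str) -> float:
    H, O = ATOMIC_MASS["H"], ATOMIC_MASS["O"]
    e = ELECTRON_MASS
    return {
        "M-H": -H + e,
        "M-H2O-H": -(2 * H + O) - H + e,
        "M+K-2H": ATOMIC_MASS["K"] - 2 * H + e,
        "M+Na-2H": ATOMIC_MASS["Na"] - 2 * H + e,
        "M+Cl": ATOMIC_MASS["Cl"] + e,
    }[name]


# the five supported negative adducts; shifts are hard-coded and validated
# at import against a recomputation from atomic masses
ADDUCT_RULES: dict[str, AdductRule] = {
    "M-H": AdductRule("M-H", -1.00727645),
    "M-H2O-H": AdductRule("M-H2O-H", -19.01784113),
    "M+K-2H": AdductRule("M+K-2H", 36.94860501),
    "M+Na-2H": AdductRule("M+Na-2H", 20.97466780),
    "M+Cl": AdductRule("M+Cl", 34.96940126),
}

for _name, _rule in ADDUCT_RULES.items():
    assert abs(_rule.mass_shift - _computed_shift(_name)) < 1e-6, _name


def adduct_mz(neutral_mass: float, rule: AdductRule | str) -> float:
    """Observed m/z of a neutral metabolite under an adduct rule."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be > 0")
    if isinstance(rule, str):
        if rule not in ADDUCT_RULES:
            raise KeyError(f"unknown adduct rule {rule!r}")
        rule = ADDUCT_RULES[rule]
    return neutral_mass + rule.mass_shift


def annotate_peaks(
    peak_mz: Sequence[float],
    mass_table: pd.DataFrame,
    tol_ppm: float = 4.0,
) -> pd.DataFrame:
    """Match observed peaks against a metabolite mass table via all adducts.

    ``mass_table`` needs columns ``id`` and ``monoisotopic_mass``. Every
    (peak, metabolite, adduct) combination within ``tol_ppm`` is reported;
    hits are ranked by absolute ppm error within each peak.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    if "id" not in mass_table.columns or "monoisotopic_mass" not in mass_table.columns:
        raise ValueError("mass table needs 'id' and 'monoisotopic_mass' columns")
    peaks = np.asarray(peak_mz, dtype=float)
    rows = []
    for _, met in mass_table.iterrows():
        m0 = float(met["monoisotopic_mass"])
        if m0 <= 0:
            raise ValueError(f"non-positive mass for metabolite {met['id']!r}")
        for rule in ADDUCT_RULES.values():
            theo = adduct_mz(m0, rule)
            ppm = (peaks - theo) / theo * 1e6
            for idx in np.flatnonzero(np.abs(ppm) <= tol_ppm):
                rows.append(
                    (float(peaks[idx]), str(met["id"]), m0, rule.name, float(ppm[idx]))
                )
    df = pd.DataFrame(
        rows, columns=["observed_mz", "metabolite", "neutral_mass", "adduct", "ppm_error"]
    )
    if not df.empty:
        df["abs_ppm"] = df["ppm_error"].abs()
        df = (
            df.sort_values(["observed_mz", "abs_ppm"], kind="stable")
            .drop(columns="abs_ppm")
            .reset_index(drop=True)
        )
    return df


def enrich_pathways(
    query: set[str],
    universe: set[str],
    pathways: Mapping[str, set[str]],
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per pathway, BH-corrected.

    Pathway memberships are intersected with the universe first; the query
    must be a subset of the universe.
    """
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N = len(universe)
    n = len(query)
    rows = []
    for name, members in pathways.items():
        members = members & universe
        K = len(members)
        if K == 0:
            continue
        overlap = len(query & members)
        # P(X >= overlap) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(overlap - 1, N, K, n))
        rows.append((name, overlap, K, N, p))
    df = pd.DataFrame(
        rows, columns=["pathway", "overlap", "pathway_size", "universe_size", "p"]
    )
    if not df.empty:
        df["q"] = bh_adjust(df["p"].to_numpy())
        df["significant"] = df["q"] < q_threshold
        df = df.sort_values(["p", "pathway"], kind="stable").reset_index(drop=True)
    return df


def correlation_network(
    intensities: np.ndarray,
    channel_names: Sequence | None = None,
    directions: Mapping | None = None,
    alpha: float = 0.05,
    min_pixels: int = 10,
) -> tuple[nx.Graph, pd.DataFrame]:
    """Spearman correlation network over channels of one subpopulation's pixels.

    Edges keep pairs whose BH-adjusted p (over all channel pairs) is below
    ``alpha``; each edge carries ``rho``, ``sign`` and ``weight=|rho|``.
    Constant channels are excluded with a log entry. Returns the graph and
    the full pairwise table.
    """
    X = np.asarray(intensities, dtype=float)
    if X.shape[0] < min_pixels:
        raise ValueError(f"need at least {min_pixels} pixels, got {X.shape[0]}")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 channels")
    names = list(channel_names) if channel_names is not None else list(range(X.shape[1]))
    variable = np.ptp(X, axis=0) > 0
    if not variable.all():
        dropped = [names[i] for i in np.flatnonzero(~variable)]
        logger.info("excluding %d constant channel(s): %s", len(dropped), dropped)
    idx = np.flatnonzero(variable)
    if idx.size < 2:
        raise ValueError("fewer than 2 non-constant channels")
    sub = X[:, idx]
    rho_mat, p_mat = stats.spearmanr(sub)
    if idx.size == 2:  # scipy returns scalars for exactly two columns
        rho_mat = np.array([[1.0, rho_mat], [rho_mat, 1.0]])
        p_mat = np.array([[0.0, p_mat], [p_mat, 0.0]])
    iu, ju = np.triu_indices(idx.size, k=1)
    pairs = pd.DataFrame(
        {
            "a": [names[idx[i]] for i in iu],
            "b": [names[idx[j]] for j in ju],
            "rho": rho_mat[iu, ju],
            "p": p_mat[iu, ju],
        }
    )
    pairs["q"] = bh_adjust(pairs["p"].to_numpy())

    g = nx.Graph()
    for i in idx:
        attrs = {}
        if directions is not None and names[i] in directions:
            attrs["direction"] = directions[names[i]]
        g.add_node(names[i], **attrs)
    for _, row in pairs[pairs["q"] < alpha].iterrows():
        g.add_edge(
            row["a"],
            row["b"],
            rho=float(row["rho"]),
            q=float(row["q"]),
            sign="positive" if row["rho"] > 0 else "negative",
            weight=float(abs(row["rho"])),
        )
    return g, pairs


def load_demo_mass_table() -> pd.DataFrame:
    """Small bundled metabolite table (masses computed from formulas)."""
    with resources.files("msihetero.data").joinpath("demo_metabolites.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["monoisotopic_mass"] = df["formula"].map(monoisotopic_mass)
    return df


def load_demo_pathways() -> dict[str, set[str]]:
    """Bundled toy pathway sets over the demo metabolites."""
    pathways: dict[str, set[str]] = {}
    with resources.files("msihetero.data").joinpath("demo_pathways.gmt").open() as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                pathways[parts[0]] = {m for m in parts[2:] if m}
    return pathways
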