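"""Efficiency-corrected relative expression from qPCR and array data.

The apparent expression level of a target gene relative to an internal
reference gene is computed as

    level = Er^Ct(ref) / Et^Ct(target) × F

where Er and Et are the per-cycle amplification efficiencies of the
reference and target primer pairs (≈1.8–2.0; 2 is perfect doubling), Ct is
each gene's cycle threshold, and F is the amplicon size factor (reference
amplicon length / target amplicon length).  The exponents are read as the
*reference* gene's Ct on Er and the *target* gene's Ct on Et — the only
reading under which more target mRNA yields a higher level.  When
Er = Et = E the level reduces to E^(Ct_ref − Ct_target) × F.

Efficiencies come from dilution series: the least-squares slope m of Ct
against log10(input amount) gives efficiency 10^(−1/m) (perfect doubling
gives m = −3.3219 and E = 2).

Group comparisons (heat-stressed vs control) report the fold change of
group means with a two-sided Welch t-test; the test choice is a documented
convention (published asterisk annotations rarely name their test) and no
multiple-testing correction is applied by default, with Benjamini–Hochberg
available as an option.  Array re-analysis consumes already-normalized
non-log signal matrices; probe sets with both group means below the
detectability threshold (default 20) are reported as not detectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QpcrModel",
    "GroupComparison",
    "relative_expression",
    "efficiency_from_dilution",
    "compare_groups",
    "array_response",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class QpcrModel:
    """Amplification efficiencies and amplicon size factor."""

    er: float = 2.0           # reference-gene per-cycle efficiency
    et: float = 2.0           # target-gene efficiency
    f: float = 1.0            # reference amplicon size / target amplicon size
    reference_gene: str = "TaRP15"

    def __post_init__(self):
        for name, e in (("Er", self.er), ("Et", self.et)):
            if not (1.0 < e <= 2.2):
                raise ValueError(f"{name}={e} outside (1, 2.2]")
        if self.f <= 0:
            raise ValueError("amplicon size factor must be positive")


def relative_expression(ct_ref: float, ct_target: float, model: QpcrModel = QpcrModel()) -> float:
    """Apparent expression level Er^Ct(ref) / Et^Ct(target) × F."""
    if ct_ref <= 0 or ct_target <= 0:
        raise ValueError("Ct values must be positive")
    return model.er ** ct_ref / model.et ** ct_target * model.f


@dataclass(frozen=True)
class DilutionFit:
    efficiency: float
    slope: float
    intercept: float
    r_squared: float


def efficiency_from_dilution(series: Sequence[tuple]) -> DilutionFit:
    """PCR efficiency from a dilution series of (log10 amount, Ct) pairs.

    Least-squares slope m of Ct on log10(amount); efficiency = 10^(−1/m).
    Requires ≥3 points and a negative slope (more template ⇒ fewer cycles).
    """
    if len(series) < 3:
        raise ValueError("dilution series needs at least 3 points")
    x = np.array([p[0] for p in series], dtype=float)
    y = np.array([p[1] for p in series], dtype=float)
    res = stats.linregress(x, y)
    if res.slope >= 0:
        raise ValueError(f"non-negative dilution slope {res.slope:.4g}")
    return DilutionFit(
        efficiency=10.0 ** (-1.0 / res.slope),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
    )


@dataclass(frozen=True)
class GroupComparison:
    gene: str
    fold: float               # treated mean / control mean
    p_value: float
    direction: str            # up | down | ns
    n_control: int
    n_treated: int


def compare_groups(
    control: Sequence[float],
    treated: Sequence[float],
    alpha: float = 0.05,
    gene: str = "",
) -> GroupComparison:
    """Fold change and two-sided Welch t-test between replicate groups."""
    c = np.asarray(control, dtype=float)
    t = np.asarray(treated, dtype=float)
    if len(c) < 2 or len(t) < 2:
        raise ValueError("need at least 2 replicates per group")
    if c.mean() <= 0:
        raise ValueError("degenerate control: mean must be positive")
    fold = t.mean() / c.mean()
    if c.std(ddof=1) == 0 and t.std(ddof=1) == 0:
        p = 1.0 if math.isclose(c.mean(), t.mean()) else 0.0
    else:
        p = float(stats.ttest_ind(t, c, equal_var=False).pvalue)
    if p < alpha:
        direction = "up" if fold > 1 else "down"
    else:
        direction = "ns"
    return GroupComparison(gene, float(fold), p, direction, len(c), len(t))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up FDR)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj


def array_response(
    matrix: pd.DataFrame,
    groups: dict,
    control_group: str,
    stress_group: str,
    alpha: float = 0.05,
    detect_threshold: float = 20.0,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-probe-set stress response from a normalized non-log array matrix.

    ``matrix`` is probe sets × samples; ``groups`` maps sample name →
    group label.  Probe sets with both group means below the
    detectability threshold are "nd".  Otherwise the relative level is
    stress mean / control mean (the control is 1 by construction) with a
    two-sided Welch t-test at ``alpha`` (Benjamini–Hochberg optional).
    """
    for g in (control_group, stress_group):
        if g not in set(groups.values()):
            raise ValueError(f"group label {g!r} missing from the group map")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("array signals must be non-negative")
    control_cols = [s for s, g in groups.items() if g == control_group and s in matrix.columns]
    stress_cols = [s for s, g in groups.items() if g == stress_group and s in matrix.columns]
    if not control_cols or not stress_cols:
        raise ValueError("both groups must map to at least one matrix column")
    rows = []
    for probe, row in matrix.iterrows():
        c = row[control_cols].to_numpy(dtype=float)
        s = row[stress_cols].to_numpy(dtype=float)
        if c.mean() < detect_threshold and s.mean() < detect_threshold:
            rows.append({"probe_set": probe, "status": "nd", "relative_level": np.nan,
                         "p_value": np.nan, "direction": "nd"})
            continue
        if c.std(ddof=1) == 0 and s.std(ddof=1) == 0:
            p = 1.0 if math.isclose(c.mean(), s.mean()) else 0.0
        else:
            p = float(stats.ttest_ind(s, c, equal_var=False).pvalue)
        rel = s.mean() / c.mean() if c.mean() > 0 else np.inf
        rows.append({"probe_set": probe, "status": "detected", "relative_level": rel,
                     "p_value": p, "direction": "pending"})
    out = pd.DataFrame(rows).set_index("probe_set")
    detected = out["status"] == "detected"
    pvals = out.loc[detected, "p_value"]
    if fdr and detected.any():
        out.loc[detected, "p_adjusted"] = benjamini_hochberg(pvals.to_numpy())
        crit = out.loc[detected, "p_adjusted"] < alpha
    else:
        crit = pvals < alpha
    up = detected & crit.reindex(out.index, fill_value=False) & (out["relative_level"] > 1)
    down = detected & crit.reindex(out.index, fill_value=False) & (out["relative_level"] < 1)
    out.loc[detected, "direction"] = "ns"
    out.loc[up, "direction"] = "up"
    out.loc[down, "direction"] = "down"
    return out
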