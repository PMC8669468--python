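"""Differential protein abundance via a two-component-uncertainty Z score.

For each protein quantified in both conditions, the total uncertainty per
condition is the root-square sum of (i) the SD of the protein's log2
abundance across biological replicates and (ii) the mean within-replicate
standard error.  The Z statistic divides the difference of condition
means by the SUM of the two total uncertainties (a deliberately
conservative denominator), two-sided p-values follow a standard normal,
and multiplicity is controlled with q-values (Storey) at 0.05.

Proteins detected in only one condition cannot be scored and are reported
as presence/absence calls instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GluconeofluxError


@dataclass
class ConditionSummary:
    mean: float
    total_uncertainty: float
    n: int


def condition_summary(log2_abundances, within_se) -> ConditionSummary:
    """Mean and total uncertainty for one condition.

    total u = sqrt(sd_across_replicates^2 + mean(within-replicate SE)^2).
    """
    x = np.asarray([v for v in log2_abundances if np.isfinite(v)], dtype=float)
    se = np.asarray([v for v in np.atleast_1d(within_se) if np.isfinite(v)],
                    dtype=float)
    if len(x) < 2:
        raise GluconeofluxError("need >= 2 finite replicates per condition")
    sd_rep = float(np.std(x, ddof=1))
    mean_se = float(np.mean(se)) if len(se) else 0.0
    return ConditionSummary(float(np.mean(x)),
                            float(np.hypot(sd_rep, mean_se)), len(x))


def protein_z(cond1: ConditionSummary, cond2: ConditionSummary) -> float:
    """Z = (mean1 - mean2) / (u1 + u2)."""
    denom = cond1.total_uncertainty + cond2.total_uncertainty
    if denom <= 0:
        raise GluconeofluxError("zero total uncertainty in both conditions")
    return (cond1.mean - cond2.mean) / denom


def storey_qvalues(pvalues, lambdas=None) -> np.ndarray:
    """Storey q-values with smoothed pi0 estimation over a lambda grid."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    lambdas = np.asarray(lambdas, dtype=float)
    if len(lambdas) >= 4 and m >= 10:
        pi0_l = np.array([(p > lam).mean() / (1 - lam) for lam in lambdas])
        # cubic polynomial smoother evaluated at the largest lambda
        coef = np.polyfit(lambdas, pi0_l, 3)
        pi0 = float(np.polyval(coef, lambdas.max()))
    else:
        pi0 = float((p > 0.5).mean() / 0.5) if m else 1.0
    pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        val = pi0 * p[i] * m / (rank + 1)
        prev = min(prev, val)
        q[i] = prev
    return np.clip(q, 0.0, 1.0)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH adjusted p-values (fallback multiplicity control)."""
    return storey_qvalues(pvalues, lambdas=np.array([]))  # pi0 = 1 path


def z_to_q(z_values, alpha: float = 0.05, method: str = "storey") -> pd.DataFrame:
    """Two-sided standard-normal p-values and q-values for Z scores."""
    z = np.asarray(z_values, dtype=float)
    finite = np.isfinite(z)
    if not finite.any():
        raise GluconeofluxError("need at least one finite Z")
    p = np.where(finite, 2 * stats.norm.sf(np.abs(z)), np.nan)
    q = np.full_like(p, np.nan)
    if method == "storey":
        q[finite] = storey_qvalues(p[finite])
    elif method == "bh":
        q[finite] = benjamini_hochberg(p[finite])
    else:
        raise GluconeofluxError(f"unknown method {method!r}")
    return pd.DataFrame({"z": z, "p": p, "q": q,
                         "significant": (q <= alpha) & finite})


def differential_abundance(table: pd.DataFrame, alpha: float = 0.05,
                           method: str = "storey",
                           conditions: tuple[str, str] | None = None
                           ) -> pd.DataFrame:
    """Score a two-condition protein table.

    ``table`` columns: ``protein``, ``condition`` (two levels),
    ``log2_abundance``, ``within_se``; one row per replicate.
    ``conditions`` fixes the contrast orientation: log2fc and Z are
    conditions[0] - conditions[1].  The default (reverse-alphabetical)
    makes the succinate/gluconate design read succinate - gluconate.

    Returns one row per protein with log2fc, z, p, q, significant and
    detection status ("both", "<cond>_only").
    """
    found = sorted(table["condition"].unique())
    if len(found) != 2:
        raise GluconeofluxError(f"expected exactly 2 conditions, got {found}")
    if conditions is None:
        conditions = (found[1], found[0])
    elif sorted(conditions) != found:
        raise GluconeofluxError(
            f"conditions {conditions} do not match table levels {found}")
    c1, c2 = conditions
    conds = [c1, c2]
    rows = []
    for protein, grp in table.groupby("protein", sort=True):
        summaries = {}
        for cond in conds:
            sub = grp[grp["condition"] == cond]
            x = sub["log2_abundance"].to_numpy()
            if np.isfinite(x).sum() >= 2:
                summaries[cond] = condition_summary(x, sub["within_se"].to_numpy())
        if len(summaries) < 2:
            status = f"{c1}_only" if c1 in summaries else (
                f"{c2}_only" if c2 in summaries else "undetected")
            rows.append({"protein": protein, "detection": status,
                         "log2fc": np.nan, "z": np.nan, "p": np.nan})
            continue
        z = protein_z(summaries[c1], summaries[c2])
        rows.append({"protein": protein, "detection": "both",
                     "log2fc": summaries[c1].mean - summaries[c2].mean,
                     "z": z, "p": 2 * stats.norm.sf(abs(z))})
    out = pd.DataFrame(rows)
    tested = out["detection"] == "both"
    out["q"] = np.nan
    if tested.any():
        pvals = out.loc[tested, "p"].to_numpy()
        if method == "storey":
            out.loc[tested, "q"] = storey_qvalues(pvals)
        elif method == "bh":
            out.loc[tested, "q"] = benjamini_hochberg(pvals)
        else:
            raise GluconeofluxError(f"unknown method {method!r}")
    out["significant"] = (out["q"] <= alpha).fillna(False)
    return out
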