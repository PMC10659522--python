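"""Variance-inflation-factor diagnostics and sequential backward pruning.

VIF_j = 1/(1 - R^2_j), with R^2_j from regressing predictor j on all other
predictors in the subset (with intercept). For centred, scaled data this is
the j-th diagonal of the inverse correlation matrix, which is how it is
computed here; a singular correlation matrix (perfect collinearity) falls
back to per-variable least squares and reports +inf for the affected
variables. Pruning removes the single largest-VIF variable (ties broken by
lexicographically first label, logged) until all VIFs fall below the
threshold, default 5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["VifTrace", "compute_vif", "backward_prune"]

_R2_TOL = 1e-12


@dataclass
class VifTrace:
    steps: list[tuple[str, float]] = field(default_factory=list)
    surviving: list[str] = field(default_factory=list)
    final_vifs: dict[str, float] = field(default_factory=dict)
    threshold: float = 5.0

    def to_dict(self) -> dict:
        return {
            "steps": [{"removed": v, "vif": x} for v, x in self.steps],
            "surviving": self.surviving,
            "final_vifs": self.final_vifs,
            "threshold": self.threshold,
        }


def compute_vif(mets: pd.DataFrame, subset: list[str] | None = None) -> pd.Series:
    """Per-variable VIF over ``subset`` (all columns when omitted)."""
    cols = list(subset) if subset is not None else list(mets.columns)
    x = mets[cols].to_numpy(float)
    n, p = x.shape
    if n <= p + 1:
        raise ValueError("need more samples than variables to compute VIFs")
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = [c for c, s in zip(cols, sd) if s == 0]
        raise ValueError(f"constant column(s): {bad}")
    if p == 1:
        return pd.Series([1.0], index=cols)
    z = (x - x.mean(axis=0)) / sd
    corr = z.T @ z / n
    try:
        inv = np.linalg.inv(corr)
        vif = np.diag(inv).copy()
        if np.any(vif < 0) or np.linalg.cond(corr) > 1 / _R2_TOL:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        vif = np.empty(p)
        for j in range(p):
            others = np.delete(z, j, axis=1)
            coef, *_ = np.linalg.lstsq(others, z[:, j], rcond=None)
            resid = z[:, j] - others @ coef
            r2 = 1.0 - resid @ resid / n
            vif[j] = np.inf if r2 >= 1 - _R2_TOL else 1.0 / (1.0 - r2)
    return pd.Series(vif, index=cols)


def backward_prune(
    mets: pd.DataFrame,
    start_set: list[str] | None = None,
    threshold: float = 5.0,
) -> VifTrace:
    """Remove the largest-VIF variable until every VIF is below threshold."""
    current = list(start_set) if start_set is not None else list(mets.columns)
    trace = VifTrace(threshold=threshold)
    if len(current) < 2:
        trace.surviving = current
        trace.final_vifs = {c: 1.0 for c in current}
        return trace
    while len(current) >= 2:
        vifs = compute_vif(mets, current)
        worst = vifs.max()
        if worst < threshold:
            break
        # ties -> lexicographically first label
        candidates = sorted(vifs.index[vifs == worst])
        victim = candidates[0]
        if len(candidates) > 1:
            logger.info("VIF tie at %.4g among %s; removing %r", worst, candidates, victim)
        trace.steps.append((victim, float(worst)))
        current.remove(victim)
    final = compute_vif(mets, current) if len(current) >= 2 else pd.Series(1.0, index=current)
    trace.surviving = current
    trace.final_vifs = {c: float(v) for c, v in final.items()}
    return trace
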