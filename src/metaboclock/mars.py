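"""Multivariate adaptive regression splines, degree-capped, GCV-pruned.

The model is an expansion in products of hinge functions
``h(x) = max(0, +/-(x - t))``. The forward pass greedily adds reflected
hinge pairs — optionally multiplied into an existing basis term, with at
most ``max_degree`` hinge factors per term — choosing the (parent,
variable, knot) candidate with the largest residual-SSE reduction, computed
against an orthonormalized running basis so each sweep is a few BLAS calls.
The backward pass deletes terms greedily while the generalized
cross-validation score

    GCV(M) = MSE(M) / (1 - C(M)/N)^2,   C(M) = n_coef + d * n_knots

keeps decreasing (d is the knot penalty; n_knots counts distinct
(variable, knot) pairs in the retained terms). Knot candidates are
quantile-spaced with the extreme quantiles trimmed to avoid end-interval
knots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["HingeFactor", "MarsTerm", "MarsModel", "fit_mars", "mars_predict"]


@dataclass(frozen=True)
class HingeFactor:
    var: str
    knot: float
    direction: int  # +1: max(0, x - t); -1: max(0, t - x)

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        return np.maximum(0.0, self.direction * (x - self.knot))


@dataclass(frozen=True)
class MarsTerm:
    factors: tuple[HingeFactor, ...] = ()

    @property
    def degree(self) -> int:
        return len(self.factors)

    def evaluate(self, mets: pd.DataFrame) -> np.ndarray:
        out = np.ones(len(mets))
        for f in self.factors:
            out *= f.evaluate(mets[f.var].to_numpy(float))
        return out


@dataclass
class MarsModel:
    terms: list[MarsTerm]
    coefficients: np.ndarray
    gcv: float
    gcv_penalty: float
    variables: list[str] = field(default_factory=list)

    @property
    def n_knots(self) -> int:
        return len({(f.var, f.knot) for t in self.terms for f in t.factors})


def _candidate_knots(x: np.ndarray, max_knots: int) -> np.ndarray:
    u = np.unique(x)
    if len(u) <= 2:
        return np.array([])
    inner = u[1:-1]  # knots at the extremes produce empty hinges
    if len(inner) <= max_knots:
        return inner
    probs = np.linspace(0, 1, max_knots + 2)[1:-1]
    return np.unique(np.quantile(inner, probs, method="nearest"))


def _gcv(sse: float, n: int, n_coef: int, n_knots: int, d: float) -> float:
    c = n_coef + d * n_knots
    if c >= n:
        return np.inf
    return (sse / n) / (1.0 - c / n) ** 2


def fit_mars(
    mets: pd.DataFrame,
    y: np.ndarray | pd.Series,
    max_degree: int = 2,
    max_terms: int | None = None,
    gcv_penalty: float = 3.0,
    max_knots: int = 16,
    min_sse_decrease: float = 1e-10,
    prune: bool = True,
) -> MarsModel:
    """Fit a degree-``max_degree`` MARS model of ``y`` on the metabolites.

    ``prune=False`` returns the unpruned forward-pass model (diagnostics).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    variables = list(mets.columns)
    if max_terms is None:
        max_terms = int(min(2 * np.sqrt(n), 40))
    if np.ptp(y) == 0:  # constant response -> intercept only
        return MarsModel([MarsTerm()], np.array([y[0] if n else 0.0]), 0.0,
                         gcv_penalty, variables)

    xcols = {v: mets[v].to_numpy(float) for v in variables}
    knots = {v: _candidate_knots(xcols[v], max_knots) for v in variables}

    terms: list[MarsTerm] = [MarsTerm()]
    basis = [np.ones(n)]
    # orthonormal running basis for fast SSE-reduction scoring
    q = np.ones((n, 1)) / np.sqrt(n)
    resid = y - q @ (q.T @ y)
    sse = float(resid @ resid)

    while len(terms) + 2 <= max_terms:
        best = None  # (reduction, parent_idx, var, knot)
        # score all (parent, var, knot) candidates in one batch per (parent, var)
        for pi, parent in enumerate(terms):
            if parent.degree >= max_degree:
                continue
            parent_col = basis[pi]
            used = {f.var for f in parent.factors}
            for v in variables:
                if v in used:
                    continue
                tt = knots[v]
                if len(tt) == 0:
                    continue
                x = xcols[v]
                c1 = parent_col[:, None] * np.maximum(0.0, x[:, None] - tt)
                c2 = parent_col[:, None] * np.maximum(0.0, tt - x[:, None])
                u1 = c1 - q @ (q.T @ c1)
                u2 = c2 - q @ (q.T @ c2)
                n1 = (u1 * u1).sum(axis=0)
                a1 = u1.T @ resid
                safe1 = n1 > 1e-12
                red1 = np.where(safe1, a1**2 / np.where(safe1, n1, 1.0), 0.0)
                # orthogonalize the reflected column against its twin
                dot12 = (u1 * u2).sum(axis=0)
                w2 = u2 - u1 * np.where(safe1, dot12 / np.where(safe1, n1, 1.0), 0.0)
                n2 = (w2 * w2).sum(axis=0)
                a2 = w2.T @ resid
                safe2 = n2 > 1e-12
                red2 = np.where(safe2, a2**2 / np.where(safe2, n2, 1.0), 0.0)
                red = red1 + red2
                j = int(np.argmax(red))
                if best is None or red[j] > best[0]:
                    best = (float(red[j]), pi, v, float(tt[j]))
        if best is None or best[0] < min_sse_decrease * max(sse, 1e-300):
            break
        _, pi, v, t = best
        parent = terms[pi]
        for direction in (+1, -1):
            factor = HingeFactor(v, t, direction)
            term = MarsTerm(parent.factors + (factor,))
            col = term.evaluate(mets)
            u = col - q @ (q.T @ col)
            norm = float(np.sqrt(u @ u))
            if norm > 1e-8:
                terms.append(term)
                basis.append(col)
                qnew = (u / norm)[:, None]
                q = np.hstack([q, qnew])
                resid = resid - qnew[:, 0] * float(qnew[:, 0] @ resid)
        sse = float(resid @ resid)

    b = np.column_stack(basis)
    coef, model_sse = _ls(b, y)
    model = MarsModel(list(terms), coef,
                      _gcv(model_sse, n, len(terms), _count_knots(terms), gcv_penalty),
                      gcv_penalty, variables)
    if not prune:
        return model
    return _backward_prune(model, b, y, n)


def _ls(b: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, *_ = np.linalg.lstsq(b, y, rcond=None)
    r = y - b @ coef
    return coef, float(r @ r)


def _count_knots(terms: list[MarsTerm]) -> int:
    return len({(f.var, f.knot) for t in terms for f in t.factors})


def _backward_prune(model: MarsModel, b: np.ndarray, y: np.ndarray, n: int) -> MarsModel:
    """Greedy deletion while GCV strictly decreases."""
    terms = list(model.terms)
    cols = list(range(b.shape[1]))
    current_gcv = model.gcv
    improved = True
    while improved and len(cols) > 1:
        improved = False
        best = None
        for drop in range(1, len(cols)):  # never drop the intercept
            keep = cols[:drop] + cols[drop + 1 :]
            kept_terms = [terms[i] for i in range(len(terms)) if i != drop]
            _, sse = _ls(b[:, keep], y)
            g = _gcv(sse, n, len(keep), _count_knots(kept_terms), model.gcv_penalty)
            if g < current_gcv and (best is None or g < best[0]):
                best = (g, drop)
        if best is not None:
            g, drop = best
            cols.pop(drop)
            terms.pop(drop)
            current_gcv = g
            improved = True
    coef, sse = _ls(b[:, cols], y)
    return MarsModel(terms, coef, current_gcv, model.gcv_penalty, model.variables)


def mars_predict(model: MarsModel, mets: pd.DataFrame) -> np.ndarray:
    missing = {f.var for t in model.terms for f in t.factors} - set(mets.columns)
    if missing:
        raise KeyError(f"missing model variable(s): {sorted(missing)}")
    b = np.column_stack([t.evaluate(mets) for t in model.terms])
    return b @ model.coefficients
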