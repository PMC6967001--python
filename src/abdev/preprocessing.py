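"""Feature preprocessing and selection.

Four pieces, applied in this order when a platform model is built:

1. variance-inflation-factor (VIF) pruning of collinear features
   (``vif_all`` set);
2. mixed stepwise selection minimizing AIC (``vif_selected`` set);
3. z-scaling of the explanatory variables (training mean/sd);
4. optional ordered-quantile (ORQ) normalization of the response:
   the value with average rank r among n training values maps to the
   normal score Phi^-1((r - 0.5) / n), with piecewise-linear
   interpolation (and linear extrapolation) for new values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError

_EPS = 1e-12


# ---------------------------------------------------------------------------
# scaling

@dataclass
class ScalerParams:
    """Per-feature center (mean) and spread (sd, n-1 denominator)."""

    center: pd.Series
    spread: pd.Series

    @property
    def features(self) -> list[str]:
        return list(self.center.index)


def fit_scaler(X: pd.DataFrame) -> ScalerParams:
    """Learn z-scaling parameters; zero-spread features are dropped."""
    center = X.mean()
    spread = X.std(ddof=1)
    dead = spread.index[spread <= _EPS]
    if len(dead):
        warnings.warn(
            f"dropping zero-spread features: {list(dead)}", stacklevel=2
        )
        center = center.drop(dead)
        spread = spread.drop(dead)
    return ScalerParams(center=center, spread=spread)


def apply_scaler(params: ScalerParams, X: pd.DataFrame) -> pd.DataFrame:
    Xs = X[params.features]
    return (Xs - params.center) / params.spread


def invert_scaler(params: ScalerParams, Xs: pd.DataFrame) -> pd.DataFrame:
    return Xs * params.spread + params.center


# ---------------------------------------------------------------------------
# ordered-quantile response transform

@dataclass
class TransformSpec:
    """Response transform: identity, or fitted ordered-quantile pairs."""

    kind: str                      # "identity" | "ordered_quantile"
    values: np.ndarray | None = None   # sorted unique raw training values
    scores: np.ndarray | None = None   # matching normal scores
    n: int = 0

    def to_jsonable(self) -> dict:
        d = {"kind": self.kind, "n": self.n}
        if self.kind == "ordered_quantile":
            d["values"] = self.values.tolist()
            d["scores"] = self.scores.tolist()
        return d

    @classmethod
    def from_jsonable(cls, d: dict) -> "TransformSpec":
        if d["kind"] == "identity":
            return cls(kind="identity", n=d.get("n", 0))
        return cls(kind="ordered_quantile",
                   values=np.asarray(d["values"], dtype=float),
                   scores=np.asarray(d["scores"], dtype=float),
                   n=d["n"])


def identity_transform() -> TransformSpec:
    return TransformSpec(kind="identity")


def fit_orq(y) -> TransformSpec:
    """Fit the ordered-quantile transform on training responses."""
    y = np.asarray(y, dtype=float)
    if len(y) < 10:
        raise DegenerateDataError(
            f"ordered-quantile transform needs >= 10 values, got {len(y)}"
        )
    if np.ptp(y) <= _EPS:
        raise DegenerateDataError(
            "constant response: ordered-quantile transform is degenerate"
        )
    n = len(y)
    ranks = stats.rankdata(y, method="average")
    scores = stats.norm.ppf((ranks - 0.5) / n)
    order = np.argsort(y, kind="stable")
    ys, ss = y[order], scores[order]
    # collapse ties: tied raw values share one (value, score) pair
    uniq_vals, first = np.unique(ys, return_index=True)
    return TransformSpec(kind="ordered_quantile", values=uniq_vals,
                         scores=ss[first], n=n)


def _interp_extrap(x, xp, fp):
    """np.interp with linear extrapolation from the two extreme pairs."""
    x = np.asarray(x, dtype=float)
    out = np.interp(x, xp, fp)
    if len(xp) >= 2:
        lo_slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
        hi_slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        out = np.where(x < xp[0], fp[0] + (x - xp[0]) * lo_slope, out)
        out = np.where(x > xp[-1], fp[-1] + (x - xp[-1]) * hi_slope, out)
    return out


def apply_orq(spec: TransformSpec, v):
    """Map raw values to the transform's scale (vectorized)."""
    if spec.kind == "identity":
        return np.asarray(v, dtype=float)
    return _interp_extrap(v, spec.values, spec.scores)


def invert_orq(spec: TransformSpec, z):
    """Map transformed scores back to the raw scale (vectorized)."""
    if spec.kind == "identity":
        return np.asarray(z, dtype=float)
    return _interp_extrap(z, spec.scores, spec.values)


# ---------------------------------------------------------------------------
# collinearity pruning

def compute_vif(X: pd.DataFrame) -> pd.Series:
    """VIF_j = 1 / (1 - R2_j), feature j regressed on all others (OLS with

    intercept). Perfectly collinear features get +inf, not an exception."""
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 features")
    vifs = {}
    arr = X.to_numpy(dtype=float)
    n = arr.shape[0]
    ones = np.ones((n, 1))
    for j, name in enumerate(X.columns):
        yj = arr[:, j]
        others = np.delete(arr, j, axis=1)
        design = np.hstack([ones, others])
        coef, _, _, _ = np.linalg.lstsq(design, yj, rcond=None)
        resid = yj - design @ coef
        tss = np.sum((yj - yj.mean()) ** 2)
        if tss <= _EPS:
            vifs[name] = np.inf
            continue
        r2 = 1.0 - np.sum(resid ** 2) / tss
        vifs[name] = np.inf if (1.0 - r2) <= _EPS else 1.0 / (1.0 - r2)
    return pd.Series(vifs)


@dataclass
class FeatureSelection:
    """Outcome of collinearity pruning and stepwise selection."""

    vif_all: list[str]
    vif_selected: list[str] = field(default_factory=list)
    removal_log: list[tuple[str, float]] = field(default_factory=list)
    aic_log: list[tuple[int, str, str, float]] = field(default_factory=list)


def prune_collinear(X: pd.DataFrame, threshold: float = 10.0
                    ) -> FeatureSelection:
    """Iteratively remove the feature with the largest VIF >= threshold.

    Tie-break (within 1e-9): the later feature in column order is removed,
    keeping earlier features in the canonical ordering. Stops when every
    VIF is below the threshold or fewer than 2 features remain.
    """
    if threshold <= 1:
        raise ValueError("VIF threshold must exceed 1")
    cols = list(X.columns)
    log: list[tuple[str, float]] = []
    while len(cols) >= 2:
        vifs = compute_vif(X[cols])
        vmax = vifs.max()
        if not (vmax >= threshold):
            break
        tied = [c for c in cols if vifs[c] >= vmax - 1e-9
                or (np.isinf(vmax) and np.isinf(vifs[c]))]
        victim = tied[-1]
        log.append((victim, float(vifs[victim])))
        cols.remove(victim)
    if len(cols) < 2:
        warnings.warn("VIF pruning left fewer than 2 features", stacklevel=2)
    return FeatureSelection(vif_all=cols, removal_log=log)


# ---------------------------------------------------------------------------
# stepwise AIC selection

def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    design = np.hstack([np.ones((len(y), 1)), X])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(np.sum(resid ** 2))


def aic_ols(X: np.ndarray, y: np.ndarray) -> float:
    """Gaussian-likelihood AIC of an OLS fit: n*ln(RSS/n) + 2*(k+1)."""
    n = len(y)
    rss = max(_ols_rss(X, y), 1e-300)
    k = X.shape[1]
    return n * np.log(rss / n) + 2 * (k + 1)


def stepwise_aic(X: pd.DataFrame, y, start: list[str] | None = None
                 ) -> FeatureSelection:
    """Mixed (bidirectional) stepwise selection minimizing AIC.

    Starts from the full candidate set (all columns of ``X`` unless
    ``start`` is given); at each step the single add or drop move that most
    lowers AIC is taken; terminates when no move improves. Moves that leave
    fewer than 3 residual degrees of freedom are disallowed.
    """
    y = np.asarray(y, dtype=float)
    candidates = list(X.columns)
    current = list(start) if start is not None else list(candidates)
    arr = {c: X[c].to_numpy(dtype=float) for c in candidates}
    n = len(y)

    def fit(sel: list[str]) -> float:
        mat = (np.column_stack([arr[c] for c in sel]) if sel
               else np.empty((n, 0)))
        return aic_ols(mat, y)

    log: list[tuple[int, str, str, float]] = []
    current_aic = fit(current)
    log.append((0, "start", "", current_aic))
    step = 0
    while True:
        step += 1
        best_move: tuple[str, str, float] | None = None
        for c in current:
            cand_aic = fit([f for f in current if f != c])
            if best_move is None or cand_aic < best_move[2]:
                best_move = ("drop", c, cand_aic)
        for c in candidates:
            if c in current:
                continue
            if n <= len(current) + 3:   # too few rows to grow the model
                continue
            cand_aic = fit(current + [c])
            if best_move is None or cand_aic < best_move[2]:
                best_move = ("add", c, cand_aic)
        if best_move is None or best_move[2] >= current_aic - 1e-10:
            break
        action, feat, current_aic = best_move
        if action == "drop":
            current.remove(feat)
        else:
            current.append(feat)
        log.append((step, action, feat, current_aic))
    selected = [c for c in candidates if c in current]
    return FeatureSelection(vif_all=candidates, vif_selected=selected,
                            aic_log=log)


def select_features(X: pd.DataFrame, y, vif_threshold: float = 10.0
                    ) -> FeatureSelection:
    """VIF pruning followed by stepwise AIC: both variable sets at once."""
    pruned = prune_collinear(X, threshold=vif_threshold)
    stepped = stepwise_aic(X[pruned.vif_all], y)
    return FeatureSelection(
        vif_all=pruned.vif_all,
        vif_selected=stepped.vif_selected,
        removal_log=pruned.removal_log,
        aic_log=stepped.aic_log,
    )
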