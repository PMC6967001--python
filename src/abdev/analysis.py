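"""Interpretive analyses over a dataset.

Two computations: the feature x platform Pearson correlation matrix
(which sequence properties track which assays), and the aromatic x charge
interaction model for HIC retention — HIC correlates positively with
aromatic content and negatively with absolute charge, but the two
interact: the ionic-strength gradient used for elution screens charge at
short retention times and not at long ones, so a linear main-effects
model misses the coupling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateDataError
from .features import FEATURE_NAMES, feature_table

_DEFAULT_HIC_CENSOR = 25.0


@dataclass
class CorrelationMatrix:
    """Pearson r per (feature, platform) plus per-cell sample size."""

    r: pd.DataFrame           # features x platforms; NaN where undefined
    n: pd.DataFrame
    undefined: dict[tuple[str, str], str]


@dataclass
class InteractionModel:
    """OLS fit of HIC ~ aro + absQ + aro:absQ."""

    intercept: float
    beta_aro: float
    beta_absQ: float
    beta_interaction: float
    stderr: dict[str, float]
    r2: float
    n: int

    def predict(self, aro, absQ):
        aro = np.asarray(aro, dtype=float)
        absQ = np.asarray(absQ, dtype=float)
        return (self.intercept + self.beta_aro * aro + self.beta_absQ * absQ
                + self.beta_interaction * aro * absQ)


def _censored_mask(dataset, platform: str, values: pd.Series) -> pd.Series:
    cfg = dataset.platform_config.get(platform)
    censor = getattr(cfg, "censor_value", None) if cfg else None
    if censor is None and platform == "HIC":
        censor = _DEFAULT_HIC_CENSOR
    if censor is None:
        return pd.Series(False, index=values.index)
    return values >= censor


def feature_platform_correlations(dataset, exclude_censored: bool = True
                                  ) -> CorrelationMatrix:
    """Pairwise-complete Pearson r between each of the 35 features and each

    platform column. HIC rows at/above the censor value are excluded by
    default, consistent with model training. Cells with a constant input
    or fewer than 3 complete pairs are NaN with a recorded reason."""
    features = feature_table(dataset.records)
    platforms = dataset.measurements.columns
    r = pd.DataFrame(np.nan, index=list(FEATURE_NAMES), columns=platforms)
    counts = pd.DataFrame(0, index=list(FEATURE_NAMES), columns=platforms)
    undefined = {}
    for pid in platforms:
        y = dataset.measurements[pid].dropna()
        if exclude_censored:
            y = y[~_censored_mask(dataset, pid, y)]
        for feat in FEATURE_NAMES:
            x = features.loc[y.index, feat]
            n = len(y)
            counts.loc[feat, pid] = n
            if n < 3:
                undefined[(feat, pid)] = "fewer than 3 complete pairs"
                continue
            if x.std() <= 1e-12:
                undefined[(feat, pid)] = "constant feature"
                continue
            if y.std() <= 1e-12:
                undefined[(feat, pid)] = "constant platform column"
                continue
            r.loc[feat, pid] = float(np.corrcoef(x, y)[0, 1])
    return CorrelationMatrix(r=r, n=counts, undefined=undefined)


def fit_hic_interaction(dataset, platform: str = "HIC",
                        scaled: bool = False) -> InteractionModel:
    """OLS interaction model: platform ~ aro + absQ + aro * absQ.

    Censored rows are removed first. By default aro and absQ enter on
    their raw composition-fraction scale (so the fitted surface's axes
    are directly interpretable); ``scaled=True`` z-scales them for
    coefficient comparability.
    """
    if platform not in dataset.measurements.columns:
        raise DegenerateDataError(f"{platform}: no measurement column")
    y = dataset.measurements[platform].dropna()
    y = y[~_censored_mask(dataset, platform, y)]
    if len(y) < 10:
        raise DegenerateDataError(
            f"{platform}: only {len(y)} usable rows (< 10 required)"
        )
    features = feature_table(dataset.records).loc[y.index]
    aro = features["aro"]
    absQ = features["absQ"]
    if scaled:
        aro = (aro - aro.mean()) / aro.std(ddof=1)
        absQ = (absQ - absQ.mean()) / absQ.std(ddof=1)
    X = pd.DataFrame({"aro": aro, "absQ": absQ, "aro:absQ": aro * absQ})
    fit = sm.OLS(y.to_numpy(), sm.add_constant(X.to_numpy())).fit()
    names = ["intercept", "aro", "absQ", "aro:absQ"]
    return InteractionModel(
        intercept=float(fit.params[0]),
        beta_aro=float(fit.params[1]),
        beta_absQ=float(fit.params[2]),
        beta_interaction=float(fit.params[3]),
        stderr=dict(zip(names, np.asarray(fit.bse, dtype=float))),
        r2=float(fit.rsquared),
        n=int(fit.nobs),
    )


def interaction_surface(model: InteractionModel,
                        aro_range: tuple[float, float],
                        absq_range: tuple[float, float],
                        steps: int = 50) -> pd.DataFrame:
    """Gridded prediction surface (aro, absQ, predicted) for heat maps."""
    aro = np.linspace(*aro_range, steps)
    absq = np.linspace(*absq_range, steps)
    A, Q = np.meshgrid(aro, absq)
    pred = model.predict(A.ravel(), Q.ravel())
    return pd.DataFrame({"aro": A.ravel(), "absQ": Q.ravel(),
                         "predicted": pred})
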