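"""Scoring candidate sequences against a trained model suite.

A candidate gets, per platform: the model-scale prediction (raw scale
attached when the response transform is invertible), a 1-100 ranking
within the reference panel (1 = best), and a green/red threshold flag.
Two combined scores summarize the panel: META X averages the ranks of the
six cross/self-interaction assays (ELISA, BVP, PSR, CSI, ACC-STAB, CIC)
and META Y the two hydrophobic-interaction assays (SMAC, HIC); the closer
a candidate sits to the origin of the (META X, META Y) plane, the better
it is predicted to behave on average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import load_platform_defaults
from .errors import AbdevError
from .features import featurize
from .preprocessing import invert_orq


@dataclass
class PredictionReport:
    """Full scoring of one candidate against the suite's reference panel."""

    candidate_id: str
    predictions: dict[str, float]            # model scale
    predictions_raw: dict[str, float]        # raw assay scale
    ranks: dict[str, float]                  # 1-100, 1 = best
    flags: dict[str, str]                    # "green" | "red"
    meta_x: float | None
    meta_y: float | None
    notices: list[str] = field(default_factory=list)

    def to_jsonable(self) -> dict:
        return {
            "candidate_id": self.candidate_id,
            "predictions": self.predictions,
            "predictions_raw": self.predictions_raw,
            "ranks": self.ranks,
            "flags": self.flags,
            "meta_x": self.meta_x,
            "meta_y": self.meta_y,
            "notices": self.notices,
        }


def predict_platforms(suite, fv: str) -> tuple[dict, dict, list[str]]:
    """Per-platform predictions for one Fv sequence.

    Returns (model-scale predictions, raw-scale predictions, notices for
    platforms missing from the suite).
    """
    feats = featurize(fv).to_frame().T
    preds, raws, notices = {}, {}, []
    from .config import PLATFORMS
    for pid in PLATFORMS:
        model = suite.models.get(pid)
        if model is None:
            notices.append(f"{pid}: no trained model in suite")
            continue
        native = float(model.predict(feats)[0])
        preds[pid] = native
        raws[pid] = float(invert_orq(model.pipeline.transform,
                                     np.array([native]))[0])
    return preds, raws, notices


def rank_candidate(value: float, reference_values, direction: str) -> float:
    """1-100 rank of a candidate value within a reference panel.

    The references are ordered from best to worst according to
    ``direction``; the candidate's position is 1 + (number of references
    strictly better). A candidate tying one or more references takes the
    average of the tied references' positions. Position p in [1, n+1] is
    rescaled as rank = 1 + 99 * (p - 1) / n, so 1 (better than all) and
    100 (worse than all) are exactly attainable.
    """
    refs = np.asarray(reference_values, dtype=float)
    n = len(refs)
    if n < 2:
        raise AbdevError("ranking needs at least 2 reference values")
    if direction == "lower_better":
        badness, ref_badness = value, refs
    elif direction == "higher_better":
        badness, ref_badness = -value, -refs
    else:
        raise ValueError(f"unknown direction {direction!r}")
    better = int(np.sum(ref_badness < badness))
    ties = int(np.sum(ref_badness == badness))
    # tied references occupy positions better+1 .. better+ties
    position = better + (ties + 1) / 2 if ties else better + 1
    return 1.0 + 99.0 * (position - 1.0) / n


def meta_scores(ranks: dict[str, float], allow_partial: bool = False
                ) -> tuple[float | None, float | None, list[str]]:
    """(META X, META Y) arithmetic means of the two platform groups.

    Missing member platforms leave the meta value absent (with a notice)
    unless ``allow_partial`` permits averaging the platforms present.
    """
    groups = load_platform_defaults()["meta"]
    notices = []
    out = []
    for label, members in (("META X", groups["x"]), ("META Y", groups["y"])):
        present = [ranks[p] for p in members if p in ranks]
        missing = [p for p in members if p not in ranks]
        if missing and not allow_partial:
            notices.append(f"{label}: missing platform(s) "
                           + ", ".join(missing))
            out.append(None)
        elif not present:
            notices.append(f"{label}: no member platforms available")
            out.append(None)
        else:
            out.append(float(np.mean(present)))
    return out[0], out[1], notices


def flag_thresholds(predictions_raw: dict[str, float], suite,
                    direction_aware: bool = True) -> dict[str, str]:
    """Green/red flag per platform with a threshold.

    Red means the raw-scale prediction lies on the unfavourable side of
    the platform's threshold (for the ``worst_10pct`` rule, the boundary
    resolved against the reference panel at suite-build time). With
    ``direction_aware=False`` the literal rule "above the threshold is
    red" applies regardless of direction.
    """
    flags = {}
    for pid, value in predictions_raw.items():
        model = suite.models.get(pid)
        if model is None or model.resolved_threshold is None:
            continue
        thr = model.resolved_threshold
        if direction_aware and model.config.direction == "higher_better":
            bad = value <= thr
        else:
            bad = value > thr
        flags[pid] = "red" if bad else "green"
    return flags


def build_report(suite, fv: str, candidate_id: str = "candidate",
                 allow_partial: bool = False,
                 rank_against: str = "predictions") -> PredictionReport:
    """Compose predictions, ranks, flags, and meta scores for one Fv.

    ``rank_against`` chooses the reference panel for ranking: the refit
    model's predictions over the panel (default, same scale and estimator
    as the candidate's value) or the observed responses.
    """
    preds, raws, notices = predict_platforms(suite, fv)
    ranks = {}
    for pid, value in preds.items():
        model = suite.models[pid]
        panel = (model.training_predictions if rank_against == "predictions"
                 else model.reference_values)
        ranks[pid] = rank_candidate(value, panel, model.config.direction)
    flags = flag_thresholds(raws, suite)
    meta_x, meta_y, meta_notices = meta_scores(ranks,
                                               allow_partial=allow_partial)
    return PredictionReport(
        candidate_id=candidate_id,
        predictions=preds,
        predictions_raw=raws,
        ranks=ranks,
        flags=flags,
        meta_x=meta_x,
        meta_y=meta_y,
        notices=notices + meta_notices,
    )


def scatter_context(suite, report: PredictionReport) -> pd.DataFrame:
    """Long-form (platform, id, observed, predicted) table of the reference

    panel with the candidate appended at x = y, for scatter plotting."""
    rows = []
    for pid, model in suite.models.items():
        for rid, obs, pred in zip(model.reference_ids,
                                  model.reference_values,
                                  model.training_predictions):
            rows.append({"platform": pid, "id": rid,
                         "observed": float(obs), "predicted": float(pred)})
        if pid in report.predictions:
            v = report.predictions[pid]
            rows.append({"platform": pid, "id": report.candidate_id,
                         "observed": v, "predicted": v})
    return pd.DataFrame(rows)
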