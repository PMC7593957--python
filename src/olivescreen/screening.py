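"""Hierarchical EVOO / VOO / LOO screening with a reject-to-panel option.

Two cascaded binary PLS1-DA models grade an oil: model 1 separates EVOO
(dummy 1) from non-EVOO; model 2, fitted on the non-EVOO training subset,
separates LOO (dummy 1) from VOO. For each model an uncertainty range is
derived from the ROC of its cross-validated predicted values (PV): the
lower threshold is the PV at which sensitivity reaches 1 (the smallest PV
among true positives) and the upper threshold the PV at which specificity
reaches 1 (the largest PV among true negatives). Samples with PV inside the
range are deferred to the sensory panel instead of being forced into a
category; when the classes separate perfectly the range is empty and a
single midpoint threshold is used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .chemometrics import (
    CVANOVAResult,
    CVResult,
    PermutationResult,
    PLSDAModel,
    cross_validate,
    cv_anova,
    permutation_test,
    pls1_fit,
    pls1_predict,
)
from .chromatograms import FingerprintMatrix

log = logging.getLogger(__name__)

Outcome = Literal["EVOO", "VOO", "LOO", "UNCERTAIN"]


# ---------------------------------------------------------------------------
# ROC and uncertainty ranges

@dataclass
class ROCCurve:
    cutoffs: np.ndarray
    sensitivity: np.ndarray   # fraction of positives with PV >= cutoff
    specificity: np.ndarray   # fraction of negatives with PV < cutoff
    positive_label: str = "positive"


def roc_from_cv(oof_pv: np.ndarray, labels: np.ndarray,
                positive_label: str = "positive") -> ROCCurve:
    """ROC over all distinct PVs plus sentinels below/above the range."""
    pv = np.asarray(oof_pv, float)
    lab = np.asarray(labels).astype(bool)
    if lab.all() or not lab.any():
        raise ValueError("both classes must be present")
    uniq = np.unique(pv)
    span = max(uniq[-1] - uniq[0], 1.0)
    cutoffs = np.concatenate([[uniq[0] - 0.01 * span], uniq,
                              [uniq[-1] + 0.01 * span]])
    pos = pv[lab]
    neg = pv[~lab]
    sens = np.array([(pos >= c).mean() for c in cutoffs])
    spec = np.array([(neg < c).mean() for c in cutoffs])
    return ROCCurve(cutoffs=cutoffs, sensitivity=sens, specificity=spec,
                    positive_label=positive_label)


@dataclass
class UncertaintyRange:
    """PV band inside which classification is deferred to the panel.

    ``lower`` is the smallest cross-validated PV among true positives and
    ``upper`` the largest among true negatives. If the classes separate
    perfectly (lower > upper) the range is empty and ``single_threshold``
    (the midpoint of the gap) decides alone.
    """

    lower: float
    upper: float

    @property
    def empty(self) -> bool:
        return self.lower > self.upper

    @property
    def single_threshold(self) -> float | None:
        if not self.empty:
            return None
        return (self.lower + self.upper) / 2.0

    def to_dict(self) -> dict:
        return {"lower": self.lower, "upper": self.upper}


def uncertainty_range(oof_pv: np.ndarray, labels: np.ndarray) -> UncertaintyRange:
    """ROC-derived uncertainty range from CV predicted values and truth."""
    pv = np.asarray(oof_pv, float)
    lab = np.asarray(labels).astype(bool)
    if lab.all() or not lab.any():
        raise ValueError("both classes must be present")
    return UncertaintyRange(lower=float(pv[lab].min()),
                            upper=float(pv[~lab].max()))


def decide_binary(pv: float, rng: UncertaintyRange) -> Literal["positive", "negative", "uncertain"]:
    """Classify one PV against an uncertainty range.

    PVs exactly on a threshold are uncertain (closed interval — conservative
    deferral); with an empty range, PV >= the midpoint threshold is positive.
    """
    if rng.empty:
        return "positive" if pv >= rng.single_threshold else "negative"
    if pv > rng.upper:
        return "positive"
    if pv < rng.lower:
        return "negative"
    return "uncertain"


# ---------------------------------------------------------------------------
# hierarchical model

@dataclass
class ModelDiagnostics:
    cv: CVResult | None
    permutation: PermutationResult | None
    anova: CVANOVAResult | None
    q2_flag: bool          # True when Q2 at the chosen LV fails the > 0.4 benchmark
    anova_flag: bool       # True when CV-ANOVA p >= 0.05
    permutation_flag: bool  # True when a permuted Q2 matches or beats the original

    @property
    def clean(self) -> bool:
        return not (self.q2_flag or self.anova_flag or self.permutation_flag)


@dataclass
class ScreeningConfig:
    max_lv: int = 10
    n_folds: int = 10
    n_permutations: int = 20
    q2_benchmark: float = 0.4
    anova_alpha: float = 0.05
    seed: int = 0


@dataclass
class HierarchicalScreeningModel:
    model1: PLSDAModel            # EVOO = 1 vs non-EVOO = 0
    range1: UncertaintyRange
    model2: PLSDAModel            # LOO = 1 vs VOO = 0, non-EVOO subset
    range2: UncertaintyRange
    diagnostics1: ModelDiagnostics
    diagnostics2: ModelDiagnostics
    config: ScreeningConfig
    rt_axis: np.ndarray | None = None

    def to_json(self, path: str | Path) -> None:
        d = {
            "model1": self.model1.to_dict(),
            "range1": self.range1.to_dict(),
            "model2": self.model2.to_dict(),
            "range2": self.range2.to_dict(),
            "config": vars(self.config),
            "rt_axis": None if self.rt_axis is None else list(self.rt_axis),
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "HierarchicalScreeningModel":
        d = json.loads(Path(path).read_text())
        dummy = ModelDiagnostics(cv=None, permutation=None, anova=None,
                                 q2_flag=False, anova_flag=False,
                                 permutation_flag=False)
        return cls(
            model1=PLSDAModel.from_dict(d["model1"]),
            range1=UncertaintyRange(**d["range1"]),
            model2=PLSDAModel.from_dict(d["model2"]),
            range2=UncertaintyRange(**d["range2"]),
            diagnostics1=dummy, diagnostics2=dummy,
            config=ScreeningConfig(**d["config"]),
            rt_axis=None if d["rt_axis"] is None else np.asarray(d["rt_axis"]),
        )


@dataclass
class ScreeningDecision:
    sample_id: str
    pv1: float
    pv2: float | None
    outcome: Outcome
    deferred_at: Literal["model1", "model2", "none"]


def _diagnose(X: np.ndarray, y: np.ndarray, cv: CVResult,
              config: ScreeningConfig) -> ModelDiagnostics:
    anova = cv_anova(cv, y)
    perm = None
    perm_flag = False
    if config.n_permutations > 0:
        perm = permutation_test(X, y, n_lv=cv.chosen_lv,
                                n_perm=config.n_permutations,
                                seed=config.seed, n_folds=config.n_folds)
        perm_flag = not perm.original_exceeds_all
    q2 = float(cv.q2[cv.chosen_lv - 1])
    diag = ModelDiagnostics(
        cv=cv, permutation=perm, anova=anova,
        q2_flag=not (q2 > config.q2_benchmark),
        anova_flag=not (anova.p_value < config.anova_alpha),
        permutation_flag=perm_flag,
    )
    if not diag.clean:
        log.warning(
            "model diagnostics flagged: Q2=%.3f (flag=%s), ANOVA p=%.3g (flag=%s), "
            "permutation flag=%s", q2, diag.q2_flag, anova.p_value,
            diag.anova_flag, diag.permutation_flag)
    return diag


def fit_screening_model(
    training: FingerprintMatrix,
    categories: Sequence[str],
    config: ScreeningConfig | None = None,
) -> HierarchicalScreeningModel:
    """Train the two-step cascade with CV-based uncertainty ranges.

    Model 1 is fitted on all training rows (EVOO dummy); model 2 on the true
    non-EVOO subset with its own preprocessor (LOO dummy). Each model's LV
    count is chosen by RMSEcv; its uncertainty range comes from the
    out-of-fold PVs at that LV count. Models failing the Q² > 0.4 or
    CV-ANOVA p < 0.05 benchmarks are flagged in the diagnostics, not
    rejected. By construction every training sample assigned by the ranges
    is assigned correctly (asserted).
    """
    config = config or ScreeningConfig()
    cats = np.asarray([str(c) for c in categories])
    if cats.size != training.n_samples:
        raise ValueError("categories length does not match matrix rows")
    for needed in ("EVOO", "VOO", "LOO"):
        if not (cats == needed).any():
            raise ValueError(f"category {needed} absent from training set")

    X = training.values
    y1 = (cats == "EVOO").astype(float)
    cv1 = cross_validate(X, y1, max_lv=config.max_lv, n_folds=config.n_folds,
                         seed=config.seed)
    model1 = pls1_fit(X, y1, n_lv=cv1.chosen_lv,
                      dummy_coding={"EVOO": 1, "non-EVOO": 0},
                      training_ids=list(training.sample_ids))
    range1 = uncertainty_range(cv1.oof_at_chosen, y1 == 1)
    diag1 = _diagnose(X, y1, cv1, config)

    sub_idx = np.flatnonzero(cats != "EVOO")
    X2 = X[sub_idx]
    y2 = (cats[sub_idx] == "LOO").astype(float)
    cv2 = cross_validate(X2, y2, max_lv=config.max_lv, n_folds=config.n_folds,
                         seed=config.seed + 1)
    model2 = pls1_fit(X2, y2, n_lv=cv2.chosen_lv,
                      dummy_coding={"LOO": 1, "VOO": 0},
                      training_ids=[training.sample_ids[i] for i in sub_idx])
    range2 = uncertainty_range(cv2.oof_at_chosen, y2 == 1)
    diag2 = _diagnose(X2, y2, cv2, config)

    model = HierarchicalScreeningModel(
        model1=model1, range1=range1, model2=model2, range2=range2,
        diagnostics1=diag1, diagnostics2=diag2, config=config,
        rt_axis=np.asarray(training.rt_axis),
    )
    _assert_training_guarantee(cv1.oof_at_chosen, y1, range1)
    _assert_training_guarantee(cv2.oof_at_chosen, y2, range2)
    return model


def _assert_training_guarantee(oof_pv: np.ndarray, y: np.ndarray,
                               rng: UncertaintyRange) -> None:
    """Every training sample the range assigns must be assigned correctly."""
    for pv, truth in zip(oof_pv, y):
        d = decide_binary(float(pv), rng)
        if d == "positive":
            assert truth == 1, "assigned positive but truth is negative"
        elif d == "negative":
            assert truth == 0, "assigned negative but truth is positive"


def screen(
    model: HierarchicalScreeningModel,
    samples: FingerprintMatrix,
) -> list[ScreeningDecision]:
    """Run the cascade on new samples.

    PV1 decides EVOO / uncertain / non-EVOO; only clear non-EVOO samples get
    a PV2 and a VOO/LOO (or uncertain) call. Samples uncertain at model 1 go
    straight to the panel.
    """
    if model.rt_axis is not None and samples.rt_axis.size != model.rt_axis.size:
        raise ValueError("sample grid does not match the training grid")
    if model.rt_axis is not None and not np.allclose(samples.rt_axis, model.rt_axis):
        raise ValueError("sample retention axis differs from the training axis")
    pv1 = pls1_predict(model.model1, samples.values)
    decisions: list[ScreeningDecision] = []
    for i, sid in enumerate(samples.sample_ids):
        d1 = decide_binary(float(pv1[i]), model.range1)
        if d1 == "positive":
            decisions.append(ScreeningDecision(sid, float(pv1[i]), None,
                                               "EVOO", "none"))
        elif d1 == "uncertain":
            decisions.append(ScreeningDecision(sid, float(pv1[i]), None,
                                               "UNCERTAIN", "model1"))
        else:
            pv2 = float(pls1_predict(model.model2, samples.values[i])[0])
            d2 = decide_binary(pv2, model.range2)
            if d2 == "positive":
                outcome: Outcome = "LOO"
                deferred = "none"
            elif d2 == "negative":
                outcome = "VOO"
                deferred = "none"
            else:
                outcome = "UNCERTAIN"
                deferred = "model2"
            decisions.append(ScreeningDecision(sid, float(pv1[i]), pv2,
                                               outcome, deferred))
    return decisions


def decisions_to_frame(decisions: Sequence[ScreeningDecision]) -> pd.DataFrame:
    return pd.DataFrame([
        {"sample_id": d.sample_id, "pv1": d.pv1, "pv2": d.pv2,
         "outcome": d.outcome, "deferred_at": d.deferred_at}
        for d in decisions
    ])


def write_decisions_tsv(decisions: Sequence[ScreeningDecision],
                        path: str | Path) -> None:
    decisions_to_frame(decisions).to_csv(path, sep="\t", index=False)
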