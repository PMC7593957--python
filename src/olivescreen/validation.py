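"""Repeated external validation of the screening tool.

The study design: the sample set is stratified-split several times (default
seven) into 80% training / 20% validation per category; the full cascade
(CV, uncertainty ranges) is refit on each training set and applied to the
held-out oils. Reports mirror the study's tables: per-category uncertain /
assigned / correct-of-assigned / reliable percentages (reliable counts a
deferred sample as resolved correctly by the panel, the reference method),
per-split thresholds, and a breakdown of non-EVOO results by main perceived
defect (MPD) with the "(k/n)" count pairs retained next to percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chromatograms import FingerprintMatrix
from .screening import (
    HierarchicalScreeningModel,
    ScreeningConfig,
    ScreeningDecision,
    fit_screening_model,
    screen,
)
from .simulate import DEFECTS, SampleTruth

log = logging.getLogger(__name__)

CATEGORIES = ("EVOO", "VOO", "LOO")


def pct(k: int, n: int) -> float | None:
    """Percentage to table precision; None (printed blank) when n = 0."""
    if n == 0:
        return None
    return round(100.0 * k / n, 1)


# ---------------------------------------------------------------------------
# splits

@dataclass
class SplitSpec:
    split_id: int
    seed: int
    train_fraction: float
    train_ids: list[str]
    validation_ids: list[str]


def stratified_split(
    metadata: Sequence[SampleTruth] | pd.DataFrame,
    fraction: float = 0.8,
    seed: int = 0,
    split_id: int = 0,
) -> SplitSpec:
    """Seeded per-category 80/20 split.

    The training count per category is round-half-up(fraction * n_cat); the
    remainder goes to validation. For the study's post-outlier category
    counts 122/108/71 this yields exactly 98/86/57 training and 24/22/14
    validation samples.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if isinstance(metadata, pd.DataFrame):
        ids = [str(s) for s in metadata["sample_id"]]
        cats = [str(c) for c in metadata["category"]]
    else:
        ids = [t.sample_id for t in metadata]
        cats = [t.category for t in metadata]
    cats_arr = np.asarray(cats)
    rng = np.random.default_rng(seed % (2**31))
    train: list[str] = []
    valid: list[str] = []
    for cat in CATEGORIES:
        idx = np.flatnonzero(cats_arr == cat)
        if idx.size == 0:
            raise ValueError(f"category {cat} has no samples")
        n_train = int(np.floor(fraction * idx.size + 0.5))  # round half up
        perm = rng.permutation(idx)
        train.extend(ids[i] for i in perm[:n_train])
        valid.extend(ids[i] for i in perm[n_train:])
    return SplitSpec(split_id=split_id, seed=seed, train_fraction=fraction,
                     train_ids=train, validation_ids=valid)


# ---------------------------------------------------------------------------
# per-split evaluation

@dataclass
class StratumMetrics:
    n_total: int
    n_uncertain: int
    n_assigned: int
    n_correct: int

    @property
    def pct_uncertain(self) -> float | None:
        return pct(self.n_uncertain, self.n_total)

    @property
    def pct_assigned(self) -> float | None:
        return pct(self.n_assigned, self.n_total)

    @property
    def pct_correct_of_assigned(self) -> float | None:
        return pct(self.n_correct, self.n_assigned)

    @property
    def pct_reliable(self) -> float | None:
        """Correct plus panel-resolved-uncertain, out of all samples."""
        return pct(self.n_correct + self.n_uncertain, self.n_total)


@dataclass
class SplitResult:
    split_id: int
    per_category: dict[str, StratumMetrics]
    total: StratumMetrics
    decisions: list[ScreeningDecision] = field(default_factory=list)
    model: HierarchicalScreeningModel | None = None


def _tally(decisions: Sequence[ScreeningDecision],
           truth_of: dict[str, str], ids: Sequence[str]) -> StratumMetrics:
    n_total = len(ids)
    n_unc = 0
    n_correct = 0
    for d in decisions:
        if d.sample_id not in ids:
            continue
        if d.outcome == "UNCERTAIN":
            n_unc += 1
        elif d.outcome == truth_of[d.sample_id]:
            n_correct += 1
    n_assigned = n_total - n_unc
    m = StratumMetrics(n_total=n_total, n_uncertain=n_unc,
                       n_assigned=n_assigned, n_correct=n_correct)
    assert m.n_uncertain + m.n_assigned == m.n_total
    assert m.n_correct <= m.n_assigned
    return m


def evaluate_split(
    model: HierarchicalScreeningModel,
    validation: FingerprintMatrix,
    truths: Sequence[SampleTruth],
    split_id: int = 0,
) -> SplitResult:
    """Screen the held-out samples and tabulate per-category metrics.

    Validation ids must be disjoint from both models' training ids (leakage
    guard on the PLS/threshold fitting; alignment is fitted upstream on the
    full matrix, mirroring the study workflow).
    """
    train_ids = set(model.model1.training_ids)
    overlap = train_ids & set(validation.sample_ids)
    if overlap:
        raise ValueError(f"validation overlaps training: {sorted(overlap)[:5]}")
    truth_of = {t.sample_id: t.category for t in truths}
    missing = [s for s in validation.sample_ids if s not in truth_of]
    if missing:
        raise ValueError(f"truths missing for {missing[:5]}")
    decisions = screen(model, validation)
    per_cat: dict[str, StratumMetrics] = {}
    for cat in CATEGORIES:
        ids = {s for s in validation.sample_ids if truth_of[s] == cat}
        per_cat[cat] = _tally(decisions, truth_of, ids)
    total = _tally(decisions, truth_of, set(validation.sample_ids))
    return SplitResult(split_id=split_id, per_category=per_cat, total=total,
                       decisions=decisions, model=model)


# ---------------------------------------------------------------------------
# repeated validation

@dataclass
class AggregateReport:
    splits: list[SplitResult]
    split_specs: list[SplitSpec]
    master_seed: int
    summary: pd.DataFrame            # rows EVOO/VOO/LOO/Total, mean +/- SD
    thresholds: pd.DataFrame         # per-split ranges and CV uncertain %


def _weighted_mean_sd(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    w = weights / weights.sum()
    mean = float((w * values).sum())
    var = float((w * (values - mean) ** 2).sum())
    return mean, float(np.sqrt(var))


def summarize_splits(splits: Sequence[SplitResult]) -> pd.DataFrame:
    """Mean and SD across splits, per category and total.

    The total correct-of-assigned uses the weighted mean over splits
    (weights = assigned counts), as an overall rate should.
    """
    rows = []
    for cat in list(CATEGORIES) + ["Total"]:
        get = (lambda r, c=cat: r.total if c == "Total" else r.per_category[c])
        unc = np.array([get(r).pct_uncertain for r in splits], float)
        asg = np.array([get(r).pct_assigned for r in splits], float)
        cor = np.array([m if (m := get(r).pct_correct_of_assigned) is not None
                        else np.nan for r in splits], float)
        rel = np.array([get(r).pct_reliable for r in splits], float)
        row = {
            "stratum": cat,
            "uncertain_mean": np.nanmean(unc), "uncertain_sd": np.nanstd(unc, ddof=1),
            "assigned_mean": np.nanmean(asg), "assigned_sd": np.nanstd(asg, ddof=1),
            "reliable_mean": np.nanmean(rel), "reliable_sd": np.nanstd(rel, ddof=1),
        }
        if cat == "Total":
            weights = np.array([get(r).n_assigned for r in splits], float)
            ok = ~np.isnan(cor)
            row["correct_mean"], row["correct_sd"] = _weighted_mean_sd(
                cor[ok], weights[ok])
        else:
            row["correct_mean"] = np.nanmean(cor)
            row["correct_sd"] = np.nanstd(cor, ddof=1)
        rows.append(row)
    return pd.DataFrame(rows)


def thresholds_table(splits: Sequence[SplitResult]) -> pd.DataFrame:
    """Per-split uncertainty thresholds and CV uncertain rates (both models)."""
    rows = []
    for r in splits:
        m = r.model
        row = {"split": r.split_id}
        for which, rng, diag in (
            ("model1", m.range1, m.diagnostics1),
            ("model2", m.range2, m.diagnostics2),
        ):
            oof = diag.cv.oof_at_chosen
            if rng.empty:
                lo, up = rng.single_threshold, None
                n_unc = 0
            else:
                lo, up = rng.lower, rng.upper
                n_unc = int(((oof >= rng.lower) & (oof <= rng.upper)).sum())
            row[f"{which}_lower"] = lo
            row[f"{which}_upper"] = up
            row[f"{which}_n_lv"] = diag.cv.chosen_lv
            row[f"{which}_q2"] = float(diag.cv.q2[diag.cv.chosen_lv - 1])
            row[f"{which}_pct_uncertain_cv"] = pct(n_unc, oof.size)
        rows.append(row)
    df = pd.DataFrame(rows)
    means = df.drop(columns="split").mean(numeric_only=True)
    sds = df.drop(columns="split").std(numeric_only=True, ddof=1)
    df.loc[len(df)] = {"split": "mean", **means.to_dict()}
    df.loc[len(df)] = {"split": "sd", **sds.to_dict()}
    return df


def run_repeated_validation(
    matrix: FingerprintMatrix,
    truths: Sequence[SampleTruth],
    n_splits: int = 7,
    master_seed: int = 0,
    config: ScreeningConfig | None = None,
    train_fraction: float = 0.8,
) -> AggregateReport:
    """Fit and externally validate the cascade on repeated stratified splits.

    One master seed spawns per-split seeds (recorded in each SplitSpec for
    replay). The input matrix should already be aligned.
    """
    if n_splits < 2:
        raise ValueError("n_splits must be >= 2")
    base = config or ScreeningConfig()
    rng = np.random.default_rng(master_seed % (2**31))
    split_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_splits)]
    truth_list = list(truths)
    id_to_row = {s: i for i, s in enumerate(matrix.sample_ids)}
    results: list[SplitResult] = []
    specs: list[SplitSpec] = []
    for k, sd in enumerate(split_seeds, start=1):
        spec = stratified_split(truth_list, fraction=train_fraction,
                                seed=sd, split_id=k)
        specs.append(spec)
        tr_idx = [id_to_row[s] for s in spec.train_ids]
        va_idx = [id_to_row[s] for s in spec.validation_ids]
        train_m = matrix.subset(tr_idx)
        valid_m = matrix.subset(va_idx)
        cat_of = {t.sample_id: t.category for t in truth_list}
        train_cats = [cat_of[s] for s in train_m.sample_ids]
        cfg = ScreeningConfig(**{**vars(base), "seed": sd})
        model = fit_screening_model(train_m, train_cats, cfg)
        results.append(evaluate_split(model, valid_m, truth_list, split_id=k))
        log.info("split %d/%d done", k, n_splits)
    return AggregateReport(
        splits=results,
        split_specs=specs,
        master_seed=master_seed,
        summary=summarize_splits(results),
        thresholds=thresholds_table(results),
    )


# ---------------------------------------------------------------------------
# MPD breakdown

@dataclass
class MPDRow:
    mpd: str
    n: int
    n_uncertain: int
    n_assigned: int
    n_survived_model1: int        # assigned samples classified non-EVOO
    n_voo_true: int               # true VOO reaching a final model-2 call
    n_voo_correct: int
    n_loo_true: int
    n_loo_correct: int
    boundary_n: int = 0
    boundary_uncertain: int = 0
    boundary_correct: int = 0

    @property
    def pct_uncertain(self) -> float | None:
        return pct(self.n_uncertain, self.n)

    @property
    def pct_assigned(self) -> float | None:
        return pct(self.n_assigned, self.n)

    @property
    def pct_correct_as_nonevoo(self) -> float | None:
        return pct(self.n_survived_model1, self.n_assigned)

    @property
    def pct_correct_as_voo(self) -> float | None:
        return pct(self.n_voo_correct, self.n_voo_true)

    @property
    def pct_correct_as_loo(self) -> float | None:
        return pct(self.n_loo_correct, self.n_loo_true)


def mpd_breakdown(
    decisions: Sequence[ScreeningDecision],
    truths: Sequence[SampleTruth],
) -> list[MPDRow]:
    """Non-EVOO screening results by main perceived defect.

    Convention (count pairs kept alongside): uncertain out of all samples
    with the defect; correct-as-nonEVOO out of assigned samples (those not
    deferred); correct-as-VOO/LOO out of true-VOO/true-LOO samples that
    reached a final model-2 category. Every non-EVOO decision lands in
    exactly one row.
    """
    truth_of = {t.sample_id: t for t in truths}
    dec_of = {d.sample_id: d for d in decisions}
    non_evoo = [t for t in truths if t.sample_id in dec_of and t.category != "EVOO"]
    for t in non_evoo:
        if t.mpd == "none":
            raise ValueError(f"non-EVOO sample {t.sample_id} lacks an MPD")
    rows = []
    for defect in DEFECTS:
        members = [t for t in non_evoo if t.mpd == defect]
        n = len(members)
        unc = [t for t in members if dec_of[t.sample_id].outcome == "UNCERTAIN"]
        assigned = [t for t in members if dec_of[t.sample_id].outcome != "UNCERTAIN"]
        survived = [t for t in assigned
                    if dec_of[t.sample_id].outcome in ("VOO", "LOO")]
        voo_true = [t for t in assigned
                    if t.category == "VOO" and dec_of[t.sample_id].pv2 is not None]
        loo_true = [t for t in assigned
                    if t.category == "LOO" and dec_of[t.sample_id].pv2 is not None]
        boundary = [t for t in members if t.boundary_flag]
        rows.append(MPDRow(
            mpd=defect, n=n,
            n_uncertain=len(unc),
            n_assigned=len(assigned),
            n_survived_model1=len(survived),
            n_voo_true=len(voo_true),
            n_voo_correct=sum(dec_of[t.sample_id].outcome == "VOO" for t in voo_true),
            n_loo_true=len(loo_true),
            n_loo_correct=sum(dec_of[t.sample_id].outcome == "LOO" for t in loo_true),
            boundary_n=len(boundary),
            boundary_uncertain=sum(
                dec_of[t.sample_id].outcome == "UNCERTAIN" for t in boundary),
            boundary_correct=sum(
                dec_of[t.sample_id].outcome == t.category for t in boundary),
        ))
    return rows


def mpd_rows_to_frame(rows: Sequence[MPDRow]) -> pd.DataFrame:
    def cell(p, k, n):
        return "" if p is None else f"{p} ({k}/{n})"

    return pd.DataFrame([
        {
            "mpd": r.mpd,
            "n": r.n,
            "uncertain": cell(r.pct_uncertain, r.n_uncertain, r.n),
            "assigned": cell(r.pct_assigned, r.n_assigned, r.n),
            "correct_as_nonEVOO": cell(r.pct_correct_as_nonevoo,
                                       r.n_survived_model1, r.n_assigned),
            "correct_as_VOO": cell(r.pct_correct_as_voo,
                                   r.n_voo_correct, r.n_voo_true),
            "correct_as_LOO": cell(r.pct_correct_as_loo,
                                   r.n_loo_correct, r.n_loo_true),
            "boundary_n": r.boundary_n,
            "boundary_uncertain": r.boundary_uncertain,
            "boundary_correct": r.boundary_correct,
        }
        for r in rows
    ])
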