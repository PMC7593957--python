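"""Interval correlation-optimized shifting of chromatographic fingerprints.

Retention times drift within and between GC batches, so raw fingerprints are
aligned before modelling: the axis is cut into equal-width intervals and each
row's interval segment is shifted by the integer number of scans (within
±max_shift) that maximizes its Pearson correlation with the reference
segment, vacated positions being filled with the nearest retained boundary
value. Batched data are pre-aligned batch by batch against each batch's own
mean, then globally against the grand mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .chromatograms import FingerprintMatrix

log = logging.getLogger(__name__)


class AlignmentConfigError(ValueError):
    """Interval/shift configuration is inconsistent with the axis length."""


@dataclass
class AlignmentResult:
    """Applied integer shifts (scans), per row and interval."""

    shifts: np.ndarray            # n x n_intervals, int
    reference: np.ndarray         # the target row segments were matched to
    intervals: list[tuple[int, int]]  # half-open [start, end) scan ranges
    max_shift: int


def _make_intervals(p: int, n_intervals: int) -> list[tuple[int, int]]:
    if n_intervals < 1:
        raise AlignmentConfigError("n_intervals must be >= 1")
    if n_intervals > p:
        raise AlignmentConfigError("more intervals than scan points")
    edges = np.linspace(0, p, n_intervals + 1).astype(int)
    return [(int(edges[i]), int(edges[i + 1])) for i in range(n_intervals)]


def _shift_segment(seg: np.ndarray, shift: int) -> np.ndarray:
    """Shift segment content by `shift` scans, edge-padding vacated positions."""
    if shift == 0:
        return seg
    out = np.empty_like(seg)
    if shift > 0:
        out[shift:] = seg[:-shift]
        out[:shift] = seg[0]
    else:
        out[:shift] = seg[-shift:]
        out[shift:] = seg[-1]
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa = a.std()
    sb = b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.dot(a - a.mean(), b - b.mean()) / (a.size * sa * sb))


def _candidate_order(max_shift: int) -> list[int]:
    """Shift candidates in tie-break preference order: 0, -1, +1, -2, +2, ..."""
    order = [0]
    for k in range(1, max_shift + 1):
        order.extend((-k, k))
    return order


def _best_shift(seg: np.ndarray, ref_seg: np.ndarray, max_shift: int) -> int:
    best, best_corr = 0, _pearson(seg, ref_seg)
    if np.isnan(best_corr):
        best_corr = -np.inf
    for cand in _candidate_order(max_shift):
        if cand == 0:
            continue
        c = _pearson(_shift_segment(seg, cand), ref_seg)
        if not np.isnan(c) and c > best_corr + 1e-12:
            best, best_corr = cand, c
    return best


def _reference_row(values: np.ndarray, reference) -> np.ndarray:
    if isinstance(reference, str):
        if reference == "mean":
            return values.mean(axis=0)
        if reference == "median":
            return np.median(values, axis=0)
        raise ValueError(f"unknown reference {reference!r}")
    return values[int(reference)].copy()


def icoshift_align(
    matrix: FingerprintMatrix,
    reference="mean",
    n_intervals: int = 50,
    max_shift: int | None = None,
) -> tuple[FingerprintMatrix, AlignmentResult]:
    """Align every row to the reference, interval by interval.

    ``max_shift=None`` uses 10% of the interval length (at least 1 scan).
    Correlation ties break toward the smaller absolute shift, then the
    negative one; a row whose full-row correlation with the reference would
    decrease is left unshifted, so per-row correlation never degrades.
    """
    if matrix.n_samples < 2:
        raise ValueError("alignment needs at least 2 rows")
    values = matrix.values
    p = matrix.n_points
    intervals = _make_intervals(p, n_intervals)
    ref = _reference_row(values, reference)

    min_len = min(e - s for s, e in intervals)
    if max_shift is None:
        ms = max(1, min_len // 10)
    else:
        ms = int(max_shift)
        if ms < 0:
            raise AlignmentConfigError("max_shift must be >= 0")
    if min_len < 2 * ms + 2:
        raise AlignmentConfigError(
            f"interval length {min_len} too short for max_shift {ms} "
            f"(needs >= {2 * ms + 2} scans)")

    n = matrix.n_samples
    shifts = np.zeros((n, len(intervals)), dtype=int)
    aligned = values.copy()
    for i in range(n):
        for j, (s, e) in enumerate(intervals):
            sh = _best_shift(values[i, s:e], ref[s:e], ms)
            shifts[i, j] = sh
            if sh:
                aligned[i, s:e] = _shift_segment(values[i, s:e], sh)
        # whole-row guard: never let alignment degrade the row's correlation
        before = _pearson(values[i], ref)
        after = _pearson(aligned[i], ref)
        if not np.isnan(before) and (np.isnan(after) or after < before - 1e-12):
            aligned[i] = values[i]
            shifts[i, :] = 0

    out = FingerprintMatrix(
        sample_ids=list(matrix.sample_ids),
        rt_axis=matrix.rt_axis,
        values=aligned,
        aligned=True,
        batch_of=dict(matrix.batch_of),
    )
    return out, AlignmentResult(shifts=shifts, reference=ref,
                                intervals=intervals, max_shift=ms)


def align_batched(
    matrix: FingerprintMatrix,
    n_intervals: int = 50,
    max_shift: int | None = None,
) -> tuple[FingerprintMatrix, list[AlignmentResult]]:
    """Two-stage alignment: per batch against the batch mean, then globally.

    Every sample must carry a batch label. Single-sample batches skip the
    per-batch stage (logged). With a single batch this reduces to one global
    icoshift pass.
    """
    missing = [s for s in matrix.sample_ids if s not in matrix.batch_of]
    if missing:
        raise ValueError(f"samples missing batch labels: {missing[:5]}")
    batches = matrix.batches()
    values = matrix.values.copy()
    results: list[AlignmentResult] = []
    unique = np.unique(batches)
    if unique.size > 1:
        for b in unique:
            idx = np.flatnonzero(batches == b)
            if idx.size < 2:
                log.info("batch %s has a single sample; skipping stage 1", b)
                continue
            sub = matrix.subset(idx)
            sub_aligned, res = icoshift_align(
                sub, reference="mean", n_intervals=n_intervals, max_shift=max_shift)
            values[idx] = sub_aligned.values
            results.append(res)
    staged = FingerprintMatrix(
        sample_ids=list(matrix.sample_ids),
        rt_axis=matrix.rt_axis,
        values=values,
        aligned=False,
        batch_of=dict(matrix.batch_of),
    )
    final, res_global = icoshift_align(
        staged, reference="mean", n_intervals=n_intervals, max_shift=max_shift)
    results.append(res_global)
    return final, results


def mean_row_correlation(matrix: FingerprintMatrix, reference="mean") -> float:
    """Mean per-row Pearson correlation with the reference chromatogram."""
    ref = _reference_row(matrix.values, reference)
    cors = [_pearson(row, ref) for row in matrix.values]
    return float(np.nanmean(cors))
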