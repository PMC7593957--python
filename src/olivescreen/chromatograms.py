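"""Chromatogram containers and standard-format readers.

A :class:`Chromatogram` holds one sample's total ion chromatogram (TIC):
the per-scan sum of MS intensities over the acquired m/z range, indexed by
retention time in minutes. A :class:`FingerprintMatrix` stacks many samples
interpolated onto a shared retention grid; the raw, untargeted signal is the
feature vector ("fingerprint") — no peak picking or integration happens here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input file violates the chromatogram contract."""


@dataclass
class Chromatogram:
    """One sample's TIC: retention times (minutes) and intensities."""

    sample_id: str
    rt: np.ndarray
    intensity: np.ndarray
    batch: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.ndim != 1 or self.intensity.ndim != 1:
            raise FormatError("rt and intensity must be 1-D")
        if self.rt.size != self.intensity.size:
            raise FormatError("rt and intensity lengths differ")
        if self.rt.size < 2:
            raise FormatError("chromatogram needs at least 2 scans")
        if not np.all(np.diff(self.rt) > 0):
            raise FormatError("retention times must be strictly increasing")

    def __len__(self) -> int:
        return self.rt.size


@dataclass
class FingerprintMatrix:
    """Samples x scan-points intensity matrix on a shared retention axis."""

    sample_ids: list[str]
    rt_axis: np.ndarray
    values: np.ndarray
    aligned: bool = False
    batch_of: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rt_axis = np.asarray(self.rt_axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("values must be 2-D")
        n, p = self.values.shape
        if n < 1:
            raise FormatError("matrix needs at least one sample")
        if len(self.sample_ids) != n:
            raise FormatError("sample_ids length does not match row count")
        if self.rt_axis.size != p:
            raise FormatError("rt_axis length does not match column count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_points(self) -> int:
        return self.values.shape[1]

    def batches(self) -> np.ndarray:
        """Batch label per row, in row order (0 where unknown)."""
        return np.array([self.batch_of.get(s, 0) for s in self.sample_ids])

    def subset(self, idx: Sequence[int]) -> "FingerprintMatrix":
        idx = np.asarray(idx, dtype=int)
        ids = [self.sample_ids[i] for i in idx]
        return FingerprintMatrix(
            sample_ids=ids,
            rt_axis=self.rt_axis,
            values=self.values[idx],
            aligned=self.aligned,
            batch_of={s: self.batch_of[s] for s in ids if s in self.batch_of},
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"{t:.6f}" for t in self.rt_axis])
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        aligned: bool = False,
        batch_of: Mapping[str, int] | None = None,
    ) -> "FingerprintMatrix":
        df = pd.read_csv(path)
        if df.columns[0] != "sample_id":
            raise FormatError("matrix CSV must start with a sample_id column")
        rt = np.array([float(c) for c in df.columns[1:]])
        return cls(
            sample_ids=[str(s) for s in df["sample_id"]],
            rt_axis=rt,
            values=df.iloc[:, 1:].to_numpy(float),
            aligned=aligned,
            batch_of=dict(batch_of or {}),
        )


def read_tic_csv(path: str | Path, sample_id: str | None = None, batch: int = 0) -> Chromatogram:
    """Read a two-column (rt_min, intensity) CSV into a Chromatogram."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected at least two columns (rt_min, intensity)")
    rt = df.iloc[:, 0].to_numpy(float)
    inten = df.iloc[:, 1].to_numpy(float)
    return Chromatogram(
        sample_id=sample_id or Path(path).stem,
        rt=rt,
        intensity=inten,
        batch=batch,
        metadata={"source": str(path)},
    )


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"

# controlled-vocabulary accessions used by the reader
_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"


def _decode_binary_array(bda) -> np.ndarray:
    import base64
    import zlib

    dtype = "<f8"
    compressed = False
    for cv in bda.iter(f"{_MZML_NS}cvParam"):
        acc = cv.get("accession")
        if acc == _ACC_F32:
            dtype = "<f4"
        elif acc == _ACC_ZLIB:
            compressed = True
    node = bda.find(f"{_MZML_NS}binary")
    raw = base64.b64decode(node.text or "")
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _iter_mzml_tic(path: str | Path):
    """Yield (rt_minutes, summed_intensity) for each MS1 spectrum."""
    import xml.etree.ElementTree as ET

    for _event, elem in ET.iterparse(str(path), events=("end",)):
        if elem.tag != f"{_MZML_NS}spectrum":
            continue
        level = 1
        for cv in elem.findall(f"{_MZML_NS}cvParam"):
            if cv.get("accession") == _ACC_MS_LEVEL:
                level = int(cv.get("value", "1"))
        if level != 1:
            elem.clear()
            continue
        rt = None
        for cv in elem.iter(f"{_MZML_NS}cvParam"):
            if cv.get("accession") == _ACC_SCAN_START:
                rt = float(cv.get("value"))
                unit = (cv.get("unitName") or "minute").lower()
                if "second" in unit:
                    rt /= 60.0
        intensity = None
        for bda in elem.iter(f"{_MZML_NS}binaryDataArray"):
            accs = {cv.get("accession") for cv in bda.iter(f"{_MZML_NS}cvParam")}
            if _ACC_INTENSITY_ARRAY in accs:
                intensity = _decode_binary_array(bda)
        if rt is None or intensity is None:
            raise FormatError(f"{path}: MS1 spectrum lacks scan time or intensity array")
        yield rt, float(intensity.sum())
        elem.clear()


def read_tic_mzml(
    path: str | Path,
    rt_min_cutoff: float = 5.0,
    sample_id: str | None = None,
    batch: int = 0,
) -> Chromatogram:
    """Extract the TIC from an mzML file.

    For every MS1 scan the intensity array is summed over the whole acquired
    m/z range; scans eluting before ``rt_min_cutoff`` minutes are dropped
    (the early chromatogram carries only solvent/air signal).
    """
    rts: list[float] = []
    tic: list[float] = []
    for rt, total in _iter_mzml_tic(path):
        rts.append(rt)
        tic.append(total)
    if not rts:
        raise FormatError(f"{path}: no MS1 scans found")
    rts_arr = np.asarray(rts)
    tic_arr = np.asarray(tic)
    keep = rts_arr >= rt_min_cutoff
    if not keep.any():
        raise FormatError(f"{path}: no scans at or after {rt_min_cutoff} min")
    return Chromatogram(
        sample_id=sample_id or Path(path).stem,
        rt=rts_arr[keep],
        intensity=tic_arr[keep],
        batch=batch,
        metadata={"source": str(path), "rt_min_cutoff": rt_min_cutoff},
    )


def resample_to_grid(
    chromatograms: Sequence[Chromatogram], n_points: int
) -> FingerprintMatrix:
    """Linearly interpolate chromatograms onto a shared uniform grid.

    The grid spans the common retention window (max of starts to min of
    ends). The result is marked unaligned: resampling fixes the axis, it
    does not correct retention-time shifts.
    """
    if not chromatograms:
        raise ValueError("no chromatograms given")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    lo = max(c.rt[0] for c in chromatograms)
    hi = min(c.rt[-1] for c in chromatograms)
    if not lo < hi:
        raise ValueError("chromatograms share no common retention window")
    grid = np.linspace(lo, hi, n_points)
    values = np.vstack([np.interp(grid, c.rt, c.intensity) for c in chromatograms])
    return FingerprintMatrix(
        sample_ids=[c.sample_id for c in chromatograms],
        rt_axis=grid,
        values=values,
        aligned=False,
        batch_of={c.sample_id: c.batch for c in chromatograms},
    )
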