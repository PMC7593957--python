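"""Synthetic GC-MS volatile fingerprints of virgin olive oils.

The real screening study rests on headspace GC-MS total ion chromatograms of
oils graded EVOO / VOO / LOO by sensory panels; that dataset is proprietary,
so this module provides a forward model with the same statistical structure:

* a library of volatile marker peaks (Gaussian in retention time) whose
  log-amplitudes respond linearly to the sensory attribute intensities
  (fruity, rancid, fusty-muddy, musty-humid-earthy) — defect intensity maps
  multiplicatively onto marker abundance;
* per-sample biological lognormal amplitude spread, retention-time jitter,
  systematic per-batch shifts, and proportional (constant-CV) detector noise
  with an optional between-day component;
* pooled quality-control replicates for intra-/inter-day repeatability, and
  boundary samples whose defect median sits near the VOO/LOO cut.

Everything is seeded and bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .chromatograms import Chromatogram, FingerprintMatrix

log = logging.getLogger(__name__)

Category = Literal["EVOO", "VOO", "LOO"]
Defect = Literal["none", "rancid", "fusty-muddy", "musty-humid-earthy"]

DEFECTS: tuple[str, ...] = ("rancid", "fusty-muddy", "musty-humid-earthy")
ATTRIBUTES: tuple[str, ...] = ("fruity",) + DEFECTS


class TruthValidationError(ValueError):
    """A SampleTruth violates a category/defect consistency rule."""


@dataclass(frozen=True)
class VocPeakSpec:
    """One volatile marker peak.

    ``class_loadings`` maps sensory attributes to the slope of the peak's
    log-amplitude per unit of attribute intensity (panel median scale, 0-10).
    """

    name: str
    rt_center: float
    rt_sigma: float
    base_log_amp: float
    class_loadings: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rt_sigma <= 0:
            raise ValueError(f"peak {self.name}: rt_sigma must be > 0")
        for attr in self.class_loadings:
            if attr not in ATTRIBUTES:
                raise ValueError(f"peak {self.name}: unknown attribute {attr!r}")


@dataclass
class SampleTruth:
    """Ground-truth description of one simulated oil."""

    sample_id: str
    category: Category
    mpd: Defect = "none"
    defect_median: float = 0.0
    fruity_median: float = 0.0
    boundary_flag: bool = False
    batch: int = 0
    day: int = 1
    replicate: int = 1
    secondary_mpd: Defect = "none"
    secondary_median: float = 0.0

    def attribute_intensities(self) -> dict[str, float]:
        attrs = dict.fromkeys(ATTRIBUTES, 0.0)
        attrs["fruity"] = self.fruity_median
        if self.mpd != "none":
            attrs[self.mpd] += self.defect_median
        if self.secondary_mpd != "none":
            attrs[self.secondary_mpd] += self.secondary_median
        return attrs


@dataclass(frozen=True)
class SimulationConfig:
    """Acquisition and noise parameters of the simulated GC-MS system.

    The retention window and point count default to a desk-scale version of
    a 60 m polar-column volatiles run (TIC extracted from minute 5); the full
    16,347-point grid is one configuration change.
    """

    rt_start: float = 5.0
    rt_end: float = 55.0
    n_points: int = 2000
    baseline_level: float = 100.0
    noise_sd_intra: float = 0.05
    noise_sd_inter: float = 0.05
    rt_jitter_sd: float = 2.0   # scans
    batch_shift: float = 3.0    # scans
    amp_log_sd: float = 0.2
    voo_loo_cut: float = 3.5    # trade-standard defect-median cut
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.rt_start < self.rt_end:
            raise ValueError("rt_start must be < rt_end")
        if self.n_points < 100:
            raise ValueError("n_points must be >= 100")
        for name in ("noise_sd_intra", "noise_sd_inter", "rt_jitter_sd",
                     "batch_shift", "amp_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def rt_axis(self) -> np.ndarray:
        return np.linspace(self.rt_start, self.rt_end, self.n_points)

    @property
    def scan_dt(self) -> float:
        return (self.rt_end - self.rt_start) / (self.n_points - 1)


def make_default_peak_library() -> list[VocPeakSpec]:
    """Default volatile marker library.

    Named markers follow the compounds used for suitability checks (hexanal,
    1-hexanol, (Z)-3-hexenyl acetate, (E)-2-heptenal, pentanoic acid) plus
    common green/fruity esters and aldehydes, oxidation (rancid) aldehydes
    and acids, fermentative (fusty-muddy) alcohols/acids, and mould-related
    (musty-humid-earthy) C8 compounds. Loadings are per-unit-median
    log-amplitude slopes; they are free parameters of the simulator, not
    measured concentrations.
    """
    def peak(name, rt, sigma, amp, **loadings):
        return VocPeakSpec(name, rt, sigma, amp, dict(loadings))

    return [
        # green/fruity volatiles (high in EVOO)
        peak("ethyl butanoate", 9.5, 0.05, 6.2, fruity=0.12, **{"fusty-muddy": 0.25}),
        peak("hexanal", 12.5, 0.06, 7.3, fruity=0.18, rancid=0.30),
        peak("(E)-2-hexenal", 16.0, 0.07, 8.0, fruity=0.35),
        peak("(Z)-3-hexenyl acetate", 19.5, 0.06, 6.8, fruity=0.40),
        peak("hexyl acetate", 20.3, 0.06, 6.4, fruity=0.35),
        peak("(E)-2-heptenal", 21.8, 0.06, 6.0, rancid=0.45),
        peak("1-hexanol", 23.2, 0.07, 6.6, fruity=0.10, **{"fusty-muddy": 0.30}),
        peak("(Z)-3-hexen-1-ol", 24.0, 0.07, 6.9, fruity=0.30),
        peak("1-octen-3-ol", 25.6, 0.07, 5.8, **{"musty-humid-earthy": 0.45}),
        peak("2-heptanol", 26.8, 0.08, 5.5, **{"musty-humid-earthy": 0.35}),
        peak("nonanal", 28.4, 0.07, 6.1, rancid=0.30),
        peak("(E)-2-decenal", 33.0, 0.08, 5.9, rancid=0.40),
        peak("acetic acid", 35.5, 0.10, 6.7, **{"fusty-muddy": 0.35}),
        peak("propanoic acid", 38.0, 0.10, 5.6, **{"fusty-muddy": 0.30,
                                                   "musty-humid-earthy": 0.15}),
        peak("pentanoic acid", 42.5, 0.10, 5.4, rancid=0.35),
        peak("guaiacol", 47.0, 0.09, 5.2, **{"musty-humid-earthy": 0.30}),
    ]


def validate_truth(truth: SampleTruth, cut: float = 3.5) -> None:
    """Check category/defect consistency; raise naming the violated rule."""
    if truth.defect_median < 0 or truth.fruity_median < 0:
        raise TruthValidationError(
            f"{truth.sample_id}: attribute medians must be >= 0")
    if truth.category == "EVOO":
        if truth.defect_median != 0 or truth.mpd != "none":
            raise TruthValidationError(
                f"{truth.sample_id}: EVOO requires defect_median = 0 and no MPD")
        if truth.fruity_median <= 0:
            raise TruthValidationError(
                f"{truth.sample_id}: EVOO requires fruity_median > 0")
    elif truth.category == "VOO":
        if not (0 < truth.defect_median <= cut):
            raise TruthValidationError(
                f"{truth.sample_id}: VOO requires 0 < defect_median <= {cut}")
        if truth.mpd == "none":
            raise TruthValidationError(f"{truth.sample_id}: VOO requires an MPD")
    elif truth.category == "LOO":
        if not (truth.defect_median > cut or truth.fruity_median == 0):
            raise TruthValidationError(
                f"{truth.sample_id}: LOO requires defect_median > {cut} "
                "or fruity_median = 0")
    else:
        raise TruthValidationError(
            f"{truth.sample_id}: unknown category {truth.category!r}")


def _batch_offset_scans(batch: int, batch_shift: float) -> float:
    """Deterministic systematic shift for a batch: 0, +1, -1, +2, -2, ... units."""
    if batch <= 0:
        k = 0
    else:
        k = (batch + 1) // 2 * (1 if batch % 2 == 1 else -1)
    return k * batch_shift


def _day_effects(config: SimulationConfig, day: int) -> tuple[float, float]:
    """(log amplitude day factor, day-level RT shift in scans), shared per day.

    Day 1 is the reference day with no between-day deviation.
    """
    if day <= 1:
        return 0.0, 0.0
    rng = np.random.default_rng([config.seed % (2**31), 7919, int(day)])
    log_factor = rng.normal(0.0, config.noise_sd_inter)
    rt_shift = rng.normal(0.0, config.rt_jitter_sd)
    return log_factor, rt_shift


def _peak_amplitudes(
    truth: SampleTruth,
    library: Sequence[VocPeakSpec],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Noise-free (analytically) per-peak amplitudes with biological spread."""
    attrs = truth.attribute_intensities()
    log_amp = np.empty(len(library))
    for k, pk in enumerate(library):
        la = pk.base_log_amp
        for attr, slope in pk.class_loadings.items():
            la += slope * attrs[attr]
        log_amp[k] = la
    log_amp += rng.normal(0.0, config.amp_log_sd, size=len(library))
    return np.exp(log_amp)


def _render(
    amplitudes: np.ndarray,
    library: Sequence[VocPeakSpec],
    config: SimulationConfig,
    delta_scans: float,
) -> np.ndarray:
    rt = config.rt_axis
    delta_min = delta_scans * config.scan_dt
    signal = np.full(config.n_points, config.baseline_level)
    for amp, pk in zip(amplitudes, library):
        center = pk.rt_center + delta_min
        # evaluate only within 6 sigma of the center to keep rendering cheap
        lo = np.searchsorted(rt, center - 6 * pk.rt_sigma)
        hi = np.searchsorted(rt, center + 6 * pk.rt_sigma)
        if hi > lo:
            seg = rt[lo:hi]
            signal[lo:hi] += amp * np.exp(-((seg - center) ** 2) / (2 * pk.rt_sigma**2))
    return signal


def _add_analytical_noise(
    clean: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    day_log_factor: float = 0.0,
) -> np.ndarray:
    """Proportional detector noise: sd(t) = cv * max(clean(t), baseline)."""
    signal = clean * np.exp(day_log_factor)
    if config.noise_sd_intra > 0:
        sd = config.noise_sd_intra * np.maximum(signal, config.baseline_level)
        signal = signal + rng.normal(0.0, 1.0, size=signal.size) * sd
    return np.clip(signal, 0.0, None)


def simulate_sample(
    truth: SampleTruth,
    library: Sequence[VocPeakSpec],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Chromatogram:
    """Render one sample's TIC from its sensory ground truth.

    intensity(t) = baseline + sum_k A_k exp(-(t - rt_k - delta)^2 / 2 sigma_k^2) + noise,
    with log A_k = base_k + sum_attr loading * median + N(0, amp_log_sd);
    delta combines the deterministic batch shift, the shared day shift and
    per-sample jitter. Intensities are clipped at zero.
    """
    validate_truth(truth, cut=config.voo_loo_cut)
    amps = _peak_amplitudes(truth, library, config, rng)
    day_log, day_shift = _day_effects(config, truth.day)
    delta = (
        _batch_offset_scans(truth.batch, config.batch_shift)
        + day_shift
        + rng.normal(0.0, config.rt_jitter_sd)
    )
    clean = _render(amps, library, config, delta)
    noisy = _add_analytical_noise(clean, config, rng, day_log_factor=day_log)
    return Chromatogram(
        sample_id=truth.sample_id,
        rt=config.rt_axis,
        intensity=noisy,
        batch=truth.batch,
        metadata={"category": truth.category, "mpd": truth.mpd, "day": truth.day},
    )


def _draw_truths(
    n_evoo: int,
    n_voo: int,
    n_loo: int,
    mpd_mix: Sequence[float],
    n_batches: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    boundary_fraction: float,
    boundary_band: float,
) -> list[SampleTruth]:
    cut = config.voo_loo_cut
    mix = np.asarray(mpd_mix, dtype=float)
    if mix.size != len(DEFECTS):
        raise ValueError(f"mpd_mix must have {len(DEFECTS)} proportions")
    if not np.isclose(mix.sum(), 1.0):
        raise ValueError("mpd_mix proportions must sum to 1")

    truths: list[SampleTruth] = []
    idx = 0

    def next_id() -> str:
        nonlocal idx
        idx += 1
        return f"S{idx:04d}"

    for _ in range(n_evoo):
        truths.append(SampleTruth(
            sample_id=next_id(), category="EVOO",
            fruity_median=float(np.clip(rng.normal(5.0, 0.7), 1.0, 8.0)),
        ))
    for cat, n in (("VOO", n_voo), ("LOO", n_loo)):
        for _ in range(n):
            mpd = DEFECTS[rng.choice(len(DEFECTS), p=mix)]
            boundary = bool(rng.random() < boundary_fraction)
            if cat == "VOO":
                if boundary:
                    m = float(rng.uniform(cut - boundary_band, cut))
                else:
                    m = float(rng.uniform(1.0, cut))
                fruity = float(np.clip(rng.normal(2.0, 0.7), 0.5, 6.0))
            else:
                if boundary:
                    m = float(rng.uniform(cut, cut + boundary_band)) + 1e-9
                else:
                    m = float(rng.uniform(cut + boundary_band, 7.0))
                fruity = float(rng.uniform(0.0, 1.0))
            truths.append(SampleTruth(
                sample_id=next_id(), category=cat, mpd=mpd,
                defect_median=m, fruity_median=fruity, boundary_flag=boundary,
            ))
    # round-robin batches; each batch is acquired on its own day
    for i, t in enumerate(truths):
        t.batch = i % max(n_batches, 1)
        t.day = t.batch + 1
    return truths


def simulate_dataset(
    n_evoo: int,
    n_voo: int,
    n_loo: int,
    mpd_mix: Sequence[float] = (0.36, 0.50, 0.14),
    n_batches: int = 5,
    config: SimulationConfig | None = None,
    seed: int = 0,
    library: Sequence[VocPeakSpec] | None = None,
    boundary_fraction: float = 0.13,
    boundary_band: float = 0.5,
) -> tuple[FingerprintMatrix, list[SampleTruth]]:
    """Simulate a full study set (unaligned: rows carry their own RT shifts).

    Default ``mpd_mix`` follows the approximate defect frequencies of the
    study population (rancid / fusty-muddy / musty-humid-earthy); defaults for
    counts in the validation workflow are 122/108/75 EVOO/VOO/LOO.
    """
    if min(n_evoo, n_voo, n_loo) < 0:
        raise ValueError("counts must be >= 0")
    if n_evoo + n_voo + n_loo == 0:
        raise ValueError("empty dataset")
    config = config or SimulationConfig(seed=seed)
    if config.seed != seed:
        config = replace(config, seed=seed)
    library = list(library or make_default_peak_library())
    rng = np.random.default_rng(seed % (2**31))
    truths = _draw_truths(
        n_evoo, n_voo, n_loo, mpd_mix, n_batches, config, rng,
        boundary_fraction, boundary_band,
    )
    rows = np.empty((len(truths), config.n_points))
    for i, truth in enumerate(truths):
        rows[i] = simulate_sample(truth, library, config, rng).intensity
    matrix = FingerprintMatrix(
        sample_ids=[t.sample_id for t in truths],
        rt_axis=config.rt_axis,
        values=rows,
        aligned=False,
        batch_of={t.sample_id: t.batch for t in truths},
    )
    return matrix, truths


def default_qc_controls() -> list[SampleTruth]:
    """The six pooled-QC control oils: two EVOO and four LOO.

    The lampante controls carry rancid (x2, M > 4), fusty-muddy (M > 5) and
    fusty-muddy + musty-humid-earthy (M > 5 each) defect profiles.
    """
    return [
        SampleTruth("QC-EVOO-1", "EVOO", fruity_median=4.5),
        SampleTruth("QC-EVOO-2", "EVOO", fruity_median=5.0),
        SampleTruth("QC-LR-1", "LOO", mpd="rancid", defect_median=4.5,
                    fruity_median=0.5),
        SampleTruth("QC-LR-2", "LOO", mpd="rancid", defect_median=4.8,
                    fruity_median=0.3),
        SampleTruth("QC-LF", "LOO", mpd="fusty-muddy", defect_median=5.5,
                    fruity_median=0.2),
        SampleTruth("QC-LFH", "LOO", mpd="fusty-muddy", defect_median=5.2,
                    fruity_median=0.0, secondary_mpd="musty-humid-earthy",
                    secondary_median=5.2),
    ]


def simulate_qc_pool(
    controls: Sequence[SampleTruth] | None = None,
    n_replicates: int = 7,
    mode: Literal["intra_day", "inter_day"] = "intra_day",
    config: SimulationConfig | None = None,
    seed: int = 0,
    library: Sequence[VocPeakSpec] | None = None,
) -> FingerprintMatrix:
    """Replicate injections of a pooled QC sample.

    The pooled amplitude vector is the arithmetic mean of the controls'
    analytically-noise-free amplitude vectors (their biological spread is
    drawn once, not re-sampled per replicate). Intra-day replicates add only
    proportional analytical noise; inter-day replicates additionally get a
    per-day amplitude factor and day-level RT jitter.
    """
    if controls is None:
        controls = default_qc_controls()
    if not controls:
        raise ValueError("controls must be non-empty")
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if mode not in ("intra_day", "inter_day"):
        raise ValueError(f"unknown mode {mode!r}")
    config = config or SimulationConfig(seed=seed)
    library = list(library or make_default_peak_library())
    rng = np.random.default_rng([seed % (2**31), 4099])
    for truth in controls:
        validate_truth(truth, cut=config.voo_loo_cut)
    amp_stack = np.vstack([
        _peak_amplitudes(t, library, config, rng) for t in controls
    ])
    pooled = amp_stack.mean(axis=0)
    rows = np.empty((n_replicates, config.n_points))
    for r in range(n_replicates):
        if mode == "inter_day":
            day_log = rng.normal(0.0, config.noise_sd_inter)
            day_shift = rng.normal(0.0, config.rt_jitter_sd)
        else:
            day_log, day_shift = 0.0, 0.0
        clean = _render(pooled, library, config, day_shift)
        rows[r] = _add_analytical_noise(clean, config, rng, day_log_factor=day_log)
    ids = [f"QC-{'intra' if mode == 'intra_day' else 'inter'}-{r + 1}"
           for r in range(n_replicates)]
    return FingerprintMatrix(
        sample_ids=ids,
        rt_axis=config.rt_axis,
        values=rows,
        aligned=(mode == "intra_day"),
        batch_of=dict.fromkeys(ids, 0),
    )


# ---------------------------------------------------------------------------
# metadata / dataset IO

METADATA_COLUMNS = [
    "sample_id", "category", "mpd", "defect_median", "fruity_median",
    "boundary_flag", "batch", "day", "replicate",
]


def truths_to_frame(truths: Sequence[SampleTruth]) -> pd.DataFrame:
    return pd.DataFrame([
        {c: getattr(t, c) for c in METADATA_COLUMNS} for t in truths
    ])


def truths_from_frame(df: pd.DataFrame) -> list[SampleTruth]:
    out = []
    for rec in df.to_dict("records"):
        out.append(SampleTruth(
            sample_id=str(rec["sample_id"]),
            category=rec["category"],
            mpd=rec.get("mpd", "none"),
            defect_median=float(rec.get("defect_median", 0.0)),
            fruity_median=float(rec.get("fruity_median", 0.0)),
            boundary_flag=bool(rec.get("boundary_flag", False)),
            batch=int(rec.get("batch", 0)),
            day=int(rec.get("day", 1)),
            replicate=int(rec.get("replicate", 1)),
        ))
    return out


def write_dataset(
    out_dir: str | Path,
    matrix: FingerprintMatrix,
    truths: Sequence[SampleTruth],
    per_sample_csv: bool = True,
) -> None:
    """Write per-sample TIC CSVs, a metadata TSV and the combined matrix CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truths_to_frame(truths).to_csv(out / "metadata.tsv", sep="\t", index=False)
    matrix.to_csv(out / "matrix.csv")
    if per_sample_csv:
        tic_dir = out / "tics"
        tic_dir.mkdir(exist_ok=True)
        for i, sid in enumerate(matrix.sample_ids):
            pd.DataFrame({
                "rt_min": matrix.rt_axis, "intensity": matrix.values[i],
            }).to_csv(tic_dir / f"{sid}.csv", index=False)
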