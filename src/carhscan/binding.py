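"""Cooperative dimer binding to repeat arrays, EMSA fitting, SEC and qPCR.

The binding model: each repressor dimer engages two contiguous intact
11-bp repeats, one repeat per DNA-binding domain (a "full" placement).
A stable super-shifted EMSA band (two dimers) therefore needs at least
four repeats.  On three-repeat probes one dimer binds fully and a
second can engage a single flanking repeat with one DBD (a "partial"
placement), which shows up only as a weak upper band.  Mutating the
central repeat of a three-repeat probe leaves no two contiguous intact
repeats and abolishes binding.

Footprint geometry follows from the same placements: each engaged
repeat contributes one short hydroxyl-radical protection tract per
strand, centred in the repeat, so adjacent tract centres fall 11 nt
apart (~one helical pitch); DNase I protection covers the engaged
repeats plus a margin; Exo III is arrested a few nucleotides outside
the bound block on each strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RepeatArray",
    "OccupancyConfig",
    "BandPrediction",
    "FootprintPrediction",
    "BindingCurve",
    "HillFit",
    "SECCalibration",
    "OligomerCall",
    "ExpressionTable",
    "REPEAT_BP",
    "enumerate_occupancy",
    "predict_bands",
    "predict_footprints",
    "fraction_bound_from_intensities",
    "hill",
    "fit_hill",
    "sec_apparent_mr",
    "sec_elution_volume",
    "call_oligomer",
    "relative_expression",
]

REPEAT_BP = 11


@dataclass(frozen=True)
class RepeatArray:
    """Intact/mutated layout of a probe's 11-bp repeats.

    Compact string form: ``I`` intact, ``M`` mutated, e.g. ``"IMII"``.
    """

    units: tuple[bool, ...]  # True = intact

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError("a repeat array needs at least one repeat")

    @classmethod
    def from_string(cls, s: str) -> "RepeatArray":
        if not set(s.upper()) <= {"I", "M"}:
            raise ValueError(f"repeat array string must use I/M, got {s!r}")
        return cls(tuple(ch == "I" for ch in s.upper()))

    def __len__(self) -> int:
        return len(self.units)

    def __str__(self) -> str:
        return "".join("I" if u else "M" for u in self.units)


@dataclass(frozen=True)
class DimerPlacement:
    """One dimer on the array: starts at ``start`` (1-based repeat index)
    and engages ``engaged`` contiguous repeats (2 = full, 1 = partial)."""

    start: int
    engaged: int

    @property
    def repeats(self) -> tuple[int, ...]:
        return tuple(range(self.start, self.start + self.engaged))


@dataclass(frozen=True)
class OccupancyConfig:
    placements: tuple[DimerPlacement, ...]

    @property
    def n_full(self) -> int:
        return sum(p.engaged == 2 for p in self.placements)

    @property
    def engaged_repeats(self) -> tuple[int, ...]:
        out: list[int] = []
        for p in self.placements:
            out.extend(p.repeats)
        return tuple(sorted(out))


@dataclass(frozen=True)
class BandPrediction:
    category: str  # none | single | single_plus_weak_upper | double
    max_full_dimers: int


@dataclass(frozen=True)
class FootprintPrediction:
    """Predicted nuclease/radical footprints, coordinates 1-based in bp
    from the first base of the repeat array."""

    oh_tracts: tuple[tuple[int, int], ...]  # same on both strands
    dnase_span: tuple[int, int]
    exo3_sense_stop: int  # bp downstream of the 3' edge of the bound block
    exo3_antisense_stop: int  # bp upstream of the 5' edge


def enumerate_occupancy(
    array: RepeatArray,
    max_dimers: int = 2,
    allow_partial: bool = True,
) -> list[OccupancyConfig]:
    """All non-overlapping dimer placements on the array.

    A full placement engages two contiguous intact repeats; a partial
    placement (if enabled) engages a single intact repeat with one DBD.
    Configurations are enumerated exhaustively up to ``max_dimers``
    dimers, including the empty configuration.
    """
    if max_dimers < 1:
        raise ValueError("max_dimers must be >= 1")
    n = len(array)
    configs: list[OccupancyConfig] = []

    def options_from(pos: int) -> list[DimerPlacement]:
        opts = []
        for start in range(pos, n + 1):
            if start + 1 <= n and array.units[start - 1] and array.units[start]:
                opts.append(DimerPlacement(start, 2))
            if allow_partial and array.units[start - 1]:
                opts.append(DimerPlacement(start, 1))
        return opts

    def recurse(pos: int, placed: list[DimerPlacement]) -> None:
        configs.append(OccupancyConfig(tuple(placed)))
        if len(placed) == max_dimers:
            return
        for p in options_from(pos):
            recurse(p.start + p.engaged, placed + [p])

    recurse(1, [])
    return configs


def predict_bands(array: RepeatArray) -> BandPrediction:
    """Qualitative EMSA outcome for a probe layout.

    * ``double`` — two full dimers fit simultaneously (>= 4 repeats
      available as two disjoint intact tandem pairs): stable
      super-shifted band.
    * ``single_plus_weak_upper`` — only one full dimer fits but a
      partial placement can join it (3 contiguous intact repeats).
    * ``single`` — exactly one full dimer, no partial extension.
    * ``none`` — no two contiguous intact repeats anywhere.
    """
    full_only = enumerate_occupancy(array, max_dimers=2, allow_partial=False)
    max_full = max(c.n_full for c in full_only)
    if max_full >= 2:
        return BandPrediction("double", max_full_dimers=max_full)
    if max_full == 0:
        return BandPrediction("none", max_full_dimers=0)
    # one full dimer: can a partial dimer bind alongside it?
    with_partial = enumerate_occupancy(array, max_dimers=2, allow_partial=True)
    weak_upper = any(
        c.n_full == 1 and len(c.placements) == 2 for c in with_partial
    )
    return BandPrediction(
        "single_plus_weak_upper" if weak_upper else "single", max_full_dimers=1
    )


def predict_footprints(
    array: RepeatArray,
    config: OccupancyConfig,
    tract_width: int = 3,
    dnase_margin: int = 4,
    exo3_sense_offset: int = 4,
    exo3_antisense_offset: int = 3,
) -> FootprintPrediction:
    """Footprint geometry for a given occupancy configuration.

    One hydroxyl-radical protection tract per engaged repeat per
    strand, ``tract_width`` nt (default 3) centred in the repeat, so
    adjacent engaged repeats give tract centres 11 nt apart.  The
    DNase I span is the engaged-repeat union widened by
    ``dnase_margin`` nt on each side.  Exo III stops are placed
    ``exo3_sense_offset`` nt downstream of the 3' edge (sense strand)
    and ``exo3_antisense_offset`` nt upstream of the 5' edge
    (antisense strand).
    """
    engaged = config.engaged_repeats
    if not engaged:
        raise ValueError("occupancy configuration engages no repeats")
    n = len(array)
    for r in engaged:
        if not 1 <= r <= n:
            raise ValueError(f"engaged repeat {r} outside array of length {n}")
        if not array.units[r - 1]:
            raise ValueError(f"engaged repeat {r} is mutated")

    half = tract_width // 2
    tracts = []
    for r in engaged:
        repeat_start = (r - 1) * REPEAT_BP + 1
        center = repeat_start + REPEAT_BP // 2  # 6th bp of the repeat
        tracts.append((center - half, center - half + tract_width - 1))

    block_start = (engaged[0] - 1) * REPEAT_BP + 1
    block_end = engaged[-1] * REPEAT_BP
    return FootprintPrediction(
        oh_tracts=tuple(tracts),
        dnase_span=(block_start - dnase_margin, block_end + dnase_margin),
        exo3_sense_stop=block_end + exo3_sense_offset,
        exo3_antisense_stop=block_start - exo3_antisense_offset,
    )


@dataclass(frozen=True)
class BindingCurve:
    """Protein titration: concentrations in nM vs fraction bound."""

    concentrations: tuple[float, ...]
    fraction_bound: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.concentrations) != len(self.fraction_bound):
            raise ValueError("concentration and fraction-bound lengths differ")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be strictly positive")


@dataclass(frozen=True)
class HillFit:
    amplitude: float
    kd: float  # nM, concentration at half-maximal binding
    hill_h: float
    rss: float
    converged: bool

    def predict(self, conc) -> np.ndarray:
        return hill(np.asarray(conc, dtype=float), self.amplitude, self.kd, self.hill_h)


def fraction_bound_from_intensities(
    free_intensities: Sequence[float],
    zero_protein_intensity: float,
    concentrations: Sequence[float] | None = None,
) -> BindingCurve | np.ndarray:
    """Fraction bound per lane from free-DNA band intensities.

    f = 1 - I_free / I_free(no protein), clipped to [0, 1].  With
    ``concentrations`` given, a :class:`BindingCurve` is returned.
    """
    if zero_protein_intensity <= 0:
        raise ValueError("zero-protein reference intensity must be positive")
    f = 1.0 - np.asarray(free_intensities, dtype=float) / zero_protein_intensity
    f = np.clip(f, 0.0, 1.0)
    if concentrations is None:
        return f
    return BindingCurve(tuple(float(c) for c in concentrations), tuple(float(x) for x in f))


def hill(conc: np.ndarray, amplitude: float, kd: float, h: float) -> np.ndarray:
    """3-parameter Hill equation: f = A * c^h / (KD^h + c^h)."""
    c = np.asarray(conc, dtype=float)
    ch = np.power(c, h)
    return amplitude * ch / (np.power(kd, h) + ch)


HILL_BOUNDS = ((1e-6, 1e-6, 0.1), (1.05, np.inf, 6.0))


def fit_hill(curve: BindingCurve) -> HillFit:
    """Least-squares 3-parameter Hill fit (amplitude, KD, Hill h).

    Initialisation is fixed for determinism: A0 = max(f), KD0 = the
    concentration whose response is nearest A0/2, h0 = 1.  Bounds:
    0 < A <= 1.05, KD > 0, 0.1 < h <= 6.  Raises on fewer than 4
    points or a flat curve.
    """
    from scipy.optimize import curve_fit

    c = np.asarray(curve.concentrations, dtype=float)
    f = np.asarray(curve.fraction_bound, dtype=float)
    if len(c) < 4:
        raise ValueError("Hill fit needs at least 4 titration points")
    if np.allclose(f, f[0]):
        raise ValueError("Hill fit is undefined for a flat binding curve")

    a0 = max(float(np.max(f)), 1e-3)
    kd0 = float(c[np.argmin(np.abs(f - a0 / 2.0))])
    p0 = (a0, kd0, 1.0)
    try:
        popt, _ = curve_fit(
            hill, c, f, p0=p0, bounds=HILL_BOUNDS, maxfev=20000
        )
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    resid = f - hill(c, *popt)
    return HillFit(
        amplitude=float(popt[0]),
        kd=float(popt[1]),
        hill_h=float(popt[2]),
        rss=float(np.sum(resid**2)),
        converged=converged,
    )


@dataclass(frozen=True)
class SECCalibration:
    """Log-linear column calibration: log10(Mr/Da) = intercept - slope * Ve(ml)."""

    intercept: float = 8.1537
    slope: float = 0.2316  # per ml
    ve_range: tuple[float, float] = (8.0, 20.0)


@dataclass(frozen=True)
class OligomerCall:
    apparent_mr: float  # kDa
    protomer_mr: float  # kDa
    n: int
    within_tolerance: bool


def sec_apparent_mr(ve_ml: float, calib: SECCalibration | None = None) -> float:
    """Apparent molecular mass (kDa) from an elution volume (ml)."""
    import logging

    calib = calib or SECCalibration()
    if ve_ml <= 0:
        raise ValueError("elution volume must be positive")
    lo, hi = calib.ve_range
    if not lo <= ve_ml <= hi:
        logging.getLogger("carhscan").warning(
            "elution volume %.2f ml outside calibrated range %.1f-%.1f ml", ve_ml, lo, hi
        )
    return 10.0 ** (calib.intercept - calib.slope * ve_ml) / 1000.0


def sec_elution_volume(mr_kda: float, calib: SECCalibration | None = None) -> float:
    """Inverse calibration: elution volume (ml) at which Mr (kDa) elutes."""
    calib = calib or SECCalibration()
    if mr_kda <= 0:
        raise ValueError("molecular mass must be positive")
    return (calib.intercept - math.log10(mr_kda * 1000.0)) / calib.slope


def call_oligomer(
    apparent_mr: float, protomer_mr: float, tol: float = 0.25
) -> OligomerCall:
    """Nearest-integer oligomeric state from apparent vs protomer mass.

    n = round(apparent / protomer), at least 1; within_tolerance is
    true when |apparent - n*protomer| / (n*protomer) <= tol (default
    25%, the usual slack of analytical SEC mass estimates).
    """
    if apparent_mr <= 0 or protomer_mr <= 0:
        raise ValueError("masses must be positive")
    n = max(1, round(apparent_mr / protomer_mr))
    deviation = abs(apparent_mr - n * protomer_mr) / (n * protomer_mr)
    return OligomerCall(apparent_mr, protomer_mr, n, deviation <= tol)


@dataclass(frozen=True)
class ExpressionSample:
    condition: str
    target_cq: float
    reference_cq: float


@dataclass(frozen=True)
class ExpressionTable:
    """qRT-PCR Cq values per sample with a baseline condition.

    The reference gene (rpoD in the source assays) normalises each
    sample; fold changes are reported relative to the baseline
    condition (dark with B12 present in the source assays).
    """

    samples: tuple[ExpressionSample, ...]
    baseline: str

    def __post_init__(self) -> None:
        if not any(s.condition == self.baseline for s in self.samples):
            raise ValueError(f"baseline condition {self.baseline!r} absent from table")


def relative_expression(table: ExpressionTable):
    """Delta-delta-Cq fold changes per condition.

    Per sample dCq = Cq_target - Cq_reference; per condition
    fold = 2^-(dCq - mean dCq of baseline).  Returns a DataFrame with
    mean fold change and standard error over replicates.
    """
    import pandas as pd

    rows = [
        {"condition": s.condition, "dcq": s.target_cq - s.reference_cq}
        for s in table.samples
    ]
    df = pd.DataFrame(rows)
    base_dcq = df.loc[df.condition == table.baseline, "dcq"].mean()
    df["fold"] = 2.0 ** -(df["dcq"] - base_dcq)
    out = df.groupby("condition")["fold"].agg(
        mean_fold="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0,
        n="count",
    )
    return out.reset_index()
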