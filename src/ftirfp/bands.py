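"""Band assignments and lipid intensity ratios from second-derivative spectra.

The packaged band table maps literature wavenumbers to vibrational modes
and biomolecular assignments (lipid C-H stretches, ester carbonyl, amide
I/II with their approximate mode compositions, carbohydrate/nucleic-acid
fingerprint bands). Intensities are measured on the second-derivative
spectrum, where an absorbance maximum appears as a negative lobe: peak
intensity is the magnitude of the local second-derivative minimum near
the literature position.

Three ratios summarize lipid state:

* CH2/CH3 = I(~2922) / I(~2959) — mean acyl chain length,
* Carbonyl/Total lipid = I(~1747) / (I(~2922) + I(~2851)) — ester
  carbonyl content, a lipid peroxidation readout,
* Unsaturated/Saturated = I(~3013) / (I(~2922) + I(~2851)) — double-bond
  content of the acyl chains.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra_io import Spectrum, SpectraSet

__all__ = [
    "BandAssignment",
    "BandTable",
    "NoPeakError",
    "default_band_table",
    "assign_band",
    "peak_intensity",
    "ch2_ch3_ratio",
    "carbonyl_total_lipid_ratio",
    "unsat_sat_ratio",
    "RatioResult",
    "compute_ratios",
]

# literature target positions (cm^-1) of the ratio bands
CH2_ASYM = 2922.0
CH3_ASYM = 2959.0
CH2_SYM = 2851.0
CARBONYL = 1747.0
OLEFINIC = 3013.0

#: half-width (cm^-1) of the search window around each literature target;
#: wide enough to follow group-dependent shifts (e.g. 2925 vs 2916) without
#: reaching the neighboring band
DEFAULT_SEARCH_HALFWIDTH = 15.0


class NoPeakError(ValueError):
    """No second-derivative minimum below zero inside the search window."""

    def __init__(self, target: float, low: float, high: float, sample_id: str = ""):
        self.target, self.low, self.high = target, low, high
        where = f" in sample {sample_id!r}" if sample_id else ""
        super().__init__(
            f"no absorbance peak near {target:g} cm^-1 (window [{low:g}, {high:g}]){where}"
        )


@dataclass(frozen=True)
class BandAssignment:
    center: float
    mode: str
    assignment: str
    note: str = ""

    def __post_init__(self):
        if not 600.0 <= self.center <= 4000.0:
            raise ValueError("band center outside the mid-IR range 600-4000 cm^-1")


@dataclass
class BandTable:
    """Inventory of literature band assignments with a matching tolerance.

    The default tolerance of 8 cm^-1 matches the spectral resolution the
    fingerprinting acquisition uses.
    """

    entries: list[BandAssignment] = field(default_factory=list)
    match_tolerance: float = 8.0

    def __post_init__(self):
        if not self.entries:
            raise ValueError("band table is empty")
        if self.match_tolerance <= 0:
            raise ValueError("match tolerance must be positive")

    @classmethod
    def from_csv(cls, path, match_tolerance: float = 8.0) -> "BandTable":
        df = pd.read_csv(path).fillna({"note": ""})
        entries = [
            BandAssignment(float(r.center_cm1), str(r.mode), str(r.assignment), str(r.note))
            for r in df.itertuples()
        ]
        return cls(entries=entries, match_tolerance=match_tolerance)


def default_band_table(match_tolerance: float = 8.0) -> BandTable:
    """The packaged literature band inventory."""
    ref = importlib.resources.files("ftirfp").joinpath("data/band_table.csv")
    with importlib.resources.as_file(ref) as path:
        return BandTable.from_csv(path, match_tolerance=match_tolerance)


def assign_band(wavenumber: float, table: BandTable | None = None) -> BandAssignment | None:
    """Nearest band entry within the table's tolerance, or None.

    Distance ties are broken toward the lower-wavenumber entry.
    """
    table = table or default_band_table()
    best: BandAssignment | None = None
    best_key = None
    for e in table.entries:
        d = abs(e.center - wavenumber)
        if d > table.match_tolerance:
            continue
        key = (d, e.center)
        if best_key is None or key < best_key:
            best, best_key = e, key
    return best


# ---------------------------------------------------------------------------
# peak intensities
# ---------------------------------------------------------------------------

def peak_intensity(second_deriv: Spectrum, target_cm1: float,
                   search_halfwidth: float = DEFAULT_SEARCH_HALFWIDTH):
    """Magnitude of the absorbance peak near ``target_cm1``.

    Locates the deepest local minimum of the second-derivative spectrum
    inside the closed window ``target +- search_halfwidth`` and returns
    ``(magnitude, located_wavenumber)``. The window must lie within the
    grid; a window containing no local minimum below zero raises
    :class:`NoPeakError`.
    """
    w, y = second_deriv.wavenumbers, second_deriv.absorbance
    lo, hi = target_cm1 - search_halfwidth, target_cm1 + search_halfwidth
    if lo < w[0] - 1e-9 or hi > w[-1] + 1e-9:
        raise ValueError(
            f"search window [{lo:g}, {hi:g}] cm^-1 extends beyond the spectrum grid "
            f"[{w[0]:g}, {w[-1]:g}]; ratios need the full-range second derivative"
        )
    idx = np.nonzero((w >= lo - 1e-12) & (w <= hi + 1e-12))[0]
    best_i = None
    for i in idx:
        if y[i] >= 0:
            continue
        left_ok = i == 0 or y[i] <= y[i - 1]
        right_ok = i == y.size - 1 or y[i] <= y[i + 1]
        if left_ok and right_ok and (best_i is None or y[i] < y[best_i]):
            best_i = i
    if best_i is None:
        raise NoPeakError(target_cm1, lo, hi, second_deriv.sample_id)
    return float(-y[best_i]), float(w[best_i])


def _intensity(spec: Spectrum, target: float, hw: float) -> float:
    return peak_intensity(spec, target, hw)[0]


def ch2_ch3_ratio(second_deriv: Spectrum, search_halfwidth: float = DEFAULT_SEARCH_HALFWIDTH) -> float:
    """I(CH2 asym ~2922) / I(CH3 asym ~2959): acyl chain length proxy."""
    num = _intensity(second_deriv, CH2_ASYM, search_halfwidth)
    den = _intensity(second_deriv, CH3_ASYM, search_halfwidth)
    if den == 0:
        raise ValueError("zero CH3 intensity: ratio undefined")
    return num / den


def _total_lipid(second_deriv: Spectrum, hw: float) -> float:
    return (_intensity(second_deriv, CH2_ASYM, hw) + _intensity(second_deriv, CH2_SYM, hw))


def carbonyl_total_lipid_ratio(second_deriv: Spectrum,
                               search_halfwidth: float = DEFAULT_SEARCH_HALFWIDTH,
                               allow_zero: bool = False) -> float:
    """I(C=O ~1747) / (I(~2922) + I(~2851)): lipid peroxidation readout.

    A missing carbonyl peak raises :class:`NoPeakError` unless
    ``allow_zero`` is set, in which case the ratio is reported as 0.
    """
    den = _total_lipid(second_deriv, search_halfwidth)
    if den == 0:
        raise ValueError("zero total-lipid intensity: ratio undefined")
    try:
        num = _intensity(second_deriv, CARBONYL, search_halfwidth)
    except NoPeakError:
        if allow_zero:
            return 0.0
        raise
    return num / den


def unsat_sat_ratio(second_deriv: Spectrum,
                    search_halfwidth: float = DEFAULT_SEARCH_HALFWIDTH,
                    allow_zero: bool = False) -> float:
    """I(olefinic ~3013) / (I(~2922) + I(~2851)): acyl unsaturation.

    The grid must extend above 3013 cm^-1, i.e. this acts on the
    full-range second derivative, not a 3000-2800 region crop.
    """
    den = _total_lipid(second_deriv, search_halfwidth)
    if den == 0:
        raise ValueError("zero total-lipid intensity: ratio undefined")
    try:
        num = _intensity(second_deriv, OLEFINIC, search_halfwidth)
    except NoPeakError:
        if allow_zero:
            return 0.0
        raise
    return num / den


# ---------------------------------------------------------------------------
# batch ratios
# ---------------------------------------------------------------------------

@dataclass
class RatioResult:
    sample_id: str
    group: str
    replicate: int
    ch2_ch3: float | None = None
    carbonyl_total_lipid: float | None = None
    unsat_sat: float | None = None
    peak_intensities: dict[float, float] = field(default_factory=dict)
    located: dict[float, float] = field(default_factory=dict)
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


def compute_ratios(set_second_deriv: SpectraSet,
                   search_halfwidth: float = DEFAULT_SEARCH_HALFWIDTH) -> list[RatioResult]:
    """All three lipid ratios for every row of a second-derivative set.

    Per-sample failures (e.g. a flat spectrum with no peaks) are recorded
    in that sample's ``error`` field without aborting the batch.
    """
    out: list[RatioResult] = []
    for spec in set_second_deriv.rows():
        res = RatioResult(sample_id=spec.sample_id, group=spec.group, replicate=spec.replicate)
        try:
            for target in (CH3_ASYM, CH2_ASYM, CH2_SYM, CARBONYL, OLEFINIC):
                mag, loc = peak_intensity(spec, target, search_halfwidth)
                res.peak_intensities[target] = mag
                res.located[target] = loc
            res.ch2_ch3 = res.peak_intensities[CH2_ASYM] / res.peak_intensities[CH3_ASYM]
            den = res.peak_intensities[CH2_ASYM] + res.peak_intensities[CH2_SYM]
            res.carbonyl_total_lipid = res.peak_intensities[CARBONYL] / den
            res.unsat_sat = res.peak_intensities[OLEFINIC] / den
        except (NoPeakError, ValueError) as exc:
            res.error = str(exc)
        out.append(res)
    return out


def ratios_to_frame(results: list[RatioResult]) -> pd.DataFrame:
    """Tidy long-format table: sample_id, group, replicate, ratio, value."""
    rows = []
    for r in results:
        for name, value in (("ch2_ch3", r.ch2_ch3),
                            ("carbonyl_total_lipid", r.carbonyl_total_lipid),
                            ("unsat_sat", r.unsat_sat)):
            rows.append({"sample_id": r.sample_id, "group": r.group,
                         "replicate": r.replicate, "ratio": name, "value": value,
                         "error": r.error})
    return pd.DataFrame(rows)
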