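"""Synthetic ATR-FTIR cohorts with known group structure.

Spectra are sums of Gaussian bands on a uniform wavenumber grid plus a
smooth quadratic baseline and white noise. Group differences are encoded
in band positions and amplitudes the way the fibroblast study conditions
differ: a long-repeat-like group whose CH2 asymmetric stretch sits at
2916 instead of 2925 cm^-1 with reduced ester carbonyl, and severe-onset
groups with elevated C-H stretch amplitudes and elevated carbonyl.

Biological variability is modeled as per-sample lognormal amplitude
scaling shared by that sample's technical replicates; baseline and noise
are redrawn per replicate. Because the second derivative of a Gaussian
band has amplitude A/sigma^2 at its center, every cohort ships with the
analytically implied "true" band ratios for its groups, giving ground
truth for the whole ratio engine.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .spectra_io import Spectrum, SpectraSet

__all__ = [
    "BandSpec",
    "CohortConfig",
    "SCENARIOS",
    "default_profiles",
    "simulate_spectrum",
    "simulate_cohort",
    "analytic_true_ratios",
]

RATIO_TARGETS = {"ch3_asym": 2959.0, "ch2_asym": 2922.0, "ch2_sym": 2851.0,
                 "carbonyl": 1747.0, "olefinic": 3013.0}


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorbance band: A * exp(-(x - center)^2 / (2 sigma^2))."""

    center: float          # cm^-1
    sigma: float           # cm^-1
    amplitude: float       # AU
    amplitude_cv: float = 0.0  # relative biological (between-sample) variability

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("band sigma must be positive")
        if self.amplitude < 0 or self.amplitude_cv < 0:
            raise ValueError("amplitude and amplitude_cv must be >= 0")


@dataclass
class CohortConfig:
    """Cohort layout and nuisance levels for the generator."""

    groups: dict[str, list[BandSpec]]
    n_samples_per_group: int = 4
    replicates_per_sample: int = 3
    grid_min: float = 600.0
    grid_max: float = 4000.0
    spacing: float = 2.0          # cm^-1; finer than the 8 cm^-1 acquisition
                                  # resolution so derivative discretization
                                  # error stays negligible
    baseline_coeff_max: tuple[float, float, float] = (0.05, 0.02, 0.02)
    noise_sd: float = 0.002       # AU, per point per replicate
    seed: int = 0

    def __post_init__(self):
        if not self.groups:
            raise ValueError("at least one group required")
        if self.n_samples_per_group < 1 or self.replicates_per_sample < 1:
            raise ValueError("sample and replicate counts must be >= 1")
        if self.spacing <= 0 or self.grid_min >= self.grid_max:
            raise ValueError("invalid grid specification")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def grid(self) -> np.ndarray:
        n = int(np.floor((self.grid_max - self.grid_min) / self.spacing + 1e-9)) + 1
        return self.grid_min + self.spacing * np.arange(n)


# ---------------------------------------------------------------------------
# scenario band inventories
# ---------------------------------------------------------------------------

def _base_profile(cv: float) -> list[BandSpec]:
    """Fibroblast-like band inventory shared by all unaffected groups."""
    # the five ratio bands share one width so the Savitzky-Golay
    # attenuation cancels exactly in every intensity ratio
    return [
        BandSpec(3013.0, 9.0, 0.08, cv),    # olefinic =C-H stretch
        BandSpec(2959.0, 9.0, 0.35, cv),    # CH3 asymmetric stretch
        BandSpec(2925.0, 9.0, 0.55, cv),    # CH2 asymmetric stretch
        BandSpec(2874.0, 9.0, 0.20, cv),    # CH3 symmetric stretch
        BandSpec(2851.0, 9.0, 0.40, cv),    # CH2 symmetric stretch
        BandSpec(1747.0, 9.0, 0.28, cv),    # ester C=O stretch
        BandSpec(1651.0, 18.0, 1.00, cv),   # amide I (alpha-helix)
        BandSpec(1545.0, 16.0, 0.60, cv),   # amide II
        BandSpec(1080.0, 14.0, 0.45, cv),   # phosphate/nucleic acid
        BandSpec(1025.0, 12.0, 0.35, cv),   # carbohydrate C-O
    ]


def _edit(bands: list[BandSpec], at: float, **changes) -> list[BandSpec]:
    return [replace(b, **changes) if b.center == at else b for b in bands]


def _scale_amp(bands: list[BandSpec], centers: tuple[float, ...], factor: float) -> list[BandSpec]:
    return [replace(b, amplitude=b.amplitude * factor) if b.center in centers else b
            for b in bands]


def _coriell_groups(cv: float) -> dict[str, list[BandSpec]]:
    base = _base_profile(cv)
    dm1_1000 = _edit(base, 1747.0, amplitude=0.19)
    dm1_2000 = _base_profile(cv)
    dm1_2000 = _edit(dm1_2000, 2925.0, center=2916.0)   # CH2/CH3 phospholipid shift
    dm1_2000 = _edit(dm1_2000, 2959.0, center=2953.0)
    dm1_2000 = _edit(dm1_2000, 1747.0, amplitude=0.10)  # reduced ester carbonyl
    dm1_2000 = _edit(dm1_2000, 1651.0, amplitude=0.80)
    dm1_2000 = dm1_2000 + [BandSpec(1628.0, 14.0, 0.50, cv)]  # parallel beta-sheet amide I
    return {"control": base, "DM1_1000": dm1_1000, "DM1_2000": dm1_2000}


def _neurolab_groups(cv: float) -> dict[str, list[BandSpec]]:
    base = _base_profile(cv)
    ch = (2959.0, 2925.0, 2874.0, 2851.0)
    severe = _scale_amp(_base_profile(cv), ch, 1.4)     # elevated C-H stretches
    severe_carbonyl = _edit(_scale_amp(_base_profile(cv), ch, 1.4), 1747.0, amplitude=0.42)
    return {
        "control": base,
        "lDM1": [replace(b) for b in base],
        "aDM1": [replace(b) for b in base],
        "jDM1": severe,
        "iDM1": severe_carbonyl,
        "cDM1": [replace(b) for b in severe_carbonyl],
    }


def _null_groups(cv: float) -> dict[str, list[BandSpec]]:
    return {name: _base_profile(cv) for name in ("g1", "g2", "g3")}


SCENARIOS = ("coriell", "neurolab", "null")


def default_profiles(scenario: str, amplitude_cv: float = 0.08,
                     n_samples_per_group: int = 4, replicates_per_sample: int = 3,
                     spacing: float = 2.0, noise_sd: float = 0.002,
                     seed: int = 0) -> CohortConfig:
    """Cohort configuration for a named study-like scenario.

    ``coriell``: control / DM1_1000 / DM1_2000, with the long-repeat
    group's CH2 asymmetric band at 2916 (others 2925), its CH3 asymmetric
    band at 2953 (others 2959), an extra parallel-beta-sheet amide-I band
    at 1628 and a reduced 1747 carbonyl; DM1_1000 has a mildly reduced
    carbonyl. ``neurolab``: control / lDM1 / aDM1 / jDM1 / iDM1 / cDM1,
    with elevated C-H stretch amplitudes in the severe-onset groups and
    elevated 1747 carbonyl in iDM1/cDM1. ``null``: three groups with
    identical band lists.
    """
    if scenario == "coriell":
        groups = _coriell_groups(amplitude_cv)
    elif scenario == "neurolab":
        groups = _neurolab_groups(amplitude_cv)
    elif scenario == "null":
        groups = _null_groups(amplitude_cv)
    else:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    return CohortConfig(groups=groups, n_samples_per_group=n_samples_per_group,
                        replicates_per_sample=replicates_per_sample, spacing=spacing,
                        noise_sd=noise_sd, seed=seed)


# ---------------------------------------------------------------------------
# spectrum and cohort synthesis
# ---------------------------------------------------------------------------

def _band_matrix(grid: np.ndarray, bands: list[BandSpec]) -> np.ndarray:
    """n_bands x n_points matrix of unit-amplitude Gaussian profiles."""
    if not bands:
        return np.zeros((0, grid.size))
    centers = np.array([b.center for b in bands])[:, None]
    sigmas = np.array([b.sigma for b in bands])[:, None]
    return np.exp(-((grid[None, :] - centers) ** 2) / (2.0 * sigmas**2))


def _baseline(grid: np.ndarray, coeffs) -> np.ndarray:
    """Quadratic baseline in the normalized coordinate u in [-1, 1]."""
    u = (2.0 * grid - (grid[0] + grid[-1])) / (grid[-1] - grid[0])
    c0, c1, c2 = coeffs
    return c0 + c1 * u + c2 * u**2


def simulate_spectrum(band_specs: list[BandSpec], baseline_coeffs=(0.0, 0.0, 0.0),
                      noise_sd: float = 0.0, grid: np.ndarray | None = None,
                      seed: int | np.random.Generator | None = 0,
                      sample_id: str = "synthetic", group: str = "unlabeled",
                      replicate: int = 1) -> Spectrum:
    """One synthetic spectrum: Gaussian bands + quadratic baseline + noise."""
    if grid is None:
        grid = CohortConfig(groups={"g": band_specs or [BandSpec(2000, 10, 0)]}).grid()
    grid = np.asarray(grid, dtype=float)
    amps = np.array([b.amplitude for b in band_specs])
    y = amps @ _band_matrix(grid, band_specs) if band_specs else np.zeros(grid.size)
    y = y + _baseline(grid, baseline_coeffs)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, grid.size)
    return Spectrum(grid, y, sample_id=sample_id, group=group, replicate=replicate)


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-1 lognormal multiplier with the given coefficient of variation."""
    if cv <= 0:
        return 1.0
    s2 = np.log1p(cv**2)
    return float(rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2)))


def _analytic_second_derivative(bands: list[BandSpec], x: np.ndarray) -> np.ndarray:
    """Closed-form d2A/dx2 of the Gaussian band sum at points x."""
    y = np.zeros_like(x)
    for b in bands:
        t = x - b.center
        y += (b.amplitude / b.sigma**2) * (t**2 / b.sigma**2 - 1.0) * np.exp(-(t**2) / (2.0 * b.sigma**2))
    return y


def analytic_true_ratios(bands: list[BandSpec], window: float = 15.0) -> dict[str, float]:
    """Ratios implied by the analytic second derivative of the band model.

    Mirrors the measurement rule exactly: the intensity at each literature
    target is the magnitude of the minimum of the closed-form second
    derivative within ``target +- window`` (an isolated band contributes
    amplitude / sigma^2 at its center; overlapping neighbors perturb it).
    A window with no negative minimum contributes intensity 0.
    """
    def intensity(target: float) -> float:
        x = np.linspace(target - window, target + window, 601)
        m = float(_analytic_second_derivative(bands, x).min())
        return -m if m < 0 else 0.0

    i2959 = intensity(RATIO_TARGETS["ch3_asym"])
    i2922 = intensity(RATIO_TARGETS["ch2_asym"])
    i2851 = intensity(RATIO_TARGETS["ch2_sym"])
    i1747 = intensity(RATIO_TARGETS["carbonyl"])
    i3013 = intensity(RATIO_TARGETS["olefinic"])
    total = i2922 + i2851
    return {
        "ch2_ch3": i2922 / i2959 if i2959 else float("nan"),
        "carbonyl_total_lipid": i1747 / total if total else float("nan"),
        "unsat_sat": i3013 / total if total else float("nan"),
    }


def simulate_cohort(config: CohortConfig, seed: int | None = None):
    """Generate a full cohort and its ground-truth record.

    Returns ``(SpectraSet, ground_truth)``. Per sample, one lognormal
    amplitude factor per band (cv from the BandSpec) is drawn and shared
    across that sample's replicates; baseline coefficients and noise are
    redrawn per replicate. Fully deterministic for a fixed config + seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    grid = config.grid()
    spectra = []
    truth = {"groups": {}, "samples": {}}
    for gname in config.groups:
        truth["groups"][gname] = {
            "bands": [vars(b).copy() for b in config.groups[gname]],
            "true_ratios": analytic_true_ratios(config.groups[gname]),
        }
    b0, b1, b2 = config.baseline_coeff_max
    for gname, bands in config.groups.items():
        profiles = _band_matrix(grid, bands)
        nominal = np.array([b.amplitude for b in bands])
        for s in range(1, config.n_samples_per_group + 1):
            sid = f"{gname}_s{s}"
            factors = np.array([_lognormal_factor(rng, b.amplitude_cv) for b in bands])
            amps = nominal * factors
            truth["samples"][sid] = {"group": gname, "amplitudes": amps.tolist()}
            signal = amps @ profiles if bands else np.zeros(grid.size)
            for r in range(1, config.replicates_per_sample + 1):
                coeffs = (rng.uniform(0.0, b0), rng.uniform(-b1, b1), rng.uniform(-b2, b2))
                y = signal + _baseline(grid, coeffs)
                if config.noise_sd > 0:
                    y = y + rng.normal(0.0, config.noise_sd, grid.size)
                spectra.append(Spectrum(grid, y, sample_id=sid, group=gname, replicate=r))
    sset = SpectraSet.from_spectra(spectra, provenance={
        "simulated": True,
        "n_samples_per_group": config.n_samples_per_group,
        "replicates_per_sample": config.replicates_per_sample,
        "noise_sd": config.noise_sd,
        "spacing": config.spacing,
    })
    return sset, truth
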