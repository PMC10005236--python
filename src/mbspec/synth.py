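"""Synthetic mid-IR tissue spectra with the statistical structure the
analysis pipeline assumes.

The forward model per spectrum is

    A(nu) = sum_bands a_i * exp(-(nu - c_i)^2 / (2 sigma_i^2)) + baseline(nu) + eps(nu)

on the canonical 800-3500 cm^-1 grid (1800-2800 cm^-1 gap).  Band
positions and presence/absence per histological group follow the
reference atlas; the amide I region additionally carries six narrow
secondary-structure components whose centers are group-specific and
whose relative areas realize the group's secondary-structure
composition (beta-sheet / alpha-helix / others percentages, class mass
split equally among the class's components, "others" realized as the
beta-turn component).  A smooth concave baseline gives the rubberband
stage real work; additive white noise and per-sample amplitude/center
jitter emulate measurement and biological variability.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import dynamics as _dynamics
from . import preprocess as _preprocess
from .atlas import REFERENCE_BANDS
from .spectra import CANONICAL_GRID, GROUPS, Region, Spectrum, SpectrumSet

# ---------------------------------------------------------------------------
# reference parameterization

#: Amide I component centers (cm^-1) per group; structure classes of the
#: six components are (beta, beta, alpha, alpha, turn, beta).
AMIDE_CENTERS: dict[str, tuple[int, ...]] = {
    "control": (1631, 1641, 1652, 1658, 1680, 1691),
    "classic": (1630, 1641, 1649, 1659, 1679, 1691),
    "anaplastic": (1630, 1641, 1649, 1659, 1680, 1691),
    "desmoplastic": (1631, 1641, 1648, 1659, 1680, 1691),
}

AMIDE_STRUCTURES = ("beta_sheet", "beta_sheet", "alpha_helix", "alpha_helix", "beta_turn", "beta_sheet")

#: Secondary-structure composition (percent beta-sheet, alpha-helix, others).
COMPOSITIONS: dict[str, tuple[float, float, float]] = {
    "control": (68.5, 19.5, 12.0),
    "classic": (68.2, 21.2, 10.6),
    "desmoplastic": (73.7, 15.8, 10.5),
    "anaplastic": (70.5, 23.6, 5.9),
}

#: Default amplitudes for the atlas bands, one per REFERENCE_BANDS row.
#: Chosen so that amide I is the global fingerprint maximum and the
#: noiseless between-group contrasts reproduce the observed cluster
#: topology (classic+anaplastic most similar; desmoplastic and control
#: separated).
BAND_AMPLITUDES: tuple[float, ...] = (
    0.10,  # 889
    0.10,  # 920
    0.15,  # 964 (tumor only)
    0.20,  # 1063
    0.12,  # 1087/1085/1090 (tumor only)
    0.18,  # 1125 (control only)
    0.15,  # 1168
    0.30,  # 1233
    0.12,  # 1303
    0.04,  # 1341 (anaplastic only)
    0.45,  # 1377 paraffin
    0.55,  # 1466 paraffin
    0.80,  # amide II
    1.00,  # amide I main envelope
    0.02,  # 1737 (weak C=O shoulder)
    0.35,  # 2847 paraffin
    0.50,  # 2915 paraffin
    0.30,  # 2956 paraffin
    0.45,  # 3283 broad N-H/O-H
)

SIGMA_FINGERPRINT = 8.0
SIGMA_BROAD = 12.0       # the 3283 cm^-1 N-H/O-H band
SIGMA_AMIDE_COMPONENT = 2.5

#: Total amplitude scale of the amide sub-components inside full spectra
#: (kept subordinate to the 1.0 amide I envelope).
AMIDE_COMPONENT_WEIGHT = 1.0

DEFAULT_BASELINE = (0.05, 0.04, 0.03)

#: Cohort sizes of the emulated study: 40 tumors (21/5/14) and 4 controls.
DEFAULT_COHORT: dict[str, int] = {
    "control": 4,
    "classic": 21,
    "desmoplastic": 5,
    "anaplastic": 14,
}

#: Carbonyl-shoulder band whose dynamics separate tumor from control.
SIGNATURE_BAND = Region(1714.0, 1716.0, "thymine/guanine C=O")


@dataclass(frozen=True)
class BandSpec:
    center: float
    sigma: float
    amplitude: float
    label: str = ""
    paraffin: bool = False

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    def evaluate(self, grid: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-((grid - self.center) ** 2) / (2 * self.sigma**2))


@dataclass(frozen=True)
class NoiseModel:
    additive_sd: float = 0.004
    amplitude_jitter_cv: float = 0.05
    center_jitter_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.additive_sd, self.amplitude_jitter_cv, self.center_jitter_sd) < 0:
            raise ValueError("noise parameters must be non-negative")


NOISELESS = NoiseModel(additive_sd=0.0, amplitude_jitter_cv=0.0, center_jitter_sd=0.0)


@dataclass(frozen=True)
class GroupProfile:
    group: str
    bands: tuple[BandSpec, ...]
    amide1_components: tuple[BandSpec, ...]
    baseline_coeffs: tuple[float, ...] = DEFAULT_BASELINE
    dynamics_signature: tuple | None = None  # (Region, magnitude)

    def baseline(self, grid: np.ndarray) -> np.ndarray:
        t = (grid - grid[0]) / (grid[-1] - grid[0])
        return sum(c * t**k for k, c in enumerate(self.baseline_coeffs))

    def forward(self, grid: np.ndarray) -> np.ndarray:
        """Noiseless model: bands + amide components + baseline."""
        a = self.baseline(grid)
        for b in self.bands:
            a = a + b.evaluate(grid)
        for b in self.amide1_components:
            a = a + b.evaluate(grid)
        return a


def _amide_components(
    group: str,
    composition: tuple[float, float, float],
    sigma: float = SIGMA_AMIDE_COMPONENT,
    total_area: float = 1.0,
) -> tuple[BandSpec, ...]:
    """Six Gaussian components realizing a composition row.

    Class mass is split equally among the class's components: beta over
    the three beta-sheet centers, alpha over the two alpha-helix centers,
    and "others" assigned entirely to the beta-turn component.
    """
    beta, alpha, others = composition
    fractions = (beta / 3, beta / 3, alpha / 2, alpha / 2, others, beta / 3)
    total = sum(fractions)
    comps = []
    for center, frac, structure in zip(AMIDE_CENTERS[group], fractions, AMIDE_STRUCTURES):
        area = total_area * frac / total
        comps.append(
            BandSpec(
                center=float(center),
                sigma=sigma,
                amplitude=area / (sigma * np.sqrt(2 * np.pi)),
                label=f"amide I {structure}",
            )
        )
    return tuple(comps)


def make_group_profile(
    group: str,
    composition_row: tuple[float, float, float] | None = None,
    baseline_coeffs: tuple[float, ...] = DEFAULT_BASELINE,
) -> GroupProfile:
    """Profile realizing one group's atlas column and composition row."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    if composition_row is None:
        composition_row = COMPOSITIONS[group]
    bands = []
    for ref, amp in zip(REFERENCE_BANDS, BAND_AMPLITUDES):
        pos = ref.position(group)
        if pos is None:
            continue
        sigma = SIGMA_BROAD if pos > 3000 else SIGMA_FINGERPRINT
        bands.append(
            BandSpec(center=float(pos), sigma=sigma, amplitude=amp,
                     label=ref.assignment, paraffin=ref.paraffin)
        )
    # the amide sub-components ride on the amide I envelope; their total
    # area is scaled so the envelope remains the fingerprint maximum
    comp_total_area = AMIDE_COMPONENT_WEIGHT * SIGMA_AMIDE_COMPONENT * np.sqrt(2 * np.pi)
    comps = _amide_components(group, composition_row, total_area=comp_total_area)
    return GroupProfile(
        group=group,
        bands=tuple(bands),
        amide1_components=comps,
        baseline_coeffs=tuple(baseline_coeffs),
    )


def amide_band(
    group: str = "control",
    composition: tuple[float, float, float] | None = None,
    grid: np.ndarray | None = None,
    sigma: float = SIGMA_AMIDE_COMPONENT,
    total_area: float = 1.0,
    sample_id: str | None = None,
) -> Spectrum:
    """Pure amide I band: six Gaussians realizing a composition row.

    This is the construction used for deconvolution round-trip checks;
    the default grid extends a little beyond 1600-1700 cm^-1 so the
    extraction step has something to slice.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if composition is None:
        composition = COMPOSITIONS[group]
    if grid is None:
        grid = np.arange(1580.0, 1721.0)
    comps = _amide_components(group, composition, sigma=sigma, total_area=total_area)
    a = np.zeros_like(grid, dtype=float)
    for c in comps:
        a += c.evaluate(grid)
    return Spectrum(
        grid,
        a,
        sample_id=sample_id or f"amide_{group}",
        group=group,
        provenance=f"six-Gaussian amide I band, composition={composition}, sigma={sigma}",
    )


def jitter_profile(profile: GroupProfile, noise: NoiseModel, rng: np.random.Generator) -> GroupProfile:
    """Per-sample biological variability: amplitude and center jitter."""
    def jit(b: BandSpec) -> BandSpec:
        amp = b.amplitude * max(0.0, 1.0 + noise.amplitude_jitter_cv * rng.standard_normal())
        center = b.center + noise.center_jitter_sd * rng.standard_normal()
        return replace(b, amplitude=amp, center=center)

    return replace(
        profile,
        bands=tuple(jit(b) for b in profile.bands),
        amide1_components=tuple(jit(b) for b in profile.amide1_components),
    )


def synth_spectrum(
    profile: GroupProfile,
    noise: NoiseModel = NOISELESS,
    sample_id: str = "synthetic",
    grid: np.ndarray | None = None,
    replicate: int = 1,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """One spectrum from a profile: forward model plus additive noise."""
    if grid is None:
        grid = CANONICAL_GRID
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    a = profile.forward(grid)
    if noise.additive_sd > 0:
        a = a + noise.additive_sd * rng.standard_normal(grid.size)
    return Spectrum(
        grid.copy(),
        a,
        sample_id=sample_id,
        group=profile.group,
        replicate=replicate,
        provenance=f"synthetic {profile.group} (additive_sd={noise.additive_sd})",
    )


def synth_cohort(
    n_per_group: dict[str, int] | None = None,
    noise: NoiseModel = NoiseModel(),
    replicates: int = 3,
    grid: np.ndarray | None = None,
    signature: tuple[Region, float] | None = None,
) -> SpectrumSet:
    """Simulate a cohort with per-sample jitter and per-replicate noise.

    Replicates of a sample share the sample's jittered profile but not
    noise draws.  If ``signature`` is given as ``(region, magnitude)``,
    an absorbance-dynamics signature of that magnitude (in units of the
    cohort's own control first-derivative SD) is injected into every
    non-control spectrum.
    """
    if n_per_group is None:
        n_per_group = dict(DEFAULT_COHORT)
    if grid is None:
        grid = CANONICAL_GRID
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(noise.seed)
    spectra = []
    for group in GROUPS:
        count = n_per_group.get(group, 0)
        if count == 0:
            continue
        if count < 0:
            raise ValueError(f"negative count for group {group!r}")
        base = make_group_profile(group)
        for i in range(1, count + 1):
            sid = f"{group}_{i:02d}"
            sample_profile = jitter_profile(base, noise, rng)
            for r in range(1, replicates + 1):
                spectra.append(
                    synth_spectrum(sample_profile, noise, sample_id=sid, grid=grid,
                                   replicate=r, rng=rng)
                )
    cohort = SpectrumSet(spectra)
    if signature is not None:
        region, magnitude = signature
        cohort = apply_cohort_signature(cohort, region=region, magnitude=magnitude)
    return cohort


def cohort_manifest(cohort: SpectrumSet, directory: str = ".") -> pd.DataFrame:
    """Manifest rows (path, sample_id, group, replicate) for a cohort."""
    rows = [
        {
            "path": f"{directory}/{s.sample_id}_r{s.replicate}.csv",
            "sample_id": s.sample_id,
            "group": s.group,
            "replicate": s.replicate,
        }
        for s in cohort
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dynamics signature injection


def _unit_step(grid: np.ndarray, region: Region) -> np.ndarray:
    """Smooth unit step (erf) centered on the region midpoint.

    Its first derivative is a Gaussian spanning the whole band, so the
    slope perturbation covers every grid point of the region.
    """
    from scipy.special import erf

    center = 0.5 * (region.lo + region.hi)
    width = max(region.hi - region.lo, 2.0)
    return 0.5 * (1.0 + erf((grid - center) / (width * np.sqrt(2))))


def inject_dynamics_signature(
    spectrum: Spectrum,
    region: Region,
    magnitude: float,
    scale: float | np.ndarray,
    config: "_preprocess.PreprocessConfig | None" = None,
) -> Spectrum:
    """Reshape the carbonyl shoulder so its absorbance dynamics deviate.

    A smooth downward step (loss of C=O shoulder intensity) is added,
    with amplitude calibrated so the Savitzky-Golay first derivative of
    the perturbation reaches at least ``magnitude * scale`` at every grid
    point inside ``region``.  ``scale`` is the control first-derivative
    SD in the units of this spectrum (scalar, or per-wavenumber over the
    region's grid points).  ``magnitude = 0`` returns the spectrum
    unchanged.
    """
    if config is None:
        config = _preprocess.PreprocessConfig()
    mask = region.mask(spectrum.wavenumbers)
    if not mask.any():
        raise ValueError(f"region [{region.lo}, {region.hi}] lies outside the grid")
    if magnitude == 0:
        return spectrum
    step = _unit_step(spectrum.wavenumbers, region)
    probe = spectrum.with_absorbance(step)
    dstep = _preprocess.savgol_derivative(probe, config, order=1).absorbance[mask]
    if np.any(np.abs(dstep) <= 0):
        raise ValueError("degenerate step derivative inside region")
    amplitude = float(np.max(magnitude * np.asarray(scale) / np.abs(dstep)))
    out = spectrum.with_absorbance(spectrum.absorbance - amplitude * step)
    out.provenance = spectrum.provenance + f" + dynamics signature x{magnitude} in [{region.lo},{region.hi}]"
    return out


def apply_cohort_signature(
    cohort: SpectrumSet,
    region: Region = SIGNATURE_BAND,
    magnitude: float = 5.0,
    config: "_preprocess.PreprocessConfig | None" = None,
) -> SpectrumSet:
    """Inject the signature into every non-control spectrum of a cohort.

    The magnitude is expressed in units of the cohort's own control
    first-derivative SD *after* preprocessing (the scale on which the
    dynamics statistic thresholds), mapped back to raw absorbance via the
    recorded vector-normalization factors of the control spectra.
    """
    if config is None:
        config = _preprocess.PreprocessConfig()
    controls = cohort.select("control")
    processed = _preprocess.preprocess_set(controls, config, average=False)
    envelope = _dynamics.control_envelope(processed, config)
    band_mask = region.mask(envelope.grid)
    if not band_mask.any():
        raise ValueError(f"region [{region.lo}, {region.hi}] not on the dynamics grid")
    sd_band = envelope.sd_dynamics[band_mask]
    norm_med = float(np.median([s.meta["norm_factor"] for s in processed]))
    scale_raw = sd_band * norm_med

    def maybe_inject(s: Spectrum) -> Spectrum:
        if s.group == "control":
            return s
        return inject_dynamics_signature(s, region, magnitude, scale_raw, config)

    return cohort.map(maybe_inject)
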