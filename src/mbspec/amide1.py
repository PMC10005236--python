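"""Amide I secondary-structure deconvolution.

The amide I band (1600-1700 cm^-1, backbone C=O stretching) is a
superposition of component bands whose positions report protein
secondary structure: beta-sheet components near 1630/1641/1691 cm^-1,
alpha-helix near 1648-1659 cm^-1, and beta-turn near 1680 cm^-1.  The
workflow is

1. slice the 1600-1700 cm^-1 region and subtract the chord through its
   endpoints (local linear baseline);
2. seed component positions at the minima of the Savitzky-Golay second
   derivative;
3. fit a sum of Gaussians (plus a free linear term absorbing the
   detrending residue) by bounded nonlinear least squares;
4. classify each fitted center into a structure class and report the
   percentage composition by relative component area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit.models import GaussianModel, LinearModel
from scipy.signal import find_peaks

from .preprocess import PreprocessConfig, savgol_derivative
from .spectra import AMIDE_I, Spectrum, SpectrumError

STRUCTURE_CLASSES = ("beta_sheet", "alpha_helix", "beta_turn", "other")

#: Half-open class boundaries (cm^-1), interpolated between the reference
#: component assignments: 1631/1641 beta < 1645 <= 1648-1659 alpha < 1662
#: <= 1679-1680 turn < 1685 <= 1691 beta.
BETA_ALPHA_BOUNDARY = 1645.0
ALPHA_TURN_BOUNDARY = 1662.0
TURN_BETA_BOUNDARY = 1685.0

MIN_AREA_FRACTION = 0.005   # components below 0.5% of total area are dropped
CENTER_SLACK = 3.0          # cm^-1 around each seed during fitting
SIGMA_BOUNDS = (2.0, 20.0)  # cm^-1


class FitError(RuntimeError):
    """Deconvolution failed to converge."""


@dataclass
class AmideComponent:
    center: float
    sigma: float
    amplitude: float   # peak height
    structure: str = field(init=False)

    def __post_init__(self) -> None:
        self.structure = classify_structure(self.center)

    @property
    def area(self) -> float:
        return self.amplitude * self.sigma * np.sqrt(2 * np.pi)


@dataclass
class AmideIFit:
    components: list[AmideComponent]
    residual_rmse: float
    composition: dict  # {"beta_sheet","alpha_helix","others"} -> percent


def extract_amide1(spectrum: Spectrum) -> Spectrum:
    """Closed-interval amide I slice with an endpoint-anchored detrend.

    A straight line through the two endpoint absorbances is subtracted,
    so both ends of the returned slice sit at exactly zero.
    """
    if spectrum.wavenumbers[0] > AMIDE_I.lo or spectrum.wavenumbers[-1] < AMIDE_I.hi:
        raise SpectrumError(
            f"grid [{spectrum.wavenumbers[0]:g}, {spectrum.wavenumbers[-1]:g}] does not "
            f"cover the amide I region [{AMIDE_I.lo:g}, {AMIDE_I.hi:g}]"
        )
    sl = spectrum.slice(AMIDE_I)
    x, y = sl.wavenumbers, sl.absorbance
    chord = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
    return sl.with_absorbance(y - chord)


def seed_components(
    amide_region: Spectrum,
    config: PreprocessConfig = PreprocessConfig(),
    min_prominence_fraction: float = 0.05,
    merge_distance: float = 3.0,
) -> np.ndarray:
    """Component positions: minima of the SG second derivative.

    Only negative-curvature minima count (a positive second derivative
    marks a valley between bands, not a band).  Minima with prominence
    below ``min_prominence_fraction`` of the deepest minimum are noise;
    minima closer than ``merge_distance`` cm^-1 are merged keeping the
    deeper one.  Positions are returned sorted ascending.
    """
    d2 = savgol_derivative(amide_region, config, order=2)
    x, v = d2.wavenumbers, d2.absorbance
    depth = float(np.max(-v))
    if depth <= 0:
        raise SpectrumError("no component structure detectable (second derivative non-negative)")
    idx, _ = find_peaks(-v, prominence=min_prominence_fraction * depth)
    idx = idx[v[idx] < 0]
    if idx.size == 0:
        raise SpectrumError("no component structure detectable")
    # merge close minima, keeping the deeper
    merged: list[int] = []
    for i in sorted(idx, key=lambda i: v[i]):  # deepest first
        if all(abs(x[i] - x[j]) >= merge_distance for j in merged):
            merged.append(i)
    return np.array(sorted(x[i] for i in merged))


def fit_components(
    amide_region: Spectrum,
    seeds: np.ndarray,
    config: PreprocessConfig = PreprocessConfig(),
) -> AmideIFit:
    """Bounded least-squares fit of a Gaussian sum to the amide I slice.

    Centers are constrained to seed +/- 3 cm^-1, sigmas to [2, 20] cm^-1,
    amplitudes to be non-negative; a free linear term absorbs the residue
    of the endpoint detrend.  Components whose fitted area falls below
    0.5% of the total are dropped without re-fitting.  Raises
    :class:`FitError` if the fit fails to converge even after one restart
    with perturbed seeds.
    """
    seeds = np.asarray(seeds, dtype=float)
    if seeds.size < 1:
        raise SpectrumError("need at least one seed position")
    x, y = amide_region.wavenumbers, amide_region.absorbance

    def build_and_fit(seed_positions: np.ndarray):
        model = LinearModel(prefix="lin_")
        params = model.make_params(slope=0.0, intercept=0.0)
        for i, c in enumerate(seed_positions):
            g = GaussianModel(prefix=f"g{i}_")
            model = model + g
            height = max(float(np.interp(c, x, y)), 1e-3 * float(np.max(np.abs(y))))
            sigma0 = 3.0
            params.update(g.make_params(center=c, sigma=sigma0,
                                        amplitude=height * sigma0 * np.sqrt(2 * np.pi)))
            params[f"g{i}_center"].set(min=c - CENTER_SLACK, max=c + CENTER_SLACK)
            params[f"g{i}_sigma"].set(min=SIGMA_BOUNDS[0], max=SIGMA_BOUNDS[1])
            params[f"g{i}_amplitude"].set(min=0.0)
        return model.fit(y, params, x=x, method="least_squares",
                         fit_kws={"xtol": 1e-12, "ftol": 1e-12, "gtol": 1e-12})

    result = build_and_fit(seeds)
    if not result.success:
        result = build_and_fit(seeds + 0.5)
        if not result.success:
            raise FitError(f"amide I fit did not converge: {result.message}")

    comps = []
    for i in range(seeds.size):
        amp_area = result.params[f"g{i}_amplitude"].value
        sigma = result.params[f"g{i}_sigma"].value
        center = result.params[f"g{i}_center"].value
        height = amp_area / (sigma * np.sqrt(2 * np.pi))
        comps.append(AmideComponent(center=center, sigma=sigma, amplitude=height))
    total_area = sum(c.area for c in comps)
    if total_area <= 0:
        raise FitError("fit produced zero total area")
    comps = [c for c in comps if c.area >= MIN_AREA_FRACTION * total_area]
    rmse = float(np.sqrt(np.mean(result.residual**2)))
    fit = AmideIFit(components=comps, residual_rmse=rmse, composition={})
    fit.composition = composition(fit)
    return fit


def classify_structure(center: float) -> str:
    """Structure class of a component center (half-open boundaries)."""
    if not (AMIDE_I.lo <= center < AMIDE_I.hi):
        raise SpectrumError(f"center {center:g} cm^-1 outside the amide I region")
    if center < BETA_ALPHA_BOUNDARY:
        return "beta_sheet"
    if center < ALPHA_TURN_BOUNDARY:
        return "alpha_helix"
    if center < TURN_BETA_BOUNDARY:
        return "beta_turn"
    return "beta_sheet"


def composition(fit: AmideIFit) -> dict:
    """Percent of total component area per structure class.

    "others" pools beta-turn and unassigned components, matching the
    three-way beta-sheet / alpha-helix / others reporting convention.
    """
    total = sum(c.area for c in fit.components)
    if total <= 0:
        raise SpectrumError("zero total component area")
    sums = {"beta_sheet": 0.0, "alpha_helix": 0.0, "others": 0.0}
    for c in fit.components:
        key = c.structure if c.structure in ("beta_sheet", "alpha_helix") else "others"
        sums[key] += c.area
    return {k: float(100.0 * v / total) for k, v in sums.items()}


def deconvolve(
    spectrum: Spectrum, config: PreprocessConfig = PreprocessConfig()
) -> AmideIFit:
    """Full chain: extract -> seed -> fit -> compose."""
    region = extract_amide1(spectrum)
    seeds = seed_components(region, config)
    return fit_components(region, seeds, config)
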