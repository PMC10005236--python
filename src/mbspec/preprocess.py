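"""Spectral pre-treatment: rubberband baseline, vector normalization,
replicate averaging, and Savitzky-Golay derivatives.

The standard chain for tissue spectra is

    resample -> average replicates -> rubberband baseline -> vector normalize

with derivatives computed on demand by downstream stages.  Baseline
correction precedes normalization so that the unit-norm contract holds
for the signal actually analyzed.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .spectra import Spectrum, SpectrumSet, SpectrumError


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the pre-treatment chain.

    n_baseline_points
        Number of rubberband support segments (concave rubber band with
        64 base points is the instrument-software convention).
    sg_window, sg_polyorder, deriv_order
        Savitzky-Golay parameters for the *second* derivative used in
        fingerprint analyses; window 9 / polyorder 3 resolves bands a few
        cm^-1 apart on a 1 cm^-1 grid without ringing.
    sg_window_d1, sg_polyorder_d1
        Parameters for the milder *first* derivative used by the
        absorbance-dynamics statistic.
    """

    n_baseline_points: int = 64
    sg_window: int = 9
    sg_polyorder: int = 3
    deriv_order: int = 2
    sg_window_d1: int = 7
    sg_polyorder_d1: int = 2

    def __post_init__(self) -> None:
        for w, p in ((self.sg_window, self.sg_polyorder), (self.sg_window_d1, self.sg_polyorder_d1)):
            if w % 2 == 0 or w <= p:
                raise ValueError(f"SG window must be odd and > polyorder, got {w}/{p}")
        if self.n_baseline_points < 3:
            raise ValueError("need at least 3 baseline points")
        if self.deriv_order not in (0, 1, 2):
            raise ValueError("deriv_order must be 0, 1 or 2")

    def first_derivative(self) -> "PreprocessConfig":
        return replace(self, sg_window=self.sg_window_d1,
                       sg_polyorder=self.sg_polyorder_d1, deriv_order=1)


def vector_normalize(spectrum: Spectrum) -> Spectrum:
    """Subtract the mean, then scale to unit Euclidean norm.

    This is the normalization convention of common FTIR acquisition
    software: it removes path-length / sample-amount effects.  The scale
    factor divided out is recorded in ``meta['norm_factor']`` so that
    absolute absorbance amplitudes can be reconstructed.
    """
    if np.ptp(spectrum.absorbance) == 0.0:
        raise SpectrumError("cannot vector-normalize a constant spectrum")
    y = spectrum.absorbance - spectrum.absorbance.mean()
    norm = float(np.linalg.norm(y))
    if norm == 0.0:
        raise SpectrumError("cannot vector-normalize a constant spectrum")
    return spectrum.with_absorbance(y / norm, norm_factor=norm)


def _lower_hull(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lower convex hull of the points (x, y), x strictly increasing."""
    hull: list[int] = []
    for i in range(len(x)):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # pop k if it lies on or above the chord j -> i
            if (y[k] - y[j]) * (x[i] - x[j]) >= (y[i] - y[j]) * (x[k] - x[j]):
                hull.pop()
            else:
                break
        hull.append(i)
    idx = np.array(hull)
    return x[idx], y[idx]


def rubberband_baseline(
    spectrum: Spectrum, config: PreprocessConfig = PreprocessConfig()
) -> tuple[Spectrum, Spectrum]:
    """Concave rubberband baseline with ``n_baseline_points`` base points.

    The axis is split into equal-width segments; the spectrum minimum of
    each segment is a candidate node; the baseline is the piecewise-linear
    lower convex hull through the candidate nodes plus both endpoints.
    Returns ``(baseline, corrected)`` with ``corrected = A - baseline``.
    The corrected spectrum is exactly zero at every hull support point.
    """
    x, y = spectrum.wavenumbers, spectrum.absorbance
    n = config.n_baseline_points
    if len(x) < n:
        raise SpectrumError(f"grid has {len(x)} points, fewer than {n} baseline segments")
    edges = np.linspace(x[0], x[-1], n + 1)
    nodes = {0, len(x) - 1}
    start = 0
    for k in range(n):
        hi = edges[k + 1]
        stop = len(x) if k == n - 1 else int(np.searchsorted(x, hi, side="left"))
        if stop > start:
            nodes.add(start + int(np.argmin(y[start:stop])))
        start = stop
    idx = np.array(sorted(nodes))
    hx, hy = _lower_hull(x[idx], y[idx])
    baseline = np.interp(x, hx, hy)
    # anchor hull vertices exactly (interp is exact there, but be explicit)
    corrected = y - baseline
    b = spectrum.with_absorbance(baseline)
    c = spectrum.with_absorbance(corrected, baseline_nodes=hx.tolist())
    return b, c


def savgol_derivative(
    spectrum: Spectrum, config: PreprocessConfig = PreprocessConfig(), order: int | None = None
) -> Spectrum:
    """Savitzky-Golay smoothed derivative, in absorbance per (cm^-1)^order.

    The grid must be piecewise uniform; the filter is applied per
    contiguous uniform segment (the 1800-2800 cm^-1 gap and any excised
    windows break the grid into segments).  Output length equals input
    length; margins are handled by polynomial fits (scipy ``mode='interp'``).
    """
    if order is None:
        order = config.deriv_order
    window = config.sg_window if order != 1 else config.sg_window_d1
    poly = config.sg_polyorder if order != 1 else config.sg_polyorder_d1
    x, y = spectrum.wavenumbers, spectrum.absorbance
    out = np.empty_like(y)
    for seg in spectrum.segments():
        n_seg = seg.stop - seg.start
        if n_seg < window:
            raise SpectrumError(
                f"grid segment of {n_seg} points is shorter than SG window {window}"
            )
        delta = float(x[seg.start + 1] - x[seg.start])
        out[seg] = savgol_filter(y[seg], window, poly, deriv=order, delta=delta, mode="interp")
    return spectrum.with_absorbance(out, deriv_order=order)


def average_replicates(spectrum_set: SpectrumSet) -> SpectrumSet:
    """One spectrum per sample_id: the arithmetic mean over its replicates."""
    by_sample: dict[str, list[Spectrum]] = defaultdict(list)
    order: list[str] = []
    for s in spectrum_set:
        if s.sample_id not in by_sample:
            order.append(s.sample_id)
        by_sample[s.sample_id].append(s)
    averaged = []
    for sid in order:
        members = by_sample[sid]
        mean = np.mean([m.absorbance for m in members], axis=0)
        proto = members[0]
        averaged.append(
            replace(
                proto,
                absorbance=mean,
                replicate=1,
                provenance=f"mean of {len(members)} replicates of {sid}",
            )
        )
    return SpectrumSet(averaged)


def group_mean(spectrum_set: SpectrumSet, group: str) -> Spectrum:
    """Pointwise mean spectrum of one group."""
    members = [s for s in spectrum_set if s.group == group]
    if not members:
        raise SpectrumError(f"no spectra in group {group!r}")
    mean = np.mean([m.absorbance for m in members], axis=0)
    return replace(
        members[0],
        absorbance=mean,
        sample_id=f"mean_{group}",
        replicate=1,
        provenance=f"mean of {len(members)} {group} spectra",
    )


def preprocess_spectrum(
    spectrum: Spectrum, config: PreprocessConfig = PreprocessConfig()
) -> Spectrum:
    """Rubberband baseline correction followed by vector normalization."""
    _, corrected = rubberband_baseline(spectrum, config)
    return vector_normalize(corrected)


def preprocess_set(
    spectrum_set: SpectrumSet,
    config: PreprocessConfig = PreprocessConfig(),
    average: bool = True,
) -> SpectrumSet:
    """Standard chain on a cohort: (average replicates) -> baseline -> normalize."""
    out = average_replicates(spectrum_set) if average else spectrum_set
    return out.map(lambda s: preprocess_spectrum(s, config))
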