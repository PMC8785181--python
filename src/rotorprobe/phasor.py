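"""Phasor analysis of time-correlated single-photon-counting (TCSPC) decays.

Each pixel's decay histogram is mapped to a point (g, s): the cosine and
sine Fourier coefficients of the count-normalised decay at the repetition
(angular) frequency omega = 2 pi n / T.  Monoexponential decays fall on the
universal semicircle of radius 1/2 centred at (1/2, 0); mixtures of
distinguishable states combine by intensity-weighted vector addition, so a
two-phase system lies on the segment joining its two reference phasors and
the position along that segment is the intensity fraction.

No instrument response function is modelled (delta IRF) and the first
harmonic is the default; bin centres are used as the timestamps in the
Fourier sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DecayHistogram",
    "DecayStack",
    "Phasor",
    "PhasorCloud",
    "ReferenceSegment",
    "MixtureResult",
    "phasor_transform",
    "mono_phasor",
    "circle_distance",
    "mixture_fraction",
    "image_phasor",
]


@dataclass
class DecayHistogram:
    """TCSPC histogram over one repetition period: ``counts`` in uniform
    bins tiling [0, T) with ``period`` T in ns."""

    counts: np.ndarray
    period: float

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 1 or c.size == 0:
            raise ValueError("counts must be a nonempty 1-D array")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        if self.period <= 0:
            raise ValueError("period must be positive")
        self.counts = c

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def bin_width(self) -> float:
        return self.period / self.n_bins

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class DecayStack:
    """Per-pixel decay histograms of a FLIM acquisition: ``counts`` with
    shape (ny, nx, n_bins), sharing one repetition ``period`` (ns)."""

    counts: np.ndarray
    period: float

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 3:
            raise ValueError("counts must have shape (ny, nx, n_bins)")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        if self.period <= 0:
            raise ValueError("period must be positive")
        self.counts = c

    def pixel(self, iy: int, ix: int) -> DecayHistogram:
        return DecayHistogram(self.counts[iy, ix], self.period)


@dataclass(frozen=True)
class Phasor:
    """A point of the phasor plot; ``total`` carries the photon count it
    was computed from (None for closed-form phasors)."""

    g: float
    s: float
    total: int | None = None

    def as_array(self) -> np.ndarray:
        return np.array([self.g, self.s])


@dataclass(frozen=True)
class ReferenceSegment:
    """Segment joining two reference phasors (e.g. the centroids of the
    liquid-ordered and liquid-disordered clouds)."""

    a: Phasor
    b: Phasor

    def __post_init__(self):
        if np.allclose(self.a.as_array(), self.b.as_array()):
            raise ValueError("segment endpoints must be distinct")


@dataclass(frozen=True)
class MixtureResult:
    """Intensity fraction of endpoint A (clamped to [0, 1]) and the
    perpendicular off-segment residual."""

    fraction_a: float
    residual: float


@dataclass
class PhasorCloud:
    """Per-pixel phasors of an image: maps of g, s and counts, the validity
    mask (counts >= min_counts), the cloud centroid and covariance, and an
    optional per-pixel fraction map when a reference segment was supplied."""

    g: np.ndarray
    s: np.ndarray
    counts: np.ndarray
    valid: np.ndarray
    centroid: np.ndarray
    covariance: np.ndarray
    fractions: np.ndarray | None = None

    @property
    def points(self) -> np.ndarray:
        """(n_valid, 2) array of the valid phasor coordinates."""
        return np.column_stack([self.g[self.valid], self.s[self.valid]])


def phasor_transform(decay: DecayHistogram, harmonic: int = 1) -> Phasor:
    """Phasor of a decay histogram at the given harmonic of 2 pi / T,
    using bin centres as timestamps."""
    total = decay.total
    if total <= 0:
        raise ValueError("phasor undefined for a decay with zero total counts")
    omega = 2.0 * np.pi * harmonic / decay.period
    t = decay.bin_centers
    c = decay.counts.astype(float)
    g = float(c @ np.cos(omega * t) / total)
    s = float(c @ np.sin(omega * t) / total)
    return Phasor(g=g, s=s, total=total)


def mono_phasor(tau: float, period: float, harmonic: int = 1) -> Phasor:
    """Closed-form phasor of an ideal monoexponential decay:
    g = 1/(1+(w tau)^2), s = w tau/(1+(w tau)^2) with w = 2 pi n / T."""
    if tau < 0 or period <= 0:
        raise ValueError("tau must be nonnegative and period positive")
    wt = 2.0 * np.pi * harmonic / period * tau
    d = 1.0 + wt * wt
    return Phasor(g=1.0 / d, s=wt / d)


def circle_distance(ph: Phasor) -> float:
    """Euclidean distance from the universal-circle centre (1/2, 0);
    monoexponential phasors sit at exactly 0.5."""
    return float(np.hypot(ph.g - 0.5, ph.s))


def mixture_fraction(ph: Phasor, seg: ReferenceSegment) -> MixtureResult:
    """Project a phasor onto a two-reference segment: by vector addition the
    normalised position is the intensity fraction of endpoint A."""
    p = ph.as_array()
    a = seg.a.as_array()
    b = seg.b.as_array()
    d = b - a
    t = float((p - a) @ d / (d @ d))
    residual = float(np.linalg.norm(p - (a + t * d)))
    return MixtureResult(fraction_a=float(np.clip(1.0 - t, 0.0, 1.0)),
                         residual=residual)


def image_phasor(stack: DecayStack, min_counts: int = 50, harmonic: int = 1,
                 segment: ReferenceSegment | None = None) -> PhasorCloud:
    """Per-pixel phasor transform of a decay stack.

    Pixels with fewer than ``min_counts`` photons are excluded (not
    smoothed).  With a reference segment, a per-pixel intensity-fraction
    map is attached (NaN on excluded pixels).
    """
    c = stack.counts.astype(float)
    totals = c.sum(axis=-1)
    valid = totals >= max(min_counts, 1)
    if not valid.any():
        raise ValueError("no pixel reaches min_counts photons")
    n_bins = c.shape[-1]
    t = (np.arange(n_bins) + 0.5) * stack.period / n_bins
    omega = 2.0 * np.pi * harmonic / stack.period
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(valid, c @ np.cos(omega * t) / totals, np.nan)
        s = np.where(valid, c @ np.sin(omega * t) / totals, np.nan)
    pts = np.column_stack([g[valid], s[valid]])
    centroid = pts.mean(axis=0)
    cov = (np.cov(pts.T) if pts.shape[0] > 1
           else np.zeros((2, 2)))
    fractions = None
    if segment is not None:
        fractions = np.full(g.shape, np.nan)
        iy, ix = np.nonzero(valid)
        for y, x in zip(iy, ix):
            fractions[y, x] = mixture_fraction(
                Phasor(g[y, x], s[y, x]), segment).fraction_a
    return PhasorCloud(g=g, s=s, counts=totals, valid=valid,
                       centroid=centroid, covariance=np.atleast_2d(cov),
                       fractions=fractions)
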