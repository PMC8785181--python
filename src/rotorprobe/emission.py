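"""Statistics of per-snapshot emission ensembles.

A vertical-transition calculation on a few hundred trajectory snapshots
yields one emission wavelength per snapshot; this module condenses such
ensembles into the summaries used for rotor probes: mean/spread, Gaussian
fits of the wavelength distribution, Stokes shifts against a fixed
absorption maximum, the association between emission and the twist of the
flexible dihedral (the twisted charge-transfer signature), and the
Forster-Hoffmann log-log relation between a viscosity proxy and the
fluorescence response.

All statistics are carried out directly in nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "EmissionEnsemble",
    "GaussianFit",
    "StokesRecord",
    "ViscosityRelation",
    "WindowAssociation",
    "emission_stats",
    "gaussian_fit",
    "stokes_shift",
    "wavelength_vs_dihedral",
    "forster_hoffmann",
]


@dataclass
class EmissionEnsemble:
    """Per-snapshot emission wavelengths (nm) for one environment, with an
    optional paired flexible-dihedral angle (deg) per snapshot."""

    wavelengths: np.ndarray
    environment: str = ""
    dihedral1: np.ndarray | None = None

    def __post_init__(self):
        w = np.asarray(self.wavelengths, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("wavelengths must be a nonempty 1-D array")
        if np.any(w <= 0):
            raise ValueError("wavelengths must be positive")
        self.wavelengths = w
        if self.dihedral1 is not None:
            d = np.asarray(self.dihedral1, dtype=float)
            if d.shape != w.shape:
                raise ValueError("paired dihedral angles must match wavelengths")
            self.dihedral1 = d

    def __len__(self):
        return self.wavelengths.size


@dataclass(frozen=True)
class GaussianFit:
    mu: float
    sigma: float
    amplitude: float
    rms: float


@dataclass(frozen=True)
class StokesRecord:
    lambda_abs: float
    lambda_em: float
    shift: float


@dataclass(frozen=True)
class ViscosityRelation:
    """OLS of log10(response) on log10(viscosity proxy)."""

    slope: float
    intercept: float
    r: float
    n: int


@dataclass
class WindowAssociation:
    """Windowed emission means over |dihedral| plus a permutation test of
    the twist window against the rest of the ensemble."""

    table: pd.DataFrame
    twist_window: tuple
    observed_diff: float
    p_value: float
    flagged: bool


def emission_stats(ens: EmissionEnsemble):
    """(mean nm, sample sd nm, n) — the '442 (+/-29)' style of summary."""
    w = ens.wavelengths
    if w.size < 2:
        raise ValueError("at least two snapshots are required for a spread")
    return float(w.mean()), float(w.std(ddof=1)), int(w.size)


def gaussian_fit(bin_centers, counts) -> GaussianFit:
    """Nonlinear least-squares Gaussian fit of a wavelength histogram."""
    x = np.asarray(bin_centers, dtype=float)
    y = np.asarray(counts, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("bin_centers and counts must be equal-length 1-D arrays")
    nonempty = y > 0
    if nonempty.sum() < 5:
        raise ValueError("at least 5 nonempty bins are required")
    if (nonempty.sum() == 1) or np.ptp(x[nonempty]) == 0:
        raise ValueError("degenerate histogram")
    w = y / y.sum()
    mu0 = float(x @ w)
    sig0 = float(np.sqrt(np.maximum(((x - mu0) ** 2) @ w, (x[1] - x[0]) ** 2)))
    amp0 = float(y.max())

    def model(t, mu, sig, amp):
        return amp * np.exp(-0.5 * ((t - mu) / sig) ** 2)

    popt, _ = curve_fit(model, x, y, p0=[mu0, sig0, amp0], maxfev=20000)
    mu, sig, amp = popt
    if not (x.min() <= mu <= x.max()):
        raise ValueError("fitted centre falls outside the data range")
    rms = float(np.sqrt(np.mean((model(x, *popt) - y) ** 2)))
    return GaussianFit(mu=float(mu), sigma=float(abs(sig)),
                       amplitude=float(amp), rms=rms)


def stokes_shift(lambda_abs: float, lambda_em: float) -> float:
    """Stokes shift lambda_em - lambda_abs in nm (warns if negative)."""
    if lambda_abs <= 0 or lambda_em <= 0:
        raise ValueError("wavelengths must be positive")
    shift = float(lambda_em - lambda_abs)
    if shift < 0:
        warnings.warn("negative Stokes shift: emission is blue of absorption",
                      stacklevel=2)
    return shift


def wavelength_vs_dihedral(ens: EmissionEnsemble, window: float = 15.0,
                           twist_window=(70.0, 120.0),
                           n_resamples: int = 10_000, seed: int = 0,
                           alpha: float = 0.01) -> WindowAssociation:
    """Windowed mean emission over |dihedral| and a two-sample permutation
    test of the twist window (where charge-transfer character raises the
    emission energy, i.e. shortens the wavelength) against all other angles.
    """
    if ens.dihedral1 is None:
        raise ValueError("the ensemble carries no paired dihedral angles")
    a = np.abs(ens.dihedral1)
    w = ens.wavelengths
    edges = np.arange(0.0, 180.0 + window, window)
    idx = np.digitize(a, edges) - 1
    rows = []
    for i in range(len(edges) - 1):
        sel = idx == i
        if sel.any():
            rows.append({"center": 0.5 * (edges[i] + edges[i + 1]),
                         "mean_nm": float(w[sel].mean()), "n": int(sel.sum())})
    table = pd.DataFrame(rows)

    in_twist = (a >= twist_window[0]) & (a <= twist_window[1])
    if not in_twist.any() or in_twist.all():
        raise ValueError("twist window is empty or covers the whole ensemble")
    obs = float(w[~in_twist].mean() - w[in_twist].mean())
    rng = np.random.default_rng(seed)
    n_in = int(in_twist.sum())
    count = 0
    for _ in range(n_resamples):
        perm = rng.permutation(w)
        diff = perm[n_in:].mean() - perm[:n_in].mean()
        if abs(diff) >= abs(obs):
            count += 1
    p = (count + 1) / (n_resamples + 1)
    return WindowAssociation(table=table, twist_window=tuple(twist_window),
                             observed_diff=obs, p_value=float(p),
                             flagged=bool(p < alpha))


def forster_hoffmann(x, y) -> ViscosityRelation:
    """Forster-Hoffmann power law: OLS of log10 y on log10 x.

    ``x`` is the viscosity proxy (a viscosity, or a rotational relaxation
    time standing in for it) and ``y`` the response (quantum yield or
    fluorescence lifetime); both strictly positive, length >= 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D arrays of size >= 3")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("entries must be positive before taking logs")
    res = stats.linregress(np.log10(x), np.log10(y))
    return ViscosityRelation(slope=float(res.slope),
                             intercept=float(res.intercept),
                             r=float(res.rvalue), n=int(x.size))
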