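"""Synthetic-data generators with known ground truth.

Every input the analysis stages consume can be generated here without a
quantum-chemistry or molecular-dynamics engine: torsional scans from cosine
series, isotropic rotational diffusion of unit vectors, well-to-well
dihedral jump dynamics, idealised bilayer snapshots with controlled chain
tilt, Gaussian emission ensembles, and Poisson-sampled TCSPC photon decays.
Each generator is seeded (same seed => byte-identical output) and attaches
a :class:`GroundTruth` record carrying the construction parameters, so
recovery tests can compare what the analysis measures with what was built.

Units follow the analysis modules: degrees in (-180, 180] (scan grids may
include both +/-180 endpoints), ps and nm for trajectories and frames,
ns for decays, kcal/mol for energies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phasor import DecayHistogram, DecayStack
from .torsion import CosineSeries, TorsionalProfile, wrap_degrees
from .trajectory import LipidFrame, VectorTrajectory

__all__ = [
    "GroundTruth",
    "DihedralSeries",
    "make_bistable_series",
    "gen_torsional_scan",
    "gen_rotational_diffusion",
    "gen_jump_dihedral",
    "gen_membrane_snapshot",
    "gen_emission_ensemble",
    "gen_tcspc",
    "gen_tcspc_image",
]

# masses (amu) of the coarse construction sites
_MASS = {"phosphate": 94.97, "chain-carbon": 12.011, "chain-hydrogen": 1.008,
         "probe": 497.0, "sterol-oxygen": 17.007}
_CC_BOND = 0.127          # nm, carbon spacing along a chain
_CH_BOND = 0.109          # nm
_MIN_AREA_PER_LIPID = 0.40  # nm^2, packing floor for the lateral grid


@dataclass(frozen=True)
class GroundTruth:
    """Construction parameters of a synthetic artefact.

    kind: 'scan' | 'rotdiff' | 'jump' | 'membrane' | 'decay' | 'emission';
    params: the named scalars/lists that define the object (diffusion
    coefficient in rad^2/ps, lifetimes in ns, fractions, tilt spread in
    degrees, ...); seed: the integer that reproduces it.
    """

    kind: str
    params: dict
    seed: int


def _rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed, -1
    return np.random.default_rng(seed), int(seed)


def _attach(obj, kind, params, seed):
    truth = GroundTruth(kind=kind, params=params, seed=seed)
    try:
        obj.ground_truth = truth
    except AttributeError:  # frozen dataclass (e.g. TorsionalProfile)
        object.__setattr__(obj, "ground_truth", truth)
    return obj


# ---------------------------------------------------------------------------
# torsional scans
# ---------------------------------------------------------------------------


def make_bistable_series(barrier_planar: float, barrier_ortho: float,
                         ) -> CosineSeries:
    """Even, 180-degree-periodic cosine series (multiplicities 2 and 4) with
    four symmetry-related minima and prescribed barrier heights at the
    planar (0/180 deg) and orthogonal (+/-90 deg) geometries.

    Solving the two-term family  A cos 2phi + B cos 4phi + const  for the
    barrier pair fixes the minima positions as a by-product: barriers (7, 3)
    kcal/mol put them at +/-51.0 and +/-129.0 deg, barriers (2.5, 5.0) at
    +/-40.1 and +/-139.9 deg.
    """
    a = 0.5 * (barrier_planar - barrier_ortho)
    bp = barrier_planar
    disc = (bp - a) ** 2 - a * a
    if disc <= 0:
        raise ValueError("barrier pair admits no interior minima in the "
                         "two-term family")
    b = ((bp - a) + np.sqrt(disc)) / 4.0
    c_star = -a / (4.0 * b)
    if not (-1.0 < c_star < 1.0):
        raise ValueError("no interior minimum for this barrier pair")
    trig_min = a * c_star + b * (2.0 * c_star**2 - 1.0)
    terms = ((abs(a), 2, 0.0 if a >= 0 else 180.0), (b, 4, 0.0))
    offset = -(abs(a) + b) - trig_min
    return CosineSeries(terms=terms, offset=offset)


def gen_torsional_scan(series: CosineSeries, angles, noise_sd: float = 0.0,
                       seed=0) -> TorsionalProfile:
    """Evaluate a cosine series on a scan grid, add Gaussian noise
    (kcal/mol) and shift so the sampled minimum is zero."""
    rng, seed_id = _rng(seed)
    ang = np.asarray(angles, dtype=float)
    if ang.size == 0:
        raise ValueError("empty angle list")
    if np.any(ang < -180.0) or np.any(ang > 180.0):
        raise ValueError("angles must lie in [-180, 180]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    e = series(ang) + rng.normal(0.0, noise_sd, ang.shape)
    profile = TorsionalProfile.from_raw(ang, e)
    return _attach(profile, "scan",
                   {"terms": series.terms, "offset": series.offset,
                    "noise_sd": noise_sd}, seed_id)


# ---------------------------------------------------------------------------
# rotational diffusion
# ---------------------------------------------------------------------------


def gen_rotational_diffusion(D: float, dt: float, n_steps: int,
                             n_traj: int = 1, seed=0,
                             label: str = "rotdiff") -> VectorTrajectory:
    """Isotropic rotational diffusion of unit vectors.

    Per step each vector is rotated about a uniformly random perpendicular
    axis by an angle drawn from N(0, sqrt(4 D dt)), which reproduces the
    P2 contract <P2(p(0).p(t))> -> exp(-6 D t).  D in rad^2/ps, dt in ps.
    """
    if D < 0 or dt <= 0:
        raise ValueError("require D >= 0 and dt > 0")
    rng, seed_id = _rng(seed)
    v = rng.normal(size=(n_traj, 3))
    v /= np.linalg.norm(v, axis=-1, keepdims=True)
    out = np.empty((n_traj, n_steps + 1, 3))
    out[:, 0] = v
    if D == 0.0:
        out[:] = v[:, None, :]
    else:
        sigma = np.sqrt(4.0 * D * dt)
        for step in range(1, n_steps + 1):
            w = rng.normal(size=(n_traj, 3))
            axis = w - (np.sum(w * v, axis=-1, keepdims=True)) * v
            axis /= np.linalg.norm(axis, axis=-1, keepdims=True)
            delta = rng.normal(0.0, sigma, size=(n_traj, 1))
            v = v * np.cos(delta) + np.cross(axis, v) * np.sin(delta)
            v /= np.linalg.norm(v, axis=-1, keepdims=True)
            out[:, step] = v
    traj = VectorTrajectory(vectors=out, dt=dt, label=label)
    return _attach(traj, "rotdiff",
                   {"D": D, "dt": dt, "n_steps": n_steps, "n_traj": n_traj},
                   seed_id)


# ---------------------------------------------------------------------------
# dihedral jump dynamics
# ---------------------------------------------------------------------------


@dataclass
class DihedralSeries:
    """A dihedral-angle time series from well-to-well jump dynamics:
    angles (deg, wrapped), the occupied well index per frame, the well
    centres and the time step (ps)."""

    angles: np.ndarray
    wells: np.ndarray
    minima: np.ndarray
    dt: float


def gen_jump_dihedral(minima, rate: float, libration_sd: float, dt: float,
                      n_steps: int, seed=0) -> DihedralSeries:
    """Markov jumps among torsional wells with a symmetric total escape
    rate (1/ps) plus Gaussian libration about the current well centre."""
    centres = np.asarray(minima, dtype=float)
    if centres.size < 2:
        raise ValueError("at least two wells are required")
    if rate < 0 or dt <= 0 or libration_sd < 0:
        raise ValueError("require rate >= 0, dt > 0, libration_sd >= 0")
    rng, seed_id = _rng(seed)
    m = centres.size
    wells = np.empty(n_steps + 1, dtype=int)
    wells[0] = rng.integers(m)
    p_jump = 1.0 - np.exp(-rate * dt)
    jumps = rng.random(n_steps) < p_jump
    # uniform choice among the other wells, drawn unconditionally so the
    # stream length is independent of the realised jump pattern
    choices = rng.integers(1, m, size=n_steps)
    wells[1:] = (wells[0] + np.cumsum(np.where(jumps, choices, 0))) % m
    angles = wrap_degrees(centres[wells]
                          + rng.normal(0.0, libration_sd, n_steps + 1))
    series = DihedralSeries(angles=np.asarray(angles), wells=wells,
                            minima=centres, dt=dt)
    return _attach(series, "jump",
                   {"minima": tuple(centres), "rate": rate,
                    "libration_sd": libration_sd, "dt": dt}, seed_id)


# ---------------------------------------------------------------------------
# bilayer snapshots
# ---------------------------------------------------------------------------


def _tilted_axis(rng, tilt_sd_deg: float, down: bool) -> np.ndarray:
    """Chain axis: the inward bilayer normal tilted by N(0, sd) about a
    uniform azimuth."""
    beta = np.deg2rad(rng.normal(0.0, tilt_sd_deg)) if tilt_sd_deg > 0 else 0.0
    az = rng.uniform(0.0, 2.0 * np.pi)
    sz = -1.0 if down else 1.0
    return np.array([np.sin(beta) * np.cos(az), np.sin(beta) * np.sin(az),
                     sz * np.cos(beta)])


def gen_membrane_snapshot(n_lipids: int, chain_tilt_sd: float,
                          thickness: float, box_xy: float, seed=0,
                          n_frames: int = 1, n_carbons: int = 8,
                          n_sterols: int = 0, include_probe: bool = False,
                          ch_perp: bool = True) -> list:
    """Idealised bilayer snapshots with known structural ground truth.

    Two phosphate layers separated by ``thickness`` (nm) on a jittered
    lateral grid in a ``box_xy`` x ``box_xy`` box; each lipid carries two
    acyl chains whose axes are the inward normal tilted by N(0,
    ``chain_tilt_sd``) degrees, with two C-H bonds perpendicular to the
    chain axis per carbon (``ch_perp``).  Area per lipid is therefore
    exactly box_xy^2 / (n_lipids/2) and the phosphate density profile is
    bimodal with separation ``thickness``.
    """
    if n_lipids % 2:
        raise ValueError("n_lipids must be even (split across leaflets)")
    n_leaf = n_lipids // 2
    if box_xy * box_xy < n_leaf * _MIN_AREA_PER_LIPID:
        raise ValueError("box too small for n_lipids at the minimal area "
                         f"per lipid ({_MIN_AREA_PER_LIPID} nm^2)")
    rng, seed_id = _rng(seed)
    chain_len = 0.1 + n_carbons * _CC_BOND
    box_z = thickness + 2.0 * max(0.0, chain_len - thickness / 2.0) + 2.0
    box = np.array([box_xy, box_xy, box_z])
    z_mid = box_z / 2.0
    grid_n = int(np.ceil(np.sqrt(n_leaf)))
    spacing = box_xy / grid_n

    frames = []
    for _ in range(n_frames):
        pos, rows = [], []

        def add(p, role, lipid_id, leaflet, chain="", carbon=-1, parent=-1):
            pos.append(p)
            rows.append({"role": role, "lipid_id": lipid_id,
                         "leaflet": leaflet, "chain": chain,
                         "carbon_index": carbon, "parent": parent,
                         "mass": _MASS[role]})
            return len(pos) - 1

        lipid_id = 0
        for leaflet, zsign in (("upper", 1.0), ("lower", -1.0)):
            for i in range(n_leaf):
                gx, gy = divmod(i, grid_n)
                head = np.array([
                    (gx + 0.5) * spacing + rng.uniform(-0.05, 0.05) * spacing,
                    (gy + 0.5) * spacing + rng.uniform(-0.05, 0.05) * spacing,
                    z_mid + zsign * thickness / 2.0])
                add(head, "phosphate", lipid_id, leaflet)
                for chain, dx in (("sn1", -0.11), ("sn2", 0.11)):
                    axis = _tilted_axis(rng, chain_tilt_sd, down=zsign > 0)
                    start = head + np.array([dx, 0.0, -zsign * 0.1])
                    # orthonormal frame perpendicular to the chain axis
                    ref = (np.array([1.0, 0.0, 0.0])
                           if abs(axis[2]) > 0.9 else np.array([0.0, 0.0, 1.0]))
                    e1 = np.cross(axis, ref)
                    e1 /= np.linalg.norm(e1)
                    e2 = np.cross(axis, e1)
                    for ci in range(1, n_carbons + 1):
                        cpos = start + ci * _CC_BOND * axis
                        cidx = add(cpos, "chain-carbon", lipid_id, leaflet,
                                   chain, ci)
                        psi = rng.uniform(0.0, 2.0 * np.pi)
                        h_dir = np.cos(psi) * e1 + np.sin(psi) * e2
                        if not ch_perp:
                            h_dir = axis
                        for sgn in (1.0, -1.0):
                            add(cpos + sgn * _CH_BOND * h_dir,
                                "chain-hydrogen", lipid_id, leaflet, chain,
                                ci, parent=cidx)
                lipid_id += 1
        for _s in range(n_sterols):
            zsign = 1.0 if _s % 2 == 0 else -1.0
            p = np.array([rng.uniform(0, box_xy), rng.uniform(0, box_xy),
                          z_mid + zsign * (thickness / 2.0 - 0.5)])
            add(p, "sterol-oxygen", lipid_id,
                "upper" if zsign > 0 else "lower")
            lipid_id += 1
        if include_probe:
            add(np.array([box_xy / 2.0, box_xy / 2.0,
                          z_mid + thickness / 2.0 - 0.9]),
                "probe", -1, "")
        frame = LipidFrame(positions=np.array(pos),
                           atoms=pd.DataFrame(rows), box=box).validate()
        frames.append(frame)
    truth = GroundTruth(
        kind="membrane",
        params={"n_lipids": n_lipids, "chain_tilt_sd": chain_tilt_sd,
                "thickness": thickness, "box_xy": box_xy,
                "area_per_lipid_nm2": box_xy * box_xy / n_leaf,
                "n_sterols": n_sterols},
        seed=seed_id)
    for frame in frames:
        frame.ground_truth = truth
    return frames


# ---------------------------------------------------------------------------
# emission ensembles
# ---------------------------------------------------------------------------


def gen_emission_ensemble(mean_nm: float, sd_nm: float, n: int = 200,
                          seed=0, environment: str = ""):
    """Gaussian ensemble of per-snapshot emission wavelengths."""
    from .emission import EmissionEnsemble

    if mean_nm <= 0 or sd_nm < 0 or n < 1:
        raise ValueError("require mean_nm > 0, sd_nm >= 0, n >= 1")
    rng, seed_id = _rng(seed)
    w = rng.normal(mean_nm, sd_nm, n)
    ens = EmissionEnsemble(wavelengths=np.abs(w), environment=environment)
    return _attach(ens, "emission",
                   {"mean_nm": mean_nm, "sd_nm": sd_nm, "n": n}, seed_id)


# ---------------------------------------------------------------------------
# TCSPC decays
# ---------------------------------------------------------------------------


def _sample_mixture_times(rng, lifetimes, fractions, n_photons, period):
    taus = np.asarray(lifetimes, dtype=float)
    frac = np.asarray(fractions, dtype=float)
    if np.any(taus <= 0):
        raise ValueError("lifetimes must be positive")
    if frac.shape != taus.shape or np.any(frac < 0) or \
            abs(frac.sum() - 1.0) > 1e-8:
        raise ValueError("fractions must be nonnegative and sum to 1")
    # explicit inverse CDF over components: the stream consumed does not
    # depend on how many components carry zero weight
    u = rng.random(n_photons)
    comp = np.searchsorted(np.cumsum(frac), u, side="right")
    comp = np.minimum(comp, taus.size - 1)
    t = rng.exponential(1.0, n_photons) * taus[comp]
    return np.mod(t, period)  # fold into one repetition period, no loss


def gen_tcspc(lifetimes, fractions, n_photons: int, period: float,
              n_bins: int, seed=0) -> DecayHistogram:
    """Photon decay histogram: arrival times from a mixture of exponentials
    (intensity ``fractions``), folded modulo the repetition ``period`` (ns)
    and histogrammed into ``n_bins`` equal bins.  Delta IRF."""
    if n_photons <= 0:
        raise ValueError("n_photons must be positive")
    if period <= 0 or n_bins < 1:
        raise ValueError("require period > 0 and n_bins >= 1")
    rng, seed_id = _rng(seed)
    t = _sample_mixture_times(rng, lifetimes, fractions, n_photons, period)
    counts, _ = np.histogram(t, bins=n_bins, range=(0.0, period))
    decay = DecayHistogram(counts=counts.astype(np.int64), period=period)
    return _attach(decay, "decay",
                   {"lifetimes": tuple(np.atleast_1d(lifetimes)),
                    "fractions": tuple(np.atleast_1d(fractions)),
                    "n_photons": n_photons}, seed_id)


def gen_tcspc_image(region_map, components: dict, photons_per_pixel: int,
                    period: float, n_bins: int, seed=0) -> DecayStack:
    """Per-pixel decay stack from an integer-labelled region map.

    ``components`` maps each region label to a (lifetimes, fractions) pair;
    every pixel of that region receives ``photons_per_pixel`` photons drawn
    from that mixture.
    """
    labels = np.asarray(region_map)
    if labels.ndim != 2:
        raise ValueError("region_map must be 2-D")
    missing = set(np.unique(labels)) - set(components)
    if missing:
        raise ValueError(f"region labels without components: {sorted(missing)}")
    rng, seed_id = _rng(seed)
    ny, nx = labels.shape
    counts = np.zeros((ny, nx, n_bins), dtype=np.int64)
    for iy in range(ny):
        for ix in range(nx):
            taus, frac = components[int(labels[iy, ix])]
            t = _sample_mixture_times(rng, taus, frac, photons_per_pixel,
                                      period)
            counts[iy, ix], _ = np.histogram(t, bins=n_bins,
                                             range=(0.0, period))
    stack = DecayStack(counts=counts, period=period)
    return _attach(stack, "decay",
                   {"components": {int(k): (tuple(v[0]), tuple(v[1]))
                                   for k, v in components.items()},
                    "photons_per_pixel": photons_per_pixel}, seed_id)
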