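"""Trajectory-derived observables for rotor probes and lipid bilayers.

Covers the rotational side (signed dihedrals, ring-plane normals, the P2
orientational autocorrelation C_p(t) = <P2(p(0).p(t))> and its relaxation
time) and the membrane side (deuterium order parameters S_CD, centre-of-mass
radial distribution functions, axial density profiles, area per lipid and
bilayer thickness).

Conventions: times in ps, coordinates in nm, the bilayer normal is z, and
all distances use the minimum-image convention in rectangular boxes.
Dihedral angles follow the signed IUPAC convention (cis = 0) and are
reported in degrees wrapped to (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.fft import next_fast_len, rfft, irfft
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .torsion import wrap_degrees

__all__ = [
    "VectorTrajectory",
    "AutocorrelationResult",
    "RelaxationSummary",
    "LipidFrame",
    "MembraneGeometry",
    "NonDecayingACFError",
    "dihedral_angle",
    "plane_normal",
    "p2_acf",
    "p2_acf_blocks",
    "relaxation_time",
    "rotational_relaxation",
    "deuterium_order_param",
    "com_rdf",
    "density_profile",
    "membrane_geometry",
]


class NonDecayingACFError(ValueError):
    """The autocorrelation does not decay far enough to extract a time."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class VectorTrajectory:
    """Time series of unit 3-vectors with a uniform time step.

    ``vectors`` has shape (n_traj, n_frames, 3); a single (n_frames, 3)
    series is promoted to n_traj = 1.  ``label`` names what the vector is
    (e.g. a ring normal or the molecular-axis plane normal).
    """

    vectors: np.ndarray
    dt: float
    label: str = ""

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim == 2:
            v = v[None]
        if v.ndim != 3 or v.shape[-1] != 3:
            raise ValueError("vectors must have shape (n_traj, n_frames, 3)")
        norms = np.linalg.norm(v, axis=-1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("vectors must have unit norm (within 1e-6)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.vectors = v

    @property
    def n_traj(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_frames(self) -> int:
        return self.vectors.shape[1]


@dataclass(frozen=True)
class AutocorrelationResult:
    """P2 orientational autocorrelation: lags (ps), values (C_p(0)=1 after
    normalisation) and the number of (origin, trajectory) pairs per lag."""

    lags: np.ndarray
    values: np.ndarray
    n_origins: np.ndarray


@dataclass(frozen=True)
class RelaxationSummary:
    """A rotational relaxation time with its block-averaging uncertainty."""

    tau: float
    uncertainty: float
    method: str
    label: str = ""
    n_blocks: int = 0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("relaxation time must be positive")
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be nonnegative")


@dataclass
class LipidFrame:
    """One bilayer snapshot: positions (N, 3) in nm wrapped into ``box``,
    and per-particle metadata in ``atoms`` (columns: role, lipid_id,
    leaflet, chain, carbon_index, parent, mass).

    Roles: 'phosphate', 'chain-carbon', 'chain-hydrogen', 'probe',
    'sterol-oxygen'.  ``parent`` holds, for each chain hydrogen, the row
    index of its bonded carbon (-1 elsewhere).
    """

    positions: np.ndarray
    atoms: pd.DataFrame
    box: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if len(self.atoms) != len(self.positions):
            raise ValueError("positions / atoms length mismatch")
        self.positions = np.mod(self.positions, self.box)

    def validate(self):
        """Check the bilayer invariants (two non-empty leaflets, every
        chain carbon with at least one bonded hydrogen)."""
        leaflets = set(self.atoms.loc[self.atoms.leaflet != "", "leaflet"])
        if not {"upper", "lower"} <= leaflets:
            raise ValueError("both leaflets must be populated")
        carbons = set(self.atoms.index[self.atoms.role == "chain-carbon"])
        bonded = set(self.atoms.loc[self.atoms.role == "chain-hydrogen", "parent"])
        if carbons - bonded:
            raise ValueError("chain carbon without a bonded hydrogen reference")
        return self

    def select(self, role: str) -> np.ndarray:
        return self.positions[np.asarray(self.atoms.role == role)]


@dataclass(frozen=True)
class MembraneGeometry:
    """Bilayer structural metrics, in the units membranes are reported in."""

    area_per_lipid_A2: float
    thickness_A: float
    n_lipids_per_leaflet: int


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------


def plane_normal(pi, pj, pk) -> np.ndarray:
    """Unit normal of the plane through three points, (r_j - r_i) x (r_k - r_j)."""
    pi, pj, pk = (np.asarray(p, dtype=float) for p in (pi, pj, pk))
    n = np.cross(pj - pi, pk - pj)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("points are collinear; plane normal undefined")
    return n / norm


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed IUPAC dihedral (degrees in (-180, 180], cis = 0)."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("collinear points; dihedral undefined")
    x = n1 @ n2
    y = np.cross(n1, n2) @ (b2 / np.linalg.norm(b2))
    # signed IUPAC convention: cis (eclipsed) = 0, trans folds onto +180
    return wrap_degrees(np.degrees(np.arctan2(y, x)))


# ---------------------------------------------------------------------------
# P2 autocorrelation and relaxation times
# ---------------------------------------------------------------------------

_TENSOR_PAIRS = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
_TENSOR_WEIGHTS = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])


def _autocorr_sums(x: np.ndarray, n_lags: int) -> np.ndarray:
    """sum_s x(s) x(s+t) for t < n_lags along the last axis, via FFT."""
    n = x.shape[-1]
    nfft = next_fast_len(2 * n)
    fx = rfft(x, nfft)
    return irfft(fx * np.conj(fx), nfft)[..., :n_lags]


def p2_acf(traj: VectorTrajectory, max_lag: float | None = None) -> AutocorrelationResult:
    """C_p(t) = <P2(p(s) . p(s+t))> over all time origins s (and over
    trajectories), with P2(x) = (3 x^2 - 1) / 2.

    ``max_lag`` is in ps and must be shorter than the trajectory; the
    default is half the trajectory length.
    """
    v = traj.vectors
    n = traj.n_frames
    if n < 2:
        raise ValueError("at least two frames are required")
    if max_lag is None:
        n_lags = max(n // 2, 2)
    else:
        n_lags = int(round(max_lag / traj.dt)) + 1
        if n_lags > n:
            raise ValueError("max_lag must be shorter than the trajectory")
    # <(p(s).p(s+t))^2> as the autocorrelation of the symmetric tensor p p^T
    comp = np.stack([v[..., a] * v[..., b] for a, b in _TENSOR_PAIRS], axis=0)
    sums = _autocorr_sums(comp, n_lags)          # (6, n_traj, n_lags)
    dot2 = np.tensordot(_TENSOR_WEIGHTS, sums.sum(axis=1), axes=1)
    n_origins = traj.n_traj * (n - np.arange(n_lags))
    c2 = dot2 / n_origins
    cp = 1.5 * c2 - 0.5
    cp = cp / cp[0]
    return AutocorrelationResult(lags=np.arange(n_lags) * traj.dt,
                                 values=cp, n_origins=n_origins)


def p2_acf_blocks(traj: VectorTrajectory, n_blocks: int = 5,
                  max_lag: float | None = None) -> list:
    """Per-block ACFs for block-averaged uncertainties: the ensemble is split
    across trajectories when possible, otherwise into contiguous time blocks."""
    if traj.n_traj >= n_blocks:
        parts = np.array_split(np.arange(traj.n_traj), n_blocks)
        subs = [VectorTrajectory(traj.vectors[idx], traj.dt, traj.label)
                for idx in parts]
    else:
        edges = np.linspace(0, traj.n_frames, n_blocks + 1, dtype=int)
        subs = [VectorTrajectory(traj.vectors[:, a:b], traj.dt, traj.label)
                for a, b in zip(edges[:-1], edges[1:])]
    return [p2_acf(s, max_lag=max_lag) for s in subs]


def _exp_fit_tau(lags, values) -> float:
    below = np.nonzero(values < 1.0 / np.e)[0]
    if below.size == 0:
        raise NonDecayingACFError("ACF never decays below 1/e in the lag window")
    tau0 = max(lags[below[0]], lags[1])
    # restrict to the decaying part; lags where C has fallen under 0.05 are
    # dominated by noise and left out
    under = np.nonzero(values < 0.05)[0]
    stop = under[0] + 1 if under.size else len(lags)
    popt, _ = curve_fit(lambda t, tau: np.exp(-t / tau),
                        lags[:stop], values[:stop], p0=[tau0],
                        maxfev=10000)
    return float(popt[0])


def _integral_tau(lags, values) -> float:
    under = np.nonzero(values < 0.05)[0]
    if under.size == 0:
        raise NonDecayingACFError("ACF never decays below 0.05; integral "
                                  "truncation undefined")
    cut = under[0]
    area = float(np.trapezoid(values[: cut + 1], lags[: cut + 1]))
    # analytic exponential tail beyond the truncation point
    tau_tail = _exp_fit_tau(lags, values)
    return area + float(values[cut]) * tau_tail


def relaxation_time(acf: AutocorrelationResult, method: str = "exp_fit",
                    acf_blocks=None, label: str = "") -> RelaxationSummary:
    """Extract a relaxation time from a P2 ACF.

    ``exp_fit`` fits C(t) = exp(-t/tau); ``integral`` integrates the ACF up
    to its first crossing below 0.05 and adds the analytic exponential tail.
    When per-block ACFs are supplied the uncertainty is the standard error
    of the per-block times.
    """
    extract = {"exp_fit": _exp_fit_tau, "integral": _integral_tau}.get(method)
    if extract is None:
        raise ValueError(f"unknown method {method!r}")
    tau = extract(acf.lags, acf.values)
    unc = 0.0
    n_blocks = 0
    if acf_blocks:
        taus = [extract(b.lags, b.values) for b in acf_blocks]
        n_blocks = len(taus)
        unc = float(np.std(taus, ddof=1) / np.sqrt(n_blocks))
    return RelaxationSummary(tau=tau, uncertainty=unc, method=method,
                             label=label, n_blocks=n_blocks)


def rotational_relaxation(traj: VectorTrajectory, method: str = "exp_fit",
                          max_lag: float | None = None,
                          n_blocks: int = 5) -> RelaxationSummary:
    """Convenience pipeline: ACF, relaxation time, block uncertainty."""
    acf = p2_acf(traj, max_lag=max_lag)
    blocks = p2_acf_blocks(traj, n_blocks=n_blocks, max_lag=max_lag)
    return relaxation_time(acf, method=method, acf_blocks=blocks,
                           label=traj.label)


# ---------------------------------------------------------------------------
# membrane observables
# ---------------------------------------------------------------------------


def _min_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    return delta - box * np.round(delta / box)


def _frames_list(frames):
    return [frames] if isinstance(frames, LipidFrame) else list(frames)


def deuterium_order_param(frames, chain: str = "both",
                          probe_cutoff_nm: float | None = None) -> pd.DataFrame:
    """Deuterium order parameter profile S_CD(carbon) per acyl chain.

    S_CD = <(3 cos^2 theta - 1)/2> over C-H vectors and frames, theta the
    angle between the C-H bond and the bilayer normal (z).  With
    ``probe_cutoff_nm`` set, only lipids with any atom within that
    minimum-image distance of a probe atom contribute.  Returns a table
    (chain, carbon, s_cd, se, n) where ``se`` is the standard error over
    individual C-H samples.
    """
    frames = _frames_list(frames)
    if not frames:
        raise ValueError("at least one frame is required")
    chains = ("sn1", "sn2") if chain == "both" else (chain,)
    samples: dict = {}
    for fr in frames:
        at = fr.atoms
        hyd = at.index[at.role == "chain-hydrogen"]
        keep_lipids = None
        if probe_cutoff_nm is not None:
            probe = fr.select("probe")
            if probe.size == 0:
                raise ValueError("probe cutoff requested but no probe present")
            d = _min_image(fr.positions[:, None, :] - probe[None, :, :], fr.box)
            near = np.sqrt((d**2).sum(-1)).min(axis=1) <= probe_cutoff_nm
            keep_lipids = set(at.loc[near, "lipid_id"]) - {-1}
        for h in hyd:
            c = int(at.at[h, "parent"])
            if c < 0:
                raise ValueError("chain hydrogen without a bonded carbon")
            if at.at[c, "chain"] not in chains:
                continue
            if keep_lipids is not None and at.at[h, "lipid_id"] not in keep_lipids:
                continue
            v = _min_image(fr.positions[h] - fr.positions[c], fr.box)
            cos = v[2] / np.linalg.norm(v)
            key = (at.at[c, "chain"], int(at.at[c, "carbon_index"]))
            samples.setdefault(key, []).append(0.5 * (3.0 * cos * cos - 1.0))
    rows = []
    for (ch, idx), vals in sorted(samples.items()):
        arr = np.asarray(vals)
        se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
        rows.append({"chain": ch, "carbon": idx, "s_cd": float(arr.mean()),
                     "se": se, "n": arr.size})
    return pd.DataFrame(rows)


def com_rdf(group_a: np.ndarray, group_b: np.ndarray, box,
            bins: int = 100, r_max: float | None = None) -> pd.DataFrame:
    """Centre-of-mass radial distribution function g(r) between two groups
    of points in a periodic rectangular box, normalised by the ideal-gas
    expectation at the same density.  Returns a table (r, g)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    box = np.asarray(box, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    same = a is group_b or (a.shape == b.shape and np.array_equal(a, b))
    if r_max is None:
        r_max = float(box.min()) / 2.0
    if r_max > box.min() / 2.0 + 1e-12:
        raise ValueError("r_max must not exceed half the smallest box length")
    edges = np.linspace(0.0, r_max, bins + 1)
    ta = cKDTree(np.mod(a, box), boxsize=box)
    tb = cKDTree(np.mod(b, box), boxsize=box)
    cum = ta.count_neighbors(tb, edges)          # ordered pairs within r
    if same:
        cum = cum - len(a)                       # remove self pairs (r = 0)
    counts = np.diff(cum).astype(float)
    vol = float(np.prod(box))
    n_pairs = len(a) * (len(b) - 1) if same else len(a) * len(b)
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = n_pairs / vol * shell
    r = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"r": r, "g": counts / ideal})


def density_profile(frames, roles=None, axis: int = 2,
                    bins: int = 50) -> pd.DataFrame:
    """Mass density (amu/nm^3) along a box axis, averaged over frames.
    ``roles`` restricts the selection to the given particle roles."""
    frames = _frames_list(frames)
    if bins < 10:
        raise ValueError("at least 10 bins are required")
    box = frames[0].box
    if box[axis] <= 0:
        raise ValueError("zero-thickness box")
    edges = np.linspace(0.0, box[axis], bins + 1)
    area = float(np.prod(np.delete(box, axis)))
    slab = area * (edges[1] - edges[0])
    dens = np.zeros(bins)
    for fr in frames:
        mask = (np.ones(len(fr.atoms), bool) if roles is None
                else np.asarray(fr.atoms.role.isin(roles)))
        hist, _ = np.histogram(fr.positions[mask, axis], bins=edges,
                               weights=np.asarray(fr.atoms.mass)[mask])
        dens += hist / slab
    dens /= len(frames)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"z": centers, "density": dens})


def membrane_geometry(frames, bin_width_nm: float = 0.05) -> MembraneGeometry:
    """Area per lipid (lateral box area / phospholipids per leaflet; sterols
    carry no phosphate and are excluded) and bilayer thickness (distance
    between the upper and lower phosphate density maxima), in A^2 and A."""
    frames = _frames_list(frames)
    fr0 = frames[0]
    phos = fr0.atoms[fr0.atoms.role == "phosphate"]
    per_leaflet = phos.groupby("leaflet")["lipid_id"].nunique()
    if not {"upper", "lower"} <= set(per_leaflet.index):
        raise ValueError("both leaflets must contain phospholipids")
    n_leaflet = int(per_leaflet.mean())
    area_nm2 = float(fr0.box[0] * fr0.box[1])
    apl = area_nm2 / per_leaflet.mean() * 100.0  # nm^2 -> A^2

    box_z = fr0.box[2]
    bins = max(int(round(box_z / bin_width_nm)), 10)
    edges = np.linspace(0.0, box_z, bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peaks = {}
    for leaflet in ("upper", "lower"):
        hist = np.zeros(bins)
        for fr in frames:
            mask = np.asarray((fr.atoms.role == "phosphate")
                              & (fr.atoms.leaflet == leaflet))
            h, _ = np.histogram(fr.positions[mask, 2], bins=edges)
            hist += h
        imax = int(np.argmax(hist))
        # refine the maximum by the count-weighted centroid of the peak
        # neighbourhood (sub-bin resolution for narrow distributions)
        lo, hi = max(imax - 1, 0), min(imax + 2, bins)
        peaks[leaflet] = float(np.average(centers[lo:hi],
                                          weights=hist[lo:hi]))
    thickness = abs(peaks["upper"] - peaks["lower"]) * 10.0  # nm -> A
    return MembraneGeometry(area_per_lipid_A2=float(apl),
                            thickness_A=float(thickness),
                            n_lipids_per_leaflet=n_leaflet)
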