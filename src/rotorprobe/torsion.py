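"""Intramolecular force field for a propeller-shaped fluorescent rotor.

The model follows the standard classical decomposition: harmonic penalties
for bonds, valence angles and rigid/improper dihedrals, cosine series for
the flexible ring torsions, and Lennard-Jones + Coulomb nonbonded terms.
Flexible-torsion force constants are obtained by linear least squares
against relaxed-scan energies (FIRA: only the scanned dihedral moves), or
by minimising a weighted objective over scan energies plus the gradient and
Hessian at the minimum (the "Joyce" objective), whose three blocks are each
normalised by their number of terms so the weights are size-independent.

Units: energies in kcal/mol, angles/phases in degrees (wrapped to
(-180, 180]), bond lengths in nm.  Harmonic angle/dihedral force constants
are kcal/mol/rad^2; the degree values are converted internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CosineSeries",
    "TorsionalProfile",
    "HarmonicTerm",
    "NonbondedParams",
    "InternalGeometry",
    "ReferenceScanData",
    "CosineFitResult",
    "TorsionLandscape",
    "JoyceModel",
    "JoyceResults",
    "eval_cosine_series",
    "eval_ff_bonded",
    "fit_cosine_series",
    "joyce_objective",
    "minimize_joyce",
    "locate_minima_barriers",
    "wrap_degrees",
]

KCAL_TO_KJ = 4.184
#: Coulomb constant in kcal mol^-1 nm e^-2
COULOMB_KCAL_NM = 33.2063713


def wrap_degrees(angle):
    """Wrap angles (degrees) into the (-180, 180] convention."""
    a = np.asarray(angle, dtype=float)
    wrapped = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return wrapped if wrapped.shape else float(wrapped)


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CosineSeries:
    """Flexible-torsion potential  sum_j k_j (1 + cos(n_j phi - gamma_j)) + offset.

    ``terms`` is a sequence of (k [kcal/mol], multiplicity n (positive int),
    phase gamma [deg]) tuples; multiplicities must be distinct within one
    series.  The 1+cos convention is the common topology-file dialect and is
    the one used by the parameter writer.
    """

    terms: tuple = ()
    offset: float = 0.0

    def __post_init__(self):
        terms = tuple((float(k), int(n), float(g)) for k, n, g in self.terms)
        object.__setattr__(self, "terms", terms)
        mults = [n for _, n, _ in terms]
        if len(set(mults)) != len(mults):
            raise ValueError(f"multiplicities must be distinct, got {mults}")
        if any(n < 1 for n in mults):
            raise ValueError("multiplicities must be positive integers")
        if not all(np.isfinite(k) and np.isfinite(g) for k, _, g in terms):
            raise ValueError("force constants and phases must be finite")

    def __call__(self, phi_deg):
        """Evaluate the series at ``phi_deg`` (scalar or array), kcal/mol."""
        phi = np.deg2rad(np.asarray(phi_deg, dtype=float))
        e = np.full_like(phi, self.offset, dtype=float)
        for k, n, g in self.terms:
            e = e + k * (1.0 + np.cos(n * phi - np.deg2rad(g)))
        return e if e.shape else float(e)


def eval_cosine_series(series: CosineSeries, phi_deg):
    """Functional alias for :meth:`CosineSeries.__call__`."""
    return series(phi_deg)


@dataclass(frozen=True)
class TorsionalProfile:
    """A torsional scan: angles (deg, strictly increasing in [-180, 180])
    and relative energies (kcal/mol) with the sampled minimum at zero."""

    angles: np.ndarray
    energies: np.ndarray

    def __post_init__(self):
        ang = np.asarray(self.angles, dtype=float)
        ene = np.asarray(self.energies, dtype=float)
        if ang.ndim != 1 or ang.shape != ene.shape:
            raise ValueError("angles and energies must be equal-length 1-D arrays")
        if ang.size == 0:
            raise ValueError("empty scan")
        if np.any(np.diff(ang) <= 0):
            raise ValueError("angles must be strictly increasing")
        if ang[0] < -180.0 - 1e-9 or ang[-1] > 180.0 + 1e-9:
            raise ValueError("angles must lie in [-180, 180]")
        if abs(float(ene.min())) > 1e-8:
            raise ValueError("profile energies must be relative to the scan minimum")
        object.__setattr__(self, "angles", ang)
        object.__setattr__(self, "energies", ene)

    @classmethod
    def from_raw(cls, angles, energies) -> "TorsionalProfile":
        """Build a profile from raw energies, shifting the minimum to zero."""
        e = np.asarray(energies, dtype=float)
        return cls(np.asarray(angles, dtype=float), e - e.min())

    def __len__(self):
        return self.angles.size


@dataclass(frozen=True)
class HarmonicTerm:
    """Harmonic bonded term 1/2 k (x - eq)^2.

    kind: 'bond' | 'angle' | 'rigid_dihedral' | 'improper'.
    k in kcal/mol/nm^2 for bonds, kcal/mol/rad^2 otherwise; eq_value in nm
    or degrees accordingly.
    """

    kind: str
    k: float
    eq_value: float

    def __post_init__(self):
        if self.kind not in ("bond", "angle", "rigid_dihedral", "improper"):
            raise ValueError(f"unknown harmonic kind {self.kind!r}")
        if self.k < 0:
            raise ValueError("harmonic force constants must be nonnegative")


@dataclass(frozen=True)
class NonbondedParams:
    """Per-atom charges (e) and Lennard-Jones sigma (nm) / epsilon (kcal/mol),
    with an exclusion list of bonded pairs.  Lorentz-Berthelot combination."""

    charge: dict
    sigma: dict
    epsilon: dict
    exclusions: frozenset = frozenset()

    def __post_init__(self):
        if any(s <= 0 for s in self.sigma.values()):
            raise ValueError("sigma must be positive")
        if any(e < 0 for e in self.epsilon.values()):
            raise ValueError("epsilon must be nonnegative")
        excl = frozenset(frozenset(p) for p in self.exclusions)
        object.__setattr__(self, "exclusions", excl)

    def pair_energy(self, i, j, r_nm: float) -> float:
        if frozenset((i, j)) in self.exclusions:
            return 0.0
        sig = 0.5 * (self.sigma[i] + self.sigma[j])
        eps = np.sqrt(self.epsilon[i] * self.epsilon[j])
        sr6 = (sig / r_nm) ** 6
        e_lj = 4.0 * eps * (sr6 * sr6 - sr6)
        e_q = COULOMB_KCAL_NM * self.charge[i] * self.charge[j] / r_nm
        return e_lj + e_q


@dataclass
class InternalGeometry:
    """Values of the internal coordinates of one conformation.

    Each dict maps a coordinate name to its value (bonds nm; angles and
    dihedrals degrees).  ``pair_distances`` maps (atom_i, atom_j) to the
    interatomic distance (nm) for nonbonded pairs.
    """

    bonds: dict = field(default_factory=dict)
    angles: dict = field(default_factory=dict)
    rigid_dihedrals: dict = field(default_factory=dict)
    impropers: dict = field(default_factory=dict)
    flexible_dihedrals: dict = field(default_factory=dict)
    pair_distances: dict = field(default_factory=dict)


def eval_ff_bonded(
    geom: InternalGeometry,
    harmonics: dict,
    cosine_series_map: dict | None = None,
    nonbonded: NonbondedParams | None = None,
) -> float:
    """Total intramolecular energy (kcal/mol) of one conformation.

    ``harmonics`` maps coordinate name -> :class:`HarmonicTerm` and must cover
    every bond/angle/rigid-dihedral/improper in ``geom`` exactly once;
    ``cosine_series_map`` maps flexible-dihedral name -> :class:`CosineSeries`.
    """
    cosine_series_map = cosine_series_map or {}
    kind_of = {"bonds": "bond", "angles": "angle",
               "rigid_dihedrals": "rigid_dihedral", "impropers": "improper"}
    covered = set()
    energy = 0.0
    for attr, kind in kind_of.items():
        for name, value in getattr(geom, attr).items():
            if name not in harmonics:
                raise ValueError(f"missing harmonic parameter for {kind} {name!r}")
            term = harmonics[name]
            if term.kind != kind:
                raise ValueError(
                    f"parameter {name!r} has kind {term.kind!r}, expected {kind!r}")
            covered.add(name)
            if kind == "bond":
                delta = value - term.eq_value
            else:
                delta = np.deg2rad(wrap_degrees(value - term.eq_value))
            energy += 0.5 * term.k * delta * delta
    extra = set(harmonics) - covered
    if extra:
        raise ValueError(f"harmonic parameters without a coordinate: {sorted(extra)}")

    for name, phi in geom.flexible_dihedrals.items():
        if name not in cosine_series_map:
            raise ValueError(f"missing cosine series for flexible dihedral {name!r}")
        energy += cosine_series_map[name](phi)
    unused = set(cosine_series_map) - set(geom.flexible_dihedrals)
    if unused:
        raise ValueError(f"cosine series without a coordinate: {sorted(unused)}")

    if nonbonded is not None:
        for (i, j), r in geom.pair_distances.items():
            energy += nonbonded.pair_energy(i, j, r)
    return float(energy)


# ---------------------------------------------------------------------------
# scan fitting (FIRA)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CosineFitResult:
    """Result of a linear least-squares torsional fit."""

    series: CosineSeries
    rms: float
    residuals: np.ndarray
    n_points: int

    def summary(self) -> str:
        lines = ["Torsional cosine-series fit",
                 f"  points: {self.n_points}   RMS: {self.rms:.3e} kcal/mol",
                 "  n    k (kcal/mol)   gamma (deg)"]
        for k, n, g in self.series.terms:
            lines.append(f"  {n:<4d} {k:>12.6f}   {g:>10.3f}")
        lines.append(f"  offset: {self.series.offset:.6f} kcal/mol")
        return "\n".join(lines)


def _confounded_multiplicities(columns, mults) -> list:
    """Pairs of multiplicities whose design columns are (nearly) collinear
    on the sampled grid."""
    pairs = []
    norms = np.linalg.norm(columns, axis=0)
    for i in range(len(mults)):
        for j in range(i + 1, len(mults)):
            if norms[i] < 1e-12 or norms[j] < 1e-12:
                continue
            c = abs(columns[:, i] @ columns[:, j]) / (norms[i] * norms[j])
            if c > 1.0 - 1e-8:
                pairs.append((mults[i], mults[j]))
    return pairs


def fit_cosine_series(
    profile: TorsionalProfile,
    multiplicities,
    phases=None,
) -> CosineFitResult:
    """Fit a cosine series to a relaxed torsional scan (FIRA) by linear
    least squares in the force constants.

    phases: None (all 0 deg), a list of fixed phases (deg, one per
    multiplicity), or ``"free"`` to fit the phases too (via the cos/sin
    expansion of each harmonic, still a linear problem).
    """
    mults = [int(n) for n in multiplicities]
    if len(set(mults)) != len(mults):
        raise ValueError("multiplicities must be distinct")
    phi = np.deg2rad(profile.angles)
    free_phase = isinstance(phases, str) and phases == "free"
    if phases is None:
        phase_list = [0.0] * len(mults)
    elif not free_phase:
        phase_list = [float(g) for g in phases]
        if len(phase_list) != len(mults):
            raise ValueError("one phase per multiplicity required")

    if free_phase:
        trig = np.column_stack(
            [np.cos(n * phi) for n in mults] + [np.sin(n * phi) for n in mults])
        n_free = 2 * len(mults) + 1
    else:
        trig = np.column_stack(
            [np.cos(n * phi - np.deg2rad(g)) for n, g in zip(mults, phase_list)])
        n_free = len(mults) + 1
    if len(profile) < n_free:
        raise ValueError(
            f"scan has {len(profile)} points but the fit has {n_free} free "
            "coefficients")
    design = np.column_stack([np.ones_like(phi), trig])
    rank = np.linalg.matrix_rank(design, tol=1e-10 * max(1.0, len(profile)))
    if rank < design.shape[1]:
        bad = _confounded_multiplicities(trig[:, : len(mults)], mults)
        raise ValueError(
            "rank-deficient torsional design on the sampled angles; "
            f"confounded multiplicities: {bad or 'unresolved'}")

    coef, *_ = np.linalg.lstsq(design, profile.energies, rcond=None)
    if free_phase:
        a = coef[1: 1 + len(mults)]
        b = coef[1 + len(mults):]
        ks = np.hypot(a, b)
        gammas = np.rad2deg(np.arctan2(b, a))
        terms = tuple(zip(ks, mults, gammas))
    else:
        ks = coef[1:]
        terms = tuple(zip(ks, mults, phase_list))
    # the constant column absorbed sum(k) from the 1+cos convention
    offset = float(coef[0] - np.sum(ks))
    series = CosineSeries(terms=terms, offset=offset)
    resid = series(profile.angles) - profile.energies
    rms = float(np.sqrt(np.mean(resid**2)))
    return CosineFitResult(series=series, rms=rms, residuals=resid,
                           n_points=len(profile))


# ---------------------------------------------------------------------------
# landscape analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TorsionLandscape:
    """Stationary-point analysis of a periodic torsional potential.

    minima: list of (angle_deg, energy) sorted by angle; barriers: one dict
    per adjacent-minimum pair walking clockwise (increasing angle), with the
    barrier top and the heights seen from either side.
    """

    minima: list
    barriers: list
    flat: bool = False


def _refine_quadratic(x0: float, h: float, em: float, e0: float, ep: float):
    """Vertex of the parabola through three equally spaced samples."""
    denom = em - 2.0 * e0 + ep
    if abs(denom) < 1e-300:
        return x0, e0
    shift = 0.5 * h * (em - ep) / denom
    energy = e0 - (em - ep) ** 2 / (8.0 * denom)
    return x0 + shift, energy


def locate_minima_barriers(series: CosineSeries, grid_step: float = 0.25,
                           flat_tol: float = 1e-10) -> TorsionLandscape:
    """Locate the minima of a cosine series on a dense periodic grid,
    refine them by local quadratic interpolation, and report the barrier
    between each pair of adjacent minima (clockwise pairing)."""
    if grid_step > 1.0:
        raise ValueError("grid step must be <= 1 degree")
    n = int(round(360.0 / grid_step))
    grid = -180.0 + 360.0 * np.arange(n) / n
    e = series(grid)
    if np.ptp(e) < flat_tol:
        return TorsionLandscape(minima=[], barriers=[], flat=True)

    prev = np.roll(e, 1)
    nxt = np.roll(e, -1)
    min_idx = np.nonzero((e < prev) & (e <= nxt))[0]
    max_idx = np.nonzero((e > prev) & (e >= nxt))[0]

    def refined(idx):
        out = []
        for i in idx:
            ang, en = _refine_quadratic(
                grid[i], 360.0 / n, e[(i - 1) % n], e[i], e[(i + 1) % n])
            out.append((wrap_degrees(ang), float(en)))
        return sorted(out)

    minima = refined(min_idx)
    maxima = refined(max_idx)
    barriers = []
    m = len(minima)
    for i in range(m):
        a0, e0 = minima[i]
        a1, e1 = minima[(i + 1) % m]
        # the unique maximum lying clockwise between the two minima
        span = (a1 - a0) % 360.0 or 360.0
        tops = [(ang, en) for ang, en in maxima if 0.0 < (ang - a0) % 360.0 <= span]
        if not tops:
            continue
        top_ang, top_e = max(tops, key=lambda t: t[1])
        barriers.append({
            "from_deg": a0, "to_deg": a1, "top_deg": top_ang,
            "top_energy": top_e,
            "forward": top_e - e0, "backward": top_e - e1,
        })
    return TorsionLandscape(minima=minima, barriers=barriers, flat=False)


# ---------------------------------------------------------------------------
# Joyce-style objective over energies, gradient and Hessian
# ---------------------------------------------------------------------------


@dataclass
class ReferenceScanData:
    """Reference data entering the weighted objective: a torsional scan
    (N_geom energies), plus the gradient and Hessian with respect to an
    opaque set of (normal) coordinates at the minimum, with block weights
    W (energy), W' (gradient), W'' (Hessian)."""

    profile: TorsionalProfile
    gradient: np.ndarray | None = None
    hessian: np.ndarray | None = None
    w_energy: float = 1.0
    w_gradient: float = 1.0
    w_hessian: float = 1.0

    def __post_init__(self):
        if min(self.w_energy, self.w_gradient, self.w_hessian) < 0:
            raise ValueError("weights must be nonnegative")
        if self.gradient is not None:
            self.gradient = np.asarray(self.gradient, dtype=float)
        if self.hessian is not None:
            h = np.asarray(self.hessian, dtype=float)
            if h.ndim != 2 or h.shape[0] != h.shape[1]:
                raise ValueError("hessian must be square")
            if not np.allclose(h, h.T, atol=1e-10):
                raise ValueError("hessian must be symmetric")
            self.hessian = h
            if self.gradient is not None and self.gradient.size != h.shape[0]:
                raise ValueError("gradient / hessian dimension mismatch")


def _tri(h):
    iu = np.triu_indices(h.shape[0])
    return np.asarray(h)[iu]


def joyce_objective(
    ref: ReferenceScanData,
    model_energy,
    model_gradient=None,
    model_hessian=None,
) -> float:
    """Weighted mean-squared mismatch over the energy, gradient and Hessian
    blocks, each normalised by its number of independent terms (upper
    triangle for the symmetric Hessian)."""
    obj = 0.0
    e = np.asarray(model_energy, dtype=float)
    if e.shape != ref.profile.energies.shape:
        raise ValueError("model energy block has wrong length")
    obj += ref.w_energy * np.mean((ref.profile.energies - e) ** 2)
    if ref.gradient is not None:
        if model_gradient is None:
            raise ValueError("reference has a gradient block but model does not")
        g = np.asarray(model_gradient, dtype=float)
        if g.shape != ref.gradient.shape:
            raise ValueError("model gradient block has wrong length")
        obj += ref.w_gradient * np.mean((ref.gradient - g) ** 2)
    if ref.hessian is not None:
        if model_hessian is None:
            raise ValueError("reference has a Hessian block but model does not")
        h = np.asarray(model_hessian, dtype=float)
        if h.shape != ref.hessian.shape:
            raise ValueError("model Hessian block has wrong shape")
        obj += ref.w_hessian * np.mean((_tri(ref.hessian) - _tri(h)) ** 2)
    return float(obj)


class JoyceModel:
    """Weighted least-squares determination of force constants that enter the
    model linearly (all force constants at fixed equilibrium values,
    multiplicities and phases do).

    The model blocks are affine in the parameter vector p:

        E(p)  = energy_offset  + energy_design  @ p        (N_geom,)
        G(p)  = gradient_offset + gradient_design @ p      (N_K,)
        H(p)  = hessian_offset + sum_m p_m hessian_basis[m]  (N_K, N_K)

    ``free`` flags (one per parameter) freeze individual parameters at their
    init values; frozen contributions are folded into the offsets at fit
    time.  ``fit`` solves the weighted normal equations; a singular system
    falls back to a ridge-regularised solve with a warning.
    """

    def __init__(self, ref: ReferenceScanData, energy_design,
                 gradient_design=None, hessian_basis=None,
                 energy_offset=0.0, gradient_offset=0.0, hessian_offset=0.0,
                 param_names=None, free=None):
        self.ref = ref
        self.energy_design = np.asarray(energy_design, dtype=float)
        self.n_params = self.energy_design.shape[1]
        self.gradient_design = (None if gradient_design is None
                                else np.asarray(gradient_design, dtype=float))
        self.hessian_basis = (None if hessian_basis is None
                              else np.asarray(hessian_basis, dtype=float))
        self.energy_offset = np.broadcast_to(
            np.asarray(energy_offset, dtype=float),
            (self.energy_design.shape[0],)).copy()
        if self.gradient_design is not None:
            self.gradient_offset = np.broadcast_to(
                np.asarray(gradient_offset, dtype=float),
                (self.gradient_design.shape[0],)).copy()
        if self.hessian_basis is not None:
            nk = self.hessian_basis.shape[1]
            self.hessian_offset = np.broadcast_to(
                np.asarray(hessian_offset, dtype=float), (nk, nk)).copy()
        self.param_names = (list(param_names) if param_names is not None
                            else [f"k{m}" for m in range(self.n_params)])
        self.free = (np.ones(self.n_params, bool) if free is None
                     else np.asarray(free, dtype=bool))
        if not self.free.any():
            raise ValueError("at least one parameter must be free")

    # -- model blocks -----------------------------------------------------
    def blocks(self, params):
        p = np.asarray(params, dtype=float)
        e = self.energy_offset + self.energy_design @ p
        g = (None if self.gradient_design is None
             else self.gradient_offset + self.gradient_design @ p)
        h = (None if self.hessian_basis is None
             else self.hessian_offset + np.tensordot(p, self.hessian_basis, axes=1))
        return e, g, h

    def objective(self, params) -> float:
        e, g, h = self.blocks(params)
        return joyce_objective(self.ref, e, g, h)

    def _stacked_system(self, frozen_values):
        ref = self.ref
        rows, rhs = [], []
        n_e = len(ref.profile)
        we = np.sqrt(ref.w_energy / n_e)
        rows.append(we * self.energy_design)
        rhs.append(we * (ref.profile.energies - self.energy_offset))
        if ref.gradient is not None:
            if self.gradient_design is None:
                raise ValueError("reference has a gradient block but the model "
                                 "defines none")
            wg = np.sqrt(ref.w_gradient / ref.gradient.size)
            rows.append(wg * self.gradient_design)
            rhs.append(wg * (ref.gradient - self.gradient_offset))
        if ref.hessian is not None:
            if self.hessian_basis is None:
                raise ValueError("reference has a Hessian block but the model "
                                 "defines none")
            nk = ref.hessian.shape[0]
            n_h = nk * (nk + 1) // 2
            wh = np.sqrt(ref.w_hessian / n_h)
            rows.append(wh * np.stack([_tri(b) for b in self.hessian_basis], axis=1))
            rhs.append(wh * (_tri(ref.hessian) - _tri(self.hessian_offset)))
        a = np.vstack(rows)
        b = np.concatenate(rhs)
        # fold frozen parameters into the right-hand side
        if not self.free.all():
            b = b - a[:, ~self.free] @ frozen_values
            a = a[:, self.free]
        return a, b

    def fit(self, init=None) -> "JoyceResults":
        """Solve for the free force constants; the returned objective is
        guaranteed not to exceed the objective at ``init``."""
        init = (np.zeros(self.n_params) if init is None
                else np.asarray(init, dtype=float))
        a, b = self._stacked_system(init[~self.free])
        rank = np.linalg.matrix_rank(a, tol=1e-10 * max(a.shape))
        if rank < a.shape[1]:
            warnings.warn("singular normal equations; using a ridge-regularised "
                          "solve", RuntimeWarning, stacklevel=2)
            lam = 1e-10 * max(1.0, float(np.sum(a * a)))
            sol = np.linalg.solve(a.T @ a + lam * np.eye(a.shape[1]), a.T @ b)
        else:
            sol, *_ = np.linalg.lstsq(a, b, rcond=None)
        params = init.copy()
        params[self.free] = sol
        obj = self.objective(params)
        obj_init = self.objective(init)
        if obj > obj_init:  # only possible through the ridge fallback
            params, obj = init, obj_init
        return JoyceResults(model=self, params=params, objective=obj,
                            objective_at_init=obj_init)


@dataclass
class JoyceResults:
    model: JoyceModel
    params: np.ndarray
    objective: float
    objective_at_init: float

    def params_dict(self) -> dict:
        return dict(zip(self.model.param_names, self.params))

    def summary(self) -> str:
        lines = ["Joyce weighted least-squares fit",
                 f"  objective: {self.objective:.6e}  "
                 f"(at init: {self.objective_at_init:.6e})",
                 f"  weights W/W'/W'': {self.model.ref.w_energy:g} / "
                 f"{self.model.ref.w_gradient:g} / {self.model.ref.w_hessian:g}",
                 "  parameter        value"]
        for name, val, fr in zip(self.model.param_names, self.params,
                                 self.model.free):
            tag = "" if fr else "  (frozen)"
            lines.append(f"  {name:<15s} {val:>12.6f}{tag}")
        return "\n".join(lines)


def minimize_joyce(model: JoyceModel, init=None) -> JoyceResults:
    """Functional wrapper: minimise the weighted objective of ``model``."""
    return model.fit(init=init)
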