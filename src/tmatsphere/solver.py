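"""Coupled multiple-scattering system for assemblies of spheres.

The exterior multipole coefficients b of all spheres satisfy the linear
system (I - T) A = L, where L is the uncoupled (single-sphere Mie) response
to the incident plane wave and the off-diagonal blocks of T re-expand each
sphere's outgoing field as a regular field about every other sphere (via the
translational addition theorem) before applying that sphere's T-matrix.

Solvers:

* ``solve_full``       -- exact dense solve of (I - T) A = L;
* ``solve_forward``    -- forward-scattering approximation: spheres ordered
  by slices along the beam axis, couplings from downstream and within the
  same slice dropped, solved by block forward substitution;
* ``solve_kinematic``  -- first Born applied to the assembly: A = L;
* ``solve_successive`` -- Neumann expansion of the forward system: the n-th
  term is the n-times-scattered amplitude, terminating exactly at the slice
  count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .mie import SphereTMatrix
from .potentials import BeamParameters
from .special import (
    TranslationOperator,
    block_size,
    multipole_indices,
    plane_wave_coefficients,
    translation_matrix,
)

__all__ = [
    "Scatterer",
    "ScattererArray",
    "CoefficientSet",
    "SuccessiveResult",
    "assemble_system",
    "solve_full",
    "solve_forward",
    "solve_kinematic",
    "solve_successive",
    "coefficient_error",
]

_AXIS_TOL = 1e-9


@dataclass
class Scatterer:
    """One sphere: centre (Å) and its single-sphere T-matrix."""

    centre: np.ndarray
    tmat: SphereTMatrix

    def __post_init__(self):
        self.centre = np.asarray(self.centre, dtype=float)
        if self.centre.shape != (3,):
            raise ValueError("centre must be a 3-vector")

    @property
    def radius(self) -> float:
        return self.tmat.radius


@dataclass
class ScattererArray:
    """Ordered list of spheres plus the beam and truncation order.

    The forward solvers require ascending order along the beam axis (ties
    broken by transverse coordinates); ``slice_of`` assigns spheres whose z
    differ by less than 1e-9/k to the same slice.  The axisymmetric (m = 0)
    reduction is auto-enabled when every centre lies on the beam axis and the
    incidence is axial.
    """

    scatterers: list[Scatterer]
    beam: BeamParameters
    l_max: int
    axisymmetric: bool = field(init=False)
    slice_of: np.ndarray = field(init=False)

    def __post_init__(self):
        if not self.scatterers:
            raise ValueError("at least one scatterer is required")
        self._check_overlap()
        self.axisymmetric = self.beam.is_axial and all(
            abs(s.centre[0]) < _AXIS_TOL and abs(s.centre[1]) < _AXIS_TOL
            for s in self.scatterers
        )
        self.slice_of = self._assign_slices()

    def _check_overlap(self):
        n = len(self.scatterers)
        for p in range(n):
            for q in range(p + 1, n):
                sp, sq = self.scatterers[p], self.scatterers[q]
                gap = np.linalg.norm(sp.centre - sq.centre)
                if gap <= sp.radius + sq.radius:
                    raise ValueError(
                        f"spheres {p} and {q} overlap: centre distance {gap:.6g} Å "
                        f"<= sum of radii {sp.radius + sq.radius:.6g} Å"
                    )

    def _assign_slices(self) -> np.ndarray:
        tol = _AXIS_TOL / self.beam.k
        zs = np.array([s.centre[2] for s in self.scatterers])
        order = np.argsort(zs, kind="stable")
        slice_of = np.empty(len(zs), dtype=int)
        cur, z_ref = 0, zs[order[0]]
        for i in order:
            if zs[i] - z_ref > tol:
                cur += 1
                z_ref = zs[i]
            slice_of[i] = cur
        return slice_of

    @property
    def n_spheres(self) -> int:
        return len(self.scatterers)

    @property
    def n_slices(self) -> int:
        return int(self.slice_of.max()) + 1

    @property
    def is_forward_sorted(self) -> bool:
        """Ascending slice order, ties broken by (x, y)."""
        keys = [
            (self.slice_of[i], s.centre[0], s.centre[1])
            for i, s in enumerate(self.scatterers)
        ]
        return all(keys[i] <= keys[i + 1] for i in range(len(keys) - 1))

    @property
    def block(self) -> int:
        return block_size(self.l_max, self.axisymmetric)

    def t_flat(self, p: int) -> np.ndarray:
        """Per-(l,m) diagonal of sphere p's T-matrix over the flattened basis."""
        t = self.scatterers[p].tmat.t
        idx = multipole_indices(self.l_max, self.axisymmetric)
        return np.array([t[l] for l, _ in idx])

    def c_flat(self, p: int) -> np.ndarray:
        c = self.scatterers[p].tmat.c
        idx = multipole_indices(self.l_max, self.axisymmetric)
        return np.array([c[l] for l, _ in idx])


@dataclass
class CoefficientSet:
    """Exterior (b) and interior (c) multipole coefficients, (N, block).

    ``a_in`` holds the regular (incoming) coefficients each sphere responded
    to — the plane wave plus, mode permitting, the re-expanded fields of the
    other spheres; interior fields of multi-shell spheres are reconstructed
    from it.
    """

    b: np.ndarray
    c: np.ndarray
    mode: str
    l_max: int
    axisymmetric: bool
    a_in: np.ndarray | None = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.b)):
            raise ValueError("non-finite exterior coefficients")


@dataclass
class SuccessiveResult:
    """Per-order terms and cumulative sums of the n-times-scattering expansion."""

    terms: list[CoefficientSet]
    cumulative: list[CoefficientSet]


@dataclass
class AssembledSystem:
    array: ScattererArray
    L: np.ndarray  # (N, block) uncoupled Mie solution
    a_inc: np.ndarray  # (N, block) incident-wave regular coefficients
    translations: dict[tuple[int, int], TranslationOperator]

    def coupling_block(self, p: int, q: int) -> np.ndarray:
        """Block T_pq = t_p o (outgoing q -> regular p)."""
        tp = self.array.t_flat(p)
        return tp[:, None] * self.translations[(p, q)].matrix


_translation_cache: dict[tuple, TranslationOperator] = {}


def _cached_translation(l_max: int, kd_vec: np.ndarray, axisymmetric: bool) -> TranslationOperator:
    key = (l_max, axisymmetric, tuple(np.round(kd_vec, 9)))
    if key not in _translation_cache:
        _translation_cache[key] = translation_matrix(
            l_max, kd_vec, kind="outgoing_to_regular", axisymmetric=axisymmetric
        )
    return _translation_cache[key]


def assemble_system(array: ScattererArray) -> AssembledSystem:
    """Incident-wave blocks and all pairwise translation operators."""
    N, B = array.n_spheres, array.block
    k = array.beam.k
    a_inc = np.empty((N, B), dtype=complex)
    L = np.empty((N, B), dtype=complex)
    for p, s in enumerate(array.scatterers):
        a_inc[p] = plane_wave_coefficients(array.beam, s.centre, array.l_max, array.axisymmetric)
        L[p] = array.t_flat(p) * a_inc[p]
    translations = {}
    for p in range(N):
        for q in range(N):
            if p == q:
                continue
            kd_vec = k * (array.scatterers[p].centre - array.scatterers[q].centre)
            translations[(p, q)] = _cached_translation(array.l_max, kd_vec, array.axisymmetric)
    return AssembledSystem(array=array, L=L, a_inc=a_inc, translations=translations)


def _interior_from_incoming(array: ScattererArray, a_tot: np.ndarray) -> np.ndarray:
    c = np.empty_like(a_tot)
    for p in range(array.n_spheres):
        c[p] = array.c_flat(p) * a_tot[p]
    return c


def solve_full(array: ScattererArray, system: AssembledSystem | None = None) -> CoefficientSet:
    """Exact dense solve of (I - T) A = L with a residual guarantee."""
    sys_ = system if system is not None else assemble_system(array)
    N, B = array.n_spheres, array.block
    M = np.eye(N * B, dtype=complex)
    for p in range(N):
        for q in range(N):
            if p == q:
                continue
            M[p * B:(p + 1) * B, q * B:(q + 1) * B] -= sys_.coupling_block(p, q)
    rhs = sys_.L.reshape(-1)
    if N * B > 1:
        cond = np.linalg.cond(M)
        if cond > 1e12:
            warnings.warn(f"coupled system is ill-conditioned (cond ~ {cond:.2e})")
    b = scipy.linalg.solve(M, rhs)
    norm_rhs = np.linalg.norm(rhs)
    if norm_rhs > 0:
        resid = np.linalg.norm(M @ b - rhs) / norm_rhs
        if resid > 1e-10:
            warnings.warn(f"solve residual {resid:.2e} exceeds 1e-10")
    b = b.reshape(N, B)
    a_tot = sys_.a_inc.copy()
    for p in range(N):
        for q in range(N):
            if p != q:
                a_tot[p] += sys_.translations[(p, q)].apply(b[q])
    return CoefficientSet(b=b, c=_interior_from_incoming(array, a_tot), mode="full",
                          l_max=array.l_max, axisymmetric=array.axisymmetric, a_in=a_tot)


def _require_forward_order(array: ScattererArray):
    if not array.is_forward_sorted:
        raise ValueError(
            "forward solvers require spheres sorted ascending along the beam axis "
            "(ties broken by transverse coordinates); refusing to sort silently"
        )


def solve_forward(array: ScattererArray, system: AssembledSystem | None = None) -> CoefficientSet:
    """Forward-scattering approximation: slice-by-slice forward substitution.

    Couplings from downstream slices (backscattering) and within the same
    slice (90-degree scattering) are dropped, leaving a strictly
    slice-lower-triangular coupling that is solved explicitly.
    """
    _require_forward_order(array)
    sys_ = system if system is not None else assemble_system(array)
    N, B = array.n_spheres, array.block
    b = np.zeros((N, B), dtype=complex)
    a_tot = sys_.a_inc.copy()
    for p in range(N):
        for q in range(N):
            if array.slice_of[q] < array.slice_of[p]:
                a_tot[p] += sys_.translations[(p, q)].apply(b[q])
        b[p] = array.t_flat(p) * a_tot[p]
    return CoefficientSet(b=b, c=_interior_from_incoming(array, a_tot), mode="forward",
                          l_max=array.l_max, axisymmetric=array.axisymmetric, a_in=a_tot)


def solve_kinematic(array: ScattererArray, system: AssembledSystem | None = None) -> CoefficientSet:
    """Kinematic (first Born) approximation: each sphere sees only the plane wave."""
    sys_ = system if system is not None else assemble_system(array)
    return CoefficientSet(b=sys_.L.copy(), c=_interior_from_incoming(array, sys_.a_inc),
                          mode="kinematic", l_max=array.l_max,
                          axisymmetric=array.axisymmetric, a_in=sys_.a_inc.copy())


def solve_successive(
    array: ScattererArray, n_orders: int, system: AssembledSystem | None = None
) -> SuccessiveResult:
    """Successive n-times-scattering expansion of the forward system.

    term_1 = L (kinematic); term_n = T_fwd term_{n-1} (n-times scattering);
    the cumulative sum over K slices equals the forward solution exactly at
    n = K because the strictly slice-lower-triangular T_fwd is nilpotent.
    """
    if n_orders < 1:
        raise ValueError("n_orders must be >= 1")
    _require_forward_order(array)
    sys_ = system if system is not None else assemble_system(array)
    N, B = array.n_spheres, array.block
    terms: list[CoefficientSet] = []
    cumulative: list[CoefficientSet] = []
    term_b = sys_.L.copy()
    term_in = sys_.a_inc.copy()
    cum_b = np.zeros((N, B), dtype=complex)
    cum_in = np.zeros((N, B), dtype=complex)
    for n in range(1, n_orders + 1):
        if n > 1:
            new_in = np.zeros((N, B), dtype=complex)
            for p in range(N):
                for q in range(N):
                    if array.slice_of[q] < array.slice_of[p]:
                        new_in[p] += sys_.translations[(p, q)].apply(term_b[q])
            term_in = new_in
            term_b = np.stack([array.t_flat(p) * term_in[p] for p in range(N)])
        cum_b = cum_b + term_b
        cum_in = cum_in + term_in
        terms.append(
            CoefficientSet(b=term_b.copy(), c=_interior_from_incoming(array, term_in),
                           mode=f"successive_term_{n}", l_max=array.l_max,
                           axisymmetric=array.axisymmetric, a_in=term_in.copy())
        )
        cumulative.append(
            CoefficientSet(b=cum_b.copy(), c=_interior_from_incoming(array, cum_in),
                           mode=f"successive_{n}", l_max=array.l_max,
                           axisymmetric=array.axisymmetric, a_in=cum_in.copy())
        )
    return SuccessiveResult(terms=terms, cumulative=cumulative)


def coefficient_error(approx: CoefficientSet, exact: CoefficientSet) -> float:
    """Relative l2 discrepancy of exterior coefficients, ||b_a - b_e|| / ||b_e||."""
    if approx.b.shape != exact.b.shape:
        raise ValueError("coefficient sets have mismatched shapes")
    norm = np.linalg.norm(exact.b)
    diff = np.linalg.norm(approx.b - exact.b)
    if norm == 0.0:
        return 0.0 if diff == 0.0 else np.inf
    return float(diff / norm)
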