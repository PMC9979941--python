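"""Fields, far-field patterns, cross sections and scattering probabilities.

The far-field amplitude of the assembly carries each sphere's asymptotic
pattern to the common origin with its exit-phase factor,

    f(rhat) = sum_p exp(-i k rhat . d_p) (1/k) sum_lm (-i)^{l+1} b_{plm} Y_l^m(rhat),

so that dsigma/dOmega = |f|^2 and sigma follows by angular quadrature
(Gauss--Legendre in cos(theta), trapezoid in phi).  For exact elastic
solutions the optical theorem sigma = (4 pi / k) Im f(khat0) holds to
quadrature accuracy; Born-level approximations violate it.

Scattering probabilities divide per-order cross sections by the illuminated
area S.  The split of the total cross section into per-order contributions is
ambiguous because of interference cross terms; the default telescopes
cumulative-intensity differences (sigma_n may then be negative for individual
n, reported as-is), with a pure |f^(n)|^2 variant behind an option.  The
incoherent (ballistic) baseline is the Poisson distribution in z / Lambda
with Lambda the elastic mean free path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.special import sph_harm_y, spherical_jn, spherical_yn

from .solver import CoefficientSet, ScattererArray
from .special import multipole_indices, spherical_hankel1

__all__ = [
    "FarFieldPattern",
    "ScatteringBudget",
    "ContinuityError",
    "angular_grid",
    "far_field_amplitude",
    "cross_sections",
    "optical_theorem_residual",
    "evaluate_field",
    "boundary_continuity_error",
    "scattering_probabilities",
    "poisson_probabilities",
    "mean_free_path",
]


@dataclass
class FarFieldPattern:
    """Sampled complex far-field amplitude with its quadrature rule.

    ``f`` is in Å on the nodes; ``weights`` integrate over solid angle, so
    sigma = sum(weights * |f|^2).  ``f_forward`` is the amplitude evaluated
    exactly in the incidence direction (for the optical theorem).  Axisymmetric
    patterns have ``phi is None`` and weights that already include the 2 pi.
    """

    theta: np.ndarray
    f: np.ndarray
    weights: np.ndarray
    k: float
    phi: np.ndarray | None = None
    f_forward: complex = 0.0

    def __post_init__(self):
        if np.any(self.weights < 0):
            raise ValueError("quadrature weights must be positive")


class ContinuityError(NamedTuple):
    """Surface-normalized L2 mismatch of value and radial derivative at r = a."""

    value: float
    derivative: float


def angular_grid(l_max: int, axisymmetric: bool = True, extra_bandwidth: int = 0):
    """Quadrature nodes resolving the pattern's angular bandwidth.

    A single sphere's pattern has spherical-harmonic bandwidth 2 l_max; an
    assembly's pattern additionally oscillates through the inter-sphere phase
    factors exp(-i k rhat . d_p), which adds up to k * (array extent) to the
    bandwidth — pass that as ``extra_bandwidth``.  Gauss--Legendre in
    cos(theta) with 2 l_max + extra + 16 nodes; for the general case a
    uniform trapezoid in phi with 2 l_max + extra + 1 nodes.  Returns
    (theta, weights) or (theta, phi, weights) flattened over the product grid.
    """
    n_theta = 2 * l_max + extra_bandwidth + 16
    x, w = np.polynomial.legendre.leggauss(n_theta)
    theta = np.arccos(x)
    if axisymmetric:
        return theta, 2.0 * np.pi * w
    n_phi = 2 * l_max + extra_bandwidth + 1
    phi = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    TH, PH = np.meshgrid(theta, phi, indexing="ij")
    W = np.repeat(w, n_phi) * (2.0 * np.pi / n_phi)
    return TH.ravel(), PH.ravel(), W


def _array_phase_bandwidth(array: ScattererArray) -> int:
    """k times the largest inter-sphere distance, rounded up."""
    centres = np.array([s.centre for s in array.scatterers])
    if len(centres) < 2:
        return 0
    span = np.linalg.norm(centres[:, None, :] - centres[None, :, :], axis=-1).max()
    return int(np.ceil(array.beam.k * span))


def _pattern_on_directions(array, coeffs, theta, phi):
    """f on arbitrary directions (theta, phi arrays of equal shape)."""
    k = array.beam.k
    idx = multipole_indices(coeffs.l_max, coeffs.axisymmetric)
    sin_t = np.sin(theta)
    rhat = np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), np.cos(theta)], axis=-1)
    ylm = np.stack([sph_harm_y(l, m, theta, phi) for (l, m) in idx])  # (B, nodes)
    pref = np.array([(-1j) ** (l + 1) for (l, m) in idx])
    f = np.zeros(theta.shape, dtype=complex)
    for p, s in enumerate(array.scatterers):
        phase = np.exp(-1j * k * rhat @ s.centre)
        f += phase * ((pref * coeffs.b[p]) @ ylm)
    return f / k


def far_field_amplitude(
    array: ScattererArray, coeffs: CoefficientSet, theta=None, phi=None
) -> FarFieldPattern:
    """Far-field pattern of the assembly for a given coefficient set.

    With no grid given, uses :func:`angular_grid` at the operating l_max
    (weights then integrate |f|^2 to sigma).  A custom ``theta`` (and ``phi``)
    grid may be supplied for plotting; its weights are set to zero.
    """
    k = array.beam.k
    if theta is None:
        extra = _array_phase_bandwidth(array)
        if coeffs.axisymmetric:
            theta, weights = angular_grid(coeffs.l_max, axisymmetric=True, extra_bandwidth=extra)
            phi = None
        else:
            theta, phi, weights = angular_grid(coeffs.l_max, axisymmetric=False, extra_bandwidth=extra)
    else:
        theta = np.asarray(theta, dtype=float)
        weights = np.zeros_like(theta)
    phi_eval = np.zeros_like(theta) if phi is None else np.asarray(phi, dtype=float)
    f = _pattern_on_directions(array, coeffs, theta, phi_eval)

    khat = np.asarray(array.beam.khat0)
    th0 = np.arccos(np.clip(khat[2], -1.0, 1.0))
    ph0 = np.arctan2(khat[1], khat[0])
    f0 = _pattern_on_directions(array, coeffs, np.array([th0]), np.array([ph0]))[0]
    return FarFieldPattern(theta=theta, f=f, weights=weights, k=k, phi=phi,
                           f_forward=complex(f0))


def cross_sections(pattern: FarFieldPattern):
    """Differential cross section |f|^2 on the nodes and the total by quadrature."""
    dsig = np.abs(pattern.f) ** 2
    sigma = float(np.sum(pattern.weights * dsig))
    return dsig, sigma


def optical_theorem_residual(pattern: FarFieldPattern, beam) -> float:
    """|sigma_quadrature - (4 pi / k) Im f(khat0)| / sigma_quadrature.

    Zero-potential patterns (sigma = 0) return 0 by convention.  Exact
    elastic solutions satisfy this to quadrature accuracy; kinematic (Born)
    solutions violate it, which makes the residual a useful solution-quality
    diagnostic.
    """
    _, sigma = cross_sections(pattern)
    if sigma == 0.0:
        return 0.0
    lhs = 4.0 * np.pi / beam.k * np.imag(pattern.f_forward)
    return float(abs(sigma - lhs) / sigma)


# ---------------------------------------------------------------------------
# real-space fields


def _outgoing_fields(
    array: ScattererArray, coeffs: CoefficientSet, points: np.ndarray, skip: int | None = None
) -> np.ndarray:
    """Sum of the spheres' outgoing expansions, optionally excluding one sphere."""
    points = np.atleast_2d(points)
    k = array.beam.k
    idx = multipole_indices(coeffs.l_max, coeffs.axisymmetric)
    val = np.zeros(len(points), dtype=complex)
    for p, s in enumerate(array.scatterers):
        if p == skip:
            continue
        rv = points - s.centre
        r = np.linalg.norm(rv, axis=1)
        if np.any(r == 0.0):
            raise ValueError("field evaluation exactly on a sphere centre")
        theta = np.arccos(np.clip(rv[:, 2] / r, -1, 1))
        phi = np.arctan2(rv[:, 1], rv[:, 0])
        x = k * r
        for i, (l, m) in enumerate(idx):
            if coeffs.b[p, i] == 0.0:
                continue
            val += coeffs.b[p, i] * spherical_hankel1(l, x) * sph_harm_y(l, m, theta, phi)
    return val


def _exterior_field(array: ScattererArray, coeffs: CoefficientSet, points: np.ndarray) -> np.ndarray:
    """Incident plane wave plus every sphere's outgoing expansion, evaluated directly."""
    points = np.atleast_2d(points)
    k = array.beam.k
    khat = np.asarray(array.beam.khat0)
    return np.exp(1j * k * points @ khat) + _outgoing_fields(array, coeffs, points)


def _interior_field_at(scatterer, a_in_flat, idx, r_vec):
    """Total field inside a sphere from its incoming regular coefficients."""
    r = np.linalg.norm(r_vec)
    if r == 0.0:
        raise ValueError("field evaluation exactly on a sphere centre")
    tm = scatterer.tmat
    for (r0, r1, ks, A_l, B_l) in tm.regions:
        if r0 <= r <= r1 * (1.0 + 1e-12):
            break
    else:
        raise ValueError("point not inside any radial region")
    theta = np.arccos(np.clip(r_vec[2] / r, -1, 1))
    phi = np.arctan2(r_vec[1], r_vec[0])
    x = ks * r
    val = 0.0 + 0.0j
    for i, (l, m) in enumerate(idx):
        rad = A_l[l] * spherical_jn(l, x)
        if B_l[l] != 0.0:
            rad += B_l[l] * spherical_yn(l, x)
        val += a_in_flat[i] * rad * sph_harm_y(l, m, theta, phi)
    return val


def evaluate_field(array: ScattererArray, coeffs: CoefficientSet, points) -> np.ndarray:
    """Total wavefunction at arbitrary points (not exactly on a sphere centre).

    Exterior points: incident plane wave plus every sphere's outgoing
    expansion.  Points inside sphere p: that sphere's interior expansion.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    k = array.beam.k
    khat = np.asarray(array.beam.khat0)
    idx = multipole_indices(coeffs.l_max, coeffs.axisymmetric)
    out = np.empty(len(points), dtype=complex)
    for j, pt in enumerate(points):
        inside = None
        for p, s in enumerate(array.scatterers):
            if np.linalg.norm(pt - s.centre) < s.radius:
                inside = p
                break
        if inside is not None:
            if coeffs.a_in is None:
                raise ValueError("coefficient set lacks incoming coefficients (a_in)")
            out[j] = _interior_field_at(
                array.scatterers[inside], coeffs.a_in[inside], idx, pt - array.scatterers[inside].centre
            )
            continue
        out[j] = _exterior_field(array, coeffs, pt[None, :])[0]
    return out


def boundary_continuity_error(
    array: ScattererArray, coeffs: CoefficientSet, p: int
) -> ContinuityError:
    """Surface-integrated interior/exterior mismatch at the boundary of sphere p.

    The exterior side couples three ingredients: the incident wave expanded
    about the sphere's centre (truncated at the operating l_max, like the
    solution itself), the sphere's own outgoing expansion, and the *directly
    evaluated* outgoing fields of all other spheres.  The interior expansion
    saw those other fields only through the truncated translational
    re-expansion, so the mismatch exposes exactly that truncation and falls
    to machine accuracy as l_max grows on a converged solution.  Value and
    radial-derivative mismatches are reported separately (the other-sphere
    derivative via a 5-point finite-difference stencil of step 1e-3/k), each
    normalized by the exterior surface L2 norm.
    """
    if coeffs.a_in is None:
        raise ValueError("coefficient set lacks incoming coefficients (a_in)")
    from .special import plane_wave_coefficients

    s = array.scatterers[p]
    tm = s.tmat
    k = array.beam.k
    a = s.radius
    idx = multipole_indices(coeffs.l_max, coeffs.axisymmetric)
    ls = np.array([l for l, _ in idx])

    # surface quadrature nodes about sphere p
    if coeffs.axisymmetric:
        theta, w = angular_grid(coeffs.l_max, axisymmetric=True)
        phi = np.zeros_like(theta)
    else:
        theta, phi, w = angular_grid(coeffs.l_max, axisymmetric=False)
    rhat = np.stack([np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)], axis=1)
    ylm = np.stack([sph_harm_y(l, m, theta, phi) for (l, m) in idx])  # (B, nodes)

    # incident wave about p (truncated) and own outgoing term: analytic radial parts
    a_inc = plane_wave_coefficients(array.beam, s.centre, coeffs.l_max, coeffs.axisymmetric)
    x = k * a
    own_val = a_inc * spherical_jn(ls, x) + coeffs.b[p] * spherical_hankel1(ls, x)
    own_der = k * (
        a_inc * spherical_jn(ls, x, derivative=True)
        + coeffs.b[p] * spherical_hankel1(ls, x, derivative=True)
    )

    # other spheres: direct evaluation, radial derivative by central differences
    h_fd = 1e-3 / k
    others = {}
    for step in (-2, -1, 0, 1, 2):
        pts = s.centre + (a + step * h_fd) * rhat
        others[step] = _outgoing_fields(array, coeffs, pts, skip=p)
    ext_val = own_val @ ylm + others[0]
    ext_der = own_der @ ylm + (
        8.0 * (others[1] - others[-1]) - (others[2] - others[-2])
    ) / (12.0 * h_fd)

    # interior side: outermost radial region, analytic derivative
    r0, r1, ks, A_l, B_l = tm.regions[-1]
    xs = ks * a
    rad_val = A_l[ls] * spherical_jn(ls, xs) + B_l[ls] * spherical_yn(ls, xs)
    rad_der = ks * (
        A_l[ls] * spherical_jn(ls, xs, derivative=True)
        + B_l[ls] * spherical_yn(ls, xs, derivative=True)
    )
    int_val = (coeffs.a_in[p] * rad_val) @ ylm
    int_der = (coeffs.a_in[p] * rad_der) @ ylm

    nv = np.sqrt(np.sum(w * np.abs(ext_val) ** 2))
    nd = np.sqrt(np.sum(w * np.abs(ext_der) ** 2))
    ev = float(np.sqrt(np.sum(w * np.abs(ext_val - int_val) ** 2)) / nv) if nv > 0 else 0.0
    ed = float(np.sqrt(np.sum(w * np.abs(ext_der - int_der) ** 2)) / nd) if nd > 0 else 0.0
    return ContinuityError(value=ev, derivative=ed)


# ---------------------------------------------------------------------------
# scattering probabilities


@dataclass
class ScatteringBudget:
    """Per-order cross sections and probabilities for one electron.

    sigma_by_order telescopes to sigma_total by construction; P_n =
    sigma_n / S.  poisson_P_n is the incoherent ballistic baseline over
    n = 0..n_max (index 0 = unscattered), present when thickness and mean
    free path are known.
    """

    sigma_total: float
    sigma_by_order: np.ndarray
    S: float
    P_total: float
    P_n: np.ndarray
    P_unscattered: float
    poisson_P_n: np.ndarray | None = None
    mean_free_path: float | None = None
    thickness: float | None = None

    def to_dict(self) -> dict:
        d = {
            "sigma_total_A2": self.sigma_total,
            "sigma_by_order_A2": list(map(float, self.sigma_by_order)),
            "illuminated_area_A2": self.S,
            "P_total": self.P_total,
            "P_n": list(map(float, self.P_n)),
            "P_unscattered": self.P_unscattered,
        }
        if self.poisson_P_n is not None:
            d["poisson_P_n"] = list(map(float, self.poisson_P_n))
        if self.mean_free_path is not None:
            d["mean_free_path_A"] = self.mean_free_path
        if self.thickness is not None:
            d["thickness_A"] = self.thickness
        return d


def scattering_probabilities(
    per_order_patterns: list[FarFieldPattern],
    S: float,
    cross_terms: str = "telescoping",
    thickness: float | None = None,
    lambda_e: float | None = None,
) -> ScatteringBudget:
    """Probability budget from per-order far-field amplitudes f^(n).

    ``cross_terms`` chooses the allocation of interference between orders:
    "telescoping" (default) sets sigma_n to the difference of cumulative
    intensities, which sums exactly to the cross section of the total
    retained amplitude but may be negative for individual n;
    "pure" integrates |f^(n)|^2 alone (cross terms discarded, so the sum may
    differ from the total).  The precondition S > sigma_total keeps P_total
    below 1; its violation raises rather than clamps.
    """
    if not per_order_patterns:
        raise ValueError("at least one per-order pattern is required")
    if cross_terms not in ("telescoping", "pure"):
        raise ValueError(f"unknown cross_terms mode {cross_terms!r}")
    w = per_order_patterns[0].weights
    cum = np.zeros_like(per_order_patterns[0].f)
    sig_cum_prev = 0.0
    sigma_by_order = []
    for pat in per_order_patterns:
        cum = cum + pat.f
        if cross_terms == "telescoping":
            sig_cum = float(np.sum(w * np.abs(cum) ** 2))
            sigma_by_order.append(sig_cum - sig_cum_prev)
            sig_cum_prev = sig_cum
        else:
            sigma_by_order.append(float(np.sum(w * np.abs(pat.f) ** 2)))
    sigma_total = float(np.sum(w * np.abs(cum) ** 2))
    if S <= sigma_total:
        raise ValueError(
            f"illuminated area S={S:.6g} Å² must exceed sigma_total={sigma_total:.6g} Å² "
            "(the probability of scattering is necessarily less than 1)"
        )
    sigma_by_order = np.asarray(sigma_by_order)
    P_n = sigma_by_order / S
    P_total = sigma_total / S
    poisson = None
    if thickness is not None and lambda_e is not None:
        poisson = poisson_probabilities(thickness, lambda_e, n_max=max(len(P_n), 20))
    return ScatteringBudget(
        sigma_total=sigma_total,
        sigma_by_order=sigma_by_order,
        S=S,
        P_total=P_total,
        P_n=P_n,
        P_unscattered=1.0 - P_total,
        poisson_P_n=poisson,
        mean_free_path=lambda_e,
        thickness=thickness,
    )


def poisson_probabilities(z: float, lambda_e: float, n_max: int) -> np.ndarray:
    """Ballistic (incoherent) baseline P_n = (z/L)^n exp(-z/L) / n!, n = 0..n_max."""
    if z < 0 or lambda_e <= 0:
        raise ValueError("thickness must be >= 0 and mean free path > 0")
    mu = z / lambda_e
    n = np.arange(n_max + 1)
    from scipy.stats import poisson as _poisson

    return _poisson.pmf(n, mu)


def mean_free_path(sigma_avg: float, S: float, dz: float) -> float:
    """Elastic mean free path Lambda = 1 / (rho sigma) with rho = 1 / (S dz)."""
    if sigma_avg <= 0:
        raise ValueError("average cross section must be positive")
    return S * dz / sigma_avg
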