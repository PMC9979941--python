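"""Exact scattering by a single soft (or multi-shell) sphere.

The quantum analogue of scalar Mie theory: a constant-potential well of
normalized radius ka and refractive index n = k_in/k scatters each partial
wave independently.  Matching the value and radial derivative of
``j_l(kr) + t_l h_l^(1)(kr)`` (outside) to ``c_l j_l(n k r)`` (inside) at
r = a gives the per-l response t_l; elastic (real n) scattering obeys the
unitarity |1 + 2 t_l| = 1 of the partial-wave S-matrix S_l = 1 + 2 t_l.

Multi-shell spheres propagate the regular radial solution outward across the
shell interfaces before matching to the exterior, which generalizes the
single well without changing the exterior algebra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import spherical_jn, spherical_yn

from .potentials import BeamParameters, ShellModel
from .special import spherical_hankel1

__all__ = ["SphereTMatrix", "soft_sphere_tmatrix", "multishell_tmatrix", "single_sphere_far_field"]


@dataclass
class SphereTMatrix:
    """Per-l exterior response t_l and interior radial solution of one sphere.

    ``regions`` holds (r_inner, r_outer, k_s, A_l, B_l) tuples describing the
    interior field A_l j_l(k_s r) + B_l y_l(k_s r) in each radial region for a
    unit regular exterior coefficient; the innermost region has B_l = 0.  For
    a uniform sphere there is a single region and c_l = A_l.
    """

    t: np.ndarray
    c: np.ndarray
    ka: float
    n_ref: float
    l_max: int
    k: float = 1.0
    regions: list = field(default_factory=list)

    @property
    def radius(self) -> float:
        return self.ka / self.k


def soft_sphere_tmatrix(ka: float, n_ref: float, l_max: int, k: float = 1.0) -> SphereTMatrix:
    """Uniform constant-potential sphere: per-l 2x2 continuity solve.

    ``ka`` is the normalized radius, ``n_ref`` = k_inside/k >= 1 the
    refractive index, ``k`` the vacuum wavenumber (used only to carry
    physical units into far fields; the T-matrix itself is dimensionless).
    """
    if ka <= 0:
        raise ValueError("normalized radius ka must be positive")
    if n_ref < 1.0:
        raise ValueError("refractive index must be >= 1")
    ls = np.arange(l_max + 1)
    x = float(ka)
    nx = n_ref * x
    jx = spherical_jn(ls, x)
    djx = spherical_jn(ls, x, derivative=True)
    jn = spherical_jn(ls, nx)
    djn = spherical_jn(ls, nx, derivative=True)
    hx = spherical_hankel1(ls, x)
    dhx = spherical_hankel1(ls, x, derivative=True)

    den = jn * dhx - n_ref * djn * hx
    bad = ~np.isfinite(den) | (np.abs(den) < 1e3 * np.finfo(float).tiny)
    if np.any(bad):
        raise ArithmeticError(
            f"singular continuity system for l={ls[bad].tolist()} at ka={ka}, n={n_ref}"
        )
    t = (n_ref * djn * jx - jn * djx) / den
    c = (jx + t * hx) / jn
    tm = SphereTMatrix(t=t.astype(complex), c=c.astype(complex), ka=x, n_ref=float(n_ref),
                       l_max=l_max, k=k)
    tm.regions = [(0.0, x / k, n_ref * k, tm.c.copy(), np.zeros(l_max + 1, dtype=complex))]
    return tm


def multishell_tmatrix(shells: ShellModel, beam: BeamParameters, l_max: int) -> SphereTMatrix:
    """T-matrix of a concentric multi-shell sphere.

    The regular solution is propagated outward across shell interfaces by
    matching value and radial derivative (tracked as a normalized
    (value, derivative) pair, which avoids the overflow of raw amplitude
    pairs when many shells are present), then matched to the exterior
    ``j_l + t_l h_l^(1)`` form.  Interior amplitudes for every region are
    rescaled afterwards so that they correspond to a unit exterior regular
    coefficient.
    """
    k = beam.k
    radii = np.asarray(shells.radii)
    ns = np.asarray(shells.refr_indices)
    S = len(radii)
    a = radii[-1]
    x = k * a

    t = np.empty(l_max + 1, dtype=complex)
    c = np.empty(l_max + 1, dtype=complex)
    regions_AB = [[None, None] for _ in range(S)]
    region_bounds = [(0.0 if s == 0 else radii[s - 1], radii[s], ns[s] * k) for s in range(S)]
    A_store = np.zeros((S, l_max + 1), dtype=complex)
    B_store = np.zeros((S, l_max + 1), dtype=complex)

    for l in range(l_max + 1):
        k1 = ns[0] * k
        # state: (value, d/dr) of the interior solution at the current interface
        amps = [(1.0 + 0.0j, 0.0 + 0.0j)]  # (A, B) per region, innermost B = 0
        scale = [1.0 + 0.0j]  # accumulated normalization per region
        u = spherical_jn(l, k1 * radii[0]) + 0.0j
        v = k1 * spherical_jn(l, k1 * radii[0], derivative=True) + 0.0j
        norm = max(abs(u), abs(v), 1e-300)
        u, v = u / norm, v / norm
        running = norm  # u,v are the true state divided by `running`
        for s in range(1, S):
            ks = ns[s] * k
            r0, r1 = radii[s - 1], radii[s]
            x0 = ks * r0
            j0, y0 = spherical_jn(l, x0), spherical_yn(l, x0)
            dj0, dy0 = spherical_jn(l, x0, derivative=True), spherical_yn(l, x0, derivative=True)
            det = ks * (j0 * dy0 - y0 * dj0)  # = ks / x0^2
            A = (u * ks * dy0 - v * y0) / det
            B = (v * j0 - u * ks * dj0) / det
            if not (np.isfinite(A) and np.isfinite(B)):
                raise ArithmeticError(
                    f"non-finite interface propagation at shell {s}, l={l}"
                )
            amps.append((A, B))
            scale.append(running)
            x1 = ks * r1
            u = A * spherical_jn(l, x1) + B * spherical_yn(l, x1)
            v = ks * (A * spherical_jn(l, x1, derivative=True) + B * spherical_yn(l, x1, derivative=True))
            norm = max(abs(u), abs(v), 1e-300)
            u, v = u / norm, v / norm
            running *= norm

        jx = spherical_jn(l, x)
        djx = k * spherical_jn(l, x, derivative=True)
        hx = spherical_hankel1(l, x)
        dhx = k * spherical_hankel1(l, x, derivative=True)
        # match log-derivative: (djx + t dhx) / (jx + t hx) = v / u
        den = u * dhx - v * hx
        if abs(den) < 1e3 * np.finfo(float).tiny or not np.isfinite(den):
            raise ArithmeticError(f"singular exterior match at l={l}")
        t[l] = -(u * djx - v * jx) / den
        # rescale interior amplitudes so exterior coefficient is 1:
        # true boundary value of interior solution = u * running; must equal jx + t hx
        boundary = jx + t[l] * hx
        factor = boundary / (u * running)
        for s, (A, B) in enumerate(amps):
            A_store[s, l] = A * scale[s] * factor
            B_store[s, l] = B * scale[s] * factor
        c[l] = A_store[0, l]

    tm = SphereTMatrix(t=t, c=c, ka=float(x), n_ref=float(ns[-1]), l_max=l_max, k=k)
    tm.regions = [
        (region_bounds[s][0], region_bounds[s][1], region_bounds[s][2], A_store[s], B_store[s])
        for s in range(S)
    ]
    return tm


def single_sphere_far_field(tmat: SphereTMatrix, theta, k: float | None = None) -> np.ndarray:
    """Far-field amplitude f(theta) (Å) of one sphere under axial plane-wave incidence.

    f(theta) = (1/k) sum_l (2l + 1) (-i t_l) P_l(cos theta); the optical
    theorem sigma = (4 pi / k) Im f(0) holds exactly for real potentials.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0) or np.any(theta > np.pi):
        raise ValueError("angles must lie in [0, pi]")
    if k is None:
        k = tmat.k
    ls = np.arange(tmat.l_max + 1)
    # sum over Legendre polynomials via numpy's Legendre series
    coeffs = (2 * ls + 1) * (-1j) * tmat.t
    re = np.polynomial.legendre.legval(np.cos(theta), coeffs.real)
    im = np.polynomial.legendre.legval(np.cos(theta), coeffs.imag)
    return (re + 1j * im) / k
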