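"""Scalar spherical-wave building blocks.

Spherical Bessel/Hankel radial functions, orthonormal (Condon--Shortley)
spherical harmonics, Gaunt coefficients, the multipole expansion of an
incident plane wave and the translational addition theorem for scalar
spherical waves.  All higher-level solver code is written on top of the
functions in this module.

Conventions
-----------
Time dependence exp(-i omega t) with an exp(+ikz) incident wave (optics
convention); harmonics are orthonormal with the Condon--Shortley phase, so
``Y_l^{-m} = (-1)^m conj(Y_l^m)``.  Outgoing waves use the spherical Hankel
function of the first kind ``h_l^(1) = j_l + i y_l``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammaln, sph_harm_y, spherical_jn, spherical_yn

__all__ = [
    "multipole_indices",
    "block_size",
    "radial_function",
    "spherical_hankel1",
    "sph_harm",
    "sph_harm_unit",
    "wigner_3j",
    "gaunt_coefficient",
    "plane_wave_coefficients",
    "TranslationOperator",
    "translation_matrix",
]


# ---------------------------------------------------------------------------
# multipole bookkeeping


def multipole_indices(l_max: int, axisymmetric: bool = False) -> list[tuple[int, int]]:
    """Flattened (l, m) ordering used for all coefficient vectors.

    l ascends 0..l_max; within each l, m ascends -l..l.  In the axisymmetric
    (m = 0) reduction only the m = 0 entries are kept, giving l_max + 1
    entries instead of (l_max + 1)**2.
    """
    if l_max < 0:
        raise ValueError("l_max must be >= 0")
    if axisymmetric:
        return [(l, 0) for l in range(l_max + 1)]
    return [(l, m) for l in range(l_max + 1) for m in range(-l, l + 1)]


def block_size(l_max: int, axisymmetric: bool = False) -> int:
    return l_max + 1 if axisymmetric else (l_max + 1) ** 2


# ---------------------------------------------------------------------------
# radial functions


def spherical_hankel1(l, x, derivative: bool = False):
    """Spherical Hankel function of the first kind h_l^(1) (or its derivative)."""
    return spherical_jn(l, x, derivative=derivative) + 1j * spherical_yn(
        l, x, derivative=derivative
    )


def radial_function(kind: str, l: int, x, derivative: bool = False):
    """Evaluate j_l, y_l or h_l^(1) at x > 0.

    ``kind`` is one of ``besselJ``, ``besselY``, ``hankel1``.  x must be
    strictly positive: y_l and h_l^(1) are singular at the origin, and the
    solver never needs j_l there either.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("radial_function requires x > 0 (singular at the origin)")
    if l < 0:
        raise ValueError("order l must be >= 0")
    if kind == "besselJ":
        return spherical_jn(l, x, derivative=derivative)
    if kind == "besselY":
        return spherical_yn(l, x, derivative=derivative)
    if kind == "hankel1":
        return spherical_hankel1(l, x, derivative=derivative)
    raise ValueError(f"unknown radial function kind {kind!r}")


# ---------------------------------------------------------------------------
# spherical harmonics


def sph_harm(l: int, m: int, theta, phi):
    """Orthonormal Y_l^m(theta, phi), Condon--Shortley phase."""
    return sph_harm_y(l, m, theta, phi)


def sph_harm_unit(l: int, m: int, nhat) -> complex:
    """Y_l^m evaluated at a unit 3-vector."""
    nhat = np.asarray(nhat, dtype=float)
    r = np.linalg.norm(nhat)
    theta = np.arccos(np.clip(nhat[2] / r, -1.0, 1.0))
    phi = np.arctan2(nhat[1], nhat[0])
    return complex(sph_harm_y(l, m, theta, phi))


# ---------------------------------------------------------------------------
# Wigner 3j / Gaunt

_lnfac = lambda n: gammaln(n + 1.0)  # noqa: E731


@lru_cache(maxsize=None)
def wigner_3j(j1: int, j2: int, j3: int, m1: int, m2: int, m3: int) -> float:
    """Wigner 3j symbol via the Racah single-sum formula (log-factorials).

    Accurate to ~1e-11 relative for the orders used here (j <= ~80); exact
    zeros from the selection rules are returned as exact 0.0.
    """
    if m1 + m2 + m3 != 0:
        return 0.0
    if not (abs(j1 - j2) <= j3 <= j1 + j2):
        return 0.0
    if abs(m1) > j1 or abs(m2) > j2 or abs(m3) > j3:
        return 0.0
    t1 = j2 - m1 - j3
    t2 = j1 + m2 - j3
    t3 = j1 + j2 - j3
    t4 = j1 - m1
    t5 = j2 + m2
    tmin, tmax = max(0, t1, t2), min(t3, t4, t5)
    s = 0.0
    for t in range(tmin, tmax + 1):
        ln = _lnfac(t) + _lnfac(t - t1) + _lnfac(t - t2)
        ln += _lnfac(t3 - t) + _lnfac(t4 - t) + _lnfac(t5 - t)
        s += (-1.0) ** t * np.exp(-ln)
    ln_delta = 0.5 * (
        _lnfac(j1 + j2 - j3)
        + _lnfac(j1 - j2 + j3)
        + _lnfac(-j1 + j2 + j3)
        - _lnfac(j1 + j2 + j3 + 1)
    )
    ln_pref = 0.5 * (
        _lnfac(j1 + m1)
        + _lnfac(j1 - m1)
        + _lnfac(j2 + m2)
        + _lnfac(j2 - m2)
        + _lnfac(j3 + m3)
        + _lnfac(j3 - m3)
    )
    return float(s * np.exp(ln_delta + ln_pref) * (-1.0) ** (j1 - j2 - m3))


@lru_cache(maxsize=None)
def gaunt_coefficient(l1: int, m1: int, l2: int, m2: int, l3: int) -> float:
    """Gaunt integral ∫ Y_{l1}^{m1} Y_{l2}^{m2} (Y_{l3}^{m1+m2})* dΩ.

    Zero whenever the triangle inequality or the parity rule
    (l1 + l2 + l3 even) fails.
    """
    if abs(m1) > l1 or abs(m2) > l2:
        raise ValueError("|m| must not exceed l")
    m3 = m1 + m2
    if abs(m3) > l3:
        return 0.0
    if (l1 + l2 + l3) % 2 or not (abs(l1 - l2) <= l3 <= l1 + l2):
        return 0.0
    pref = np.sqrt((2 * l1 + 1) * (2 * l2 + 1) * (2 * l3 + 1) / (4.0 * np.pi))
    return float(
        (-1.0) ** m3
        * pref
        * wigner_3j(l1, l2, l3, 0, 0, 0)
        * wigner_3j(l1, l2, l3, m1, m2, -m3)
    )


# ---------------------------------------------------------------------------
# plane wave expansion


def plane_wave_coefficients(beam, centre, l_max: int, axisymmetric: bool = False):
    """Regular multipole coefficients of exp(i k0 . r) about ``centre``.

    a_{lm} = 4 pi i^l conj(Y_l^m(khat0)) exp(i k0 . centre).  For incidence
    along +z only the m = 0 terms survive.
    """
    khat = np.asarray(beam.khat0, dtype=float)
    if abs(np.linalg.norm(khat) - 1.0) > 1e-10:
        raise ValueError("beam direction must be a unit vector")
    centre = np.asarray(centre, dtype=float)
    phase = np.exp(1j * beam.k * khat @ centre)
    idx = multipole_indices(l_max, axisymmetric=axisymmetric)
    out = np.empty(len(idx), dtype=complex)
    for i, (l, m) in enumerate(idx):
        out[i] = 4.0 * np.pi * (1j) ** l * np.conj(sph_harm_unit(l, m, khat)) * phase
    return out


# ---------------------------------------------------------------------------
# translational addition theorem


@dataclass
class TranslationOperator:
    """Dense re-expansion map between multipole bases at two centres.

    ``matrix[i, j]`` re-expands the source multipole ``j`` (about the source
    centre) as the regular multipole ``i`` about the target centre, where
    indices follow :func:`multipole_indices`.  ``kind`` is
    ``"outgoing_to_regular"`` (valid for |k r_target| < |kd_vec|) or
    ``"regular_to_regular"`` (valid everywhere).
    """

    kd_vec: np.ndarray
    matrix: np.ndarray
    kind: str
    l_max: int
    axisymmetric: bool = False
    source: int | None = None
    target: int | None = None

    def apply(self, coeffs: np.ndarray) -> np.ndarray:
        return self.matrix @ coeffs


def _translation_entry(lp, mp, l, m, l_max_sum, z_l, y_mu) -> complex:
    mu = mp - m
    lo = max(abs(l - lp), abs(mu))
    if (lo + l + lp) % 2:
        lo += 1  # the Gaunt parity rule: L + l + l' must be even
    s = 0.0 + 0.0j
    for L in range(lo, l + lp + 1, 2):
        g = gaunt_coefficient(L, mu, l, m, lp)
        if g == 0.0:
            continue
        s += 4.0 * np.pi * (1j) ** (L + lp - l) * z_l[L] * y_mu[(L, mu)] * g
    return s


def translation_matrix(
    l_max: int,
    kd_vec,
    kind: str = "outgoing_to_regular",
    axisymmetric: bool = False,
) -> TranslationOperator:
    """Translational addition theorem as a dense matrix.

    Re-expands each source multipole about a centre displaced by
    ``kd_vec / k`` (the displacement is passed in dimensionless form,
    k * (d_target - d_source)).  Outgoing -> regular uses h_L^(1) radial
    factors and is valid inside the sphere around the target that excludes
    the source; regular -> regular uses j_L and is valid everywhere.

    The axisymmetric variant requires the displacement to lie on the z axis
    and acts on the m = 0 subspace only.
    """
    if kind not in ("outgoing_to_regular", "regular_to_regular"):
        raise ValueError(f"unknown translation kind {kind!r}")
    kd_vec = np.asarray(kd_vec, dtype=float)
    kd = float(np.linalg.norm(kd_vec))
    idx = multipole_indices(l_max, axisymmetric=axisymmetric)
    n = len(idx)

    if kd == 0.0:
        if kind == "outgoing_to_regular":
            raise ValueError("outgoing->regular translation is singular at zero displacement")
        return TranslationOperator(kd_vec, np.eye(n, dtype=complex), kind, l_max, axisymmetric)

    dhat = kd_vec / kd
    if axisymmetric and (abs(dhat[0]) > 1e-12 or abs(dhat[1]) > 1e-12):
        raise ValueError("axisymmetric translation requires a displacement along z")

    l_sum_max = 2 * l_max
    if kind == "outgoing_to_regular":
        z_l = np.array([spherical_hankel1(L, kd) for L in range(l_sum_max + 1)])
    else:
        z_l = np.array([spherical_jn(L, kd) for L in range(l_sum_max + 1)], dtype=complex)

    # conj(Y_L^mu(dhat)) table for every (L, mu) the entry loop can request
    y_mu: dict[tuple[int, int], complex] = {}
    mu_span = 0 if axisymmetric else 2 * l_max
    for L in range(l_sum_max + 1):
        for mu in range(-min(L, mu_span), min(L, mu_span) + 1):
            y_mu[(L, mu)] = np.conj(sph_harm_unit(L, mu, dhat))

    M = np.empty((n, n), dtype=complex)
    for i, (lp, mp) in enumerate(idx):
        for j, (l, m) in enumerate(idx):
            if abs(mp - m) > min(l + lp, mu_span):
                M[i, j] = 0.0
                continue
            M[i, j] = _translation_entry(lp, mp, l, m, l_sum_max, z_l, y_mu)
    return TranslationOperator(kd_vec, M, kind, l_max, axisymmetric)
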