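"""Beam parameters and muffin-tin reductions of atomic potentials.

The electron beam is characterised by its accelerating energy (keV); the
relativistic de Broglie wavelength fixes the vacuum wavenumber k = 2 pi / lambda.
Atomic electrostatic potentials use the independent-atom-model (IAM)
parameterization as a sum of three screened-Coulomb (Yukawa) and three
Gaussian terms; the muffin-tin reduction truncates the potential at a finite
radius and averages it over concentric shells of constant potential, each
described by a refractive index n_s = k_s / k = sqrt(1 + V_s / E).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.special import spherical_jn

__all__ = [
    "BeamParameters",
    "relativistic_beam",
    "iam_radial_potential",
    "ShellModel",
    "build_multishell",
    "born_form_factor_multishell",
]

# CODATA 2018
_H_PLANCK = 6.62607015e-34  # J s
_M0 = 9.1093837015e-31  # kg
_E_CHARGE = 1.602176634e-19  # C
_C_LIGHT = 299792458.0  # m / s

# Coulomb constant e/(4 pi eps0) in V Angstrom, Bohr radius in Angstrom
_E_COUL = 14.399645
_A0 = 0.529177210903


@dataclass(frozen=True)
class BeamParameters:
    """Incident electron beam: energy (keV), wavelength/wavenumber (Å, Å⁻¹), direction."""

    energy_kev: float
    wavelength: float
    k: float
    khat0: tuple[float, float, float] = (0.0, 0.0, 1.0)

    @property
    def energy_volts(self) -> float:
        return self.energy_kev * 1e3

    @property
    def is_axial(self) -> bool:
        return abs(self.khat0[0]) < 1e-12 and abs(self.khat0[1]) < 1e-12


def relativistic_beam(energy_kev: float, direction=(0.0, 0.0, 1.0)) -> BeamParameters:
    """Beam parameters with the relativistically corrected wavelength.

    lambda = h / sqrt(2 m0 e V (1 + e V / (2 m0 c^2))), V the accelerating
    voltage.  At 200 keV this gives 0.02508 Å.  The relativistic correction
    enters only through lambda (and hence k); the wave equation itself is
    solved in Schrödinger form with E as a parameter.
    """
    if energy_kev <= 0:
        raise ValueError("beam energy must be positive")
    volts = energy_kev * 1e3
    p2 = 2.0 * _M0 * _E_CHARGE * volts * (1.0 + _E_CHARGE * volts / (2.0 * _M0 * _C_LIGHT**2))
    lam_m = _H_PLANCK / np.sqrt(p2)
    lam = lam_m * 1e10
    direction = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(direction)
    if nrm == 0:
        raise ValueError("beam direction must be nonzero")
    d = tuple(direction / nrm)
    return BeamParameters(energy_kev=energy_kev, wavelength=lam, k=2.0 * np.pi / lam, khat0=d)


# ---------------------------------------------------------------------------
# IAM potential

# 3 Lorentzian (a_i, b_i) + 3 Gaussian (c_i, d_i) scattering-factor fit
# coefficients, Kirkland-style parameterization (a, c in Å; b, d in Å^-2 /
# Å^2 respectively).  Only carbon is shipped.
_IAM_TABLE = {
    "C": {
        "a": (2.12080767e-1, 1.99811865e-1, 1.68254385e-1),
        "b": (2.08605417e-1, 2.08610186e-1, 5.57870773e0),
        "c": (1.42048360e-1, 3.55524269e-1, 8.38716956e-2),
        "d": (1.33311887e0, 3.80800263e0, 4.03884143e-1),
    },
}


def iam_radial_potential(element: str, r) -> np.ndarray:
    """IAM electrostatic potential V(r) in volts at radius r (Å).

    V(r) = 2 pi^2 a0 e sum_i a_i exp(-2 pi sqrt(b_i) r) / r
         + 2 pi^{5/2} a0 e sum_i c_i d_i^{-3/2} exp(-pi^2 r^2 / d_i)

    Positive and monotonically decreasing; screened so that it is negligible
    beyond a few Å.
    """
    try:
        p = _IAM_TABLE[element]
    except KeyError:
        raise KeyError(
            f"element {element!r} not in the shipped IAM table {sorted(_IAM_TABLE)}"
        ) from None
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("radius must be positive")
    v = np.zeros_like(r)
    for a, b in zip(p["a"], p["b"]):
        v = v + 2.0 * np.pi**2 * _A0 * _E_COUL * a * np.exp(-2.0 * np.pi * np.sqrt(b) * r) / r
    for c, d in zip(p["c"], p["d"]):
        v = v + 2.0 * np.pi**2.5 * _A0 * _E_COUL * c * d**-1.5 * np.exp(-np.pi**2 * r**2 / d)
    return v


# ---------------------------------------------------------------------------
# multi-shell (muffin-tin) model


@dataclass(frozen=True)
class ShellModel:
    """Concentric constant-potential shells for one atom.

    radii are strictly ascending outer shell boundaries (Å); refr_indices the
    per-shell n_s = k_s/k >= 1 (attractive wells); the region beyond radii[-1]
    is vacuum (n = 1).
    """

    radii: tuple[float, ...]
    refr_indices: tuple[float, ...]
    k: float
    element: str = ""
    potentials: tuple[float, ...] = field(default=())

    def __post_init__(self):
        radii = np.asarray(self.radii, dtype=float)
        n = np.asarray(self.refr_indices, dtype=float)
        if radii.ndim != 1 or len(radii) != len(n) or len(radii) == 0:
            raise ValueError("radii and refr_indices must be equal-length 1-D sequences")
        if np.any(radii <= 0) or np.any(np.diff(radii) <= 0):
            raise ValueError("shell radii must be positive and strictly ascending")
        if np.any(n < 1.0):
            raise ValueError("refractive indices must be >= 1 (attractive wells)")

    @property
    def ka_values(self) -> np.ndarray:
        return self.k * np.asarray(self.radii)

    @property
    def n_shells(self) -> int:
        return len(self.radii)


def build_multishell(
    element: str,
    n_shells: int,
    r_max: float,
    beam: BeamParameters,
    spacing: str = "linear",
    r_min_factor: float = 1e-3,
) -> ShellModel:
    """Piecewise-constant reduction of the IAM potential on (0, r_max].

    Each shell's potential is the volume average of V(r) over the shell;
    n_s = sqrt(1 + V_s / E).  ``spacing`` is "linear" (equal steps in r,
    default) or "log" (shells concentrated near the nucleus, with the
    innermost boundary at ``r_min_factor * r_max``).
    """
    if n_shells < 1:
        raise ValueError("n_shells must be >= 1")
    if r_max <= 0:
        raise ValueError("r_max must be positive")
    if spacing == "linear":
        edges = np.linspace(0.0, r_max, n_shells + 1)
    elif spacing == "log":
        inner = np.geomspace(r_min_factor * r_max, r_max, n_shells)
        edges = np.concatenate([[0.0], inner])
    else:
        raise ValueError(f"unknown spacing {spacing!r}")

    pots = np.empty(n_shells)
    for s in range(n_shells):
        r0, r1 = edges[s], edges[s + 1]
        num, _ = quad(lambda r: iam_radial_potential(element, r) * r**2, r0, r1, limit=200)
        pots[s] = 3.0 * num / (r1**3 - r0**3)
    n_ref = np.sqrt(1.0 + pots / beam.energy_volts)
    return ShellModel(
        radii=tuple(edges[1:]),
        refr_indices=tuple(n_ref),
        k=beam.k,
        element=element,
        potentials=tuple(pots),
    )


def born_form_factor_multishell(shells: ShellModel, beam: BeamParameters, theta) -> np.ndarray:
    """First-Born scattering amplitude (Å) of the piecewise-constant profile.

    The profile is decomposed into nested uniform wells; each well of reduced
    potential step dU_s = k^2 (n_s^2 - n_{s+1}^2) and radius a_s contributes
    dU_s a_s^3 j_1(q a_s)/(q a_s) with q = 2 k sin(theta/2).  At theta = 0
    this reduces to sum_s dU_s a_s^3 / 3.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0) or np.any(theta > np.pi):
        raise ValueError("scattering angles must lie in [0, pi]")
    k = beam.k
    n2 = np.asarray(shells.refr_indices) ** 2
    n2_outer = np.concatenate([n2[1:], [1.0]])
    du = k**2 * (n2 - n2_outer)  # reduced potential steps, Å^-2
    a = np.asarray(shells.radii)
    q = 2.0 * k * np.sin(theta / 2.0)
    f = np.zeros_like(theta)
    for du_s, a_s in zip(du, a):
        x = q * a_s
        kernel = np.where(x > 1e-12, spherical_jn(1, np.maximum(x, 1e-300)) / np.maximum(x, 1e-12), 1.0 / 3.0)
        f = f + du_s * a_s**3 * kernel
    return f
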