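"""Configuration, geometry I/O, fixture generation, sweeps and tabular outputs.

Configs are YAML (or JSON) documents; geometry is a headered
whitespace-delimited table in Å with either explicit soft-sphere rows
(x y z radius n_ref) or element rows (x y z element n_shells r_max) that are
expanded through the multi-shell muffin-tin reduction.  Everything is
deterministic given the config; the seed only subsamples sweep grids.

Dimensionless fixture generators (normalized radius ka, spacing kd) convert
to Å using the beam's wavenumber, so the unit conversion lives in one place.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mie import multishell_tmatrix, soft_sphere_tmatrix
from .observables import (
    boundary_continuity_error,
    cross_sections,
    far_field_amplitude,
    optical_theorem_residual,
)
from .potentials import BeamParameters, build_multishell, relativistic_beam
from .solver import (
    Scatterer,
    ScattererArray,
    assemble_system,
    coefficient_error,
    solve_forward,
    solve_full,
    solve_kinematic,
    solve_successive,
)

__all__ = [
    "RunConfig",
    "auto_l_max",
    "load_geometry",
    "build_array",
    "load_run",
    "run",
    "generate_linear_array",
    "sweep",
    "write_outputs",
    "write_far_field",
    "read_far_field",
]

_SOLVERS = ("full", "forward", "kinematic", "successive")
_OUTPUTS = ("far_field", "cross_sections", "probabilities", "continuity", "coefficients")


@dataclass
class RunConfig:
    """Validated run description (see docs for the YAML schema)."""

    energy_kev: float
    direction: tuple[float, float, float]
    geometry: list[dict] | str
    solver: str
    n_orders: int = 1
    l_max: int | None = None  # None = auto: ceil(max ka) + 8
    outputs: tuple[str, ...] = ("far_field", "cross_sections")
    S: float | None = None
    seed: int = 0
    config_path: str | None = None
    raw: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.solver not in _SOLVERS:
            raise ValueError(f"solver must be one of {_SOLVERS}, got {self.solver!r}")
        if self.solver == "successive" and self.n_orders < 1:
            raise ValueError("successive mode needs n_orders >= 1")
        bad = [o for o in self.outputs if o not in _OUTPUTS]
        if bad:
            raise ValueError(f"unknown outputs {bad}; valid: {_OUTPUTS}")
        if "probabilities" in self.outputs and self.S is None:
            raise ValueError("probability outputs require the illuminated area S (Å²)")


def auto_l_max(max_ka: float) -> int:
    """Truncation rule: an integer above the largest normalized radius, plus margin."""
    return int(math.ceil(max_ka)) + 8


# ---------------------------------------------------------------------------
# geometry


def load_geometry(source) -> pd.DataFrame:
    """Geometry table from a TSV path, a DataFrame, or a list of row dicts."""
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    elif isinstance(source, (str, Path)):
        df = pd.read_csv(source, sep=r"\s+")
    elif isinstance(source, list):
        df = pd.DataFrame(source)
    else:
        raise TypeError(f"cannot read geometry from {type(source)}")
    if df.empty:
        raise ValueError("geometry table has no rows")
    cols = set(df.columns)
    if {"x", "y", "z", "radius", "n_ref"} <= cols:
        kind = "sphere"
    elif {"x", "y", "z", "element", "n_shells", "r_max"} <= cols:
        kind = "element"
    else:
        raise ValueError(
            "geometry needs columns (x y z radius n_ref) or (x y z element n_shells r_max); "
            f"got {sorted(cols)}"
        )
    df.attrs["kind"] = kind
    return df


def build_array(geometry: pd.DataFrame, beam: BeamParameters, l_max: int | None = None) -> ScattererArray:
    """Expand a geometry table into a validated scatterer array."""
    geometry = load_geometry(geometry)
    kind = geometry.attrs["kind"]
    k = beam.k
    if kind == "sphere":
        max_ka = float((geometry["radius"] * k).max())
    else:
        max_ka = float((geometry["r_max"] * k).max())
    if l_max is None:
        l_max = auto_l_max(max_ka)
    scatterers = []
    for row_num, row in enumerate(geometry.itertuples(index=False)):
        centre = np.array([row.x, row.y, row.z], dtype=float)
        try:
            if kind == "sphere":
                tm = soft_sphere_tmatrix(k * row.radius, row.n_ref, l_max, k=k)
            else:
                shells = build_multishell(row.element, int(row.n_shells), row.r_max, beam)
                tm = multishell_tmatrix(shells, beam, l_max)
        except (KeyError, ValueError) as exc:
            raise ValueError(f"geometry row {row_num}: {exc}") from exc
        scatterers.append(Scatterer(centre=centre, tmat=tm))
    return ScattererArray(scatterers=scatterers, beam=beam, l_max=l_max)


def load_run(config_path) -> tuple[RunConfig, ScattererArray]:
    """Parse + validate a config file and build its scatterer array."""
    config_path = Path(config_path)
    with open(config_path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError("config must be a mapping")
    beam_doc = doc.get("beam", {})
    cfg = RunConfig(
        energy_kev=float(beam_doc.get("energy_kev", 200.0)),
        direction=tuple(beam_doc.get("direction", (0.0, 0.0, 1.0))),
        geometry=doc.get("geometry"),
        solver=doc.get("solver", "full"),
        n_orders=int(doc.get("n_orders", 1)),
        l_max=doc.get("l_max"),
        outputs=tuple(doc.get("outputs", ("far_field", "cross_sections"))),
        S=doc.get("S"),
        seed=int(doc.get("seed", 0)),
        config_path=str(config_path),
        raw=doc,
    )
    if cfg.geometry is None:
        raise ValueError("config must provide a geometry table or path")
    geom = cfg.geometry
    if isinstance(geom, str):
        geom = (config_path.parent / geom) if not Path(geom).is_absolute() else Path(geom)
    beam = relativistic_beam(cfg.energy_kev, cfg.direction)
    array = build_array(load_geometry(geom), beam, l_max=cfg.l_max)
    return cfg, array


def run(cfg: RunConfig, array: ScattererArray) -> dict:
    """Execute the configured solver and produce the requested artifacts."""
    from .observables import mean_free_path, scattering_probabilities

    results: dict = {"l_max": array.l_max, "mode": cfg.solver}
    system = assemble_system(array)
    if cfg.solver == "full":
        coeffs = solve_full(array, system)
    elif cfg.solver == "forward":
        coeffs = solve_forward(array, system)
    elif cfg.solver == "kinematic":
        coeffs = solve_kinematic(array, system)
    else:
        succ = solve_successive(array, cfg.n_orders, system)
        coeffs = succ.cumulative[-1]
        results["successive"] = succ
    results["coefficients"] = coeffs

    pattern = far_field_amplitude(array, coeffs)
    results["far_field"] = pattern
    dsig, sigma = cross_sections(pattern)
    results["sigma_total"] = sigma
    results["optical_theorem_residual"] = optical_theorem_residual(pattern, array.beam)
    if "continuity" in cfg.outputs:
        results["continuity"] = [
            boundary_continuity_error(array, coeffs, p) for p in range(array.n_spheres)
        ]
    if "probabilities" in cfg.outputs:
        if cfg.solver != "successive":
            raise ValueError("probability outputs require the successive solver")
        patterns = [far_field_amplitude(array, t) for t in results["successive"].terms]
        zs = [s.centre[2] for s in array.scatterers]
        dz = (max(zs) - min(zs)) / max(array.n_spheres - 1, 1)
        sig_avg = np.mean(
            [cross_sections(far_field_amplitude(array, solve_kinematic(array, system)))[1]]
        ) / array.n_spheres
        lam = mean_free_path(sig_avg, cfg.S, dz) if dz > 0 else None
        thickness = max(zs) - min(zs) + dz if dz > 0 else None
        results["budget"] = scattering_probabilities(
            patterns, cfg.S, thickness=thickness, lambda_e=lam
        )
    return results


# ---------------------------------------------------------------------------
# fixtures


def generate_linear_array(
    N: int, kd: float, ka: float, n_ref: float, beam: BeamParameters
) -> pd.DataFrame:
    """N identical spheres on the beam axis, spaced kd/k, radius ka/k.

    The regular linear chain used for multiple-scattering convergence
    studies; spacing must exceed the sphere diameter (kd > 2 ka).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if ka <= 0:
        raise ValueError("ka must be positive")
    if N > 1 and kd <= 2 * ka:
        raise ValueError(f"overlap: spacing kd={kd} must exceed the diameter 2 ka={2 * ka}")
    k = beam.k
    zs = (np.arange(N) - (N - 1) / 2.0) * (kd / k)
    return pd.DataFrame(
        {
            "x": np.zeros(N),
            "y": np.zeros(N),
            "z": zs,
            "radius": np.full(N, ka / k),
            "n_ref": np.full(N, float(n_ref)),
        }
    )


# ---------------------------------------------------------------------------
# sweeps


def sweep(
    beam: BeamParameters,
    ka_values,
    kd_values,
    n_ref_values,
    N_values,
    modes=("kinematic", "forward"),
    n_orders: int | None = None,
    l_max: int | None = None,
    out_csv=None,
    seed: int | None = None,
    max_points: int | None = None,
) -> pd.DataFrame:
    """Long-format error table over a (ka, kd, n_ref, N) grid.

    Each row holds one (parameter point, mode) with the coefficient error of
    that mode against the full solve and the total cross section of the full
    solve.  Per-point failures are recorded in the ``error`` column instead of
    aborting.  ``seed``/``max_points`` optionally subsample large grids.
    Rows are appended to ``out_csv`` incrementally when given.
    """
    grid = [
        (ka, kd, n_ref, N)
        for ka in np.atleast_1d(ka_values)
        for kd in np.atleast_1d(kd_values)
        for n_ref in np.atleast_1d(n_ref_values)
        for N in np.atleast_1d(N_values)
    ]
    if max_points is not None and len(grid) > max_points:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(grid), size=max_points, replace=False)
        grid = [grid[i] for i in sorted(keep)]

    rows = []
    out_csv = Path(out_csv) if out_csv is not None else None
    for ka, kd, n_ref, N in grid:
        n_before = len(rows)
        point_lmax = l_max if l_max is not None else auto_l_max(ka)
        base = {"ka": ka, "kd": kd, "n_ref": n_ref, "N": int(N), "l_max": point_lmax}
        try:
            geom = generate_linear_array(int(N), kd, ka, n_ref, beam)
            array = build_array(geom, beam, l_max=point_lmax)
            system = assemble_system(array)
            exact = solve_full(array, system)
            _, sigma = cross_sections(far_field_amplitude(array, exact))
            for mode in modes:
                row = dict(base, mode=mode, sigma_total=sigma, error="")
                if mode == "forward":
                    approx = solve_forward(array, system)
                elif mode == "kinematic":
                    approx = solve_kinematic(array, system)
                elif mode == "successive":
                    orders = n_orders if n_orders is not None else array.n_slices
                    approx = solve_successive(array, orders, system).cumulative[-1]
                else:
                    raise ValueError(f"unknown sweep mode {mode!r}")
                row["coeff_error"] = coefficient_error(approx, exact)
                rows.append(row)
        except Exception as exc:  # noqa: BLE001 - per-point failures become rows
            rows.append(dict(base, mode="", sigma_total=np.nan, coeff_error=np.nan, error=str(exc)))
        if out_csv is not None:
            pd.DataFrame(rows[n_before:]).to_csv(
                out_csv, mode="a", header=not out_csv.exists(), index=False,
                float_format="%.17g",
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# outputs

_FLOAT_FMT = "%.17g"


def write_far_field(pattern, path):
    """Far-field TSV: theta_rad [phi_rad] Re_f Im_f dsigma_dOmega (17 s.f.)."""
    dsig, _ = cross_sections(pattern)
    cols = {"theta_rad": pattern.theta}
    if pattern.phi is not None:
        cols["phi_rad"] = pattern.phi
    cols.update(
        {"Re_f": pattern.f.real, "Im_f": pattern.f.imag, "dsigma_dOmega": dsig,
         "weight": pattern.weights}
    )
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT,
                              lineterminator="\n")


def read_far_field(path, k: float):
    """Re-read a far-field TSV into a FarFieldPattern."""
    from .observables import FarFieldPattern

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return FarFieldPattern(
        theta=df["theta_rad"].to_numpy(),
        f=df["Re_f"].to_numpy() + 1j * df["Im_f"].to_numpy(),
        weights=df["weight"].to_numpy(),
        k=k,
        phi=df["phi_rad"].to_numpy() if "phi_rad" in df.columns else None,
    )


def write_outputs(cfg: RunConfig, array: ScattererArray, results: dict, out_dir) -> dict:
    """Write the requested artifacts plus a reproducibility manifest.

    Returns a {name: path} map.  All floats are written at 17 significant
    digits so outputs regenerate bit-identically on the same platform.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if "far_field" in cfg.outputs and "far_field" in results:
        path = out_dir / "far_field.tsv"
        write_far_field(results["far_field"], path)
        written["far_field"] = path

    summary: dict = {
        "mode": results["mode"],
        "l_max": results["l_max"],
        "n_spheres": array.n_spheres,
        "sigma_total_A2": results.get("sigma_total"),
        "optical_theorem_residual": results.get("optical_theorem_residual"),
    }
    if "continuity" in results:
        summary["continuity_value"] = [c.value for c in results["continuity"]]
        summary["continuity_derivative"] = [c.derivative for c in results["continuity"]]
    if "budget" in results:
        summary["budget"] = results["budget"].to_dict()
    path = out_dir / "summary.json"
    path.write_text(json.dumps(summary, indent=2, default=float) + "\n", encoding="utf-8")
    written["summary"] = path

    if "coefficients" in cfg.outputs:
        coeffs = results["coefficients"]
        path = out_dir / "coefficients.tsv"
        recs = []
        from .special import multipole_indices

        idx = multipole_indices(coeffs.l_max, coeffs.axisymmetric)
        for p in range(coeffs.b.shape[0]):
            for i, (l, m) in enumerate(idx):
                recs.append(
                    {"sphere": p, "l": l, "m": m,
                     "Re_b": coeffs.b[p, i].real, "Im_b": coeffs.b[p, i].imag,
                     "Re_c": coeffs.c[p, i].real, "Im_c": coeffs.c[p, i].imag}
                )
        pd.DataFrame(recs).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT,
                                  lineterminator="\n")
        written["coefficients"] = path

    manifest = {
        "config_sha256": _config_hash(cfg),
        "l_max": results["l_max"],
        "solver": cfg.solver,
        "versions": _versions(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    written["manifest"] = path
    return written


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.raw, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _versions() -> dict:
    import scipy

    import tmatsphere

    return {"tmatsphere": tmatsphere.__version__, "numpy": np.__version__, "scipy": scipy.__version__}
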