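"""End-to-end preclinical workflows.

Two study designs are wired here on top of the engine and dosimetry
modules:

* optical-property lookup tables — sweep a target region's (mu_a, mu_s')
  over a grid, record the fluence rate at detector positions per run, and
  invert measured detector signals back to the generating grid point
  (least-squares in log space over all detectors);

* diffuser dose escalation — seat cylindrical diffusers inside a vessel
  lumen, cap all powers so the fluence rate on the vessel-wall (intima)
  surface stays below a limit (300 mW/cm^2 by default), and report per-
  diffuser permissible powers, the fluence profile between diffusers, and
  threshold-model necrotic volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dosimetry import (
    ThresholdSet,
    fluence_from_score,
    interface_faces,
    line_probe,
    necrosis_mask,
    surface_fluence,
)
from .engine import SimConfig, run_mc
from .mesh import TetraMesh, locate_points
from .optics import Material
from .planning import Plan, build_dose_matrix, enforce_surface_limit, sub_seed
from .sources import CylDiffuser, total_power

__all__ = [
    "SweepSpec",
    "LookupTable",
    "run_sweep",
    "invert_lookup",
    "AmbiguousInversionError",
    "dose_escalation",
    "INTIMA_LIMIT_DEFAULT",
    "liver_lookup_study",
    "tumor_plan_study",
    "vessel_escalation_study",
]

INTIMA_LIMIT_DEFAULT = 300.0  # mW/cm^2, vessel-wall fluence-rate cap


@dataclass
class SweepSpec:
    """An optical-property sweep over one mesh region.

    The target region's material is replaced per run by (mu_a, mu_s')
    from the grid (g and n fixed); every other region keeps its material
    from ``base_materials``.  Detector readout is the point fluence rate
    (piecewise-constant per tet) at each detector position.
    """

    mesh: TetraMesh
    base_materials: dict
    target_region: int
    mu_a_values: tuple        # mm^-1
    mu_s_prime_values: tuple  # mm^-1
    g: float
    n: float
    source: object
    detectors: np.ndarray     # (n_det, 3) positions mm
    packets: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if len(self.mu_a_values) == 0 or len(self.mu_s_prime_values) == 0:
            raise ValueError("mu_a and mu_s' value lists must be nonempty")
        self.detectors = np.atleast_2d(np.asarray(self.detectors, dtype=np.float64))
        tets = locate_points(self.mesh, self.detectors)
        if np.any(tets < 0):
            raise ValueError("all detector positions must lie inside the mesh")
        self._detector_tets = tets


@dataclass
class LookupTable:
    """Complete (mu_a, mu_s') -> per-detector fluence-rate grid."""

    mu_a_values: np.ndarray
    mu_s_prime_values: np.ndarray
    detectors: np.ndarray
    values: np.ndarray   # (n_mu_a, n_mu_s', n_det) mW/cm^2
    packets: int = 0
    seed: int = 0
    source_power: float = 0.0
    n_runs: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, mu_a in enumerate(self.mu_a_values):
            for j, msp in enumerate(self.mu_s_prime_values):
                for d in range(len(self.detectors)):
                    rows.append(
                        {
                            "mu_a": mu_a,
                            "mu_s_prime": msp,
                            "detector_id": d,
                            "fluence_rate": self.values[i, j, d],
                        }
                    )
        return pd.DataFrame(rows)


def run_sweep(spec: SweepSpec) -> LookupTable:
    """One MC run per (mu_a, mu_s') pair; exactly len(a) x len(s) runs."""
    n_a, n_s = len(spec.mu_a_values), len(spec.mu_s_prime_values)
    values = np.empty((n_a, n_s, len(spec.detectors)))
    run_idx = 0
    for i, mu_a in enumerate(spec.mu_a_values):
        for j, msp in enumerate(spec.mu_s_prime_values):
            mats = dict(spec.base_materials)
            mats[spec.target_region] = Material.from_reduced(
                spec.target_region, "sweep-target", float(mu_a), float(msp),
                spec.g, spec.n,
            )
            try:
                score = run_mc(
                    spec.mesh, mats, [spec.source],
                    SimConfig(n_packets=spec.packets, seed=sub_seed(spec.seed, run_idx)),
                )
            except Exception as exc:
                raise RuntimeError(
                    f"sweep run failed at grid point (mu_a={mu_a}, mu_s'={msp})"
                ) from exc
            fld = fluence_from_score(
                score, spec.mesh, mats, total_power([spec.source]),
                estimator="track_length",
            )
            values[i, j, :] = fld.phi[spec._detector_tets]
            run_idx += 1
    return LookupTable(
        mu_a_values=np.asarray(spec.mu_a_values, dtype=np.float64),
        mu_s_prime_values=np.asarray(spec.mu_s_prime_values, dtype=np.float64),
        detectors=spec.detectors,
        values=values,
        packets=spec.packets,
        seed=spec.seed,
        source_power=total_power([spec.source]),
        n_runs=run_idx,
    )


class AmbiguousInversionError(RuntimeError):
    """Multiple grid points fit the measured signals equally well."""


def invert_lookup(table: LookupTable, measured, ambiguity_tol: float = 1e-12):
    """Grid point minimizing the squared log-ratio misfit to ``measured``.

    With a single detector the inversion is frequently degenerate (many
    (mu_a, mu_s') pairs yield the same signal at one distance); if two or
    more grid points fit within ``ambiguity_tol`` of the optimum the
    inversion is reported as ambiguous rather than returning one of them
    arbitrarily.
    """
    measured = np.atleast_1d(np.asarray(measured, dtype=np.float64))
    if measured.shape[0] != table.values.shape[2]:
        raise ValueError("one measured signal per detector is required")
    if np.any(measured <= 0):
        raise ValueError("measured signals must be positive")
    tab = table.values
    if np.any(tab <= 0):
        # zero-signal cells (deep attenuation below the noise floor) are
        # excluded by an infinite misfit rather than a log of zero
        misfit = np.full(tab.shape[:2], np.inf)
        ok = np.all(tab > 0, axis=2)
        logr = np.log(tab[ok] / measured)
        misfit[ok] = np.sum(logr**2, axis=1)
    else:
        misfit = np.sum(np.log(tab / measured) ** 2, axis=2)
    flat = misfit.ravel()
    best = int(np.argmin(flat))
    ties = np.nonzero(flat <= flat[best] + ambiguity_tol)[0]
    if len(ties) > 1:
        pts = [
            (float(table.mu_a_values[t // tab.shape[1]]),
             float(table.mu_s_prime_values[t % tab.shape[1]]))
            for t in ties
        ]
        raise AmbiguousInversionError(
            f"{len(ties)} grid points fit equally well: {pts}; "
            "add detectors at more distances to break the degeneracy"
        )
    i, j = divmod(best, tab.shape[1])
    return float(table.mu_a_values[i]), float(table.mu_s_prime_values[j])


@dataclass
class EscalationReport:
    powers: np.ndarray            # scaled per-diffuser powers, mW
    scale: float                  # global factor applied to the initial powers
    max_intima_fluence: float     # mW/cm^2 at the scaled powers
    limit: float
    profile: tuple = None         # (distances mm, fluence) between diffuser midpoints
    attenuation_factor: float = None  # peak / midpoint fluence along the profile
    necrotic_volume: dict = field(default_factory=dict)  # region -> mm^3

    def to_dict(self):
        out = {
            "powers_mW": [float(p) for p in self.powers],
            "scale": float(self.scale),
            "max_intima_fluence_mW_cm2": float(self.max_intima_fluence),
            "limit_mW_cm2": float(self.limit),
            "necrotic_volume_mm3": {str(k): float(v) for k, v in self.necrotic_volume.items()},
        }
        if self.attenuation_factor is not None:
            out["attenuation_factor"] = float(self.attenuation_factor)
        if self.profile is not None:
            out["profile"] = {
                "distance_mm": [float(x) for x in self.profile[0]],
                "fluence_mW_cm2": [float(x) for x in self.profile[1]],
            }
        return out


def dose_escalation(
    mesh: TetraMesh,
    materials: dict,
    diffusers,
    lumen_region: int,
    wall_region: int,
    limit: float = INTIMA_LIMIT_DEFAULT,
    thresholds: ThresholdSet = None,
    packets: int = 100_000,
    seed: int = 0,
    profile_samples: int = 101,
) -> EscalationReport:
    """Cap diffuser powers at the vessel-wall fluence-rate limit.

    Per-diffuser unit-power fields are composed at the requested powers,
    the intima surface fluence (faces between lumen and wall) is measured,
    and all powers are scaled down together if the peak exceeds ``limit``.
    With two or more diffusers the fluence profile between the first two
    midpoints and its peak-to-midpoint attenuation factor are reported.
    """
    if not diffusers:
        raise ValueError("at least one diffuser is required")
    dm = build_dose_matrix(mesh, materials, diffusers, packets, seed)
    init_powers = np.array([d.total_power() for d in diffusers])
    faces = interface_faces(mesh, lumen_region, wall_region)
    if len(faces) == 0:
        raise ValueError(
            f"no interface faces between lumen region {lumen_region} and "
            f"wall region {wall_region}"
        )
    plan = Plan(
        powers=init_powers,
        objective=0.0,
        coverage=1.0,
        oar_overdose={},
        sources=dm.sources,
    )
    surf = surface_fluence(dm.compose(init_powers), mesh, faces)
    plan = enforce_surface_limit(plan, surf, limit)
    scale = plan.powers[0] / init_powers[0] if init_powers[0] > 0 else 1.0
    fld = dm.compose(plan.powers)
    max_intima = float(surface_fluence(fld, mesh, faces).max())

    profile = None
    atten = None
    if len(diffusers) >= 2:
        a = np.asarray(diffusers[0].center, dtype=np.float64)
        b = np.asarray(diffusers[1].center, dtype=np.float64)
        dist, vals = line_probe(fld, mesh, a, b, profile_samples)
        profile = (dist, vals)
        finite = np.isfinite(vals)
        mid = vals[finite][np.argmin(np.abs(dist[finite] - dist[-1] / 2.0))]
        peak = np.nanmax(vals)
        atten = float(peak / mid) if mid > 0 else float("inf")

    necro = {}
    if thresholds is not None:
        _, necro = necrosis_mask(fld, thresholds, mesh)
    return EscalationReport(
        powers=plan.powers,
        scale=float(scale),
        max_intima_fluence=max_intima,
        limit=float(limit),
        profile=profile,
        attenuation_factor=atten,
        necrotic_volume=necro,
    )


# ---------------------------------------------------------------------------
# Canonical study conditions
# ---------------------------------------------------------------------------
#
# These builders pin down the three bundled study set-ups (liver lookup
# sweep, sphere-tumour plan optimization, vessel diffuser escalation) so
# that scripts and tests exercise identical conditions.

def liver_lookup_study(
    packets: int = 2000,
    seed: int = 0,
    n_grid: int = 11,
    cells=(12, 24, 12),
) -> SweepSpec:
    """Liver-cube optical-property sweep.

    A 6 x 12 x 6 cm liver phantom with a 2-cm cylindrical diffuser at
    100 mW/cm through its centre; the lookup grid spans mu_a in
    [0.0005, 0.0631] mm^-1 and mu_s' in [6, 11] mm^-1 (published liver
    ranges), 11 x 11 by default.  Sweeps are parameterised by mu_s'
    directly (g = 0, the reduced-scattering similarity), and detectors sit
    on a lateral line from the diffuser centre at radii where desk-scale
    packet counts still give usable signal-to-noise.
    """
    from .phantoms import PhantomSpec, generate_phantom

    mesh = generate_phantom(
        PhantomSpec(kind="box", extents=(60.0, 120.0, 60.0), cells=tuple(cells))
    )
    diffuser = CylDiffuser(
        center=(30.0, 60.0, 30.0), axis=(0.0, 1.0, 0.0),
        radius=0.5, length=20.0, linear_density=100.0,
    )
    detectors = np.array(
        [[30.0 + r, 60.0, 30.0] for r in (5.0, 8.0, 12.0)]
    )
    return SweepSpec(
        mesh=mesh,
        base_materials={},
        target_region=0,
        mu_a_values=tuple(np.linspace(0.0005, 0.0631, n_grid)),
        mu_s_prime_values=tuple(np.linspace(6.0, 11.0, n_grid)),
        g=0.0,
        n=1.37,
        source=diffuser,
        detectors=detectors,
        packets=packets,
        seed=seed,
    )


def tumor_plan_study(seed: int = 0, cells=(15, 15, 15)):
    """Sphere-tumour / OAR-shell planning test bed.

    60 mm box, 10 mm sphere tumour (region 1) with a 3 mm organ-at-risk
    shell (region 2); three interstitial point sources on a 5 mm circle
    inside the tumour.  Homogeneous soft-tissue optics (mu_a = 0.02,
    mu_s' = 2 mm^-1, n = 1.37) and a uniform 20 mW/cm^2 fluence-rate
    threshold.  Returns (mesh, materials, sources, thresholds).
    """
    from .phantoms import generate_tumor_oar_phantom
    from .sources import PointSource

    mesh = generate_tumor_oar_phantom(10.0, 3.0, extents=(60.0, 60.0, 60.0), cells=cells)
    materials = {
        r: Material.from_reduced(r, name, 0.02, 2.0, 0.0, 1.37)
        for r, name in ((0, "background"), (1, "tumor"), (2, "oar"))
    }
    center = np.array([30.0, 30.0, 30.0])
    sources = [
        PointSource(
            position=center + 5.0 * np.array([np.cos(a), np.sin(a), 0.0]),
            power=1.0,
        )
        for a in np.deg2rad([90.0, 210.0, 330.0])
    ]
    thresholds = ThresholdSet({1: 20.0, 2: 20.0})
    return mesh, materials, sources, thresholds


def vessel_escalation_study(seed: int = 0, cells=(20, 20, 20)):
    """Vessel-in-box diffuser escalation test bed.

    30 mm block of pancreas-like tissue with an axial vessel: 2 mm lumen
    (region 1, blood-like optics) and a 1.5 mm wall (region 2, arterial
    optics).  One 1 mm radius x 10 mm cylindrical diffuser is seated in
    the lumen.  Returns (mesh, materials, [diffuser], thresholds).
    """
    from .phantoms import PhantomSpec, generate_phantom

    mesh = generate_phantom(
        PhantomSpec(
            kind="vessel_in_box",
            extents=(30.0, 30.0, 30.0),
            cells=tuple(cells),
            vessel_axis=(0.0, 0.0, 1.0),
            vessel_radius=2.0,
            vessel_label=1,
            wall_thickness=1.5,
            wall_label=2,
        )
    )
    materials = {
        0: Material.from_reduced(0, "pancreas", 0.010, 1.2, 0.0, 1.37),
        1: Material.from_reduced(1, "blood", 0.150, 2.0, 0.0, 1.37),
        2: Material.from_reduced(2, "vessel-wall", 0.040, 2.4, 0.0, 1.37),
    }
    diffuser = CylDiffuser(
        center=(15.0, 15.0, 15.0), axis=(0.0, 0.0, 1.0),
        radius=1.0, length=10.0, power=100.0,
    )
    thresholds = ThresholdSet({0: 40.0, 2: 40.0})
    return mesh, materials, [diffuser], thresholds
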