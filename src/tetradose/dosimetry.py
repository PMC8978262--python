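"""Fluence fields, dose-volume histograms and threshold dosimetry.

The engine scores energy fractions; this module turns them into physical
fluence-rate fields (mW/cm^2 for source powers in mW) via either of two
estimators, and evaluates plans against the photodynamic threshold model:
tissue is treated as necrosed wherever the delivered dose meets or exceeds
a tissue-specific threshold.  Dose-volume histograms follow the planning
convention of plotting dose as a percentage of each region's threshold
against the percentage of region volume receiving at least that dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mesh import TetraMesh, locate_points
from .optics import derive_optics

__all__ = [
    "FluenceField",
    "ThresholdSet",
    "DVHCurve",
    "CoverageReport",
    "fluence_from_score",
    "compute_dvh",
    "coverage",
    "necrosis_mask",
    "analytic_point_fluence",
    "line_probe",
    "interface_faces",
    "surface_fluence",
    "boundary_exitance",
]

MM2_TO_CM2 = 100.0  # 1 mm^-2 = 100 cm^-2


@dataclass
class FluenceField:
    """Per-tet fluence rate (mW/cm^2 when source powers are in mW)."""

    phi: np.ndarray            # (n_tets,)
    estimator: str             # 'absorption' | 'track_length'
    total_power: float         # mW
    undefined: np.ndarray = None  # mask of tets where the estimator is undefined


@dataclass
class ThresholdSet:
    """Per-region threshold doses, in the units of the field they gate."""

    thresholds: dict  # region -> T > 0

    def __post_init__(self):
        for r, t in self.thresholds.items():
            if t <= 0:
                raise ValueError(f"threshold for region {r} must be > 0, got {t}")

    def __getitem__(self, region):
        return self.thresholds[int(region)]

    def __contains__(self, region):
        return int(region) in self.thresholds

    def scaled(self, factor: float) -> "ThresholdSet":
        return ThresholdSet({r: t * factor for r, t in self.thresholds.items()})


@dataclass
class DVHCurve:
    """Per-region survival curves: x = % of threshold, y = % volume >= x."""

    curves: dict  # region -> (x, y) arrays

    def __getitem__(self, region):
        return self.curves[int(region)]


@dataclass
class CoverageReport:
    tumor_coverage: float            # volume fraction of tumour >= threshold
    oar_overdose: dict = field(default_factory=dict)    # region -> mm^3 above threshold
    necrotic_volume: dict = field(default_factory=dict)  # region -> mm^3


def fluence_from_score(
    score, mesh: TetraMesh, materials: dict, total_power: float,
    estimator: str = "track_length",
) -> FluenceField:
    """Fluence rate per tet from a :class:`RawScore`.

    absorption estimator:   Phi_i = P * A_i / (mu_a,i * V_i)
    track-length estimator: Phi_i = P * L_i / V_i
    with A_i the absorbed energy fraction, L_i the weighted path length
    (mm per unit emitted weight) and V_i in mm^3; the result is converted
    from mm^-2 to cm^-2.  The absorption estimator is undefined where
    mu_a = 0 (flagged, with a warning).
    """
    if estimator == "track_length":
        phi = total_power * score.tracklen / mesh.volume * MM2_TO_CM2
        return FluenceField(phi=phi, estimator=estimator, total_power=total_power)
    if estimator != "absorption":
        raise ValueError("estimator must be 'absorption' or 'track_length'")
    mu_a = np.array([materials[r].mu_a for r in mesh.region])
    undefined = mu_a == 0.0
    phi = np.zeros(mesh.n_tets)
    ok = ~undefined
    phi[ok] = total_power * score.absorbed[ok] / (mu_a[ok] * mesh.volume[ok]) * MM2_TO_CM2
    if undefined.any():
        import warnings

        warnings.warn(
            f"absorption estimator undefined in {int(undefined.sum())} tets with mu_a=0; "
            "use the track-length estimator there",
            stacklevel=2,
        )
    return FluenceField(
        phi=phi, estimator=estimator, total_power=total_power, undefined=undefined
    )


def _region_ratio(field: FluenceField, thresholds: ThresholdSet, mesh, region: int):
    idx = np.nonzero(mesh.region == region)[0]
    if idx.size == 0:
        raise ValueError(f"mesh has no tets in region {region}")
    if region not in thresholds:
        raise ValueError(f"no threshold defined for region {region}")
    return idx, field.phi[idx] / thresholds[region]


def compute_dvh(
    field: FluenceField, thresholds: ThresholdSet, mesh: TetraMesh,
    bins: int = 1000, regions=None,
) -> DVHCurve:
    """Volume-weighted survival curve of dose/threshold per region.

    x is sampled on a uniform grid of ``bins`` points from 0 to the maximum
    observed dose ratio (in %); y(x) is the % of region volume at or above
    x.  Dose is piecewise constant per tet, matching the scoring
    granularity.
    """
    if regions is None:
        regions = [r for r in mesh.regions_present() if int(r) in thresholds]
    curves = {}
    for region in regions:
        idx, ratio = _region_ratio(field, thresholds, mesh, int(region))
        vol = mesh.volume[idx]
        vtot = vol.sum()
        ratio_pct = ratio * 100.0
        xmax = max(ratio_pct.max(), 1e-12)
        x = np.linspace(0.0, xmax, bins)
        order = np.argsort(ratio_pct)
        sorted_r = ratio_pct[order]
        # cumulative volume of tets with ratio < x  ->  y = 100 (1 - cum/vtot)
        cum = np.concatenate([[0.0], np.cumsum(vol[order])])
        pos = np.searchsorted(sorted_r, x, side="left")
        y = 100.0 * (1.0 - cum[pos] / vtot)
        curves[int(region)] = (x, y)
    return DVHCurve(curves=curves)


def coverage(field: FluenceField, thresholds: ThresholdSet, mesh, region: int) -> float:
    """Volume fraction of ``region`` with dose at or above its threshold."""
    idx, ratio = _region_ratio(field, thresholds, mesh, int(region))
    vol = mesh.volume[idx]
    return float(vol[ratio >= 1.0].sum() / vol.sum())


def necrosis_mask(field: FluenceField, thresholds: ThresholdSet, mesh):
    """Photodynamic threshold model: tet necrotic iff Phi >= its region threshold.

    Returns (per-tet boolean mask, {region: necrotic volume mm^3}); regions
    without a threshold are never necrosed.
    """
    mask = np.zeros(mesh.n_tets, dtype=bool)
    volumes = {}
    for region in mesh.regions_present():
        region = int(region)
        if region not in thresholds:
            continue
        idx, ratio = _region_ratio(field, thresholds, mesh, region)
        hit = ratio >= 1.0
        mask[idx[hit]] = True
        volumes[region] = float(mesh.volume[idx[hit]].sum())
    return mask, volumes


def analytic_point_fluence(r: float, P: float, mu_a: float, mu_s_prime: float) -> float:
    """Diffusion-theory fluence rate of an isotropic point source.

    Phi(r) = P exp(-mu_eff r) / (4 pi D r), with r in mm, P in mW and the
    optical coefficients in mm^-1; returned in mW/cm^2.  The r -> 0
    singularity is rejected.
    """
    if r <= 0:
        raise ValueError("r must be > 0 (the diffusion solution diverges at the source)")
    if mu_a <= 0:
        raise ValueError("mu_a must be > 0 for a finite mu_eff")
    from .optics import Material

    d = derive_optics(Material.from_reduced(0, "ref", mu_a, mu_s_prime, 0.0, 1.0))
    return P * math.exp(-d.mu_eff * r) / (4.0 * math.pi * d.D * r) * MM2_TO_CM2


def line_probe(field: FluenceField, mesh: TetraMesh, p0, p1, n_samples: int):
    """Sample the piecewise-constant field at n equally spaced points on a segment.

    Returns (distances mm, values); points outside the mesh get NaN.
    """
    p0 = np.asarray(p0, dtype=np.float64)
    p1 = np.asarray(p1, dtype=np.float64)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    t = np.linspace(0.0, 1.0, n_samples) if n_samples > 1 else np.array([0.5])
    pts = p0 + t[:, None] * (p1 - p0)
    dist = t * np.linalg.norm(p1 - p0)
    tets = locate_points(mesh, pts)
    vals = np.full(n_samples, np.nan)
    inside = tets >= 0
    vals[inside] = field.phi[tets[inside]]
    return dist, vals


def interface_faces(mesh: TetraMesh, region_a: int, region_b: int) -> np.ndarray:
    """(tet, local face) pairs on the interface between two regions.

    Each shared face is listed once, from the region_a side.
    """
    out = []
    for t in np.nonzero(mesh.region == region_a)[0]:
        for f in range(4):
            nb = mesh.adjacency[t, f]
            if nb >= 0 and mesh.region[nb] == region_b:
                out.append((t, f))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def surface_fluence(field: FluenceField, mesh: TetraMesh, faces: np.ndarray) -> np.ndarray:
    """Fluence rate per interface face: mean of the two adjacent tet values."""
    if len(faces) == 0:
        return np.zeros(0)
    a = faces[:, 0]
    b = mesh.adjacency[faces[:, 0], faces[:, 1]]
    return 0.5 * (field.phi[a] + field.phi[b])


def boundary_exitance(score, mesh: TetraMesh, total_power: float) -> np.ndarray:
    """Exitance per boundary face (mW/cm^2): exit energy / face area."""
    return total_power * score.exited / mesh.boundary_area * MM2_TO_CM2
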