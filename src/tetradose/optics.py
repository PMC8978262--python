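"""Optical properties and single-interaction physics.

A :class:`Material` carries the per-region absorption coefficient mu_a,
scattering coefficient mu_s (both mm^-1), Henyey-Greenstein anisotropy g
and refractive index n.  :class:`DerivedOptics` holds the transport
quantities derived from them: the interaction coefficient mu_t, single
scattering albedo, reduced scattering coefficient mu_s' = mu_s(1-g),
effective attenuation coefficient mu_eff = sqrt(3 mu_a (mu_a + mu_s')) and
diffusion constant D = 1/(3 (mu_a + mu_s')).

The scalar physics kernels (Henyey-Greenstein inverse-CDF sampling, local
frame rotation, unpolarised Fresnel reflectance, Snell refraction) are
numba-compiled so the transport engine can call them from nopython code;
thin ufunc-style wrappers expose them to normal Python callers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "Material",
    "DerivedOptics",
    "derive_optics",
    "sample_hg_cos",
    "scatter",
    "fresnel_reflectance",
    "refract",
    "read_materials_csv",
    "write_materials_csv",
    "materials_to_arrays",
]

# below this |g| the anisotropic inverse CDF loses precision; route to the
# exact isotropic branch instead
G_ISOTROPIC_EPS = 1e-6

_FASTMATH = {"contract", "arcp", "nsz", "afn", "reassoc"}


@dataclass(frozen=True)
class Material:
    """Optical properties of one mesh region (coefficients in mm^-1)."""

    region: int
    name: str
    mu_a: float
    mu_s: float
    g: float
    n: float

    def __post_init__(self):
        if self.mu_a < 0:
            raise ValueError(f"{self.name}: mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s < 0:
            raise ValueError(f"{self.name}: mu_s must be >= 0, got {self.mu_s}")
        if not (-1.0 < self.g < 1.0):
            raise ValueError(f"{self.name}: anisotropy g must lie in (-1, 1), got {self.g}")
        if self.n < 1.0:
            raise ValueError(
                f"{self.name}: the refractive index should be at least 1, got {self.n}"
            )

    @staticmethod
    def from_reduced(region, name, mu_a, mu_s_prime, g, n) -> "Material":
        """Construct from the reduced scattering coefficient mu_s' = mu_s(1-g)."""
        if g >= 1.0:
            raise ValueError("g must be < 1 to recover mu_s from mu_s'")
        mu_s = mu_s_prime / (1.0 - g) if mu_s_prime > 0 else 0.0
        return Material(region, name, mu_a, mu_s, g, n)


@dataclass(frozen=True)
class DerivedOptics:
    mu_t: float        # mm^-1
    albedo: float      # nan when mu_t == 0
    mu_s_prime: float  # mm^-1
    mu_eff: float      # mm^-1
    D: float           # mm; inf when mu_a + mu_s' == 0


def derive_optics(m: Material) -> DerivedOptics:
    mu_t = m.mu_a + m.mu_s
    mu_s_prime = m.mu_s * (1.0 - m.g)
    mu_tr = m.mu_a + mu_s_prime  # transport attenuation
    return DerivedOptics(
        mu_t=mu_t,
        albedo=m.mu_s / mu_t if mu_t > 0 else math.nan,
        mu_s_prime=mu_s_prime,
        mu_eff=math.sqrt(3.0 * m.mu_a * mu_tr),
        D=1.0 / (3.0 * mu_tr) if mu_tr > 0 else math.inf,
    )


# ---------------------------------------------------------------------------
# Scalar kernels (numba, shared with the transport engine)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=_FASTMATH)
def _hg_cos(g, u):
    if abs(g) < G_ISOTROPIC_EPS:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True, fastmath=_FASTMATH)
def _spin(ux, uy, uz, cos_t, phi):
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(uz) > 0.99999:
        # z-aligned degenerate frame
        nx = sin_t * cp
        ny = sin_t * sp
        nz = cos_t if uz > 0 else -cos_t
    else:
        denom = math.sqrt(1.0 - uz * uz)
        nx = sin_t * (ux * uz * cp - uy * sp) / denom + ux * cos_t
        ny = sin_t * (uy * uz * cp + ux * sp) / denom + uy * cos_t
        nz = -sin_t * cp * denom + uz * cos_t
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, fastmath=_FASTMATH)
def _fresnel_R(n1, n2, cos_i):
    if n1 == n2:
        return 0.0
    sin_i2 = 1.0 - cos_i * cos_i
    ratio = n1 / n2
    sin_t2 = ratio * ratio * sin_i2
    if sin_t2 >= 1.0:
        return 1.0  # total internal reflection
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _refract_dir(ux, uy, uz, nx, ny, nz, n1, n2):
    """Snell refraction of direction u at a surface with normal n.

    Convention: n points into the incident medium (u . n < 0).  Returns
    (tir, vx, vy, vz); on total internal reflection the reflected
    direction is returned with tir = True.
    """
    cos_i = -(ux * nx + uy * ny + uz * nz)
    ratio = n1 / n2
    sin_t2 = ratio * ratio * (1.0 - cos_i * cos_i)
    if sin_t2 >= 1.0:
        # reflect
        d = 2.0 * cos_i
        return True, ux + d * nx, uy + d * ny, uz + d * nz
    cos_t = math.sqrt(1.0 - sin_t2)
    k = ratio * cos_i - cos_t
    vx = ratio * ux + k * nx
    vy = ratio * uy + k * ny
    vz = ratio * uz + k * nz
    norm = math.sqrt(vx * vx + vy * vy + vz * vz)
    return False, vx / norm, vy / norm, vz / norm


# ---------------------------------------------------------------------------
# Python-facing wrappers
# ---------------------------------------------------------------------------

def sample_hg_cos(g: float, u):
    """Inverse-CDF sample of the Henyey-Greenstein scattering cosine.

    ``u`` is a uniform(0,1) deviate (scalar or array).  u=0 maps to -1 and
    u=1 to +1 for every g; for |g| < 1e-6 the exact isotropic branch
    cos(theta) = 2u - 1 is used.
    """
    if not (-1.0 < g < 1.0):
        raise ValueError("g must lie in (-1, 1)")
    u_arr = np.asarray(u, dtype=np.float64)
    if abs(g) < G_ISOTROPIC_EPS:
        out = 2.0 * u_arr - 1.0
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u_arr)
        out = np.clip((1.0 + g * g - tmp * tmp) / (2.0 * g), -1.0, 1.0)
    return float(out) if u_arr.ndim == 0 else out


def scatter(direction, cos_theta: float, phi: float) -> np.ndarray:
    """Rotate ``direction`` by scattering angle (cos_theta, azimuth phi)."""
    d = np.asarray(direction, dtype=np.float64)
    return np.array(_spin(d[0], d[1], d[2], float(cos_theta), float(phi)))


def fresnel_reflectance(n1: float, n2: float, cos_incident: float) -> float:
    """Unpolarised Fresnel reflectance for incidence cosine in (0, 1]."""
    if n1 < 1 or n2 < 1:
        raise ValueError("refractive indices must be >= 1")
    if not (0.0 < cos_incident <= 1.0):
        raise ValueError("cos_incident must lie in (0, 1]")
    return float(_fresnel_R(n1, n2, cos_incident))


def refract(direction, normal, n1: float, n2: float):
    """Snell refraction; returns (new_direction, total_internal_reflection).

    ``normal`` must point into the incident medium (direction . normal < 0).
    """
    d = np.asarray(direction, dtype=np.float64)
    n = np.asarray(normal, dtype=np.float64)
    tir, vx, vy, vz = _refract_dir(d[0], d[1], d[2], n[0], n[1], n[2], n1, n2)
    return np.array([vx, vy, vz]), bool(tir)


# ---------------------------------------------------------------------------
# Materials table I/O
# ---------------------------------------------------------------------------

def read_materials_csv(path, reduced_scattering: bool = None) -> dict:
    """Read a materials table (CSV/TSV) into {region: Material}.

    Columns: region, name, mu_a, and either mu_s or mu_s_prime, g, n
    (coefficients mm^-1).  ``reduced_scattering`` forces one interpretation;
    by default the column name decides.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [c.strip() for c in df.columns]
    if reduced_scattering is None:
        reduced_scattering = "mu_s_prime" in df.columns and "mu_s" not in df.columns
    scol = "mu_s_prime" if reduced_scattering else "mu_s"
    if scol not in df.columns:
        raise ValueError(f"materials table lacks a {scol!r} column (have {list(df.columns)})")
    out = {}
    for _, row in df.iterrows():
        if reduced_scattering:
            m = Material.from_reduced(
                int(row["region"]), str(row["name"]), float(row["mu_a"]),
                float(row[scol]), float(row["g"]), float(row["n"]),
            )
        else:
            m = Material(
                int(row["region"]), str(row["name"]), float(row["mu_a"]),
                float(row[scol]), float(row["g"]), float(row["n"]),
            )
        out[m.region] = m
    return out


def write_materials_csv(materials: dict, path) -> None:
    import pandas as pd

    rows = [
        {"region": m.region, "name": m.name, "mu_a": m.mu_a, "mu_s": m.mu_s, "g": m.g, "n": m.n}
        for m in materials.values()
    ]
    with open(path, "w") as fh:
        fh.write("# coefficients in mm^-1\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


def materials_to_arrays(materials: dict, regions_present) -> dict:
    """Dense per-region property arrays for the transport kernel.

    Raises a configuration error listing any mesh region without a material.
    """
    regions_present = np.asarray(regions_present)
    missing = sorted(set(regions_present.tolist()) - set(materials))
    if missing:
        raise ValueError(f"no material defined for mesh regions {missing}")
    nmax = int(max(materials)) + 1
    mu_a = np.zeros(nmax)
    mu_s = np.zeros(nmax)
    g = np.zeros(nmax)
    n = np.ones(nmax)
    for r, m in materials.items():
        mu_a[r], mu_s[r], g[r], n[r] = m.mu_a, m.mu_s, m.g, m.n
    return {"mu_a": mu_a, "mu_s": mu_s, "mu_t": mu_a + mu_s, "g": g, "n": n}
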