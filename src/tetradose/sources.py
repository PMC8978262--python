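"""Light-source models and initial photon-packet sampling.

Six emitter families cover interstitial PDT practice: isotropic point
sources, collimated pencil beams, cut-end fibres emitting into a cone,
cylindrical diffusers (the workhorse of interstitial delivery), isotropic
ball emitters, and surface / volume-region emitters.  Each source samples
emission positions and unit directions in bulk with a seeded numpy
Generator; packets always start with statistical weight 1 and the number
of packets assigned to each source is proportional to its power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Source",
    "PointSource",
    "PencilBeam",
    "ConeFiber",
    "CylDiffuser",
    "BallSource",
    "SurfaceSource",
    "VolumeSource",
    "sample_emission",
    "total_power",
    "discretize_diffuser",
    "allocate_packets",
]


def _unit(v):
    v = np.asarray(v, dtype=np.float64)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("direction/axis must be a nonzero vector")
    return v / n


def _frame(axis):
    """Two unit vectors completing ``axis`` to an orthonormal frame."""
    a = _unit(axis)
    helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return a, e1, e2


def _isotropic(n, rng):
    z = 2.0 * rng.random(n) - 1.0
    phi = 2.0 * np.pi * rng.random(n)
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)


class Source:
    """Base class; concrete sources implement `_sample(n, rng, mesh)`."""

    power: float

    def total_power(self) -> float:
        return self.power

    def _check_power(self):
        if self.total_power() < 0:
            raise ValueError("source power must be >= 0")


@dataclass
class PointSource(Source):
    position: tuple
    power: float = 1.0  # mW

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=np.float64)
        self._check_power()

    def _sample(self, n, rng, mesh=None):
        return np.tile(self.position, (n, 1)), _isotropic(n, rng)


@dataclass
class PencilBeam(Source):
    position: tuple
    direction: tuple
    power: float = 1.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=np.float64)
        self.direction = _unit(self.direction)
        self._check_power()

    def _sample(self, n, rng, mesh=None):
        return np.tile(self.position, (n, 1)), np.tile(self.direction, (n, 1))


@dataclass
class ConeFiber(Source):
    """Cut-end fibre: emission uniform in solid angle within half_angle of the axis."""

    position: tuple
    direction: tuple
    half_angle: float  # rad
    power: float = 1.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=np.float64)
        self.direction = _unit(self.direction)
        if not (0.0 <= self.half_angle <= np.pi):
            raise ValueError("half_angle must lie in [0, pi] radians")
        self._check_power()

    def _sample(self, n, rng, mesh=None):
        a, e1, e2 = _frame(self.direction)
        cmin = np.cos(self.half_angle)
        cz = cmin + (1.0 - cmin) * rng.random(n)
        phi = 2.0 * np.pi * rng.random(n)
        s = np.sqrt(np.maximum(0.0, 1.0 - cz * cz))
        dirs = (
            np.outer(cz, a)
            + np.outer(s * np.cos(phi), e1)
            + np.outer(s * np.sin(phi), e2)
        )
        return np.tile(self.position, (n, 1)), dirs


@dataclass
class CylDiffuser(Source):
    """Cylindrical diffuser emitting from its lateral surface.

    Power may be given directly (mW) or as a linear density (mW/cm) times
    the diffuser length.  ``segment_weights`` shapes the relative emission
    along the length (uniform when omitted); ``emission_law`` is
    'lambertian' (cosine-weighted about the outward surface normal, the
    default) or 'isotropic' (uniform over the outward hemisphere).
    """

    center: tuple
    axis: tuple
    radius: float       # mm
    length: float       # mm
    power: float = None          # mW
    linear_density: float = None  # mW/cm
    segment_weights: np.ndarray = None
    emission_law: str = "lambertian"

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=np.float64)
        self.axis = _unit(self.axis)
        if self.radius < 0 or self.length <= 0:
            raise ValueError("diffuser radius must be >= 0 and length > 0")
        if self.power is None:
            if self.linear_density is None:
                raise ValueError("specify power (mW) or linear_density (mW/cm)")
            self.power = self.linear_density * self.length / 10.0  # mm -> cm
        if self.segment_weights is not None:
            w = np.asarray(self.segment_weights, dtype=np.float64)
            if np.any(w < 0) or w.sum() == 0:
                raise ValueError("segment_weights must be nonnegative and not all zero")
            self.segment_weights = w
        if self.emission_law not in ("lambertian", "isotropic"):
            raise ValueError("emission_law must be 'lambertian' or 'isotropic'")
        self._check_power()

    def _axial(self, n, rng):
        """Axial offset from the centre, distributed per segment_weights."""
        if self.segment_weights is None:
            return (rng.random(n) - 0.5) * self.length
        w = self.segment_weights / self.segment_weights.sum()
        k = len(w)
        seg = rng.choice(k, size=n, p=w)
        return (seg + rng.random(n)) / k * self.length - 0.5 * self.length

    def _sample(self, n, rng, mesh=None):
        a, e1, e2 = _frame(self.axis)
        t = self._axial(n, rng)
        phi = 2.0 * np.pi * rng.random(n)
        er = np.outer(np.cos(phi), e1) + np.outer(np.sin(phi), e2)
        pos = self.center + np.outer(t, a) + self.radius * er
        # local frame: z = outward radial normal
        ephi = np.outer(-np.sin(phi), e1) + np.outer(np.cos(phi), e2)
        if self.emission_law == "lambertian":
            cz = np.sqrt(rng.random(n))
        else:
            cz = rng.random(n)
        psi = 2.0 * np.pi * rng.random(n)
        s = np.sqrt(np.maximum(0.0, 1.0 - cz * cz))
        dirs = (
            cz[:, None] * er
            + (s * np.cos(psi))[:, None] * ephi
            + (s * np.sin(psi))[:, None] * a
        )
        return pos, dirs


@dataclass
class BallSource(Source):
    """Uniform volumetric emitter inside a sphere, isotropic directions."""

    center: tuple
    radius: float
    power: float = 1.0

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=np.float64)
        if self.radius < 0:
            raise ValueError("ball radius must be >= 0")
        self._check_power()

    def _sample(self, n, rng, mesh=None):
        dirs_pos = _isotropic(n, rng)
        r = self.radius * rng.random(n) ** (1.0 / 3.0)
        return self.center + r[:, None] * dirs_pos, _isotropic(n, rng)


@dataclass
class SurfaceSource(Source):
    """Emission from a set of mesh boundary faces, area-weighted.

    ``emission_law``: 'lambertian' (cosine about the inward normal) or
    'isotropic' (uniform over the inward hemisphere).
    """

    faces: np.ndarray  # boundary-face indices into mesh.boundary_faces
    power: float = 1.0
    emission_law: str = "lambertian"

    def __post_init__(self):
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size == 0:
            raise ValueError("surface source needs at least one boundary face")
        if self.emission_law not in ("lambertian", "isotropic"):
            raise ValueError("emission_law must be 'lambertian' or 'isotropic'")
        self._check_power()

    def _sample(self, n, rng, mesh=None):
        if mesh is None:
            raise ValueError("surface sources require the mesh for sampling")
        from .mesh import _FACE_OPP

        areas = mesh.boundary_area[self.faces]
        pick = rng.choice(len(self.faces), size=n, p=areas / areas.sum())
        bf = self.faces[pick]
        tets = mesh.boundary_faces[bf, 0]
        locf = mesh.boundary_faces[bf, 1]
        tri = np.array(
            [mesh.tets[t, list(_FACE_OPP[f])] for t, f in zip(tets, locf)]
        )
        a, b, c = (mesh.vertices[tri[:, i]] for i in range(3))
        u1, u2 = rng.random(n), rng.random(n)
        swap = u1 + u2 > 1
        u1[swap], u2[swap] = 1 - u1[swap], 1 - u2[swap]
        pos = a + u1[:, None] * (b - a) + u2[:, None] * (c - a)
        inward = -mesh.face_normal[tets, locf]
        dirs = np.empty((n, 3))
        for i in range(n):  # per-face frames; n is modest for surface sources
            az, e1, e2 = _frame(inward[i])
            cz = np.sqrt(rng.random()) if self.emission_law == "lambertian" else rng.random()
            psi = 2.0 * np.pi * rng.random()
            s = np.sqrt(max(0.0, 1.0 - cz * cz))
            dirs[i] = cz * az + s * np.cos(psi) * e1 + s * np.sin(psi) * e2
        return pos, dirs


@dataclass
class VolumeSource(Source):
    """A whole mesh region emitting diffusely (volume-weighted, isotropic)."""

    region: int
    power: float = 1.0

    def __post_init__(self):
        self._check_power()

    def _sample(self, n, rng, mesh=None):
        if mesh is None:
            raise ValueError("volume sources require the mesh for sampling")
        idx = np.nonzero(mesh.region == self.region)[0]
        if idx.size == 0:
            raise ValueError(f"mesh has no tets with region {self.region}")
        vols = mesh.volume[idx]
        pick = idx[rng.choice(len(idx), size=n, p=vols / vols.sum())]
        # uniform barycentric coordinates inside each tet
        u = np.sort(rng.random((n, 3)), axis=1)
        bary = np.empty((n, 4))
        bary[:, 0] = u[:, 0]
        bary[:, 1] = u[:, 1] - u[:, 0]
        bary[:, 2] = u[:, 2] - u[:, 1]
        bary[:, 3] = 1.0 - u[:, 2]
        corners = mesh.vertices[mesh.tets[pick]]  # (n, 4, 3)
        pos = np.einsum("nij,ni->nj", corners, bary)
        return pos, _isotropic(n, rng), pick

    # tets are known at sampling time; exposed via the 3-tuple return


def sample_emission(source: Source, n: int, rng, mesh=None):
    """Sample ``n`` packets: (positions, directions, tet indices or None)."""
    out = source._sample(n, rng, mesh=mesh)
    if len(out) == 3:
        return out
    pos, dirs = out
    return pos, dirs, None


def total_power(sources) -> float:
    """Total emitted power in mW (linear-density diffusers included)."""
    return float(sum(s.total_power() for s in sources))


def discretize_diffuser(d: CylDiffuser, k: int):
    """Split a diffuser into ``k`` contiguous equal-length segment sources.

    Segment powers follow ``segment_weights`` (uniform when absent); with
    uniform weights the union of segments emits identically to the parent.
    """
    if k < 1:
        raise ValueError("segment count k must be >= 1")
    if d.segment_weights is not None and len(d.segment_weights) != k:
        raise ValueError("segment_weights length must equal k")
    w = (
        np.ones(k) / k
        if d.segment_weights is None
        else d.segment_weights / d.segment_weights.sum()
    )
    seg_len = d.length / k
    out = []
    for i in range(k):
        offset = (i + 0.5) * seg_len - 0.5 * d.length
        out.append(
            CylDiffuser(
                center=d.center + offset * d.axis,
                axis=d.axis,
                radius=d.radius,
                length=seg_len,
                power=d.total_power() * w[i],
                emission_law=d.emission_law,
            )
        )
    return out


def allocate_packets(sources, n_packets: int, rng) -> np.ndarray:
    """Packets per source, proportional to power (stratified; remainders random)."""
    powers = np.array([s.total_power() for s in sources], dtype=np.float64)
    total = powers.sum()
    if total <= 0:
        out = np.zeros(len(sources), dtype=np.int64)
        out[0] = n_packets
        return out
    exact = n_packets * powers / total
    counts = np.floor(exact).astype(np.int64)
    short = n_packets - counts.sum()
    if short > 0:
        frac = exact - counts
        if frac.sum() == 0:
            frac = powers
        extra = rng.choice(len(sources), size=int(short), p=frac / frac.sum())
        np.add.at(counts, extra, 1)
    return counts
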