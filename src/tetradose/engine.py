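"""Photon-packet transport through tetrahedral meshes.

The kernel implements the classic weighted hop/drop/spin scheme: packets
take exponentially distributed dimensionless steps, deposit the fraction
mu_a/mu_t of their weight at each interaction, scatter through
Henyey-Greenstein angles, and are terminated unbiasedly by Russian
roulette.  Between interactions packets are traced tet-to-tet through the
mesh; at faces where the refractive index changes, an unpolarised Fresnel
draw decides between specular reflection and Snell refraction.  Regions
with mu_t = 0 are crossed geometrically (their fluence is recoverable via
the track-length estimator, which is accumulated everywhere).

Every run maintains a conservation ledger: emitted weight must equal
absorbed + exited + the net Russian-roulette balance to floating-point
accuracy; the residual is checked on every simulation.

Reproducibility: packet i draws from its own counter-derived stream keyed
on (seed, i), so a run is bitwise deterministic for a fixed seed
regardless of how packets are batched.  The ``threads`` field of
:class:`SimConfig` is a forward-compatibility contract only; this
implementation always traces serially.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .mesh import GeometryError, NUDGE, TetraMesh
from .optics import _fresnel_R, _hg_cos, _spin, materials_to_arrays
from .sources import allocate_packets, sample_emission

__all__ = ["SimConfig", "RawScore", "sample_step", "run_mc", "propagate"]


@dataclass
class SimConfig:
    """Monte Carlo run parameters.

    The 10^6 packet default follows standard practice for plan-guiding
    accuracy; roulette threshold/survival follow the MCML convention.
    """

    n_packets: int = 1_000_000
    seed: int = 0
    roulette_threshold: float = 1e-5
    roulette_survival: float = 0.1
    max_steps: int = 1_000_000
    threads: int = 1  # contract only; tracing is serial
    n_ambient: float = 1.0  # refractive index outside the mesh
    score_volume_absorption: bool = True
    score_surface_exit: bool = True

    def __post_init__(self):
        if self.n_packets < 1:
            raise ValueError("n_packets must be >= 1")
        if not (0.0 < self.roulette_survival < 1.0):
            raise ValueError("roulette_survival must lie in (0, 1)")


@dataclass
class RawScore:
    """Per-tet absorbed energy, per-boundary-face exit energy and the ledger.

    ``absorbed``/``exited``/``tracklen`` are normalised to fractions of the
    emitted energy (tracklen in mm of weighted path per unit emitted
    weight); the ledger keeps raw packet-weight units.
    """

    absorbed: np.ndarray       # (n_tets,) fraction of emitted energy
    exited: np.ndarray         # (n_boundary_faces,) fraction of emitted energy
    tracklen: np.ndarray       # (n_tets,) weighted mm per unit emitted weight
    ledger: dict = field(default_factory=dict)

    @property
    def residual_relative(self) -> float:
        return abs(self.ledger["residual"]) / self.ledger["emitted"]


def sample_step(mu_t: float, u: float) -> float:
    """Exponential free path: s = -ln(u)/mu_t (mm); infinite when mu_t = 0."""
    if not (0.0 < u <= 1.0):
        raise ValueError("u must lie in (0, 1]")
    if mu_t < 0:
        raise ValueError("mu_t must be >= 0")
    if mu_t == 0.0:
        return math.inf
    return -math.log(u) / mu_t


# ---------------------------------------------------------------------------
# Counter-based per-packet RNG (splitmix64 streams)
# ---------------------------------------------------------------------------

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_STREAM = np.uint64(0xD1B54A32D192ED03)
_INV53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True, inline="always")
def _finalize(z):
    z = (z ^ (z >> np.uint64(30))) * _MIX1
    z = (z ^ (z >> np.uint64(27))) * _MIX2
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _init_state(seed, i):
    z = np.uint64(seed) * _GOLDEN + np.uint64(i) * _STREAM
    return _finalize(_finalize(z))


@njit(cache=True, inline="always")
def _next_uniform(state):
    """Advance the stream; returns (state, u) with u in (0, 1]."""
    state = state + _GOLDEN
    z = _finalize(state)
    return state, float((z >> np.uint64(11)) + np.uint64(1)) * _INV53


# ---------------------------------------------------------------------------
# Transport kernel
# ---------------------------------------------------------------------------

_FASTMATH = {"contract", "arcp", "nsz", "afn", "reassoc"}  # keep NaN/inf semantics


@njit(cache=True, fastmath=_FASTMATH)
def _trace_all(
    face_normal, face_offset, adjacency, boundary_face_id, region,
    mu_a, mu_s, mu_t, g_arr, n_arr, n_ambient,
    pos, dirs, tet0, seed,
    w_thresh, p_surv, max_steps, nudge,
    absorbed, exited, tracklen, rr_out,
):
    """Trace every packet; returns the count of unrecoverable traversal errors.

    Scores are accumulated into the caller's arrays; ``rr_out[i]`` holds
    packet i's net Russian-roulette balance (kills minus survivor gains)
    so the ledger can be summed accurately outside the kernel.
    """
    n_packets = pos.shape[0]
    geom_errors = 0

    for i in range(n_packets):
        state = _init_state(seed, i)
        px, py, pz = pos[i, 0], pos[i, 1], pos[i, 2]
        ux, uy, uz = dirs[i, 0], dirs[i, 1], dirs[i, 2]
        tet = tet0[i]
        w = 1.0
        rr = 0.0
        state, u = _next_uniform(state)
        s = -math.log(u)  # dimensionless remaining step
        alive = True
        steps = 0
        relocated = False

        while alive:
            steps += 1
            if steps > max_steps:
                rr += w  # truncation sink keeps the ledger balanced
                break
            reg = region[tet]
            mt = mu_t[reg]

            # distance to the first face crossed
            best_t = np.inf
            best_f = -1
            for f in range(4):
                denom = (
                    face_normal[tet, f, 0] * ux
                    + face_normal[tet, f, 1] * uy
                    + face_normal[tet, f, 2] * uz
                )
                if denom <= 1e-12:
                    continue
                dd = face_offset[tet, f] - (
                    face_normal[tet, f, 0] * px
                    + face_normal[tet, f, 1] * py
                    + face_normal[tet, f, 2] * pz
                )
                tt = dd / denom
                if tt < -1e-7:
                    continue
                if tt < 0.0:
                    tt = 0.0
                if tt < best_t:
                    best_t = tt
                    best_f = f
            if best_f < 0:
                # corner/edge crossing seated the packet in the wrong tet:
                # walk the adjacency graph to the cell containing the point
                if not relocated:
                    relocated = True
                    found = tet
                    lost = False
                    for _ in range(4096):
                        worst = -1.0
                        worst_f = -1
                        for f in range(4):
                            sdist = (
                                face_normal[found, f, 0] * px
                                + face_normal[found, f, 1] * py
                                + face_normal[found, f, 2] * pz
                                - face_offset[found, f]
                            )
                            if sdist > worst:
                                worst = sdist
                                worst_f = f
                        if worst <= 1e-9:
                            break
                        nxt = adjacency[found, worst_f]
                        if nxt < 0:
                            # walked out of the mesh: score the exit
                            exited[boundary_face_id[found, worst_f]] += w
                            alive = False
                            lost = True
                            break
                        found = nxt
                    if not alive:
                        break
                    if not lost and found != tet:
                        tet = found
                        continue
                geom_errors += 1
                rr += w
                break
            relocated = False

            phys = s / mt if mt > 0.0 else np.inf

            if best_t <= phys:
                # ---- hop to the face
                tracklen[tet] += w * best_t
                if mt > 0.0:
                    s -= best_t * mt
                px += best_t * ux
                py += best_t * uy
                pz += best_t * uz
                nb = adjacency[tet, best_f]
                n1 = n_arr[reg]
                n2 = n_ambient if nb < 0 else n_arr[region[nb]]
                if n1 == n2:
                    if nb < 0:
                        exited[boundary_face_id[tet, best_f]] += w
                        alive = False
                    else:
                        tet = nb
                        px += nudge * ux
                        py += nudge * uy
                        pz += nudge * uz
                else:
                    nx = face_normal[tet, best_f, 0]
                    ny = face_normal[tet, best_f, 1]
                    nz = face_normal[tet, best_f, 2]
                    cos_i = ux * nx + uy * ny + uz * nz  # > 0 (outward normal)
                    if cos_i > 1.0:
                        cos_i = 1.0
                    R = _fresnel_R(n1, n2, cos_i)
                    state, u = _next_uniform(state)
                    if u <= R:
                        # specular reflection back into the current tet
                        ux -= 2.0 * cos_i * nx
                        uy -= 2.0 * cos_i * ny
                        uz -= 2.0 * cos_i * nz
                        px += nudge * ux
                        py += nudge * uy
                        pz += nudge * uz
                    else:
                        # Snell refraction across the face
                        ratio = n1 / n2
                        sin_t2 = ratio * ratio * (1.0 - cos_i * cos_i)
                        cos_t = math.sqrt(max(0.0, 1.0 - sin_t2))
                        k = ratio * cos_i - cos_t
                        ux = ratio * ux - k * nx
                        uy = ratio * uy - k * ny
                        uz = ratio * uz - k * nz
                        norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                        ux /= norm
                        uy /= norm
                        uz /= norm
                        if nb < 0:
                            exited[boundary_face_id[tet, best_f]] += w
                            alive = False
                        else:
                            tet = nb
                            px += nudge * ux
                            py += nudge * uy
                            pz += nudge * uz
            else:
                # ---- interaction inside the tet
                tracklen[tet] += w * phys
                px += phys * ux
                py += phys * uy
                pz += phys * uz
                dep = w * mu_a[reg] / mt
                if dep > 0.0:
                    absorbed[tet] += dep
                    w -= dep
                if w <= 0.0:
                    alive = False
                else:
                    state, u = _next_uniform(state)
                    cos_sc = _hg_cos(g_arr[reg], u)
                    state, u = _next_uniform(state)
                    ux, uy, uz = _spin(ux, uy, uz, cos_sc, 2.0 * math.pi * u)
                    if w < w_thresh:
                        state, u = _next_uniform(state)
                        if u <= p_surv:
                            rr -= w * (1.0 / p_surv - 1.0)
                            w /= p_surv
                        else:
                            rr += w
                            alive = False
                    if alive:
                        state, u = _next_uniform(state)
                        s = -math.log(u)

        rr_out[i] = rr

    return geom_errors


def _seat_packets(mesh, sources, counts, rng):
    """Sample emission for every source and seat packets in their tets."""
    from .mesh import locate_points

    pos_all, dir_all, tet_all = [], [], []
    for src, cnt in zip(sources, counts):
        if cnt == 0:
            continue
        pos, dirs, tets = sample_emission(src, int(cnt), rng, mesh=mesh)
        if tets is None:
            tets = locate_points(mesh, pos)
            if np.any(tets < 0):
                bad = np.nonzero(tets < 0)[0][0]
                raise ValueError(
                    f"source {type(src).__name__} emits outside the mesh "
                    f"(first offending position {pos[bad].tolist()} mm)"
                )
        pos_all.append(pos)
        dir_all.append(dirs)
        tet_all.append(np.asarray(tets, dtype=np.int64))
    return (
        np.ascontiguousarray(np.concatenate(pos_all)),
        np.ascontiguousarray(np.concatenate(dir_all)),
        np.ascontiguousarray(np.concatenate(tet_all)),
    )


def run_mc(mesh: TetraMesh, materials: dict, sources, config: SimConfig) -> RawScore:
    """Trace ``config.n_packets`` packets and return the scored energies.

    Packets are allocated to sources proportionally to power; the result is
    bitwise reproducible for identical inputs and seed.
    """
    arrays = materials_to_arrays(materials, mesh.regions_present())
    rng = np.random.default_rng(config.seed)
    counts = allocate_packets(sources, config.n_packets, rng)
    pos, dirs, tets = _seat_packets(mesh, sources, counts, rng)

    nt = mesh.n_tets
    absorbed = np.zeros(nt)
    exited = np.zeros(mesh.n_boundary_faces)
    tracklen = np.zeros(nt)
    rr_out = np.zeros(config.n_packets)

    geom_errors = _trace_all(
        mesh.face_normal, mesh.face_offset, mesh.adjacency, mesh.boundary_face_id,
        mesh.region,
        arrays["mu_a"], arrays["mu_s"], arrays["mu_t"], arrays["g"], arrays["n"],
        float(config.n_ambient),
        pos, dirs, tets, int(config.seed) & 0x7FFFFFFF,
        float(config.roulette_threshold), float(config.roulette_survival),
        int(config.max_steps), NUDGE,
        absorbed, exited, tracklen, rr_out,
    )
    if geom_errors:
        raise GeometryError(
            f"{geom_errors} packets lost to traversal failures; "
            "the mesh or packet seating is corrupted"
        )

    abs_tot = float(absorbed.sum())
    exi_tot = float(exited.sum())
    rr_net = float(rr_out.sum())
    emitted = float(config.n_packets)
    ledger = {
        "emitted": emitted,
        "absorbed_total": abs_tot,
        "exited_total": exi_tot,
        "roulette_net": rr_net,
        "residual": emitted - abs_tot - exi_tot - rr_net,
    }
    return RawScore(
        absorbed=absorbed / emitted,
        exited=exited / emitted,
        tracklen=tracklen / emitted,
        ledger=ledger,
    )


def propagate(mesh, materials, position, direction, tet, seed=0, config=None):
    """Trace a single packet (diagnostic convenience over the batch kernel)."""
    config = config or SimConfig(n_packets=1, seed=seed)
    arrays = materials_to_arrays(materials, mesh.regions_present())
    absorbed = np.zeros(mesh.n_tets)
    exited = np.zeros(mesh.n_boundary_faces)
    tracklen = np.zeros(mesh.n_tets)
    pos = np.asarray(position, dtype=np.float64)[None, :]
    d = np.asarray(direction, dtype=np.float64)
    d = d / np.linalg.norm(d)
    rr_out = np.zeros(1)
    geom_errors = _trace_all(
        mesh.face_normal, mesh.face_offset, mesh.adjacency, mesh.boundary_face_id,
        mesh.region,
        arrays["mu_a"], arrays["mu_s"], arrays["mu_t"], arrays["g"], arrays["n"],
        float(config.n_ambient),
        pos, d[None, :], np.array([tet], dtype=np.int64), int(seed) & 0x7FFFFFFF,
        float(config.roulette_threshold), float(config.roulette_survival),
        int(config.max_steps), NUDGE,
        absorbed, exited, tracklen, rr_out,
    )
    if geom_errors:
        raise GeometryError("packet lost to a traversal failure")
    abs_tot = float(absorbed.sum())
    exi_tot = float(exited.sum())
    rr_net = float(rr_out.sum())
    ledger = {
        "emitted": 1.0,
        "absorbed_total": abs_tot,
        "exited_total": exi_tot,
        "roulette_net": rr_net,
        "residual": 1.0 - abs_tot - exi_tot - rr_net,
    }
    return RawScore(absorbed=absorbed, exited=exited, tracklen=tracklen, ledger=ledger)
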