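"""Synthetic Langevin channel trajectories.

Generates the statistical structure the TST water-permeation analysis
assumes, without any MD engine: thermalized particles moving along a
finite channel (an axial potential of mean force U(z), flat in two bulk
reservoirs) between reflecting walls, integrated with inertial (velocity
Verlet + Ornstein–Uhlenbeck, "BAOAB") Langevin dynamics so that the
stationary velocity distribution is Maxwell–Boltzmann — the property the
TST flux prefactor √(RT/2πm) rests on — and the stationary position
distribution is Boltzmann, ∝ exp(−U(z)/RT).

Every stage of the pipeline is testable against this generator: plane-
crossing rates against the analytic Maxwell flux, densities against the
Boltzmann law, recrossing statistics against brute-force traversal
counting, and the Arrhenius machinery against an imposed barrier height.

Units: Å, ps, kcal/mol, g/mol, Kelvin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Sequence

import numpy as np
from numba import njit

from .errors import ConfigurationError, DataError
from .trajectory import ChannelFrame, ParticleTrack, TrajectoryBundle

#: gas constant, kcal / (mol K)
R_KCAL = 8.314462618 / 4184.0

#: acceleration unit: (kcal/mol/Å) / (g/mol)  ->  Å/ps²
ACC = 418.4


@dataclass(frozen=True)
class LangevinSpec:
    """Full parameterization of the synthetic channel world.

    A single Gaussian barrier of height ``barrier_height`` (kcal/mol) and
    width ``barrier_width`` (Å, standard deviation) sits at z = 0 — the
    dividing plane; ``potential`` may instead supply an arbitrary U(z)
    callable (kcal/mol), evaluated on an internal grid.  The channel
    occupies |z| < ``channel_halfwidth`` (its edges map to the bulk
    thresholds); beyond it lie flat reservoirs out to reflecting walls at
    ±``box_z``/2, emulating the bulk water layers flanking a membrane.

    ``friction`` (ps⁻¹) sets the velocity decorrelation time 1/γ; the
    default 10 ps⁻¹ gives liquid-like diffusivity for a water-mass
    particle.  ``single_file`` switches on hard-core exclusion of
    diameter ``sigma`` so particles cannot pass one another;
    ``lateral_mode="cylinder"`` adds free x–y motion inside a reflecting
    cylinder of radius ``cylinder_radius``.
    """

    temperature: float = 298.15  # K
    mass: float = 18.01528  # g/mol
    friction: float = 10.0  # 1/ps
    dt: float = 0.002  # ps
    n_steps: int = 100_000
    save_stride: int = 1
    n_particles: int = 50
    box_z: float = 60.0  # Å (reflecting walls at +-box_z/2)
    channel_halfwidth: float = 15.0  # Å
    barrier_height: float = 0.0  # kcal/mol
    barrier_width: float = 1.5  # Å
    potential: Callable[[np.ndarray], np.ndarray] | None = None
    lateral_mode: str = "none"  # "none" | "cylinder"
    cylinder_radius: float = 6.0  # Å
    single_file: bool = False
    sigma: float = 2.6  # Å, hard-core diameter in single-file mode
    seed: int = 0
    save_velocities: bool = True
    #: "iid" draws each initial position independently from the
    #: Boltzmann law; "stratified" assigns particle i the random
    #: quantile (i + u)/N — the pooled ensemble is then *exactly*
    #: Boltzmann-distributed from the first frame (no binomial
    #: reservoir-population noise), at the cost of per-particle
    #: marginals depending on n_particles.
    init: str = "iid"

    def __post_init__(self) -> None:
        if self.init not in ("iid", "stratified"):
            raise ConfigurationError(f"unknown init mode {self.init!r}")
        if self.dt <= 0 or self.friction < 0:
            raise ConfigurationError("dt must be > 0 and friction >= 0")
        if self.n_particles < 1 or self.save_stride < 1 or self.n_steps < 1:
            raise ConfigurationError(
                "n_particles, n_steps and save_stride must be >= 1")
        if not 0 < self.channel_halfwidth < self.box_z / 2:
            raise ConfigurationError(
                "need 0 < channel_halfwidth < box_z/2 (room for reservoirs)")
        if self.single_file and self.sigma <= 0:
            raise ConfigurationError("single_file mode needs sigma > 0")
        if self.lateral_mode not in ("none", "cylinder"):
            raise ConfigurationError(f"unknown lateral_mode {self.lateral_mode!r}")

    @property
    def n_frames(self) -> int:
        return self.n_steps // self.save_stride

    @property
    def dt_frame(self) -> float:
        return self.dt * self.save_stride

    @property
    def thermal_speed2(self) -> float:
        """RT/m in Å²/ps² (variance of each velocity component)."""
        return R_KCAL * self.temperature * ACC / self.mass


def potential_on_grid(spec: LangevinSpec,
                      spacing: float = 0.02) -> tuple[np.ndarray, np.ndarray]:
    """U(z) (kcal/mol) on a uniform grid spanning the box."""
    half = spec.box_z / 2.0
    n = int(np.ceil(spec.box_z / spacing)) + 1
    z = np.linspace(-half, half, n)
    if spec.potential is not None:
        u = np.asarray(spec.potential(z), dtype=float)
        if u.shape != z.shape:
            raise ConfigurationError("potential(z) must be vectorized over z")
    else:
        u = spec.barrier_height * np.exp(
            -(z**2) / (2.0 * spec.barrier_width**2))
    return z, u


def channel_frame(spec: LangevinSpec,
                  monomer_id: str = "synthetic") -> ChannelFrame:
    """The channel frame matching a synthetic world (plane at z = 0)."""
    return ChannelFrame(
        monomer_id=monomer_id,
        z_divide=0.0,
        z_bulk_ec=spec.channel_halfwidth,
        z_bulk_ic=-spec.channel_halfwidth,
        radius_gate=spec.cylinder_radius
        if spec.lateral_mode == "cylinder" else 1e9,
    )


def _stability_check(spec: LangevinSpec) -> None:
    """Refuse clearly unstable parameters; warn on marginal ones."""
    gdt = spec.friction * spec.dt
    z, u = potential_on_grid(spec)
    curv = np.max(np.abs(np.gradient(np.gradient(u, z), z))) if u.any() else 0.0
    omega = math.sqrt(curv * ACC / spec.mass) if curv > 0 else 0.0
    odt = omega * spec.dt
    if gdt > 1.0 or odt > 1.0:
        raise ConfigurationError(
            f"unstable integration: friction*dt={gdt:.3g}, "
            f"barrier-frequency*dt={odt:.3g}; reduce dt"
        )
    if gdt > 0.2 or odt > 0.3:
        warnings.warn(
            f"marginal integration accuracy (friction*dt={gdt:.3g}, "
            f"barrier-frequency*dt={odt:.3g})"
        )


@njit(cache=True)
def _baoab_1d(z, v, n_steps, dt, c1, c2, agrid, gmin, ginv,
              zmin, zmax, save_stride, out_z, out_v, save_v, seed):
    """BAOAB Langevin integration of one particle on an acceleration grid.

    ``agrid`` holds F(z)/m in Å/ps² on a uniform grid; linear
    interpolation in between; reflecting walls at zmin/zmax.
    """
    np.random.seed(seed)
    half = 0.5 * dt
    nf = agrid.shape[0] - 2
    k = 0
    for i in range(n_steps):
        x = (z - gmin) * ginv
        j = int(x)
        if j < 0:
            j = 0
        elif j > nf:
            j = nf
        w = x - j
        v += half * (agrid[j] * (1.0 - w) + agrid[j + 1] * w)
        z += half * v
        v = c1 * v + c2 * np.random.normal()
        z += half * v
        if z > zmax:
            z = 2.0 * zmax - z
            v = -v
        elif z < zmin:
            z = 2.0 * zmin - z
            v = -v
        x = (z - gmin) * ginv
        j = int(x)
        if j < 0:
            j = 0
        elif j > nf:
            j = nf
        w = x - j
        v += half * (agrid[j] * (1.0 - w) + agrid[j + 1] * w)
        if (i + 1) % save_stride == 0:
            out_z[k] = z
            if save_v:
                out_v[k] = v
            k += 1
    return z, v


@njit(cache=True)
def _baoab_lateral(x, y, vx, vy, n_steps, dt, c1, c2, radius,
                   save_stride, out_x, out_y, seed):
    """Free x-y Langevin motion inside a reflecting cylinder."""
    np.random.seed(seed)
    half = 0.5 * dt
    r2max = radius * radius
    k = 0
    for i in range(n_steps):
        x += half * vx
        y += half * vy
        vx = c1 * vx + c2 * np.random.normal()
        vy = c1 * vy + c2 * np.random.normal()
        x += half * vx
        y += half * vy
        r2 = x * x + y * y
        if r2 > r2max:
            r = math.sqrt(r2)
            nx = x / r
            ny = y / r
            # fold position back inside and reflect the radial velocity
            over = r - radius
            x -= 2.0 * over * nx
            y -= 2.0 * over * ny
            vr = vx * nx + vy * ny
            vx -= 2.0 * vr * nx
            vy -= 2.0 * vr * ny
        if (i + 1) % save_stride == 0:
            out_x[k] = x
            out_y[k] = y
            k += 1


@njit(cache=True)
def _baoab_single_file(z, v, n_steps, dt, c1, c2, agrid, gmin, ginv,
                       zmin, zmax, sigma, save_stride, out_z, seed):
    """Joint BAOAB update of an ordered chain with hard-core exclusion.

    After each step, overlapping neighbours are pushed apart
    symmetrically and exchange velocities (elastic collision of equal
    masses); particle order along z is preserved for all time.
    """
    np.random.seed(seed)
    n = z.shape[0]
    half = 0.5 * dt
    nf = agrid.shape[0] - 2
    k = 0
    for i in range(n_steps):
        for p in range(n):
            x = (z[p] - gmin) * ginv
            j = int(x)
            if j < 0:
                j = 0
            elif j > nf:
                j = nf
            w = x - j
            v[p] += half * (agrid[j] * (1.0 - w) + agrid[j + 1] * w)
            z[p] += half * v[p]
            v[p] = c1 * v[p] + c2 * np.random.normal()
            z[p] += half * v[p]
            if z[p] > zmax:
                z[p] = 2.0 * zmax - z[p]
                v[p] = -v[p]
            elif z[p] < zmin:
                z[p] = 2.0 * zmin - z[p]
                v[p] = -v[p]
            x = (z[p] - gmin) * ginv
            j = int(x)
            if j < 0:
                j = 0
            elif j > nf:
                j = nf
            w = x - j
            v[p] += half * (agrid[j] * (1.0 - w) + agrid[j + 1] * w)
        # resolve hard-core overlaps (two sweeps keep the chain ordered)
        for _ in range(2):
            for p in range(n - 1):
                gap = z[p + 1] - z[p]
                if gap < sigma:
                    mid = 0.5 * (z[p] + z[p + 1])
                    z[p] = mid - 0.5 * sigma
                    z[p + 1] = mid + 0.5 * sigma
                    tmp = v[p]
                    v[p] = v[p + 1]
                    v[p + 1] = tmp
        if (i + 1) % save_stride == 0:
            for p in range(n):
                out_z[k, p] = z[p]
            k += 1


def _acceleration_grid(spec: LangevinSpec) -> tuple[np.ndarray, float, float]:
    zg, u = potential_on_grid(spec)
    force = -np.gradient(u, zg)  # kcal/mol/Å
    agrid = force * ACC / spec.mass  # Å/ps²
    ginv = 1.0 / (zg[1] - zg[0])
    return agrid, float(zg[0]), float(ginv)


def _boltzmann_sampler(spec: LangevinSpec):
    """Inverse-CDF sampler of the stationary position law ∝ exp(−U/RT)."""
    zg, u = potential_on_grid(spec, spacing=0.05)
    w = np.exp(-(u - u.min()) / (R_KCAL * spec.temperature))
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1])
                                           * np.diff(zg))])
    cdf /= cdf[-1]

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return np.interp(rng.random(n), cdf, zg)

    return sample


def stationary_position_cdf(spec: LangevinSpec) -> tuple[np.ndarray, np.ndarray]:
    """(z, CDF(z)) of the analytic Boltzmann position law for this spec."""
    zg, u = potential_on_grid(spec, spacing=0.05)
    w = np.exp(-(u - u.min()) / (R_KCAL * spec.temperature))
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1])
                                           * np.diff(zg))])
    return zg, cdf / cdf[-1]


def _particle_seeds(spec: LangevinSpec) -> list[tuple[np.random.Generator, int]]:
    """Stable per-particle RNG streams split from the master seed.

    Stream i is derived from SeedSequence(seed).spawn()[i], so enlarging
    n_particles extends the ensemble without reshuffling existing
    particles' noise.
    """
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_particles)
    out = []
    for child in children:
        rng = np.random.default_rng(child)
        kernel_seed = int(child.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
        out.append((rng, kernel_seed))
    return out


def iter_tracks(spec: LangevinSpec) -> Iterator[ParticleTrack]:
    """Simulate and yield one particle track at a time (O(track) memory).

    Particles are mutually independent (requires ``single_file=False``);
    initial positions are drawn from the stationary Boltzmann law and
    velocities from Maxwell–Boltzmann, so the ensemble is stationary from
    the first frame.  Deterministic given ``spec.seed``.
    """
    if spec.single_file:
        raise ConfigurationError(
            "single-file particles interact; use simulate()")
    _stability_check(spec)
    agrid, gmin, ginv = _acceleration_grid(spec)
    sample_z = _boltzmann_sampler(spec)
    vth = math.sqrt(spec.thermal_speed2)
    c1 = math.exp(-spec.friction * spec.dt)
    c2 = math.sqrt((1.0 - c1 * c1) * spec.thermal_speed2)
    half_box = spec.box_z / 2.0
    times = np.arange(1, spec.n_frames + 1) * spec.dt_frame
    gate = spec.cylinder_radius
    zg_cdf = stationary_position_cdf(spec) if spec.init == "stratified" \
        else None

    for pid, (rng, kseed) in enumerate(_particle_seeds(spec)):
        if zg_cdf is not None:
            u = (pid + rng.random()) / spec.n_particles
            z0 = float(np.interp(u, zg_cdf[1], zg_cdf[0]))
        else:
            z0 = float(sample_z(rng, 1)[0])
        v0 = float(rng.normal(0.0, vth))
        out_z = np.empty(spec.n_frames)
        out_v = np.empty(spec.n_frames if spec.save_velocities else 0)
        _baoab_1d(z0, v0, spec.n_steps, spec.dt, c1, c2, agrid, gmin, ginv,
                  -half_box, half_box, spec.save_stride, out_z, out_v,
                  spec.save_velocities, kseed)
        lateral_ok = None
        if spec.lateral_mode == "cylinder":
            r0 = gate * math.sqrt(rng.random())
            th = rng.random() * 2 * math.pi
            out_x = np.empty(spec.n_frames)
            out_y = np.empty(spec.n_frames)
            _baoab_lateral(r0 * math.cos(th), r0 * math.sin(th),
                           float(rng.normal(0, vth)), float(rng.normal(0, vth)),
                           spec.n_steps, spec.dt, c1, c2, gate,
                           spec.save_stride, out_x, out_y, kseed + 1)
            in_slab = np.abs(out_z) < spec.channel_halfwidth
            r = np.hypot(out_x, out_y)
            lateral_ok = np.where(in_slab, r <= gate, True)
        yield ParticleTrack(
            particle_id=pid,
            times=times,
            z=out_z,
            vz=out_v if spec.save_velocities else None,
            lateral_ok=lateral_ok,
        )


def simulate(spec: LangevinSpec, monomer_id: str = "synthetic") -> TrajectoryBundle:
    """Simulate the full ensemble into a :class:`TrajectoryBundle`."""
    if spec.n_frames < 2:
        raise ConfigurationError("need n_steps/save_stride >= 2 frames")
    if spec.single_file:
        tracks = _simulate_single_file(spec)
    else:
        tracks = list(iter_tracks(spec))
    return TrajectoryBundle(
        frames_count=spec.n_frames,
        dt_frame=spec.dt_frame,
        tracks={monomer_id: tracks},
        temperature=spec.temperature,
        box=np.array([spec.box_z, spec.box_z, spec.box_z]),
    )


def _simulate_single_file(spec: LangevinSpec) -> list[ParticleTrack]:
    _stability_check(spec)
    agrid, gmin, ginv = _acceleration_grid(spec)
    half_box = spec.box_z / 2.0
    n = spec.n_particles
    if n * spec.sigma > spec.box_z:
        raise ConfigurationError("particles do not fit in the box at sigma")
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss)
    kseed = int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
    # evenly spaced start (ordered), Maxwellian velocities
    pad = 0.5 * spec.sigma
    z = np.linspace(-half_box + pad, half_box - pad, n)
    v = rng.normal(0.0, math.sqrt(spec.thermal_speed2), n)
    c1 = math.exp(-spec.friction * spec.dt)
    c2 = math.sqrt((1.0 - c1 * c1) * spec.thermal_speed2)
    out_z = np.empty((spec.n_frames, n))
    _baoab_single_file(z.copy(), v.copy(), spec.n_steps, spec.dt, c1, c2,
                       agrid, gmin, ginv, -half_box, half_box, spec.sigma,
                       spec.save_stride, out_z, kseed)
    times = np.arange(1, spec.n_frames + 1) * spec.dt_frame
    return [
        ParticleTrack(particle_id=p, times=times, z=out_z[:, p])
        for p in range(n)
    ]


def make_arrhenius_pair(
    spec: LangevinSpec, T1: float, T2: float
) -> tuple[TrajectoryBundle, TrajectoryBundle]:
    """Two simulations identical except for temperature.

    Seeds are derived from the spec's master seed per temperature index,
    so the two runs are independent but jointly reproducible.  The
    pipeline-estimated activation energy grows with the imposed barrier
    height (free diffusion contributes only the weak √T dependence of
    the thermal flux).
    """
    spec1, spec2 = arrhenius_pair_specs(spec, T1, T2)
    return simulate(spec1), simulate(spec2)


def arrhenius_pair_specs(
    spec: LangevinSpec, T1: float, T2: float
) -> tuple[LangevinSpec, LangevinSpec]:
    """The two temperature specs of :func:`make_arrhenius_pair`."""
    if T1 == T2:
        raise ConfigurationError("T1 and T2 must differ")
    base = np.random.SeedSequence(spec.seed)
    s1, s2 = base.spawn(2)
    seed1 = int(s1.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
    seed2 = int(s2.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
    return (
        replace(spec, temperature=T1, seed=seed1),
        replace(spec, temperature=T2, seed=seed2),
    )


# ---------------------------------------------------------------------------
# deterministic fixtures
# ---------------------------------------------------------------------------

def make_event_fixture(
    script: Sequence[tuple[int, Sequence[float]]] | Sequence[Sequence[float]],
    dt_frame: float = 1.0,
) -> TrajectoryBundle:
    """Tracks that pass exactly through scripted z waypoints.

    ``script`` is a list of waypoint series (optionally (particle_id,
    series) pairs); consecutive waypoints become consecutive frames.
    """
    entries = []
    for i, item in enumerate(script):
        if (isinstance(item, tuple) and len(item) == 2
                and np.isscalar(item[0])):
            pid, wp = item
        else:
            pid, wp = i, item
        entries.append((int(pid), np.asarray(wp, dtype=float)))
    n_frames = max((len(wp) for _, wp in entries), default=2)
    n_frames = max(n_frames, 2)
    tracks = [
        ParticleTrack(
            particle_id=pid,
            times=np.arange(len(wp)) * dt_frame,
            z=wp,
        )
        for pid, wp in entries
        if len(wp) >= 1
    ]
    return TrajectoryBundle(
        frames_count=n_frames,
        dt_frame=dt_frame,
        tracks={"M0": tracks},
    )


#: TIP3P-like geometry for the hydrogen-bond fixture
_OH_BOND = 0.9572  # Å
_HOH_ANGLE = math.radians(104.52)


def make_hbond_fixture(n_waters: int, spacing: float, aligned: bool = True):
    """Single-frame linear water chain along z, as an MDAnalysis Universe.

    ``aligned=True`` points each water's first hydrogen at the next
    oxygen (collinear donor geometry → exactly N−1 water–water hydrogen
    bonds for spacing ≤ the distance cutoff); ``aligned=False`` holds
    both hydrogens perpendicular to the chain axis (ground truth 0).
    """
    import MDAnalysis as mda

    if n_waters < 2 or spacing <= 0:
        raise ConfigurationError("need n_waters >= 2 and spacing > 0")
    coords = np.zeros((3 * n_waters, 3))
    for i in range(n_waters):
        o = np.array([0.0, 0.0, i * spacing])
        if aligned:
            h1 = o + np.array([0.0, 0.0, _OH_BOND])
            # second hydrogen off-axis at the water bond angle
            h2 = o + _OH_BOND * np.array(
                [math.sin(_HOH_ANGLE), 0.0, math.cos(_HOH_ANGLE)])
        else:
            half = 0.5 * _HOH_ANGLE
            h1 = o + _OH_BOND * np.array([math.cos(half), math.sin(half), 0.0])
            h2 = o + _OH_BOND * np.array([math.cos(half), -math.sin(half), 0.0])
        coords[3 * i] = o
        coords[3 * i + 1] = h1
        coords[3 * i + 2] = h2
    u = mda.Universe.empty(
        n_atoms=3 * n_waters,
        n_residues=n_waters,
        atom_resindex=np.repeat(np.arange(n_waters), 3),
        residue_segindex=np.zeros(n_waters, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", ["OH2", "H1", "H2"] * n_waters)
    u.add_TopologyAttr("resnames", ["TIP3"] * n_waters)
    u.add_TopologyAttr("resids", np.arange(1, n_waters + 1))
    u.atoms.positions = coords
    return u
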