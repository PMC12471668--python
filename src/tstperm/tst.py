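"""Transition-state-theory rate and permeability relations.

The single-channel osmotic permeability is obtained from equilibrium
sampling in three steps:

1. the equilibrium rate constant (transitions per unit time, one way)

       k₀ = κ · √(RT / 2π m_W) · n(z₀),

   where κ is the transmission (recrossing) correction measured by
   event-following (:mod:`tstperm.events`), √(RT/2πm_W) the mean positive
   Maxwell–Boltzmann axial speed, and n(z₀) the linear water density at
   the dividing plane (:mod:`tstperm.density`);

2. the permeability

       p_f = 2 k₀ ν_W / N_A   (cm³/s),

   valid in the dilute-osmolyte regime (c_e − c_i)·ν_W ≪ 1, where the
   osmotic flux is J = p_f (c_e − c_i);

3. the effective Arrhenius activation energy from two temperatures,

       E_a = R T₁ ln(p₁/p₂) / (T₁/T₂ − 1).

All public functions take an explicit :class:`PhysicalConstants`, which
defaults to CODATA values with the molar volume of water at 25 °C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .density import DensityAccumulator, DensityProfile, density_at_plane
from .errors import DataError, DomainError
from .events import EventAccumulator, EventSummary
from .trajectory import ChannelFrame, ParticleTrack

# unit conversion
_NM_PER_M = 1e9


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants and water properties used throughout.

    R is the molar gas constant (J mol⁻¹ K⁻¹; ``R_kcal`` exposes it in
    kcal mol⁻¹ K⁻¹), N_A the Avogadro number, m_W the molar mass of water
    (g/mol) and v_W its molar volume (cm³/mol; the <0.2% variation
    between 5 and 25 °C is ignored by default).
    """

    R: float = 8.314462618  # J / (mol K)
    N_A: float = 6.02214076e23  # 1 / mol
    m_W: float = 18.01528  # g / mol
    v_W: float = 18.0153  # cm^3 / mol

    @property
    def R_kcal(self) -> float:
        return self.R / 4184.0  # = 1.987204e-3 kcal / (mol K)

    def __post_init__(self) -> None:
        for name in ("R", "N_A", "m_W", "v_W"):
            if getattr(self, name) <= 0:
                raise DomainError(f"constant {name} must be positive")


CONSTANTS = PhysicalConstants()


@dataclass
class OsmoticConditions:
    """Impermeant-solute concentrations (mol/cm³) on the two sides."""

    c_e: float  # extracellular
    c_i: float  # intracellular
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.c_e < 0 or self.c_i < 0:
            raise DomainError("concentrations must be non-negative")
        if self.temperature <= 0:
            raise DomainError("temperature must be positive")

    def dilute(self, constants: PhysicalConstants = CONSTANTS,
               limit: float = 1e-2) -> bool:
        """True in the dilute regime (c_e − c_i)·ν_W ≪ 1 where the
        linearized flux relations hold (sub-molar osmolyte)."""
        return abs((self.c_e - self.c_i) * constants.v_W) < limit


@dataclass
class PermeabilityResult:
    """κ, n(z₀), k₀ and p_f at one temperature (one Table-style row)."""

    kappa: float
    n_z0: float  # molecules / nm
    k0: float  # 1/s
    p_f: float  # cm^3 / s
    temperature: float
    uncertainty_pf: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("kappa", "n_z0", "k0", "p_f"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")

    @property
    def p_f_1e13(self) -> float:
        """p_f in the conventional 10⁻¹³ cm³/s unit."""
        return self.p_f * 1e13


@dataclass
class ArrheniusResult:
    """Activation energy from a permeability pair at two temperatures."""

    E_a: float  # kcal/mol
    T1: float
    T2: float
    p1: float
    p2: float


def rate_constant_k0(
    kappa: float,
    temperature: float,
    n_z0: float,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """TST rate constant k₀ = κ √(RT/2πm_W) n(z₀), in s⁻¹.

    ``n_z0`` is the linear density in molecules per nm.  The flux factor
    √(RT/2πm_W) is the mean Maxwell–Boltzmann speed in the +z direction
    times the total density, i.e. the rate at which molecules cross a
    plane per unit linear density.
    """
    if not (0.0 <= kappa <= 1.0):
        raise DomainError(f"kappa must be in [0, 1], got {kappa}")
    if n_z0 < 0:
        raise DomainError("n_z0 must be non-negative")
    if temperature <= 0:
        raise DomainError("temperature must be positive")
    m_kg = constants.m_W * 1e-3  # kg/mol
    v_mean = math.sqrt(constants.R * temperature / (2.0 * math.pi * m_kg))
    return kappa * v_mean * n_z0 * _NM_PER_M


def single_channel_pf(k0: float,
                      constants: PhysicalConstants = CONSTANTS) -> float:
    """Single-channel osmotic permeability p_f = 2 k₀ ν_W / N_A (cm³/s)."""
    if k0 < 0:
        raise DomainError("k0 must be non-negative")
    return 2.0 * k0 * constants.v_W / constants.N_A


def osmotic_rate(
    k0: float,
    cond: OsmoticConditions,
    constants: PhysicalConstants = CONSTANTS,
    mode: str = "linearized",
) -> tuple[float, float]:
    """Net osmotic transition rate r and single-channel flux J.

    With an osmolyte imbalance the IC→EC and EC→IC rate constants split,
    k_ItoE = k_EtoI · exp((c_e − c_i)·ν_W), producing a net water efflux.

    ``mode="full"`` evaluates the rate difference with the exponential
    factor and the solute-reduced water concentrations,
    r = k₀[e^Δ (1/ν_W − c_i) − (1/ν_W − c_e)] with Δ = (c_e − c_i)ν_W;
    ``mode="linearized"`` uses the first-order expansion r = 2k₀(c_e−c_i),
    valid for sub-molar osmolyte.  In both modes J = r·ν_W/N_A (cm³/s);
    in the linearized mode J/(c_e − c_i) equals
    :func:`single_channel_pf` exactly.
    """
    if k0 < 0:
        raise DomainError("k0 must be non-negative")
    if not cond.dilute(constants):
        import warnings

        warnings.warn(
            "osmolyte imbalance outside the dilute regime "
            "((c_e - c_i)*v_W not << 1); rate relations lose accuracy"
        )
    dc = cond.c_e - cond.c_i
    if mode == "full":
        delta = dc * constants.v_W
        inv_vw = 1.0 / constants.v_W
        r = k0 * (math.exp(delta) * (inv_vw - cond.c_i) - (inv_vw - cond.c_e))
    elif mode == "linearized":
        r = 2.0 * k0 * dc
    else:
        raise DomainError(f"unknown mode {mode!r}")
    J = r * constants.v_W / constants.N_A
    return r, J


def arrhenius_activation_energy(
    p1: float,
    T1: float,
    p2: float,
    T2: float,
    constants: PhysicalConstants = CONSTANTS,
) -> ArrheniusResult:
    """Arrhenius activation energy E_a = R·T₁·ln(p₁/p₂)/(T₁/T₂ − 1).

    ``p1``/``p2`` are permeabilities at temperatures ``T1``/``T2``
    (Kelvin); only their ratio matters.  The result is in kcal/mol.
    """
    if p1 <= 0 or p2 <= 0:
        raise DomainError("permeabilities must be positive")
    if T1 <= 0 or T2 <= 0:
        raise DomainError("temperatures must be positive")
    if T1 == T2:
        raise DomainError("T1 and T2 must differ")
    E_a = constants.R_kcal * T1 * math.log(p1 / p2) / (T1 / T2 - 1.0)
    return ArrheniusResult(E_a=E_a, T1=T1, T2=T2, p1=p1, p2=p2)


def estimate_uncertainty(
    values: Sequence[float] | Sequence[PermeabilityResult],
    method: str = "monomer-sem",
) -> float:
    """Standard error of the mean over monomers (or time blocks).

    The input is either raw p_f values or :class:`PermeabilityResult`
    objects; ``method`` is recorded by callers in provenance ("monomer-
    sem" over per-monomer estimates, "block-sem" over non-overlapping
    time blocks — the arithmetic is identical, the label documents what
    the samples were).
    """
    vals = np.asarray(
        [v.p_f if isinstance(v, PermeabilityResult) else float(v)
         for v in values]
    )
    if vals.size < 2:
        raise DataError("uncertainty needs at least 2 samples")
    return float(np.std(vals, ddof=1) / math.sqrt(vals.size))


# ---------------------------------------------------------------------------
# pipeline: tracks -> PermeabilityResult
# ---------------------------------------------------------------------------

def estimate_permeability(
    tracks: Iterable[ParticleTrack],
    frame: ChannelFrame,
    temperature: float,
    bin_width: float = 0.5,
    constants: PhysicalConstants = CONSTANTS,
    observation_time: float | None = None,
) -> PermeabilityResult:
    """Full TST pipeline on one channel's tracks.

    Streams through the tracks once, accumulating crossing events (for κ)
    and the density histogram (for n(z₀)), then evaluates k₀ and p_f.
    Memory stays O(track length), so arbitrarily many particles can be
    processed.
    """
    ev = EventAccumulator(frame)
    dens = DensityAccumulator(frame, bin_width=bin_width)
    t_max = 0.0
    n_tracks = 0
    for track in tracks:
        ev.add_track(track)
        dens.add_track(track)
        t_max = max(t_max, float(track.times[-1] - track.times[0]))
        n_tracks += 1
    if n_tracks == 0:
        raise DataError("no tracks supplied")
    obs = observation_time if observation_time is not None else t_max
    summary = ev.summarize(obs)
    profile = dens.profile()
    n_z0 = density_at_plane(profile, frame.z_divide)
    kappa = summary.kappa if summary.kappa is not None else 0.0
    k0 = rate_constant_k0(kappa, temperature, n_z0, constants)
    p_f = single_channel_pf(k0, constants)
    # delta-method uncertainty: p_f tracks the success count (~Poisson)
    unc = p_f / math.sqrt(summary.successes_total) \
        if summary.successes_total > 0 else None
    return PermeabilityResult(
        kappa=kappa,
        n_z0=n_z0,
        k0=k0,
        p_f=p_f,
        temperature=temperature,
        uncertainty_pf=unc,
        provenance={
            "events": summary.to_json_dict(),
            "n_tracks": n_tracks,
            "bin_width_A": bin_width,
            "uncertainty_method": "poisson-successes",
        },
    )


def permeability_timeseries(
    summary: EventSummary,
    profile_fn: Callable[[float], DensityProfile | float],
    temperature: float,
    frame: ChannelFrame | None = None,
    min_window: float = 15000.0,
    constants: PhysicalConstants = CONSTANTS,
) -> pd.DataFrame:
    """p_f over growing windows (0, t), one row per grid time.

    ``profile_fn(t)`` must return either the density profile accumulated
    over (0, t) or directly n(z₀) for that window.  Windows shorter than
    ``min_window`` (ps; default 15 ns) are skipped with a warning, since
    κ and n(z₀) are too noisy there.  Counts are per channel: if the
    summary pools a homo-oligomer, rates are divided by
    ``summary.n_monomers``.
    """
    import warnings

    rows = []
    z_div = frame.z_divide if frame is not None else 0.0
    for _, rec in summary.cumulative.iterrows():
        t = float(rec["t_ps"])
        if t < min_window:
            continue
        prof = profile_fn(t)
        n_z0 = (
            density_at_plane(prof, z_div)
            if isinstance(prof, DensityProfile)
            else float(prof)
        )
        kappa = float(rec["kappa"])
        if not np.isfinite(kappa):
            continue
        k0 = rate_constant_k0(kappa, temperature, n_z0, constants)
        rows.append(
            {
                "t_ps": t,
                "kappa": kappa,
                "n_z0_per_nm": n_z0,
                "k0_per_s": k0,
                "p_f_cm3_per_s": single_channel_pf(k0, constants),
            }
        )
    if not rows:
        warnings.warn("no windows longer than min_window; empty series")
    return pd.DataFrame(rows)


def arrhenius_from_results(
    result1: PermeabilityResult,
    result2: PermeabilityResult,
    constants: PhysicalConstants = CONSTANTS,
) -> ArrheniusResult:
    """E_a from two pipeline results at different temperatures."""
    return arrhenius_activation_energy(
        result1.p_f, result1.temperature, result2.p_f, result2.temperature,
        constants,
    )
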