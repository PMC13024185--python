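"""Ion-track sampling: 1-ps spatial distributions of primary radiolytic species.

A track segment is modeled as a sequence of energy-deposition events.  At low
LET these are well-separated Magee-type spurs along the ion path; at high LET
the spurs overlap into a quasi-continuous cylindrical core.  A velocity-
dependent fraction of the deposited energy is exported to a penumbra of
knock-on secondary electrons (delta rays), each of which lays down its own
string of spurs along a radial path whose length is the electron range.  The
split captures, at desk scale, the core/penumbra dichotomy that makes heavy
ions chemically distinct from protons at the same LET.

Coordinates are right-handed, in nm, with the beam along +Y; the segment is
periodic along Y for pair-distance computation.  All species are born at
t = 1 ps (Dirac pulse convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import AMU_MEV, ELECTRON_MC2_KEV, GY_PER_KEV_UM3, WATER_DENSITY
from .stopping import electron_range_nm, energy_for_let

#: Default 1-ps yields (molecules/100 eV, low-LET convention).  These are the
#: standard water-radiolysis physicochemical-stage values; hydroxide is the
#: charge balance of e-aq against H+ (zero here).
DEFAULT_INITIAL_YIELDS: dict[str, float] = {
    "e-aq": 4.2,
    "OH": 5.0,
    "H": 0.6,
    "H2": 0.15,
    "H+": 4.2,
}

#: The ion set studied at fixed LET, symbol -> (Z, A).
ION_TABLE: dict[str, tuple[int, int]] = {
    "1H": (1, 1),
    "4He": (2, 4),
    "10B": (5, 10),
    "12C": (6, 12),
    "16O": (8, 16),
    "20Ne": (10, 20),
    "28Si": (14, 28),
    "32S": (16, 32),
    "40Ar": (18, 40),
}


@dataclass(frozen=True)
class IonSpec:
    symbol: str
    Z: int
    A: int
    energy_per_nucleon: float  # MeV/u

    def __post_init__(self) -> None:
        if not (1 <= self.Z <= 18):
            raise ValueError("Z outside the studied 1..18 range")
        if self.A < self.Z:
            raise ValueError("A must be >= Z")
        if self.energy_per_nucleon <= 0:
            raise ValueError("energy per nucleon must be positive")

    @classmethod
    def from_symbol(cls, symbol: str, energy_per_nucleon: float) -> "IonSpec":
        z, a = ION_TABLE[symbol]
        return cls(symbol, z, a, energy_per_nucleon)

    @classmethod
    def at_let(cls, symbol: str, let_kev_um: float) -> "IonSpec":
        """Ion with energy per nucleon chosen so its LET matches (bundled
        stopping-power interpolation)."""
        z, a = ION_TABLE[symbol]
        return cls(symbol, z, a, energy_for_let(z, let_kev_um))


def kinematics(ion: IonSpec) -> tuple[float, float, float]:
    """(beta^2, gamma, Tmax in keV) for the ion.

    gamma = 1 + E/u; beta^2 = 1 - 1/gamma^2; Tmax = 2 me c^2 beta^2 gamma^2
    (free-electron knock-on maximum).
    """
    gamma = 1.0 + ion.energy_per_nucleon / AMU_MEV
    beta2 = 1.0 - 1.0 / gamma**2
    tmax_kev = 2.0 * ELECTRON_MC2_KEV * beta2 * gamma**2
    return beta2, gamma, tmax_kev


def default_segment_length_um(let_kev_um: float) -> float:
    """1 um at low LET; 0.2 um at >= 10 keV/um (tractability at high density)."""
    return 0.2 if let_kev_um >= 10.0 else 1.0


@dataclass(frozen=True)
class PulseSpec:
    """Beam + track-model definition for one Dirac pulse."""

    ion: IonSpec
    let: float                      # keV/um
    n_ions: int = 20
    r0_um: float = 0.1              # beam radius
    segment_length_um: float | None = None  # None -> LET-based default
    initial_yields: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INITIAL_YIELDS)
    )
    # track-model parameters (see docs/methods.md)
    mean_spur_ev: float = 47.0
    sigma_eaq_nm: float = 4.0
    sigma_heavy_nm: float = 1.0
    delta_threshold_kev: float = 0.1   # knock-on energy above which a delta ray is explicit
    mean_excitation_ev: float = 75.0
    # radial dispersal of deposition sites about the ion path: the larger of a
    # Bohr-type velocity term and a floor set by sub-threshold secondary-
    # electron transport; the floor is calibrated against published pure-water
    # OH decay kinetics of ~70 keV/um proton tracks (see docs/methods.md)
    core_radius_coeff_nm: float = 11.6  # sigma_core = max(floor, coeff * beta)
    core_sigma_min_nm: float = 8.0

    def __post_init__(self) -> None:
        if self.n_ions < 1:
            raise ValueError("N must be >= 1")
        if self.r0_um <= 0 or self.let <= 0:
            raise ValueError("R0 and LET must be positive")
        if any(v < 0 for v in self.initial_yields.values()):
            raise ValueError("initial yields must be non-negative")

    @property
    def segment_nm(self) -> float:
        um = self.segment_length_um
        if um is None:
            um = default_segment_length_um(self.let)
        if um <= 0:
            raise ValueError("segment length must be positive")
        return um * 1e3

    @property
    def track_energy_kev(self) -> float:
        return self.let * self.segment_nm * 1e-3

    def penumbra_fraction(self) -> float:
        """Fraction of the deposited energy carried by explicit delta rays.

        From the 1/T^2 knock-on spectrum between the threshold and Tmax,
        with equipartition between glancing and knock-on collisions:
        f = ln(Tmax/Tcut) / (2 ln(Tmax/I)), clipped to [0, 0.5].
        """
        _, _, tmax = kinematics(self.ion)
        tcut = self.delta_threshold_kev
        if tmax <= tcut:
            return 0.0
        i_kev = self.mean_excitation_ev * 1e-3
        f = math.log(tmax / tcut) / (2.0 * math.log(tmax / i_kev))
        return min(0.5, max(0.0, f))


@dataclass
class TrackRealization:
    species: np.ndarray        # (n,) unicode species names
    positions: np.ndarray      # (n, 3) nm, beam along +Y
    deposited_energy_kev: float
    axis_position: tuple[float, float]  # (x, z) nm offset of the track axis

    @property
    def n_particles(self) -> int:
        return len(self.species)


@dataclass
class PulseRealization:
    tracks: list[TrackRealization]
    pulse: PulseSpec
    seed: int | None = None

    @property
    def total_energy_kev(self) -> float:
        return float(sum(t.deposited_energy_kev for t in self.tracks))

    @property
    def dose_gy(self) -> float:
        return absorbed_dose(self.pulse.n_ions, self.pulse.let, self.pulse.r0_um)

    def merged(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(species, positions, track_index) over all tracks."""
        species = np.concatenate([t.species for t in self.tracks])
        pos = np.concatenate([t.positions for t in self.tracks])
        idx = np.concatenate(
            [np.full(t.n_particles, i, dtype=np.int32) for i, t in enumerate(self.tracks)]
        )
        return species, pos, idx


def absorbed_dose(n_ions: int, let_kev_um: float, r0_um: float) -> float:
    """Mean absorbed dose (Gy) in the irradiated cylinder.

    dose = N * LET / (pi R0^2 rho): fluence N/(pi R0^2) [1/um^2] times LET
    [keV/um] is an energy density [keV/um^3]; at rho = 1 g/cm^3 one
    keV/um^3 = 0.1602176634 Gy.  The segment length cancels.
    """
    if n_ions < 0 or let_kev_um < 0 or r0_um <= 0:
        raise ValueError("arguments must be positive (N may be 0)")
    return n_ions * let_kev_um / (math.pi * r0_um**2) * GY_PER_KEV_UM3 / WATER_DENSITY


# ---------------------------------------------------------------------------
# sampling

def _spur_energies(total_ev: float, mean_spur_ev: float) -> np.ndarray:
    """Partition ``total_ev`` exactly into ~mean-sized deposition events."""
    if total_ev <= 0:
        return np.zeros(0)
    n_full = int(total_ev // mean_spur_ev)
    rem = total_ev - n_full * mean_spur_ev
    e = [mean_spur_ev] * n_full
    if rem > 1e-9:
        e.append(rem)
    return np.asarray(e)


def _spawn_species(
    rng: np.random.Generator,
    centers: np.ndarray,          # (m, 3)
    energies_ev: np.ndarray,      # (m,)
    yields: dict[str, float],
    sigma_eaq: float,
    sigma_heavy: float,
) -> tuple[list[str], list[np.ndarray]]:
    names: list[str] = []
    positions: list[np.ndarray] = []
    for name, g in yields.items():
        if g <= 0:
            continue
        lam = energies_ev * (g / 100.0)
        counts = rng.poisson(lam)
        total = int(counts.sum())
        if total == 0:
            continue
        ctr = np.repeat(centers, counts, axis=0)
        sigma = sigma_eaq if name == "e-aq" else sigma_heavy
        pos = ctr + rng.normal(0.0, sigma, size=(total, 3))
        names.extend([name] * total)
        positions.append(pos)
    return names, positions


def sample_track(
    pulse: PulseSpec,
    rng: np.random.Generator | int,
    axis_xz: tuple[float, float] = (0.0, 0.0),
) -> TrackRealization:
    """One track realization at 1 ps.

    Energy is split into a cylindrical core of Magee spurs along the axis and
    an explicit delta-ray penumbra; the total deposited energy equals
    LET x segment length exactly by construction.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if not any(v > 0 for v in pulse.initial_yields.values()):
        raise ValueError("all initial yields are zero")

    length = pulse.segment_nm
    e_total_ev = pulse.track_energy_kev * 1e3
    beta2, _, tmax_kev = kinematics(pulse.ion)
    f_pen = pulse.penumbra_fraction()
    e_pen_ev = f_pen * e_total_ev
    e_core_ev = e_total_ev - e_pen_ev

    sigma_core = max(pulse.core_sigma_min_nm, pulse.core_radius_coeff_nm * math.sqrt(beta2))
    x0, z0 = axis_xz

    centers: list[np.ndarray] = []
    energies: list[np.ndarray] = []

    # core: spur centers along the axis, Gaussian radial spread
    core_e = _spur_energies(e_core_ev, pulse.mean_spur_ev)
    if len(core_e):
        y = rng.uniform(0.0, length, size=len(core_e))
        x = x0 + rng.normal(0.0, sigma_core, size=len(core_e))
        z = z0 + rng.normal(0.0, sigma_core, size=len(core_e))
        centers.append(np.column_stack([x, y, z]))
        energies.append(core_e)

    # penumbra: delta rays from the 1/T^2 knock-on spectrum, each a radial
    # string of spurs over the electron range
    tcut = pulse.delta_threshold_kev
    remaining = e_pen_ev
    while remaining > 1e-6:
        u = rng.uniform()
        t_kev = tcut / (1.0 - u * (1.0 - tcut / tmax_kev))
        t_ev = min(t_kev * 1e3, remaining)
        d_e = _spur_energies(t_ev, pulse.mean_spur_ev)
        # spur spacing follows the electron's stopping power at its full
        # sampled energy; a delta ray that deposits only part of its energy
        # within the segment's budget still spreads it at that spacing
        reach = electron_range_nm(t_kev) * (t_ev / (t_kev * 1e3))
        y_emit = rng.uniform(0.0, length)
        phi = rng.uniform(0.0, 2.0 * math.pi)
        radial = np.array([math.cos(phi), 0.0, math.sin(phi)])
        d = rng.uniform(0.0, reach, size=len(d_e))
        ctr = (
            np.array([x0, y_emit, z0])
            + d[:, None] * radial[None, :]
            + rng.normal(0.0, sigma_core, size=(len(d_e), 3))
        )
        centers.append(ctr)
        energies.append(d_e)
        remaining -= t_ev

    all_centers = np.concatenate(centers) if centers else np.zeros((0, 3))
    all_energies = np.concatenate(energies) if energies else np.zeros(0)

    names, pos_blocks = _spawn_species(
        rng, all_centers, all_energies, pulse.initial_yields,
        pulse.sigma_eaq_nm, pulse.sigma_heavy_nm,
    )
    if names:
        pos = np.concatenate(pos_blocks)
        pos[:, 1] %= length  # periodic wrap along the beam axis
        species = np.asarray(names)
    else:
        pos = np.zeros((0, 3))
        species = np.asarray([], dtype="U8")

    return TrackRealization(
        species=species,
        positions=pos,
        deposited_energy_kev=pulse.track_energy_kev,
        axis_position=(x0, z0),
    )


def assemble_pulse(pulse: PulseSpec, seed: int | np.random.SeedSequence) -> PulseRealization:
    """N independent tracks with axes uniform over the disc of radius R0,
    merged into one Dirac pulse (common 1-ps time origin)."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    r0_nm = pulse.r0_um * 1e3
    tracks = []
    for _ in range(pulse.n_ions):
        r = r0_nm * math.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2.0 * math.pi)
        axis = (r * math.cos(theta), r * math.sin(theta))
        tracks.append(sample_track(pulse, rng, axis_xz=axis))
    return PulseRealization(
        tracks=tracks,
        pulse=pulse,
        seed=ss.entropy if isinstance(ss.entropy, int) else None,
    )


# ---------------------------------------------------------------------------
# dumps (Fig-4-style XY projections; beam along Y)

def dump_track(realization: TrackRealization | PulseRealization, path: str | Path,
               header: dict | None = None) -> None:
    path = Path(path)
    if isinstance(realization, PulseRealization):
        species, pos, idx = realization.merged()
    else:
        species = realization.species
        pos = realization.positions
        idx = np.zeros(len(species), dtype=np.int32)
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in (header or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write("species\tx_nm\ty_nm\tz_nm\ttrack_index\n")
        for s, (x, y, z), i in zip(species, pos, idx):
            fh.write(f"{s}\t{float(x)!r}\t{float(y)!r}\t{float(z)!r}\t{i}\n")


def load_track_dump(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    species: list[str] = []
    pos: list[list[float]] = []
    idx: list[int] = []
    with open(path, encoding="utf-8") as fh:
        header_seen = False
        for line in fh:
            if line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) < 5:
                continue
            species.append(cells[0])
            pos.append([float(cells[1]), float(cells[2]), float(cells[3])])
            idx.append(int(cells[4]))
    return (
        np.asarray(species, dtype="U8"),
        np.asarray(pos).reshape(-1, 3),
        np.asarray(idx, dtype=np.int32),
    )


def mean_radial_distance(realization: PulseRealization) -> float:
    """Energy-unweighted mean distance of species from their own track axis."""
    tot, n = 0.0, 0
    for t in realization.tracks:
        if t.n_particles == 0:
            continue
        dx = t.positions[:, 0] - t.axis_position[0]
        dz = t.positions[:, 2] - t.axis_position[1]
        tot += float(np.sqrt(dx * dx + dz * dz).sum())
        n += t.n_particles
    return tot / n if n else 0.0
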