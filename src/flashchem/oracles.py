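"""Brute-force and analytic references used to validate the IRT engine.

The step-by-step random-walk simulator propagates every particle by Gaussian
displacements and reacts pairs on encounter (with a Brownian-bridge crossing
correction between steps, so the time step bias on escape probabilities stays
below the Monte Carlo noise).  It shares the packed reaction tables and the
YieldSeries output shape with the IRT engine but none of its sampling code,
so agreement between the two is a genuine cross-method check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erfc

from . import _kernels
from .irt import YieldSeries, _series_from_events, packed_scheme
from .scheme import Scheme, build_default_scheme
from .tracks import PulseRealization, PulseSpec, IonSpec, TrackRealization


@dataclass(frozen=True)
class RandomWalkConfig:
    dt_ns: float = 0.05
    max_time_ns: float = 200.0
    seed: int = 0


def pair_survival_analytic(r_nm: float, r0_nm: float, dprime: float, t_ns) -> np.ndarray:
    """W(t) = (R/r0) erfc((r0 - R)/sqrt(4 D' t)): probability that an isolated
    pair at initial separation r0 has reacted by time t."""
    if r0_nm < r_nm:
        raise ValueError("r0 must be >= contact radius")
    t = np.asarray(t_ns, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = np.where(t > 0, (r0_nm - r_nm) / np.sqrt(4.0 * dprime * t), np.inf)
    return (r_nm / r0_nm) * erfc(arg)


def random_walk_oracle(
    pulse: PulseRealization,
    scheme: Scheme,
    cfg: RandomWalkConfig = RandomWalkConfig(),
    t_start_ns: float = 1e-3,
) -> YieldSeries:
    """Step-by-step reference chemistry (test scale: <= ~100 particles)."""
    species, pos, _ = pulse.merged()
    if len(species) > 200:
        raise ValueError("random-walk oracle is a test-scale tool (<= ~100 particles)")
    packed = packed_scheme(scheme)
    sp_codes = packed.encode_species(species)
    initial = np.bincount(sp_codes, minlength=packed.n_species).astype(np.int64)

    ev_t, ev_r, _alive = _kernels.random_walk_kernel(
        np.ascontiguousarray(pos, dtype=np.float64),
        sp_codes,
        packed.diff,
        packed.scav_total,
        packed.scav_cum,
        packed.scav_rid,
        packed.pair_rxn,
        packed.pair_radius,
        packed.pair_paccept,
        packed.spawn_sp,
        t_start_ns,
        cfg.max_time_ns,
        pulse.pulse.segment_nm,
        cfg.dt_ns,
        int(cfg.seed) & 0x7FFFFFFF,
    )
    return _series_from_events(
        packed, initial, ev_t, ev_r, pulse.total_energy_kev, t_start_ns, cfg.max_time_ns
    )


# ---------------------------------------------------------------------------
# deterministic fixtures

_FIXTURES = ("pair", "spur7", "two-track", "scavenger-only")

#: printed separation of the "pair" fixture (nm)
PAIR_SEPARATION_NM = 1.0


def _pulse_from_particles(species, positions, spec: PulseSpec) -> PulseRealization:
    track = TrackRealization(
        species=np.asarray(species, dtype="U8"),
        positions=np.asarray(positions, dtype=float).reshape(-1, 3),
        deposited_energy_kev=spec.track_energy_kev,
        axis_position=(0.0, 0.0),
    )
    return PulseRealization(tracks=[track], pulse=spec)


def make_fixture(name: str, scheme: Scheme | None = None,
                 separation_nm: float = 200.0) -> tuple[PulseRealization, Scheme]:
    """Small deterministic instances for oracle/IRT cross-validation.

    * ``pair``: one e-aq / OH pair at 1 nm separation;
    * ``spur7``: a 7-species Magee spur (2 e-aq, 2 OH, 2 H+, 1 H);
    * ``two-track``: two spur7 clusters a configurable distance apart;
    * ``scavenger-only``: a single OH in the continuum-scavenger bath.
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; catalogue: {_FIXTURES}")
    scheme = scheme or build_default_scheme()
    ion = IonSpec("1H", 1, 1, 300.0)
    spec = PulseSpec(ion=ion, let=0.3, n_ions=1, segment_length_um=1.0)

    spur = [
        ("e-aq", (0.0, 500.0, 2.0)),
        ("e-aq", (3.0, 498.0, -1.0)),
        ("OH", (0.5, 500.5, 0.0)),
        ("OH", (-1.0, 499.5, 1.0)),
        ("H+", (0.8, 500.2, -0.5)),
        ("H+", (-0.6, 499.0, 0.3)),
        ("H", (1.5, 501.0, 0.7)),
    ]

    if name == "pair":
        species = ["e-aq", "OH"]
        positions = [(0.0, 500.0, 0.0), (0.0, 500.0 + PAIR_SEPARATION_NM, 0.0)]
    elif name == "spur7":
        species = [s for s, _ in spur]
        positions = [p for _, p in spur]
    elif name == "two-track":
        species = [s for s, _ in spur] * 2
        positions = [p for _, p in spur] + [
            (x + separation_nm, y, z) for _, (x, y, z) in spur
        ]
    else:  # scavenger-only
        species = ["OH"]
        positions = [(0.0, 500.0, 0.0)]
    return _pulse_from_particles(species, positions, spec), scheme
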