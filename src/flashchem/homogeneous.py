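"""Well-mixed kinetics from the homogenization switch time to 1 s.

Once spur expansion is over (~0.2 us for low-LET pulses) the surviving
radiolytic species are uniformly distributed and the chemistry is ordinary
mass-action kinetics.  Yields are converted to concentrations through the
absorbed dose (c = G * 0.103364 umol/J * D), integrated with a stiff solver,
and mapped back to G units so the particle-stage and homogeneous-stage series
form one continuous curve from 1 ps to 1 s.

Two oxygen conventions are supported side by side:

* ``fixed`` (continuum): O2 is held at its pool concentration and its
  consumption is tallied; G(-O2) is then dose-independent, which is the
  convention for reporting yields per 100 eV.
* ``depletable`` (self-consistent): O2 is integrated like any other species,
  which is the convention for oxygen-depletion fractions at a stated dose.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .constants import G_UMOL_PER_J
from .scheme import Scheme
from .irt import YieldSeries

#: mol/L per (G unit * Gy): c = G * 0.103364e-6 * dose
M_PER_G_GY = G_UMOL_PER_J * 1e-6

#: default direct-action bio-radical concentration entering the homogeneous
#: stage (uM); from direct ionization of RH followed by deprotonation
DEFAULT_DIRECT_R_UM = 2.5


@dataclass
class ConcentrationState:
    concentrations: dict[str, float]  # mol/L
    time_s: float

    def __post_init__(self) -> None:
        for name, c in self.concentrations.items():
            if c < -1e-30:
                warnings.warn(
                    f"negative concentration for {name} clamped to 0 "
                    "(tally/convention mismatch signal)"
                )
            if c < 0:
                self.concentrations[name] = 0.0


def g_to_concentration(g: float, dose_gy: float) -> float:
    """mol/L from a G value (molecules/100 eV) at a given dose."""
    return g * M_PER_G_GY * dose_gy


def concentration_to_g(c_mol_l: float, dose_gy: float) -> float:
    if dose_gy <= 0:
        raise ValueError("dose must be positive")
    return c_mol_l / (M_PER_G_GY * dose_gy)


def yields_to_concentrations(
    series: YieldSeries,
    dose_gy: float,
    scheme: Scheme,
    direct_r_um: float = DEFAULT_DIRECT_R_UM,
) -> ConcentrationState:
    """Concentration state at the switch time.

    Surviving radiolytic species enter at G * 0.103364 umol/J * dose;
    background solutes at their pool concentration minus the tallied
    particle-stage consumption; the direct-action bio-radical R enters as a
    fixed initial concentration.
    """
    if dose_gy <= 0:
        raise ValueError("dose must be positive")
    e_ev = series.deposited_energy_kev * 1e3
    conc: dict[str, float] = {}
    for name, count in series.inventory.items():
        g = 100.0 * count / e_ev
        conc[name] = g_to_concentration(g, dose_gy)
    for name, sol in scheme.background_solutes.items():
        consumed = series.background_consumed_g.get(name, 0.0)
        conc[name] = sol.concentration - g_to_concentration(consumed, dose_gy)
    conc["R"] = conc.get("R", 0.0) + direct_r_um * 1e-6
    return ConcentrationState(conc, time_s=series.times_ns[-1] * 1e-9)


@dataclass
class HomogeneousResult:
    times_s: np.ndarray
    species: list[str]                  # dynamic species order
    conc: np.ndarray                    # (nt, n_dyn) mol/L
    extents: np.ndarray                 # (nt, n_rxn) cumulative M per reaction
    reaction_ids: list[str]
    fixed: dict[str, float]             # species held constant
    o2_mode: str
    o2_stoich: np.ndarray = field(default_factory=lambda: np.zeros(0))  # net O2 per event
    background_names: tuple[str, ...] = ()

    def concentration(self, name: str) -> np.ndarray:
        if name in self.fixed:
            return np.full(len(self.times_s), self.fixed[name])
        return self.conc[:, self.species.index(name)]

    def final_state(self) -> ConcentrationState:
        conc = {s: float(self.conc[-1, i]) for i, s in enumerate(self.species)}
        conc.update(self.fixed)
        return ConcentrationState(conc, time_s=float(self.times_s[-1]))


def run_homogeneous(
    c0: ConcentrationState,
    scheme: Scheme,
    t_switch_s: float,
    t_end_s: float = 1.0,
    o2_mode: str = "fixed",
    grid_points: int = 96,
    rtol: float = 1e-8,
    atol: float = 1e-15,
) -> HomogeneousResult:
    """Integrate mass-action kinetics on a log-spaced grid to ``t_end_s``.

    Non-depletable background solutes are held at their pool values; O2 is
    dynamic in ``depletable`` mode and held fixed in ``fixed`` mode.  The
    cumulative extent of every reaction (M) is integrated alongside the
    concentrations for the per-channel Delta-G decomposition.
    """
    if t_end_s <= t_switch_s:
        raise ValueError("t_end must exceed t_switch")
    if o2_mode not in ("fixed", "depletable"):
        raise ValueError("o2_mode must be 'fixed' or 'depletable'")

    fixed: dict[str, float] = {}
    dyn: list[str] = []
    for sp in scheme.species:
        name = sp.name
        sol = scheme.background_solutes.get(name)
        if sol is not None:
            held = (not sol.depletable) or (name == "O2" and o2_mode == "fixed")
            if held:
                fixed[name] = c0.concentrations.get(name, sol.concentration)
                continue
        dyn.append(name)
    index = {n: i for i, n in enumerate(dyn)}

    y0 = np.array([c0.concentrations.get(n, 0.0) for n in dyn])

    rxns = scheme.reactions
    nr = len(rxns)
    i1 = np.full(nr, -1, dtype=np.int64)
    f1 = np.zeros(nr)
    i2 = np.full(nr, -1, dtype=np.int64)
    f2 = np.ones(nr)  # neutral factor for first-order reactions
    kk = np.zeros(nr)
    stoich = np.zeros((nr, len(dyn)))
    for r_idx, r in enumerate(rxns):
        kk[r_idx] = r.rate_constant
        a = r.reactants[0]
        if a in index:
            i1[r_idx] = index[a]
        else:
            f1[r_idx] = fixed[a]
        if len(r.reactants) == 2:
            b = r.reactants[1]
            if b in index:
                i2[r_idx] = index[b]
            else:
                f2[r_idx] = fixed[b]
        for n in r.reactants:
            if n in index:
                stoich[r_idx, index[n]] -= 1.0
        for n in r.products:
            if n in index:
                stoich[r_idx, index[n]] += 1.0

    n_dyn = len(dyn)
    m1 = i1 >= 0
    m2 = i2 >= 0
    j1 = np.where(m1, i1, 0)
    j2 = np.where(m2, i2, 0)

    def rates_of(y: np.ndarray) -> np.ndarray:
        ys = np.maximum(y, 0.0)
        c1 = np.where(m1, ys[j1], f1)
        c2 = np.where(m2, ys[j2], f2)
        return kk * c1 * c2

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        rates = rates_of(y[:n_dyn])
        dy = rates @ stoich
        return np.concatenate([dy, rates])

    t_eval = np.geomspace(t_switch_s, t_end_s, grid_points)
    t_eval[0], t_eval[-1] = t_switch_s, t_end_s
    sol = solve_ivp(
        rhs,
        (t_switch_s, t_end_s),
        np.concatenate([y0, np.zeros(nr)]),
        method="BDF",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"stiff solver failed: {sol.message} (last t={sol.t[-1]:g})")

    conc = sol.y[:n_dyn].T
    extents = sol.y[n_dyn:].T
    o2_stoich = np.array(
        [
            sum(1 for p in r.products if p == "O2")
            - sum(1 for n in r.reactants if n == "O2")
            for r in rxns
        ],
        dtype=float,
    )
    return HomogeneousResult(
        times_s=sol.t,
        species=dyn,
        conc=conc,
        extents=extents,
        reaction_ids=[r.id for r in rxns],
        fixed=fixed,
        o2_mode=o2_mode,
        o2_stoich=o2_stoich,
        background_names=tuple(scheme.background_solutes),
    )


# ---------------------------------------------------------------------------
# stitching

@dataclass
class CombinedYieldSeries:
    """Single continuous yield series, 1 ps -> 1 s."""

    times_s: np.ndarray
    g_minus_o2: np.ndarray
    reaction_delta_g: dict[str, np.ndarray]
    species_g: dict[str, np.ndarray]
    t_switch_s: float
    dose_gy: float
    irt: YieldSeries = field(repr=False)
    homogeneous: HomogeneousResult = field(repr=False)

    @property
    def g_minus_o2_final(self) -> float:
        return float(self.g_minus_o2[-1])

    def to_frame(self):
        import pandas as pd

        data = {"time_s": self.times_s, "G_minus_O2": self.g_minus_o2}
        for name, g in sorted(self.species_g.items()):
            data[f"G[{name}]"] = g
        for rid, g in sorted(self.reaction_delta_g.items()):
            data[f"dG[{rid}]"] = g
        return pd.DataFrame(data)

    def write_csv(self, path, metadata: dict | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for k, v in (metadata or {}).items():
                fh.write(f"# {k}: {v}\n")
            self.to_frame().to_csv(fh, index=False)


def stitch(
    irt_series: YieldSeries,
    hom: HomogeneousResult,
    dose_gy: float,
    junction_rtol: float = 1e-9,
    direct_r_um: float = DEFAULT_DIRECT_R_UM,
) -> CombinedYieldSeries:
    """Concatenate the particle-stage and homogeneous-stage series in G units.

    The homogeneous concentrations are mapped back through the inverse of
    :func:`yields_to_concentrations`; continuity at the junction is enforced
    to ``junction_rtol`` (the direct-action R injection, which by construction
    appears at the junction, is accounted for in the check).
    """
    t_irt = irt_series.times_ns * 1e-9
    t_switch = float(t_irt[-1])
    if not math.isclose(t_switch, float(hom.times_s[0]), rel_tol=1e-12):
        raise ValueError("junction times differ between the two stages")

    e_ev = irt_series.deposited_energy_kev * 1e3
    conv = M_PER_G_GY * dose_gy

    # junction continuity check (unit round-trip)
    for i, name in enumerate(hom.species):
        if name in hom.background_names:
            continue  # pool species enter at pool-minus-consumption, not via G
        g_ode = hom.conc[0, i] / conv
        g_irt = 100.0 * irt_series.inventory.get(name, 0.0) / e_ev
        if name == "R":
            g_irt += direct_r_um * 1e-6 / conv
        scale = max(abs(g_ode), abs(g_irt), 1e-30)
        if abs(g_ode - g_irt) / scale > junction_rtol:
            raise ValueError(
                f"junction mismatch for {name}: {g_irt:.12g} vs {g_ode:.12g}"
            )

    # net O2 consumed per unit extent of each reaction
    consumed_o2 = -hom.o2_stoich
    ext_g = hom.extents / conv  # (nt, nr) Delta-G per reaction in the ODE stage

    times = np.concatenate([t_irt, hom.times_s[1:]])
    g_o2_irt_end = float(irt_series.g_minus_o2[-1])
    g_o2_ode = ext_g @ consumed_o2
    g_minus_o2 = np.concatenate(
        [irt_series.g_minus_o2, g_o2_irt_end + (g_o2_ode[1:] - g_o2_ode[0])]
    )

    reaction_delta_g: dict[str, np.ndarray] = {}
    for k, rid in enumerate(hom.reaction_ids):
        irt_part = irt_series.reaction_delta_g.get(
            rid, np.zeros(len(t_irt))
        )
        base = float(irt_part[-1])
        reaction_delta_g[rid] = np.concatenate(
            [irt_part, base + (ext_g[1:, k] - ext_g[0, k])]
        )

    species_g: dict[str, np.ndarray] = {}
    names = set(irt_series.species_g) | set(hom.species)
    for name in names:
        irt_part = irt_series.species_g.get(name, np.zeros(len(t_irt)))
        if name in hom.species:
            ode_part = hom.concentration(name)[1:] / conv
        else:
            ode_part = np.full(len(hom.times_s) - 1, float(irt_part[-1]))
        species_g[name] = np.concatenate([irt_part, ode_part])

    return CombinedYieldSeries(
        times_s=times,
        g_minus_o2=g_minus_o2,
        reaction_delta_g=reaction_delta_g,
        species_g=species_g,
        t_switch_s=t_switch,
        dose_gy=dose_gy,
        irt=irt_series,
        homogeneous=hom,
    )


def o2_depletion_fraction(
    g_minus_o2_at_1s: float,
    dose_gy: float,
    initial_o2_mol_l: float,
    mode: str = "continuum",
    o2_trajectory: np.ndarray | None = None,
) -> float:
    """Percent of the initial O2 pool consumed at the end of the window.

    ``continuum``: bookkeeping identity min(100, G * 0.103364 * D / [O2]0).
    ``self-consistent``: reads the end of the depletable-O2 trajectory
    (pass ``o2_trajectory`` in mol/L from a depletable-mode run); the
    transient maximum depletion is available via
    :func:`transient_depletion_fraction`.
    """
    if initial_o2_mol_l <= 0:
        raise ValueError("initial O2 must be positive")
    if mode == "continuum":
        if dose_gy == 0:
            return 0.0
        consumed = g_to_concentration(g_minus_o2_at_1s, dose_gy)
        return min(100.0, 100.0 * consumed / initial_o2_mol_l)
    if mode == "self-consistent":
        if o2_trajectory is None:
            raise ValueError("self-consistent mode needs the O2 trajectory")
        return 100.0 * (1.0 - float(o2_trajectory[-1]) / initial_o2_mol_l)
    raise ValueError("mode must be 'continuum' or 'self-consistent'")


def transient_depletion_fraction(o2_trajectory: np.ndarray,
                                 initial_o2_mol_l: float) -> float:
    """Deepest transient depletion (%) along a depletable-O2 trajectory
    (oxygen regenerated by superoxide dismutation can partially restore the
    pool after the trough)."""
    if initial_o2_mol_l <= 0:
        raise ValueError("initial O2 must be positive")
    return 100.0 * (1.0 - float(np.min(o2_trajectory)) / initial_o2_mol_l)
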