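"""The computational experiments: full pipeline runs with replicate statistics.

A single pipeline run is: sample an N-track Dirac pulse at 1 ps -> IRT
stochastic chemistry to the switch time -> convert surviving yields to
concentrations through the dose -> stiff mass-action kinetics to 1 s ->
stitched G(-O2) series and per-reaction decomposition.  Experiments wrap this
in replicate loops over independent seed streams:

* :func:`scan_let` - proton LET scan (0.3 ... 71 keV/um);
* :func:`scan_ions_fixed_let` - ion species scan at fixed LET (~70 keV/um);
* :func:`depletion_vs_initial_o2` - oxygen-depletion fraction vs [O2]0;
* :func:`calibrate_rates` - proportional calibration of measured
  mmHg/Gy oxygen-consumption rates onto simulated G(-O2) values.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .homogeneous import (
    CombinedYieldSeries,
    DEFAULT_DIRECT_R_UM,
    o2_depletion_fraction,
    run_homogeneous,
    stitch,
    transient_depletion_fraction,
    yields_to_concentrations,
)
from .irt import DEFAULT_T_SWITCH_NS, run_irt
from .scheme import Scheme, build_default_scheme
from .tracks import IonSpec, PulseSpec, absorbed_dose, assemble_pulse

#: default ion grid of the fixed-LET scan (symbol order = increasing Z)
FIXED_LET_IONS = ("1H", "4He", "10B", "12C", "16O", "20Ne", "28Si", "32S", "40Ar")


#: LET of the reference FLASH pulse that sets the cell-average dose context
REFERENCE_LET_KEV_UM = 0.3


@dataclass(frozen=True)
class RunOptions:
    t_switch_s: float = DEFAULT_T_SWITCH_NS * 1e-9
    t_end_s: float = 1.0
    direct_r_um: float = DEFAULT_DIRECT_R_UM
    compute_depletion: bool = True
    grid_points: int = 96
    #: cell-average dose (Gy) used to map yields onto homogeneous
    #: concentrations; None -> the reference FLASH pulse of the same geometry
    #: (N tracks at 0.3 keV/um), which for N=20, R0=0.1 um is ~30 Gy.  The
    #: track segment is a microcosm of the cell's track population, so the
    #: homogeneous dilution is set by the cell dose, not by the in-cylinder
    #: energy density (which exceeds it by the LET ratio at high LET).
    dose_context_gy: float | None = None


@dataclass
class SingleRunResult:
    pulse: PulseSpec
    seed: int
    dose_gy: float                       # in-cylinder dose of the realization
    dose_context_gy: float               # cell-average dose used for kinetics
    g_minus_o2_1s: float
    depletion_pct_continuum: float | None
    depletion_pct_selfconsistent: float | None
    depletion_pct_transient: float | None
    combined: CombinedYieldSeries = field(repr=False)


def _seed_pair(seed) -> tuple[np.random.SeedSequence, int]:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    track_ss, kernel_ss = ss.spawn(2)
    kernel_seed = int(kernel_ss.generate_state(1)[0] & 0x7FFFFFFF)
    return track_ss, kernel_seed


def run_single(
    pulse: PulseSpec,
    scheme: Scheme | None = None,
    seed: int | np.random.SeedSequence = 0,
    options: RunOptions = RunOptions(),
) -> SingleRunResult:
    """One full pipeline run (one pulse realization, one seed)."""
    scheme = scheme or build_default_scheme()
    track_ss, kernel_seed = _seed_pair(seed)

    realization = assemble_pulse(pulse, track_ss)
    series, _inventory = run_irt(
        realization, scheme, t_switch_ns=options.t_switch_s * 1e9, seed=kernel_seed
    )
    dose_ctx = options.dose_context_gy
    if dose_ctx is None:
        dose_ctx = absorbed_dose(pulse.n_ions, REFERENCE_LET_KEV_UM, pulse.r0_um)
    c0 = yields_to_concentrations(series, dose_ctx, scheme, options.direct_r_um)

    hom = run_homogeneous(
        c0, scheme, options.t_switch_s, options.t_end_s,
        o2_mode="fixed", grid_points=options.grid_points,
    )
    combined = stitch(series, hom, dose_ctx, direct_r_um=options.direct_r_um)
    g1s = combined.g_minus_o2_final

    depl_c = depl_sc = depl_tr = None
    if options.compute_depletion:
        o2_pool = scheme.background_concentration("O2")
        depl_c = o2_depletion_fraction(g1s, dose_ctx, o2_pool, mode="continuum")
        hom_d = run_homogeneous(
            c0, scheme, options.t_switch_s, options.t_end_s,
            o2_mode="depletable", grid_points=options.grid_points,
        )
        traj = hom_d.concentration("O2")
        depl_sc = o2_depletion_fraction(
            g1s, dose_ctx, o2_pool, mode="self-consistent", o2_trajectory=traj
        )
        depl_tr = transient_depletion_fraction(traj, o2_pool)

    seed_int = seed if isinstance(seed, int) else -1
    return SingleRunResult(
        pulse=pulse,
        seed=seed_int,
        dose_gy=realization.dose_gy,
        dose_context_gy=dose_ctx,
        g_minus_o2_1s=g1s,
        depletion_pct_continuum=depl_c,
        depletion_pct_selfconsistent=depl_sc,
        depletion_pct_transient=depl_tr,
        combined=combined,
    )


def run_replicates(
    pulse: PulseSpec,
    scheme: Scheme | None = None,
    n_replicates: int = 16,
    master_seed: int = 0,
    options: RunOptions = RunOptions(),
    keep_series: bool = False,
) -> pd.DataFrame:
    """Independent replicates of the full pipeline; one row per replicate."""
    if n_replicates < 1:
        raise ValueError("replicates must be >= 1")
    scheme = scheme or build_default_scheme()
    children = np.random.SeedSequence(master_seed).spawn(n_replicates)
    rows = []
    for k, child in enumerate(children):
        res = run_single(pulse, scheme, child, options)
        row = {
            "replicate": k,
            "ion": pulse.ion.symbol,
            "Z": pulse.ion.Z,
            "energy_per_nucleon_MeV": pulse.ion.energy_per_nucleon,
            "LET_keV_um": pulse.let,
            "N": pulse.n_ions,
            "dose_Gy": res.dose_gy,
            "dose_context_Gy": res.dose_context_gy,
            "G_minus_O2": res.g_minus_o2_1s,
            "depletion_pct_continuum": res.depletion_pct_continuum,
            "depletion_pct_selfconsistent": res.depletion_pct_selfconsistent,
            "depletion_pct_transient": res.depletion_pct_transient,
        }
        if keep_series:
            row["combined"] = res.combined
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(per_replicate: pd.DataFrame) -> pd.Series:
    """Mean and standard error of the headline quantities over replicates."""
    g = per_replicate["G_minus_O2"]
    out = {
        "ion": per_replicate["ion"].iloc[0],
        "Z": int(per_replicate["Z"].iloc[0]),
        "energy_per_nucleon_MeV": float(per_replicate["energy_per_nucleon_MeV"].iloc[0]),
        "LET_keV_um": float(per_replicate["LET_keV_um"].iloc[0]),
        "N": int(per_replicate["N"].iloc[0]),
        "replicates": len(per_replicate),
        "G_minus_O2_mean": float(g.mean()),
        "G_minus_O2_se": float(g.std(ddof=1) / np.sqrt(len(g))) if len(g) > 1 else 0.0,
    }
    for col in ("depletion_pct_continuum", "depletion_pct_selfconsistent"):
        if per_replicate[col].notna().all():
            out[col.replace("pct", "pct_mean")] = float(per_replicate[col].mean())
    return pd.Series(out)


# ---------------------------------------------------------------------------
# scans

@dataclass
class ExperimentConfig:
    scheme: Scheme | None = None
    n_ions: int = 20
    r0_um: float = 0.1
    segment_length_um: float | None = None  # None -> LET-based default
    replicates: int = 16
    master_seed: int = 1
    options: RunOptions = RunOptions()

    def resolved_scheme(self) -> Scheme:
        return self.scheme if self.scheme is not None else build_default_scheme()


def _pulse_for(config: ExperimentConfig, ion: IonSpec, let: float) -> PulseSpec:
    return PulseSpec(
        ion=ion,
        let=let,
        n_ions=config.n_ions,
        r0_um=config.r0_um,
        segment_length_um=config.segment_length_um,
    )


def scan_let(
    let_grid: list[float],
    config: ExperimentConfig = ExperimentConfig(),
) -> pd.DataFrame:
    """Proton LET scan: one summary row per LET, sorted by LET."""
    scheme = config.resolved_scheme()
    rows = []
    errors = {}
    for i, let in enumerate(sorted(let_grid)):
        ion = IonSpec.at_let("1H", let)
        pulse = _pulse_for(config, ion, let)
        try:
            reps = run_replicates(
                pulse, scheme, config.replicates,
                master_seed=config.master_seed + i, options=config.options,
            )
        except Exception as exc:  # per-point isolation
            errors[let] = repr(exc)
            continue
        rows.append(summarize(reps))
    result = pd.DataFrame(rows).reset_index(drop=True)
    result.attrs["errors"] = errors
    result.attrs["scheme_digest"] = scheme_digest(scheme)
    return result


def scan_ions_fixed_let(
    let: float = 70.0,
    ions: tuple[str, ...] = FIXED_LET_IONS,
    config: ExperimentConfig = ExperimentConfig(),
) -> pd.DataFrame:
    """Ion-species scan at fixed LET; one row per ion, sorted by Z."""
    scheme = config.resolved_scheme()
    rows = []
    errors = {}
    for i, symbol in enumerate(ions):
        ion = IonSpec.at_let(symbol, let)
        pulse = _pulse_for(config, ion, let)
        try:
            reps = run_replicates(
                pulse, scheme, config.replicates,
                master_seed=config.master_seed + 1000 + i, options=config.options,
            )
        except Exception as exc:
            errors[symbol] = repr(exc)
            continue
        rows.append(summarize(reps))
    result = pd.DataFrame(rows).sort_values("Z").reset_index(drop=True)
    result.attrs["errors"] = errors
    result.attrs["scheme_digest"] = scheme_digest(scheme)
    return result


def depletion_vs_initial_o2(
    o2_grid_mol_l: list[float],
    let: float = 0.3,
    config: ExperimentConfig = ExperimentConfig(),
) -> pd.DataFrame:
    """Depletion fractions (both conventions) per initial O2 concentration."""
    base = config.resolved_scheme()
    rows = []
    for i, c in enumerate(o2_grid_mol_l):
        scheme = base.with_background_concentration("O2", c)
        ion = IonSpec.at_let("1H", let)
        pulse = _pulse_for(config, ion, let)
        reps = run_replicates(
            pulse, scheme, config.replicates,
            master_seed=config.master_seed + 2000 + i, options=config.options,
        )
        s = summarize(reps)
        s["initial_O2_mol_l"] = c
        rows.append(s)
    return pd.DataFrame(rows).reset_index(drop=True)


# ---------------------------------------------------------------------------
# decomposition & calibration

def decompose_delta_g(combined: CombinedYieldSeries) -> pd.DataFrame:
    """Signed per-reaction contributions to G(-O2) on the full time grid.

    Consuming channels are positive, O2-regenerating channels negative; the
    row-wise sum equals the total G(-O2) exactly (partition identity).
    """
    hom = combined.homogeneous
    data = {"time_s": combined.times_s}
    total = np.zeros(len(combined.times_s))
    for k, rid in enumerate(hom.reaction_ids):
        w = -float(hom.o2_stoich[k])
        if w == 0.0:
            continue
        contrib = w * combined.reaction_delta_g[rid]
        data[rid] = contrib
        total = total + contrib
    data["total"] = total
    return pd.DataFrame(data)


def calibrate_rates(
    measured: list[tuple[float, float]],
    anchor_let: float,
    anchor_g: float,
    let_rtol: float = 0.05,
) -> list[tuple[float, float]]:
    """Proportional calibration: measured rates (mmHg/Gy) -> inferred G values.

    The measured rate at the anchor LET maps to the simulated anchor G; all
    other rates scale linearly: G = rate * anchor_G / anchor_rate.
    """
    anchor_rate = None
    for let, rate in measured:
        if abs(let - anchor_let) <= let_rtol * max(anchor_let, 1e-300):
            anchor_rate = rate
            break
    if anchor_rate is None:
        raise ValueError(f"no measured point at the anchor LET {anchor_let}")
    if anchor_rate == 0:
        raise ZeroDivisionError("anchor rate is zero")
    return [(let, rate * anchor_g / anchor_rate) for let, rate in measured]


def scheme_digest(scheme: Scheme) -> str:
    h = hashlib.sha256()
    for s in scheme.species:
        h.update(repr(s).encode())
    for r in scheme.reactions:
        h.update(repr(r).encode())
    for name in sorted(scheme.background_solutes):
        h.update(repr(scheme.background_solutes[name]).encode())
    return h.hexdigest()[:16]
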