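"""Species tables, reaction schemes and encounter parameters.

A :class:`Scheme` bundles the diffusing species, the reaction list and the
continuum (background) solutes of the aerated cellular-water model.  The
default scheme couples the standard pure-water radiolysis set at 25 C with a
cellular extension (generic oxidizable biomolecules RH, glutathione,
ascorbate, nitric oxide, alpha-tocopherol and dissolved oxygen at 30 uM).

Schemes live in editable tab-separated files so the chemistry can be audited
or swapped without touching code; see ``flashchem/data/``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

from .constants import (
    ONSAGER_RADIUS_NM,
    smoluchowski_radius_nm,
    smoluchowski_rate,
)

REACTION_CLASSES = (
    "fully-diffusion-controlled",
    "partially-diffusion-controlled",
    "background-scavenging",
    "first-order",
)


class SchemeValidationError(ValueError):
    """Raised when a scheme file violates a structural invariant."""


@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    diffusion_coefficient: float  # nm^2/ns
    charge: int
    notes: str = ""


@dataclass(frozen=True)
class ReactionSpec:
    id: str
    reactants: tuple[str, ...]          # 1 or 2 names
    products: tuple[str, ...]           # 0..4 names; implicit water omitted
    rate_constant: float                # M^-1 s^-1 or s^-1
    reaction_class: str
    encounter_radius_nm: float | None = None  # physical radius, optional
    source: str = ""

    @property
    def is_bimolecular(self) -> bool:
        return len(self.reactants) == 2


@dataclass(frozen=True)
class BackgroundSolute:
    name: str
    concentration: float  # mol/L
    depletable: bool


@dataclass
class Scheme:
    species: list[SpeciesSpec]
    reactions: list[ReactionSpec]
    background_solutes: dict[str, BackgroundSolute]
    temperature_c: float = 25.0
    _species_index: dict[str, SpeciesSpec] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._species_index = {s.name: s for s in self.species}

    def species_named(self, name: str) -> SpeciesSpec:
        return self._species_index[name]

    def has_species(self, name: str) -> bool:
        return name in self._species_index

    def reaction(self, rid: str) -> ReactionSpec:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def find_reaction(self, reactants: set[str]) -> ReactionSpec | None:
        for r in self.reactions:
            if set(r.reactants) == reactants:
                return r
        return None

    def is_background(self, name: str) -> bool:
        return name in self.background_solutes

    def background_concentration(self, name: str) -> float:
        return self.background_solutes[name].concentration

    def with_background_concentration(self, name: str, conc: float) -> "Scheme":
        """A copy of the scheme with one background pool changed."""
        if conc < 0:
            raise ValueError("background concentration must be >= 0")
        sol = dict(self.background_solutes)
        sol[name] = replace(sol[name], concentration=conc)
        return Scheme(self.species, self.reactions, sol, self.temperature_c)

    def without_reactions(self, ids: set[str]) -> "Scheme":
        """A copy of the scheme with the listed reactions removed (ablation)."""
        kept = [r for r in self.reactions if r.id not in ids]
        return Scheme(self.species, kept, dict(self.background_solutes), self.temperature_c)


# ---------------------------------------------------------------------------
# parsing / serialization

def _read_table(path: Path) -> list[dict[str, str]]:
    rows: list[dict[str, str]] = []
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = [c.strip() for c in cells]
                continue
            if len(cells) < len(header):
                cells += [""] * (len(header) - len(cells))
            rows.append({h: c.strip() for h, c in zip(header, cells)})
    if header is None:
        raise SchemeValidationError(f"{path}: empty table")
    return rows


def _resolve_paths(path: str | Path) -> tuple[Path, Path, Path]:
    p = Path(path)
    base = p if p.is_dir() else p.parent
    trio = base / "species.tsv", base / "reactions.tsv", base / "solutes.tsv"
    for f in trio:
        if not f.exists():
            raise FileNotFoundError(f"scheme table not found: {f}")
    return trio


def load_scheme(path: str | Path) -> Scheme:
    """Load and validate a scheme from a directory of TSV tables.

    ``path`` may be the directory or any one of the three table files
    (species.tsv, reactions.tsv, solutes.tsv).
    """
    sp_path, rx_path, sol_path = _resolve_paths(path)

    species = []
    for row in _read_table(sp_path):
        try:
            species.append(
                SpeciesSpec(
                    name=row["name"],
                    diffusion_coefficient=float(row["D"]),
                    charge=int(row["charge"]),
                    notes=row.get("notes", ""),
                )
            )
        except (KeyError, ValueError) as exc:
            raise SchemeValidationError(f"{sp_path}: bad species row {row}: {exc}") from exc

    reactions = []
    for row in _read_table(rx_path):
        reactants = tuple(r for r in (row["reactant1"], row.get("reactant2", "")) if r)
        products = tuple(p for p in row.get("products", "").split(";") if p)
        radius = row.get("radius_nm", "")
        try:
            reactions.append(
                ReactionSpec(
                    id=row["id"],
                    reactants=reactants,
                    products=products,
                    rate_constant=float(row["k"]),
                    reaction_class=row["class"],
                    encounter_radius_nm=float(radius) if radius else None,
                    source=row.get("source", ""),
                )
            )
        except (KeyError, ValueError) as exc:
            raise SchemeValidationError(f"{rx_path}: bad reaction row {row}: {exc}") from exc

    solutes = {}
    for row in _read_table(sol_path):
        solutes[row["name"]] = BackgroundSolute(
            name=row["name"],
            concentration=float(row["concentration"]),
            depletable=row["depletable"].lower() in ("true", "1", "yes"),
        )

    scheme = Scheme(species, reactions, solutes)
    validate_scheme(scheme)
    return scheme


def write_scheme(scheme: Scheme, directory: str | Path) -> None:
    """Write a scheme back to the three-table TSV layout (round-trips)."""
    base = Path(directory)
    base.mkdir(parents=True, exist_ok=True)
    with open(base / "species.tsv", "w", encoding="utf-8") as fh:
        fh.write("name\tD\tcharge\tnotes\n")
        for s in scheme.species:
            fh.write(f"{s.name}\t{s.diffusion_coefficient!r}\t{s.charge}\t{s.notes}\n")
    with open(base / "reactions.tsv", "w", encoding="utf-8") as fh:
        fh.write("id\treactant1\treactant2\tproducts\tk\tunits\tclass\tradius_nm\tsource\n")
        for r in scheme.reactions:
            r2 = r.reactants[1] if len(r.reactants) == 2 else ""
            units = "s-1" if r.reaction_class == "first-order" else "M-1s-1"
            rad = "" if r.encounter_radius_nm is None else repr(r.encounter_radius_nm)
            fh.write(
                f"{r.id}\t{r.reactants[0]}\t{r2}\t{';'.join(r.products)}\t"
                f"{r.rate_constant!r}\t{units}\t{r.reaction_class}\t{rad}\t{r.source}\n"
            )
    with open(base / "solutes.tsv", "w", encoding="utf-8") as fh:
        fh.write("name\tconcentration\tdepletable\n")
        for sol in scheme.background_solutes.values():
            fh.write(f"{sol.name}\t{sol.concentration!r}\t{str(sol.depletable).lower()}\n")


def build_default_scheme() -> Scheme:
    """The bundled default: pure-water set + cellular extension.

    Contains the four headline cellular reactions (ids R1-R4) with their
    printed rate constants, and the background pools of the 30 uM O2
    cellular water model.
    """
    data_dir = resources.files("flashchem") / "data"
    with resources.as_file(data_dir) as p:
        return load_scheme(p)


# ---------------------------------------------------------------------------
# validation

def validate_scheme(scheme: Scheme) -> None:
    names = [s.name for s in scheme.species]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise SchemeValidationError(f"duplicate species names: {dupes}")
    for s in scheme.species:
        if s.diffusion_coefficient < 0:
            raise SchemeValidationError(f"species {s.name}: negative diffusion coefficient")

    ids = [r.id for r in scheme.reactions]
    if len(set(ids)) != len(ids):
        raise SchemeValidationError("duplicate reaction ids")

    for r in scheme.reactions:
        if r.reaction_class not in REACTION_CLASSES:
            raise SchemeValidationError(f"reaction {r.id}: unknown class {r.reaction_class!r}")
        if not (1 <= len(r.reactants) <= 2):
            raise SchemeValidationError(f"reaction {r.id}: needs 1-2 reactants")
        if len(r.products) > 4:
            raise SchemeValidationError(f"reaction {r.id}: more than 4 products")
        if r.rate_constant <= 0:
            raise SchemeValidationError(f"reaction {r.id}: non-positive rate constant")
        for name in (*r.reactants, *r.products):
            if not scheme.has_species(name):
                raise SchemeValidationError(
                    f"reaction {r.id}: unknown species {name!r} not in species table"
                )
        q_in = sum(scheme.species_named(n).charge for n in r.reactants)
        q_out = sum(scheme.species_named(n).charge for n in r.products)
        if q_in != q_out:
            raise SchemeValidationError(
                f"reaction {r.id}: charge not conserved ({q_in} -> {q_out})"
            )
        if r.reaction_class == "first-order" and len(r.reactants) != 1:
            raise SchemeValidationError(f"reaction {r.id}: first-order needs one reactant")
        if r.reaction_class == "background-scavenging":
            n_bg = sum(scheme.is_background(n) for n in r.reactants)
            if len(r.reactants) != 2 or n_bg != 1:
                raise SchemeValidationError(
                    f"reaction {r.id}: background-scavenging needs exactly one "
                    f"background-solute reactant"
                )
        if r.reaction_class in REACTION_CLASSES[:2] and len(r.reactants) != 2:
            raise SchemeValidationError(f"reaction {r.id}: diffusion-controlled needs a pair")

    for name, sol in scheme.background_solutes.items():
        if not scheme.has_species(name):
            raise SchemeValidationError(f"background solute {name!r} not in species table")
        if sol.concentration < 0:
            raise SchemeValidationError(f"background solute {name}: negative concentration")


# ---------------------------------------------------------------------------
# encounter parameters

def debye_factor(z1z2: int, radius_nm: float) -> float:
    """Ratio of the charged to neutral diffusion-limited rate at contact R.

    f = r_c / (R * (exp(r_c/R) - 1)) with r_c = z1 z2 * Onsager radius;
    exactly 1 for an uncharged pair.
    """
    if z1z2 == 0:
        return 1.0
    rc = z1z2 * ONSAGER_RADIUS_NM
    return (rc / radius_nm) / math.expm1(rc / radius_nm)


def debye_effective_radius(z1z2: int, radius_nm: float) -> float:
    """Effective (neutral-equivalent) encounter radius of a charged pair.

    R_eff = r_c / (exp(r_c/R) - 1); > R for an attractive pair, < R for a
    repulsive one, -> R as the charge product -> 0.
    """
    if z1z2 == 0:
        return radius_nm
    rc = z1z2 * ONSAGER_RADIUS_NM
    return rc / math.expm1(rc / radius_nm)


def debye_transform_distance(z1z2: int, r_nm: float) -> float:
    """Debye-transformed separation used by the IRT first-passage kernel."""
    return debye_effective_radius(z1z2, r_nm)


def invert_debye_radius(z1z2: int, r_eff_nm: float) -> float:
    """Physical contact radius whose Debye-effective radius equals ``r_eff_nm``.

    Inverse of :func:`debye_effective_radius`.  For a repulsive pair any
    effective radius is attainable; for an attractive pair r_eff is bounded
    below by |r_c| (the Coulomb funnel), in which case the bound is an error.
    """
    if z1z2 == 0:
        return r_eff_nm
    rc = z1z2 * ONSAGER_RADIUS_NM
    arg = rc / r_eff_nm
    if arg <= -1.0:
        raise ValueError(
            "effective radius below the Coulomb-funnel bound |r_c| for an attractive pair"
        )
    return rc / math.log1p(arg)


def _pair_dsum(reaction: ReactionSpec, scheme: Scheme) -> float:
    d = 0.0
    for n in reaction.reactants:
        ds = scheme.species_named(n).diffusion_coefficient
        d += ds
    return d


def _pair_charge_product(reaction: ReactionSpec, scheme: Scheme) -> int:
    z1, z2 = (scheme.species_named(n).charge for n in reaction.reactants)
    return z1 * z2


def encounter_radius(reaction: ReactionSpec, scheme: Scheme):
    """Physical encounter parameters of a bimolecular reaction.

    Returns ``(radius_nm, activation_rate)`` where ``activation_rate`` is
    ``math.inf`` for fully diffusion-controlled reactions.

    * fully-diffusion-controlled: the radius R such that the (Debye-corrected)
      Smoluchowski rate 4 pi D' N_A R_eff equals the tabulated k;
    * partially-diffusion-controlled: the supplied physical radius plus the
      activation rate k_act with 1/k = 1/k_act + 1/k_diff (Collins-Kimball).
    """
    if not reaction.is_bimolecular:
        raise ValueError(f"reaction {reaction.id} is not bimolecular")
    dsum = _pair_dsum(reaction, scheme)
    if dsum <= 0:
        raise ValueError(f"reaction {reaction.id}: reactants have no diffusion coefficient")
    q = _pair_charge_product(reaction, scheme)

    if reaction.reaction_class == "partially-diffusion-controlled":
        radius = reaction.encounter_radius_nm
        if radius is None:
            raise ValueError(f"reaction {reaction.id}: partial control needs a physical radius")
        k_diff = smoluchowski_rate(radius, dsum) * debye_factor(q, radius)
        if reaction.rate_constant >= k_diff:
            raise ValueError(
                f"reaction {reaction.id}: k exceeds the diffusion limit at the supplied radius"
            )
        k_act = 1.0 / (1.0 / reaction.rate_constant - 1.0 / k_diff)
        return radius, k_act

    r_eff = smoluchowski_radius_nm(reaction.rate_constant, dsum)
    radius = invert_debye_radius(q, r_eff)
    if radius <= 0:
        raise ValueError(f"reaction {reaction.id}: derived radius non-positive")
    return radius, math.inf


def effective_sampling_radius(reaction: ReactionSpec, scheme: Scheme) -> float:
    """Neutral-equivalent effective radius used by the IRT kernel.

    R_eff = k_obs / (4 pi D' N_A).  This single number folds partial control
    and the Debye factor into the ultimate reaction probability W_inf =
    R_eff / r_eff(r0).
    """
    dsum = _pair_dsum(reaction, scheme)
    return smoluchowski_radius_nm(reaction.rate_constant, dsum)


def pseudo_first_order_rate(species: str, scheme: Scheme) -> dict[str, float]:
    """Scavenging capacities k*[S] (s^-1) of every background channel
    consuming ``species``, keyed by reaction id."""
    if not scheme.has_species(species):
        raise KeyError(species)
    out: dict[str, float] = {}
    for r in scheme.reactions:
        if r.reaction_class != "background-scavenging":
            continue
        if species not in r.reactants:
            continue
        partner = [n for n in r.reactants if n != species]
        if len(partner) != 1 or not scheme.is_background(partner[0]):
            continue
        if scheme.is_background(species) and not scheme.is_background(partner[0]):
            continue
        out[r.id] = r.rate_constant * scheme.background_concentration(partner[0])
    return out
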