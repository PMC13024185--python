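import numpy as np
import pytest

import flashchem as fc
from flashchem.scheme import build_default_scheme


@pytest.fixture(scope="session")
def scheme():
    return build_default_scheme()


@pytest.fixture(scope="session")
def water_only_scheme():
    """Pure-water subset with all background pools zeroed (no scavenging)."""
    s = build_default_scheme()
    s = s.without_reactions({r.id for r in s.reactions if not r.id.startswith("W")})
    for name in list(s.background_solutes):
        s = s.with_background_concentration(name, 0.0)
    return s


@pytest.fixture(scope="session")
def low_let_pulse():
    ion = fc.IonSpec.at_let("1H", 0.3)
    return fc.PulseSpec(ion=ion, let=0.3, n_ions=20)


def pair_scheme(reff_nm: float, d_each: float, charge1: int = 0, charge2: int = 0):
    """Two-species scheme with a single fully-diffusion-controlled reaction
    whose effective radius is exactly ``reff_nm``."""
    from flashchem.constants import smoluchowski_rate
    from flashchem.scheme import ReactionSpec, Scheme, SpeciesSpec

    k = smoluchowski_rate(reff_nm, 2 * d_each)
    species = [
        SpeciesSpec("A", d_each, charge1),
        SpeciesSpec("B", d_each, charge2),
        SpeciesSpec("C", 0.0, charge1 + charge2),
    ]
    rxn = ReactionSpec(
        id="P1", reactants=("A", "B"), products=("C",), rate_constant=k,
        reaction_class="fully-diffusion-controlled",
    )
    return Scheme(species, [rxn], {})
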