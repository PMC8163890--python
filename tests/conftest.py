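import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from lbpdesign.model import (
    CYTOSOL,
    EXTRACELLULAR,
    Medium,
    Metabolite,
    Reaction,
    StrainModel,
)


def make_chain_model(biomass_ub: float = 1000.0) -> StrainModel:
    """Linear toy: uptake A -> transport -> convert to B -> biomass eats B."""
    return StrainModel(
        strain_id="chain",
        metabolites=[
            Metabolite("A_e", "substrate A", EXTRACELLULAR),
            Metabolite("A_c", "substrate A", CYTOSOL),
            Metabolite("B_c", "precursor B", CYTOSOL),
        ],
        reactions=[
            Reaction("EX_A_e", {"A_e": -1.0}, 0.0, 1000.0, is_exchange=True),
            Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}, 0.0, 1000.0),
            Reaction("R_AB", {"A_c": -1.0, "B_c": 1.0}, 0.0, 1000.0),
            Reaction("BIOMASS", {"B_c": -1.0}, 0.0, biomass_ub, is_biomass=True),
        ],
        biomass_reaction_id="BIOMASS",
    )


def make_cross_feeder(strain_id: str, makes: str, needs: str) -> StrainModel:
    """One member of an obligate cross-feeding pair.

    Biomass consumes 1 unit of the shared substrate A and 1 unit of the
    partner-made compound; producing one unit of the exported compound costs
    1 unit of A.
    """
    return StrainModel(
        strain_id=strain_id,
        metabolites=[
            Metabolite("A_e", "shared substrate", EXTRACELLULAR),
            Metabolite("A_c", "shared substrate", CYTOSOL),
            Metabolite(f"{makes}_c", f"exported {makes}", CYTOSOL),
            Metabolite(f"{makes}_e", f"exported {makes}", EXTRACELLULAR),
            Metabolite(f"{needs}_c", f"required {needs}", CYTOSOL),
            Metabolite(f"{needs}_e", f"required {needs}", EXTRACELLULAR),
        ],
        reactions=[
            Reaction("EX_A_e", {"A_e": -1.0}, 0.0, 1000.0, is_exchange=True),
            Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}, 0.0, 1000.0),
            Reaction(f"SYN_{makes}", {"A_c": -1.0, f"{makes}_c": 1.0}, 0.0, 1000.0),
            Reaction(f"T_{makes}", {f"{makes}_c": -1.0, f"{makes}_e": 1.0}, -1000.0, 1000.0),
            Reaction(f"EX_{makes}_e", {f"{makes}_e": -1.0}, 0.0, 1000.0, is_exchange=True),
            Reaction(f"T_{needs}", {f"{needs}_e": -1.0, f"{needs}_c": 1.0}, 0.0, 1000.0),
            Reaction(f"EX_{needs}_e", {f"{needs}_e": -1.0}, 0.0, 1000.0, is_exchange=True),
            Reaction(
                "BIOMASS", {"A_c": -1.0, f"{needs}_c": -1.0}, 0.0, 1000.0, is_biomass=True
            ),
        ],
        biomass_reaction_id="BIOMASS",
    )


@pytest.fixture
def chain_model():
    return make_chain_model()


@pytest.fixture
def medium_a5():
    return Medium({"A_e": 5.0}, name="A5")


@pytest.fixture
def cross_feeding_pair():
    return [make_cross_feeder("P1", "x", "y"), make_cross_feeder("P2", "y", "x")]


@pytest.fixture
def shared_a10():
    return Medium({"A_e": 10.0}, name="A10")
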