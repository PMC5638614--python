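"""Strain scenario presets for the synthetic-data generator.

Each scenario bundles a chromosome map, the degradation components of the
broken-cell subpopulation, and the branching parameters of the heritable
focus-loss process.  Coordinates are documented synthetic approximations of
an MG1655-like chromosome (length 4,641,652 bp); only dif (1,588 kb) and
the terminus-deletion endpoints (1,379,810-1,617,226) follow printed
values, the remaining Ter/oriC positions are rounded field-standard
figures and can be overridden by a user-supplied map config.

Scenarios
---------
wild_type   - intact fork trap, no DNA loss.
recB        - breaks at the dif/GC-skew convergence point in 32% of cells
              (initial-event probability 0.177, transmission 0.745).
terB_star   - ectopic clockwise-blocking Ter 29 kb downstream of TerA moves
              the fork merge point away from dif; the dif break persists
              (48% of cells) plus a weaker Tus-dependent break at the new
              trap.
dLC3_R111   - 237,416 bp terminus deletion removing dif/hipA/TerC; the
              break follows the new GC-skew convergence point at the
              junction of the chromosome arms.
invT2       - 150 kb inversion flipping TerA/TerD so clockwise forks arrest
              in the inverted region; dif break persists plus a weak break
              at the inverted TerA.
invT3       - 175 kb Ter-free inversion next to dif; the dif break is
              unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import (
    CLOCKWISE,
    COUNTERCLOCKWISE,
    ChromosomeMap,
    Rearrangement,
    TerSite,
    apply_rearrangement,
)
from .lineage import BranchingParams
from .simulate import DegradationModel, ReplicationParams

GENOME_LENGTH = 4_641_652
ORIC = 3_925_000
DIF = 1_588_000
HIPA = 1_590_000

# printed deletion endpoints of the terminus-deletion strain
DLC3_START = 1_379_810
DLC3_END = 1_617_226

TER_SITES = (
    TerSite("TerE", 1_100_000, COUNTERCLOCKWISE),
    TerSite("TerD", 1_279_000, COUNTERCLOCKWISE),
    TerSite("TerA", 1_340_000, COUNTERCLOCKWISE),
    TerSite("TerC", 1_609_000, CLOCKWISE),
    TerSite("TerB", 1_682_000, CLOCKWISE),
)
TERB_STAR = 1_369_000  # ectopic TerB, 29 kb downstream (clockwise) of TerA

INVT2 = Rearrangement("inversion", 1_229_000, 1_379_000)  # spans TerD and TerA
INVT3 = Rearrangement("inversion", 1_379_000, 1_554_000)  # Ter-free, ends 34 kb from dif
DLC3 = Rearrangement("deletion", DLC3_START, DLC3_END)


@dataclass(frozen=True)
class Scenario:
    name: str
    chrom: ChromosomeMap
    degradation: tuple[DegradationModel, ...]
    branching: BranchingParams
    replication: ReplicationParams = field(default_factory=ReplicationParams)
    description: str = ""

    @property
    def break_position(self) -> int | None:
        return self.degradation[0].b if self.degradation else None


def base_map() -> ChromosomeMap:
    """Wild-type MG1655-like map (synthetic approximate coordinates)."""
    return ChromosomeMap(
        length_bp=GENOME_LENGTH,
        oriC=ORIC,
        loci={"dif": DIF, "hipA": HIPA},
        ter_sites=TER_SITES,
        name="chr",
    )


def _terb_star_map() -> ChromosomeMap:
    m = base_map()
    return ChromosomeMap(
        length_bp=m.length_bp,
        oriC=m.oriC,
        loci=m.loci,
        ter_sites=m.ter_sites + (TerSite("TerB*", TERB_STAR, CLOCKWISE),),
        name=m.name,
    )


def _scenarios() -> dict[str, Scenario]:
    wt = base_map()
    recb_branching = BranchingParams(q=0.177, h=0.745)
    dlc3_map = apply_rearrangement(wt, DLC3)
    dlc3_map = ChromosomeMap(
        length_bp=dlc3_map.length_bp,
        oriC=dlc3_map.oriC,
        loci={**dlc3_map.loci, "junction": DLC3_START},
        ter_sites=dlc3_map.ter_sites,
        rearrangements=dlc3_map.rearrangements,
        name=dlc3_map.name,
    )
    invt2_map = apply_rearrangement(wt, INVT2)
    invt3_map = apply_rearrangement(wt, INVT3)
    terb_star_map = _terb_star_map()
    inv_terA = invt2_map.ter("TerA").position

    return {
        "wild_type": Scenario(
            name="wild_type",
            chrom=wt,
            degradation=(),
            branching=BranchingParams(q=0.0, h=0.0),
            description="intact RecBCD repair: no terminus DNA loss",
        ),
        "recB": Scenario(
            name="recB",
            chrom=wt,
            degradation=(DegradationModel(f=0.32, b=DIF, L=100_000),),
            branching=recb_branching,
            description="division-induced breaks at the dif convergence point",
        ),
        "terB_star": Scenario(
            name="terB_star",
            chrom=terb_star_map,
            degradation=(
                DegradationModel(f=0.48, b=DIF, L=100_000),
                DegradationModel(f=0.12, b=TERB_STAR, L=40_000),
            ),
            branching=BranchingParams(q=0.253, h=0.8065),
            description=(
                "ectopic Ter moves the fork merge point; dif break persists "
                "with a weaker Tus-dependent break at the new trap"
            ),
        ),
        "dLC3_R111": Scenario(
            name="dLC3_R111",
            chrom=dlc3_map,
            degradation=(
                DegradationModel(f=0.49, b=DLC3_START, L=80_000),
            ),
            branching=BranchingParams(q=0.19, h=0.771),
            description="terminus deletion: break at the new arm junction",
        ),
        "invT2": Scenario(
            name="invT2",
            chrom=invt2_map,
            degradation=(
                DegradationModel(f=0.435, b=DIF, L=100_000),
                DegradationModel(f=0.12, b=inv_terA, L=40_000),
            ),
            branching=recb_branching,
            description="TerA/TerD inversion: dif break plus inverted-TerA break",
        ),
        "invT3": Scenario(
            name="invT3",
            chrom=invt3_map,
            degradation=(DegradationModel(f=0.384, b=DIF, L=110_000),),
            branching=recb_branching,
            description="Ter-free inversion next to dif: dif break unaffected",
        ),
    }


SCENARIO_NAMES = tuple(_scenarios().keys())


def get_scenario(name: str) -> Scenario:
    try:
        return _scenarios()[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}"
        ) from None
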