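"""The germinal-center (GC) B-cell logical model and its wild-type attractors.

The model couples four signaling pathways (BCR/PI3K, MAPK, NF-kB, JAK/STAT)
to the expression of the B-cell differentiation markers MYC, BCL6, BLIMP1
and BCL2 (plus the somatic-hypermutation enzyme AID as an auxiliary
read-out).  Nineteen components: three receptor inputs (BCR, CD40, IL21/4),
thirteen Boolean intermediates/markers, and three ternary components
(IKKc, NFkB, IRF4) whose level-2 activity encodes strong, CD40-driven
NF-kB signaling as opposed to the low, transient level-1 activity driven
by the BCR branch.  NF-kB is written ``NFkB`` in identifiers.

Each of the eight receptor-input combinations yields exactly one fixpoint;
five combinations are physiological GC stages (LZ1, Pre-GC, DZ, LZ2, PC)
and the three with T-cell signals but no BCR engagement are
non-physiological.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .logic import (
    Component,
    LevelRule,
    LogicalNetwork,
    State,
    enumerate_fixpoints,
    parse_expression,
)

INPUT_NAMES = ("BCR", "CD40", "IL21/4")
TERNARY_NAMES = ("IKKc", "NFkB", "IRF4")
MARKER_GENES = ("MYC", "BCL6", "BLIMP1", "BCL2")
AUXILIARY_MARKER = "AID"

# Component order used everywhere: inputs, signaling cascade, marker genes.
_COMPONENT_ORDER = (
    "BCR", "CD40", "IL21/4",
    "SYK", "BTK", "PI3K", "RAF", "ERK", "CBM", "TRAF6",
    "IKKc", "NFkB", "STAT", "IRF4",
    "MYC", "BCL6", "BLIMP1", "AID", "BCL2",
)

# Level rules.  Multi-regulator functions follow the published truth table;
# single-regulator components copy their sole activator.  IKKc integrates the
# two NF-kB-activating branches: the BCR arm (via the CARD11-BCL10-MALT1
# complex, CBM) yields level 1, the CD40 arm (via TRAF6) yields level 2, and
# NFkB / IRF4 propagate the IKKc level unchanged.
_RULES: dict[str, dict[int, str]] = {
    "SYK": {1: "BCR"},
    "BTK": {1: "BCR"},
    "PI3K": {1: "SYK & BTK"},
    "RAF": {1: "BTK"},
    "ERK": {1: "RAF & !STAT"},
    "CBM": {1: "BTK"},
    "TRAF6": {1: "CD40"},
    "IKKc": {2: "TRAF6", 1: "CBM"},
    "NFkB": {2: "IKKc:2", 1: "IKKc"},
    "STAT": {1: "IL21/4"},
    "IRF4": {2: "NFkB:2", 1: "NFkB"},
    "MYC": {1: "PI3K & NFkB & !BLIMP1 & !BCL6"},
    "BCL6": {1: "IRF4 & !IRF4:2 & !(ERK | BLIMP1)"},
    "BLIMP1": {1: "IRF4:2 & STAT & !BCL6"},
    "AID": {1: "NFkB & STAT & !BLIMP1"},
    "BCL2": {1: "(PI3K | NFkB) & !BCL6"},
}


@lru_cache(maxsize=1)
def build_gc_network() -> LogicalNetwork:
    """Construct the 19-component wild-type GC network."""
    components = tuple(
        Component(
            name,
            max_level=2 if name in TERNARY_NAMES else 1,
            is_input=name in INPUT_NAMES,
        )
        for name in _COMPONENT_ORDER
    )
    rules = {
        name: LevelRule(
            tuple((lvl, parse_expression(src)) for lvl, src in table.items())
        )
        for name, table in _RULES.items()
    }
    return LogicalNetwork(components, rules)


def builtin_model_text() -> str:
    """The GC model in the model-definition text format (shipped file)."""
    return (
        resources.files("gclogic").joinpath("data/gc_model.model").read_text("utf-8")
    )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Stage:
    """One receptor-input combination and its GC interpretation."""

    stage_id: int
    name: str
    inputs: tuple[int, int, int]  # (BCR, CD40, IL21/4)
    physiological: bool

    @property
    def input_assignment(self) -> dict[str, int]:
        return dict(zip(INPUT_NAMES, self.inputs))


def classify_nonphysiological(input_triple: tuple[int, int, int]) -> bool:
    """T-cell help (CD40 and/or IL21/4) without BCR engagement is non-physiological."""
    bcr, cd40, il = input_triple
    return bcr == 0 and (cd40 == 1 or il == 1)


def _stage_name(triple: tuple[int, int, int]) -> str:
    return {
        (0, 0, 0): "LZ1",
        (1, 0, 0): "Pre-GC",
        (1, 0, 1): "DZ",
        (1, 1, 0): "LZ2",
        (1, 1, 1): "PC",
    }.get(triple, "n.phys.")


def _stage_id(triple: tuple[int, int, int]) -> int:
    bcr, cd40, il = triple
    return 1 + 4 * bcr + 2 * cd40 + il


STAGES: tuple[Stage, ...] = tuple(
    sorted(
        (
            Stage(
                _stage_id((b, c, i)),
                _stage_name((b, c, i)),
                (b, c, i),
                not classify_nonphysiological((b, c, i)),
            )
            for b in (0, 1)
            for c in (0, 1)
            for i in (0, 1)
        ),
        key=lambda s: s.stage_id,
    )
)

PHYSIOLOGICAL_STAGE_IDS = tuple(s.stage_id for s in STAGES if s.physiological)  # 1,5,6,7,8
STAGE_BY_ID = {s.stage_id: s for s in STAGES}
STAGE_BY_NAME = {s.name: s for s in STAGES if s.physiological}


# ---------------------------------------------------------------------------
# Marker patterns and attractor profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerPattern:
    """Activity flags of the stage-defining markers; AID carried separately."""

    myc: bool
    bcl6: bool
    blimp1: bool
    bcl2: bool
    aid: bool = False

    @classmethod
    def from_state(cls, state: State) -> "MarkerPattern":
        return cls(
            myc=state["MYC"] >= 1,
            bcl6=state["BCL6"] >= 1,
            blimp1=state["BLIMP1"] >= 1,
            bcl2=state["BCL2"] >= 1,
            aid=state[AUXILIARY_MARKER] >= 1,
        )

    @property
    def active(self) -> frozenset[str]:
        """Active marker genes; AID is excluded from pattern identity."""
        flags = (self.myc, self.bcl6, self.blimp1, self.bcl2)
        return frozenset(g for g, on in zip(MARKER_GENES, flags) if on)

    @property
    def label(self) -> str:
        if not self.active:
            return "none"
        return "+".join(g for g in MARKER_GENES if g in self.active)


def marker_pattern(state: State) -> MarkerPattern:
    return MarkerPattern.from_state(state)


@dataclass(frozen=True)
class StageAttractors:
    """Fixpoints of one model under one stage's input assignment."""

    stage: Stage
    lost: bool
    fixpoints: tuple[State, ...]

    @property
    def markers(self) -> tuple[MarkerPattern, ...]:
        return tuple(MarkerPattern.from_state(s) for s in self.fixpoints)

    @property
    def marker_sets(self) -> frozenset[frozenset[str]]:
        """Marker-gene activity of each fixpoint, as a set of sets."""
        return frozenset(m.active for m in self.markers)

    @property
    def label(self) -> str:
        if self.lost:
            return "lost"
        if not self.fixpoints:
            return "no fixpoint"
        return "/".join(m.label for m in self.markers)


@dataclass(frozen=True)
class AttractorProfile:
    """Stage-resolved fixpoints of one model (wild type or patient)."""

    model_id: str
    stages: tuple[StageAttractors, ...]

    def stage(self, stage_id: int) -> StageAttractors:
        for sa in self.stages:
            if sa.stage.stage_id == stage_id:
                return sa
        raise KeyError(f"stage {stage_id} not in profile")

    def by_name(self, stage_name: str) -> StageAttractors:
        return self.stage(STAGE_BY_NAME[stage_name].stage_id)


def wild_type_profile(network: LogicalNetwork | None = None) -> AttractorProfile:
    """The eight wild-type attractors, one fixpoint per input combination.

    Raises ``RuntimeError`` if any stage does not have exactly one fixpoint,
    which would indicate an inconsistent (non-wild-type) network.
    """
    network = network or build_gc_network()
    rows = []
    for stage in STAGES:
        fps = enumerate_fixpoints(network, stage.input_assignment)
        if len(fps) != 1:
            raise RuntimeError(
                f"wild-type stage {stage.name} (id {stage.stage_id}) has "
                f"{len(fps)} fixpoints, expected exactly 1"
            )
        rows.append(StageAttractors(stage, lost=False, fixpoints=tuple(fps)))
    return AttractorProfile("WT", tuple(rows))
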