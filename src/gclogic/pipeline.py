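"""Patient-specific models: attractor profiles, wild-type comparison,
oncogenicity flags and NF-kB dependency classes.

A patient model is the wild-type GC network with the patient's genotype
clamps applied.  Its profile lists, for every physiological GC stage, the
fixpoints under that stage's receptor inputs; a stage whose input
combination contradicts an input clamp (e.g. constitutively active BCR vs
the no-signal LZ1 stage) is flagged *lost* rather than simulated.

Oncogenicity is read off the profile: aggressive marker co-expression
(BCL6 with MYC and/or BCL2), markers in the wrong stage, loss of the
plasma-cell exit, or loss of the no-signal LZ1 state (the model's
apoptosis-permissive state).  Separately, each model is assigned one of
five NF-kB dependency classes describing how its marker output relates to
NF-kB signaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .gc_model import (
    INPUT_NAMES,
    MARKER_GENES,
    PHYSIOLOGICAL_STAGE_IDS,
    STAGE_BY_ID,
    STAGES,
    AttractorProfile,
    Stage,
    StageAttractors,
    build_gc_network,
    wild_type_profile,
)
from .lesions import PerturbationSet
from .logic import LogicalNetwork, apply_clamps, enumerate_fixpoints, propagate_constants

# NF-kB dependency classes
NFKB_UNPERTURBED = "unperturbed"
NFKB_LEVEL1 = "level1"
NFKB_LEVEL2 = "level2"
NFKB_INACTIVE = "inactive"
NFKB_INDEPENDENT = "independent"
NFKB_CLASSES = (
    NFKB_UNPERTURBED,
    NFKB_LEVEL1,
    NFKB_LEVEL2,
    NFKB_INACTIVE,
    NFKB_INDEPENDENT,
)
NFKB_DEPENDENT_CLASSES = (NFKB_UNPERTURBED, NFKB_LEVEL1, NFKB_LEVEL2)


@dataclass(frozen=True)
class PatientModel:
    """A genotype-clamped network with its provenance."""

    model_id: str
    network: LogicalNetwork
    perturbations: PerturbationSet

    @property
    def genotype_clamps(self) -> Mapping[str, int]:
        return self.perturbations.clamps


def build_patient_model(
    base_network: LogicalNetwork | None,
    perturbations: PerturbationSet,
    model_id: str | None = None,
) -> PatientModel:
    """Clamp the base network with a patient's resolved perturbations."""
    base_network = base_network or build_gc_network()
    network = apply_clamps(base_network, perturbations.clamps)
    return PatientModel(model_id or perturbations.patient_id, network, perturbations)


def _stage_lost(network: LogicalNetwork, stage: Stage) -> bool:
    """An input clamp contradicting the stage's input triple makes it unreachable."""
    for name, wanted in stage.input_assignment.items():
        if name in network.clamps and network.clamps[name] != wanted:
            return True
    return False


def profile(
    model: PatientModel | LogicalNetwork,
    stage_ids: Sequence[int] | None = None,
    model_id: str | None = None,
) -> AttractorProfile:
    """Stage-resolved fixpoints of a model over the physiological stages.

    A stage with zero fixpoints (possible only for exotic clamp sets) is
    reported with an empty fixpoint list, distinct from a lost stage.
    """
    if isinstance(model, PatientModel):
        network = model.network
        model_id = model_id or model.model_id
    else:
        network = model
        model_id = model_id or "model"
    stage_ids = tuple(stage_ids) if stage_ids is not None else PHYSIOLOGICAL_STAGE_IDS
    rows = []
    for sid in stage_ids:
        stage = STAGE_BY_ID[sid]
        if _stage_lost(network, stage):
            rows.append(StageAttractors(stage, lost=True, fixpoints=()))
            continue
        assignment = {
            name: lvl
            for name, lvl in stage.input_assignment.items()
            if name not in network.clamps
        }
        fps = enumerate_fixpoints(network, assignment)
        rows.append(StageAttractors(stage, lost=False, fixpoints=tuple(fps)))
    return AttractorProfile(model_id, tuple(rows))


# ---------------------------------------------------------------------------
# Wild-type comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageDelta:
    stage_id: int
    stage_name: str
    lost: bool
    changed: bool
    gained_markers: frozenset[str]  # aberrantly active vs WT
    lost_markers: frozenset[str]    # aberrantly inactive vs WT


@dataclass(frozen=True)
class ProfileComparison:
    changed_stage_count: int
    lost_stages: tuple[int, ...]
    deltas: tuple[StageDelta, ...]

    def delta(self, stage_id: int) -> StageDelta:
        for d in self.deltas:
            if d.stage_id == stage_id:
                return d
        raise KeyError(f"stage {stage_id} not compared")


def compare_to_wild_type(
    wt_profile: AttractorProfile, patient_profile: AttractorProfile
) -> ProfileComparison:
    """Count stages whose marker pattern differs from wild type.

    Comparison is at marker-pattern level (the activity of MYC, BCL6,
    BLIMP1, BCL2); a lost stage counts as changed.  Only stages present in
    the patient profile and physiological in the stage map are compared.
    """
    deltas = []
    lost = []
    for sa in patient_profile.stages:
        if not sa.stage.physiological:
            continue
        wt_sa = wt_profile.stage(sa.stage.stage_id)
        wt_active = frozenset().union(*wt_sa.marker_sets) if wt_sa.marker_sets else frozenset()
        if sa.lost:
            lost.append(sa.stage.stage_id)
            deltas.append(
                StageDelta(
                    sa.stage.stage_id, sa.stage.name, True, True,
                    frozenset(), frozenset(),
                )
            )
            continue
        pt_active = (
            frozenset().union(*sa.marker_sets) if sa.marker_sets else frozenset()
        )
        changed = sa.marker_sets != wt_sa.marker_sets
        deltas.append(
            StageDelta(
                sa.stage.stage_id,
                sa.stage.name,
                False,
                changed,
                pt_active - wt_active,
                wt_active - pt_active,
            )
        )
    return ProfileComparison(
        changed_stage_count=sum(d.changed for d in deltas),
        lost_stages=tuple(lost),
        deltas=tuple(deltas),
    )


# ---------------------------------------------------------------------------
# Oncogenicity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OncogenicityReport:
    """Independent oncogenicity flags; any set flag marks the model oncogenic."""

    abnormal_combination: bool  # BCL6 together with MYC and/or BCL2
    wrong_stage: bool           # BCL6 outside DZ, or MYC outside Pre-GC/LZ2
    pc_loss: bool               # PC stage lost, or its attractor lacks BLIMP1
    lz1_loss: bool              # LZ1 lost, or any marker active in LZ1

    @property
    def oncogenic(self) -> bool:
        return (
            self.abnormal_combination
            or self.wrong_stage
            or self.pc_loss
            or self.lz1_loss
        )


_MYC_ALLOWED_STAGES = {"Pre-GC", "LZ2"}
_BCL6_ALLOWED_STAGES = {"DZ"}


def classify_oncogenic(patient_profile: AttractorProfile) -> OncogenicityReport:
    abnormal = False
    wrong_stage = False
    pc_loss = False
    lz1_loss = False
    for sa in patient_profile.stages:
        if not sa.stage.physiological:
            continue
        name = sa.stage.name
        if sa.lost:
            if name == "PC":
                pc_loss = True
            if name == "LZ1":
                lz1_loss = True
            continue
        for markers in sa.marker_sets:
            if "BCL6" in markers and ("MYC" in markers or "BCL2" in markers):
                abnormal = True
            if "BCL6" in markers and name not in _BCL6_ALLOWED_STAGES:
                wrong_stage = True
            if "MYC" in markers and name not in _MYC_ALLOWED_STAGES:
                wrong_stage = True
            if name == "PC" and "BLIMP1" not in markers:
                pc_loss = True
            if name == "LZ1" and markers:
                lz1_loss = True
    return OncogenicityReport(abnormal, wrong_stage, pc_loss, lz1_loss)


# ---------------------------------------------------------------------------
# NF-kB dependency
# ---------------------------------------------------------------------------

def classify_nfkb(model: PatientModel) -> str:
    """Assign one of the five NF-kB dependency classes to a patient model.

    Decision cascade (first match wins):

    1. *independent* -- the genotype clamps MYC or BCL6 active, so a marker
       gene is driven regardless of NF-kB state;
    2. *inactive* -- the genotype clamps NF-kB (or its sole driver IKKc)
       to 0;
    3. *level2* / *level1* -- the model shows constitutive NF-kB at level 2
       or 1 in its minimal reachable input condition (all unclamped
       receptors off), i.e. the genotype itself sustains NF-kB signaling;
    4. *unperturbed* -- otherwise.

    The cascade is total and deterministic for every perturbation set.
    """
    clamps = dict(model.genotype_clamps)
    if clamps.get("MYC", 0) >= 1 or clamps.get("BCL6", 0) >= 1:
        return NFKB_INDEPENDENT
    if clamps.get("NFkB") == 0 or clamps.get("IKKc") == 0:
        return NFKB_INACTIVE
    network = model.network
    assignment = {
        c.name: 0 for c in network.inputs if c.name not in network.clamps
    }
    fixed, _free = propagate_constants(network, assignment)
    if "NFkB" in fixed:
        level = fixed["NFkB"]
    else:  # pragma: no cover - NFkB upstream is acyclic in the GC model
        fps = enumerate_fixpoints(network, assignment)
        level = max((fp["NFkB"] for fp in fps), default=0)
    if level >= 2:
        return NFKB_LEVEL2
    if level == 1:
        return NFKB_LEVEL1
    return NFKB_UNPERTURBED


# ---------------------------------------------------------------------------
# Cohort-level convenience
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientReport:
    model: PatientModel
    profile: AttractorProfile
    comparison: ProfileComparison
    oncogenicity: OncogenicityReport
    nfkb_class: str
    coo_label: str | None = None


def analyze_patient(
    perturbations: PerturbationSet,
    base_network: LogicalNetwork | None = None,
    wt: AttractorProfile | None = None,
    coo_label: str | None = None,
) -> PatientReport:
    """Run the full per-patient pipeline from a resolved perturbation set."""
    base_network = base_network or build_gc_network()
    wt = wt or wild_type_profile(base_network)
    model = build_patient_model(base_network, perturbations)
    prof = profile(model)
    return PatientReport(
        model=model,
        profile=prof,
        comparison=compare_to_wild_type(wt, prof),
        oncogenicity=classify_oncogenic(prof),
        nfkb_class=classify_nfkb(model),
        coo_label=coo_label,
    )
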