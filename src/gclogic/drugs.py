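"""In-silico inhibitor simulation on patient-specific models.

Four inhibitors are modeled as full clamps of their target component to 0:
Ibrutinib (BTK), Copanlisib (PI3K), Bortezomib (NF-kB) and Venetoclax
(BCL2).  Drug clamps override genotype clamps on the same component, so a
BCL2 inhibitor silences BCL2 even in a BCL2-amplified model; conversely a
drug acting upstream of a genotype clamp has no effect on it.

Treatment response is scored with the 'no marker' surrogate: the fraction
of reachable physiological stages whose attractor has MYC, BCL6, BLIMP1
and BCL2 all inactive, taken as a proxy for loss of pro-survival signaling
(apoptosis is not modeled explicitly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .gc_model import AttractorProfile
from .logic import apply_clamps
from .pipeline import PatientModel, profile


@dataclass(frozen=True)
class Drug:
    key: str
    inhibitor: str
    target: str
    label: str


DRUGS: Mapping[str, Drug] = {
    "btk": Drug("btk", "Ibrutinib", "BTK", "BTKi"),
    "nfkb": Drug("nfkb", "Bortezomib", "NFkB", "NFKBi"),
    "pi3k": Drug("pi3k", "Copanlisib", "PI3K", "PI3Ki"),
    "bcl2": Drug("bcl2", "Venetoclax", "BCL2", "BCL2i"),
}

_DRUG_ORDER = ("btk", "nfkb", "pi3k", "bcl2")

Regimen = frozenset

#: The seven regimen blocks evaluated by default: no drug, each single
#: inhibitor, and the two BCL2-anchored combinations.
DEFAULT_REGIMENS: tuple[Regimen, ...] = (
    frozenset(),
    frozenset({"btk"}),
    frozenset({"nfkb"}),
    frozenset({"pi3k"}),
    frozenset({"bcl2"}),
    frozenset({"pi3k", "bcl2"}),
    frozenset({"nfkb", "bcl2"}),
)


def parse_regimen(text: str) -> Regimen:
    """Parse a comma combination such as ``"nfkb,bcl2"`` (``"none"`` -> empty)."""
    text = text.strip().lower()
    if text in ("", "none"):
        return frozenset()
    keys = [t.strip() for t in text.split(",")]
    unknown = [k for k in keys if k not in DRUGS]
    if unknown:
        raise KeyError(
            f"unknown drug name(s) {unknown}; choose from {sorted(DRUGS)}"
        )
    return frozenset(keys)


def regimen_label(regimen: Regimen) -> str:
    if not regimen:
        return "none"
    return "+".join(DRUGS[k].label for k in _DRUG_ORDER if k in regimen)


def regimen_clamps(regimen: Regimen) -> dict[str, int]:
    """One (target, 0) clamp per drug in the regimen."""
    unknown = [k for k in regimen if k not in DRUGS]
    if unknown:
        raise KeyError(f"unknown drug name(s) {unknown}")
    return {DRUGS[k].target: 0 for k in regimen}


@dataclass(frozen=True)
class TreatmentOutcome:
    model_id: str
    regimen: Regimen
    profile: AttractorProfile
    no_marker_stage_count: int
    reachable_stage_count: int
    total_active_markers: int

    @property
    def no_marker_fraction(self) -> float:
        if self.reachable_stage_count == 0:
            return 0.0
        return self.no_marker_stage_count / self.reachable_stage_count

    @property
    def label(self) -> str:
        return regimen_label(self.regimen)


def simulate_treatment(model: PatientModel, regimen: Regimen) -> TreatmentOutcome:
    """Profile the drug-clamped model and score the 'no marker' surrogate.

    Drug clamps are applied after the genotype clamps and therefore replace
    them wherever both touch the same component.  Lost stages are excluded
    from the denominator.
    """
    treated = apply_clamps(model.network, regimen_clamps(regimen))
    prof = profile(treated, model_id=model.model_id)
    reachable = [sa for sa in prof.stages if not sa.lost]
    no_marker = sum(
        1
        for sa in reachable
        if sa.fixpoints and all(not m.active for m in sa.markers)
    )
    total_active = sum(len(m.active) for sa in reachable for m in sa.markers)
    return TreatmentOutcome(
        model_id=model.model_id,
        regimen=frozenset(regimen),
        profile=prof,
        no_marker_stage_count=no_marker,
        reachable_stage_count=len(reachable),
        total_active_markers=total_active,
    )


def rank_regimens(
    model: PatientModel, candidate_regimens: Sequence[Regimen] | None = None
) -> list[TreatmentOutcome]:
    """Simulate candidates and order them from most to least effective.

    Sort key: more 'no marker' stages first; ties broken by fewer active
    markers summed over stages, then by smaller regimens, then
    lexicographically by drug keys for determinism.
    """
    candidates = (
        tuple(candidate_regimens) if candidate_regimens is not None else DEFAULT_REGIMENS
    )
    if not candidates:
        raise ValueError("need at least one candidate regimen")
    outcomes = [simulate_treatment(model, regimen) for regimen in candidates]
    outcomes.sort(
        key=lambda o: (
            -o.no_marker_stage_count,
            o.total_active_markers,
            len(o.regimen),
            tuple(sorted(o.regimen)),
        )
    )
    return outcomes
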