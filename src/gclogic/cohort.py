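"""Synthetic DLBCL genotype cohorts and the worked patient fixtures.

The generator emulates the statistical shape of a large DLBCL sequencing
cohort without reproducing any real patient data: per-gene lesion
frequencies with BCL2 clearly the most frequent target, 1-10 mapped
lesions per patient, cell-of-origin labels, and the characteristic
subtype split of BCL2 alterations (amplifications in ABC, mutations and
structural variants in GCB tumors).  Per-gene frequencies are free,
documented parameters of the generator, not estimates of any published
table.

``fixture_patients`` returns nine hand-curated genotypes whose mapped
perturbation sets exercise every qualitative behavior discussed for the
worked patient models (LZ1 loss, BCL6+BCL2 co-activation, constitutive
BCL6 dominance, NF-kB loss with IRF4 rescue, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .lesions import (
    CN_HIGH_GAIN,
    CN_HIGH_LOSS,
    CN_LOW_GAIN,
    CN_LOW_LOSS,
    CN_NEUTRAL,
    NONSYNONYMOUS_MUTATION,
    SV,
    SYNONYMOUS_MUTATION,
    Lesion,
    default_mapping,
    lesion_frame,
)


class CohortConfigError(ValueError):
    """A cohort specification is infeasible or malformed."""


#: DLBCL driver genes deliberately *outside* the model's mapping table,
#: used to emit realistic unmappable noise records.
UNMAPPED_NOISE_GENES = ("TP53", "KMT2D", "PIM1", "SOCS1", "B2M")

_DROPPABLE_CLASSES = (
    SYNONYMOUS_MUTATION,
    CN_LOW_GAIN,
    CN_LOW_LOSS,
    CN_NEUTRAL,
)


def _default_gene_weights() -> dict[str, float]:
    weights = {rule.gene: 1.0 for rule in default_mapping()}
    weights["BCL2"] = 3.0  # clearly the most frequent lesion target
    return weights


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic genotype generator.

    ``lesion_rate`` is the Poisson mean of the per-patient extra-lesion
    count; counts are shifted by one and truncated to
    [``min_lesions``, ``max_lesions``] so every patient carries 1-10 mapped
    lesions under the defaults.  ``noise_fraction`` is the probability of
    adding one filterable record (synonymous/low-grade/neutral event or an
    unmapped gene) per patient; the default emits none.
    """

    n_patients: int = 304
    gene_weights: Mapping[str, float] = field(default_factory=_default_gene_weights)
    coo_probs: Mapping[str, float] = field(
        default_factory=lambda: {"ABC": 0.40, "GCB": 0.45, "unclassified": 0.15}
    )
    class_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            NONSYNONYMOUS_MUTATION: 0.60,
            CN_HIGH_GAIN: 0.25,
            CN_HIGH_LOSS: 0.10,
            SV: 0.05,
        }
    )
    bcl2_by_coo: bool = True
    min_lesions: int = 1
    max_lesions: int = 10
    lesion_rate: float = 2.0
    noise_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "gene_weights", dict(self.gene_weights))
        object.__setattr__(self, "coo_probs", dict(self.coo_probs))
        object.__setattr__(self, "class_probs", dict(self.class_probs))
        if self.n_patients < 1:
            raise CohortConfigError("n_patients must be positive")
        if not 1 <= self.min_lesions <= self.max_lesions:
            raise CohortConfigError("need 1 <= min_lesions <= max_lesions")
        if self.min_lesions > len(self.gene_weights):
            raise CohortConfigError(
                "min_lesions exceeds the number of mappable genes"
            )
        for name, probs in (("coo_probs", self.coo_probs), ("class_probs", self.class_probs)):
            if any(p < 0 for p in probs.values()) or not np.isclose(
                sum(probs.values()), 1.0
            ):
                raise CohortConfigError(f"{name} must be a probability distribution")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise CohortConfigError("noise_fraction must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise CohortConfigError(f"cohort spec {path} must be a mapping")
        try:
            return cls(**data)
        except TypeError as exc:
            raise CohortConfigError(f"bad cohort spec {path}: {exc}") from exc


def generate_cohort(spec: CohortSpec | None = None, seed: int | None = None) -> pd.DataFrame:
    """Draw a reproducible synthetic lesion table.

    Returns a long-format DataFrame (patient_id, gene, alteration_class,
    coo_label).  Identical spec and seed give byte-identical tables.
    """
    spec = spec or CohortSpec()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)

    genes = sorted(spec.gene_weights)
    weights = np.array([spec.gene_weights[g] for g in genes], dtype=float)
    if (weights < 0).any() or weights.sum() <= 0:
        raise CohortConfigError("gene weights must be non-negative and not all zero")
    probs = weights / weights.sum()

    coo_labels = sorted(spec.coo_probs)
    coo_p = np.array([spec.coo_probs[c] for c in coo_labels])
    classes = sorted(spec.class_probs)
    class_p = np.array([spec.class_probs[c] for c in classes])

    width = max(3, len(str(spec.n_patients)))
    records: list[Lesion] = []
    for i in range(spec.n_patients):
        patient_id = f"P{i + 1:0{width}d}"
        coo = coo_labels[rng.choice(len(coo_labels), p=coo_p)]
        k = spec.min_lesions + int(rng.poisson(spec.lesion_rate))
        k = min(k, spec.max_lesions, len(genes))
        chosen = rng.choice(len(genes), size=k, replace=False, p=probs)
        for gi in sorted(chosen):
            gene = genes[gi]
            if gene == "BCL2" and spec.bcl2_by_coo:
                if coo == "ABC":
                    cls = CN_HIGH_GAIN
                elif coo == "GCB":
                    cls = NONSYNONYMOUS_MUTATION if rng.random() < 0.7 else SV
                else:
                    cls = classes[rng.choice(len(classes), p=class_p)]
            else:
                cls = classes[rng.choice(len(classes), p=class_p)]
            records.append(Lesion(patient_id, gene, cls, coo))
        if spec.noise_fraction and rng.random() < spec.noise_fraction:
            if rng.random() < 0.5:
                gene = UNMAPPED_NOISE_GENES[rng.choice(len(UNMAPPED_NOISE_GENES))]
                cls = NONSYNONYMOUS_MUTATION
            else:
                gene = genes[rng.choice(len(genes), p=probs)]
                cls = _DROPPABLE_CLASSES[rng.choice(len(_DROPPABLE_CLASSES))]
            records.append(Lesion(patient_id, gene, cls, coo))
    return lesion_frame(records)


def cohort_lesions(frame: pd.DataFrame) -> dict[str, list[Lesion]]:
    """Group a lesion table into per-patient lesion lists (insertion order)."""
    by_patient: dict[str, list[Lesion]] = {}
    for row in frame.itertuples(index=False):
        coo = row.coo_label or None
        by_patient.setdefault(row.patient_id, []).append(
            Lesion(row.patient_id, row.gene, row.alteration_class, coo)
        )
    return by_patient


# ---------------------------------------------------------------------------
# Worked patient fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureGenotype:
    """One worked patient genotype; lesion classes default to ``sv`` where
    the narrative does not state mutation vs amplification (both map to the
    same clamp under the default table)."""

    model_id: str
    lesions: tuple[Lesion, ...]


def _fx(model_id: str, *gene_classes: tuple[str, str]) -> FixtureGenotype:
    return FixtureGenotype(
        model_id,
        tuple(Lesion(model_id, g, c) for g, c in gene_classes),
    )


def fixture_patients() -> tuple[FixtureGenotype, ...]:
    """The nine worked patient genotypes used throughout the test suite."""
    return (
        _fx("131", ("CD79B", NONSYNONYMOUS_MUTATION)),
        _fx("73", ("MCL1", SV)),
        _fx(
            "29",
            ("BCL2", SV),
            ("STAT3", NONSYNONYMOUS_MUTATION),
            ("EZH2", NONSYNONYMOUS_MUTATION),
        ),
        _fx(
            "47",
            ("TLR2", NONSYNONYMOUS_MUTATION),
            ("PTEN", CN_HIGH_LOSS),
        ),
        _fx(
            "34",
            ("CARD11", NONSYNONYMOUS_MUTATION),
            ("MYC", CN_HIGH_GAIN),
            ("BCL2", CN_HIGH_GAIN),
        ),
        _fx(
            "60",
            ("MEF2B", NONSYNONYMOUS_MUTATION),
            ("TLR2", NONSYNONYMOUS_MUTATION),
        ),
        _fx(
            "85",
            ("EP300", NONSYNONYMOUS_MUTATION),
            ("BCL2", SV),
        ),
        _fx(
            "27",
            ("BCL2", SV),
            ("MYC", SV),
            ("EZH2", NONSYNONYMOUS_MUTATION),
            ("MEF2B", NONSYNONYMOUS_MUTATION),
            ("CREBBP", NONSYNONYMOUS_MUTATION),
            ("PTEN", NONSYNONYMOUS_MUTATION),
        ),
        _fx(
            "92",
            ("NFKBIE", CN_HIGH_GAIN),
            ("IRF4", CN_HIGH_GAIN),
        ),
    )


def fixtures_lesion_table() -> pd.DataFrame:
    """All fixture genotypes as one lesion table."""
    records = [l for fx in fixture_patients() for l in fx.lesions]
    return lesion_frame(records)
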