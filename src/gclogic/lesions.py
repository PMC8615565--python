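"""Mapping genotype lesion tables onto model-component clamps.

Lesion records use the Oncoprint-style alteration vocabulary (mutations,
copy-number categories, structural variants).  Only strong events are kept:
non-synonymous mutations, structural variants and high-grade copy-number
gains/losses.  Each retained lesion is turned into a gain-of-function (GOF)
or loss-of-function (LOF) clamp on the model component its gene acts on,
taking the sign of the gene->component edge into account: a LOF in a
tumor suppressor that *inhibits* its target (e.g. TNFAIP3/A20 on IKKc)
becomes a GOF of the target.  GOF clamps pin the component at its maximal
level (2 for the ternary components), LOF clamps pin it at 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .gc_model import build_gc_network
from .logic import LogicalNetwork

log = logging.getLogger(__name__)


class LesionTableError(ValueError):
    """A lesion record or lesion table is malformed."""


class MappingTableError(ValueError):
    """A gene->component mapping table is malformed."""


class MappingError(KeyError):
    """No mapping rule exists for a gene that was asked to be interpreted."""


# -- alteration vocabulary ---------------------------------------------------

NONSYNONYMOUS_MUTATION = "nonsynonymous_mutation"
SYNONYMOUS_MUTATION = "synonymous_mutation"
SV = "sv"
CN_HIGH_GAIN = "cn_high_gain"
CN_LOW_GAIN = "cn_low_gain"
CN_NEUTRAL = "cn_neutral"
CN_LOW_LOSS = "cn_low_loss"
CN_HIGH_LOSS = "cn_high_loss"

ALTERATION_CLASSES = frozenset(
    {
        NONSYNONYMOUS_MUTATION,
        SYNONYMOUS_MUTATION,
        SV,
        CN_HIGH_GAIN,
        CN_LOW_GAIN,
        CN_NEUTRAL,
        CN_LOW_LOSS,
        CN_HIGH_LOSS,
    }
)

#: Classes considered strong enough to perturb the model.
HIGH_IMPACT_CLASSES = frozenset(
    {NONSYNONYMOUS_MUTATION, SV, CN_HIGH_GAIN, CN_HIGH_LOSS}
)

ONCOGENE = "oncogene"
TUMOR_SUPPRESSOR = "tumor_suppressor"
ACTIVATING = "activating"
INHIBITING = "inhibiting"

GOF = "GOF"
LOF = "LOF"

COO_LABELS = ("ABC", "GCB", "unclassified")


@dataclass(frozen=True)
class Lesion:
    patient_id: str
    gene: str
    alteration_class: str
    coo_label: str | None = None

    def __post_init__(self):
        if self.alteration_class not in ALTERATION_CLASSES:
            raise LesionTableError(
                f"unknown alteration class {self.alteration_class!r} "
                f"for gene {self.gene!r} (patient {self.patient_id!r})"
            )


@dataclass(frozen=True)
class MappingRule:
    gene: str
    component: str
    gene_role: str
    edge_sign: str

    def __post_init__(self):
        if self.gene_role not in (ONCOGENE, TUMOR_SUPPRESSOR):
            raise MappingTableError(
                f"{self.gene}: bad role {self.gene_role!r} "
                f"(expected {ONCOGENE!r} or {TUMOR_SUPPRESSOR!r})"
            )
        if self.edge_sign not in (ACTIVATING, INHIBITING):
            raise MappingTableError(
                f"{self.gene}: bad edge sign {self.edge_sign!r} "
                f"(expected {ACTIVATING!r} or {INHIBITING!r})"
            )


@dataclass(frozen=True)
class PerturbationSet:
    """Resolved per-patient clamps plus notes on GOF/LOF conflicts."""

    patient_id: str
    clamps: Mapping[str, int] = field(default_factory=dict)
    conflicts: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "clamps", dict(self.clamps))


# -- default gene -> component table ----------------------------------------
#
# Every mapping documented for the model: BCR-proximal kinases, RAS family
# onto RAF, the CBM complex, the negative IKK regulator A20 (TNFAIP3),
# receptor adaptors onto TRAF6, NF-kB family members (cREL activating,
# the IkB-epsilon inhibitor NFKBIE inverted), STAT family, PTEN onto PI3K,
# the BCL6 activators MEF2B/IRF8 and the acetyltransferases CREBBP/EP300
# that restrain BCL6, EZH2 silencing BLIMP1, and the BCL2-family
# pro-survival genes lumped onto BCL2.

_DEFAULT_TABLE: tuple[tuple[str, str, str, str], ...] = (
    ("CD79B", "BCR", ONCOGENE, ACTIVATING),
    ("SYK", "SYK", ONCOGENE, ACTIVATING),
    ("BTK", "BTK", ONCOGENE, ACTIVATING),
    ("HRAS", "RAF", ONCOGENE, ACTIVATING),
    ("KRAS", "RAF", ONCOGENE, ACTIVATING),
    ("NRAS", "RAF", ONCOGENE, ACTIVATING),
    ("CARD11", "CBM", ONCOGENE, ACTIVATING),
    ("BCL10", "CBM", ONCOGENE, ACTIVATING),
    ("MALT1", "CBM", ONCOGENE, ACTIVATING),
    ("TNFAIP3", "IKKc", TUMOR_SUPPRESSOR, INHIBITING),
    ("TLR2", "TRAF6", ONCOGENE, ACTIVATING),
    ("MYD88", "TRAF6", ONCOGENE, ACTIVATING),
    ("REL", "NFkB", ONCOGENE, ACTIVATING),
    ("NFKBIE", "NFkB", ONCOGENE, INHIBITING),
    ("IRF4", "IRF4", ONCOGENE, ACTIVATING),
    ("STAT1", "STAT", ONCOGENE, ACTIVATING),
    ("STAT3", "STAT", ONCOGENE, ACTIVATING),
    ("STAT5", "STAT", ONCOGENE, ACTIVATING),
    ("STAT6", "STAT", ONCOGENE, ACTIVATING),
    ("PTEN", "PI3K", TUMOR_SUPPRESSOR, INHIBITING),
    ("MEF2B", "BCL6", ONCOGENE, ACTIVATING),
    ("IRF8", "BCL6", ONCOGENE, ACTIVATING),
    ("CREBBP", "BCL6", TUMOR_SUPPRESSOR, INHIBITING),
    ("EP300", "BCL6", TUMOR_SUPPRESSOR, INHIBITING),
    ("EZH2", "BLIMP1", ONCOGENE, INHIBITING),
    ("MYC", "MYC", ONCOGENE, ACTIVATING),
    ("BCL2", "BCL2", ONCOGENE, ACTIVATING),
    ("BCL2L1", "BCL2", ONCOGENE, ACTIVATING),
    ("MCL1", "BCL2", ONCOGENE, ACTIVATING),
)


@lru_cache(maxsize=1)
def default_mapping() -> tuple[MappingRule, ...]:
    """The built-in gene->component mapping table (documented genes only)."""
    return tuple(MappingRule(*row) for row in _DEFAULT_TABLE)


def mapping_index(rules: Iterable[MappingRule]) -> dict[str, MappingRule]:
    index: dict[str, MappingRule] = {}
    for rule in rules:
        if rule.gene in index:
            raise MappingTableError(f"duplicate mapping for gene {rule.gene!r}")
        index[rule.gene] = rule
    return index


MAPPING_COLUMNS = ("gene", "component", "role", "edge_sign")


def load_mapping_table(path, network: LogicalNetwork | None = None) -> tuple[MappingRule, ...]:
    """Read a TSV mapping table and validate it against the model components."""
    network = network or build_gc_network()
    known = set(network.names)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as exc:
        raise MappingTableError(f"cannot read mapping table {path}: {exc}") from exc
    if tuple(df.columns) != MAPPING_COLUMNS:
        raise MappingTableError(
            f"mapping table must have columns {MAPPING_COLUMNS}, got {tuple(df.columns)}"
        )
    rules = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            rule = MappingRule(row.gene, row.component, row.role, row.edge_sign)
        except MappingTableError as exc:
            raise MappingTableError(f"line {i}: {exc}") from exc
        if rule.component not in known:
            raise MappingTableError(
                f"line {i}: unknown model component {rule.component!r}"
            )
        rules.append(rule)
    return tuple(rules)


def write_mapping_table(rules: Iterable[MappingRule], path) -> None:
    df = pd.DataFrame(
        [(r.gene, r.component, r.gene_role, r.edge_sign) for r in rules],
        columns=MAPPING_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# -- lesion tables -----------------------------------------------------------

LESION_COLUMNS = ("patient_id", "gene", "alteration_class", "coo_label")


def read_lesion_table(path) -> list[Lesion]:
    """Read a long-format lesion TSV (patient_id, gene, alteration_class[, coo_label])."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as exc:
        raise LesionTableError(f"cannot read lesion table {path}: {exc}") from exc
    required = ("patient_id", "gene", "alteration_class")
    if tuple(df.columns[:3]) != required:
        raise LesionTableError(
            f"lesion table must start with columns {required}, got {tuple(df.columns)}"
        )
    has_coo = "coo_label" in df.columns
    lesions = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        coo = getattr(row, "coo_label", None) if has_coo else None
        if isinstance(coo, float):  # NaN from pandas
            coo = None
        try:
            lesions.append(Lesion(row.patient_id, row.gene, row.alteration_class, coo))
        except LesionTableError as exc:
            raise LesionTableError(f"line {i}: {exc}") from exc
    return lesions


def write_lesion_table(lesions: Iterable[Lesion], path) -> None:
    df = lesion_frame(lesions)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def lesion_frame(lesions: Iterable[Lesion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (l.patient_id, l.gene, l.alteration_class, l.coo_label or "")
            for l in lesions
        ],
        columns=LESION_COLUMNS,
    )


# -- filtering and interpretation -------------------------------------------

def filter_lesions(
    lesions: Iterable[Lesion], rules: Iterable[MappingRule] | None = None
) -> list[Lesion]:
    """Keep strong, mappable events; drop the rest.

    Retains non-synonymous mutations, structural variants and high-grade CN
    gains/losses of genes present in the mapping table; synonymous
    mutations, low-grade and neutral CN events and unmapped genes are
    discarded.
    """
    index = mapping_index(rules if rules is not None else default_mapping())
    kept = []
    for lesion in lesions:
        if lesion.alteration_class not in HIGH_IMPACT_CLASSES:
            continue
        if lesion.gene not in index:
            log.info("dropping lesion in unmapped gene %s", lesion.gene)
            continue
        kept.append(lesion)
    return kept


def lesion_direction(lesion: Lesion, rule: MappingRule) -> str:
    """GOF/LOF direction of the lesion *on the target component*.

    Copy-number gains are GOF and losses LOF of the gene; mutations and
    structural variants are GOF for oncogenes and LOF for tumor
    suppressors.  An inhibiting gene->component edge inverts the direction.
    """
    if lesion.alteration_class == CN_HIGH_GAIN:
        direction = GOF
    elif lesion.alteration_class == CN_HIGH_LOSS:
        direction = LOF
    elif lesion.alteration_class in (NONSYNONYMOUS_MUTATION, SV):
        direction = GOF if rule.gene_role == ONCOGENE else LOF
    else:
        raise LesionTableError(
            f"lesion class {lesion.alteration_class!r} is not interpretable "
            "(filter lesions first)"
        )
    if rule.edge_sign == INHIBITING:
        direction = LOF if direction == GOF else GOF
    return direction


def interpret_lesion(
    lesion: Lesion,
    rule: MappingRule | None = None,
    network: LogicalNetwork | None = None,
) -> tuple[str, int]:
    """Translate one lesion into a component clamp ``(component, level)``.

    GOF clamps to the component's maximal level (so ternary components adopt
    level 2), LOF clamps to 0.
    """
    network = network or build_gc_network()
    if rule is None:
        try:
            rule = mapping_index(default_mapping())[lesion.gene]
        except KeyError:
            raise MappingError(f"no mapping rule for gene {lesion.gene!r}")
    direction = lesion_direction(lesion, rule)
    comp = network.component(rule.component)
    level = comp.max_level if direction == GOF else 0
    return rule.component, level


def genotype_to_perturbations(
    patient_id: str,
    lesions: Iterable[Lesion],
    rules: Iterable[MappingRule] | None = None,
    network: LogicalNetwork | None = None,
) -> PerturbationSet:
    """Filter, map and resolve a patient's lesions into one clamp per component.

    Duplicate same-direction clamps merge silently.  When a component
    receives both GOF and LOF clamps, LOF wins (protein loss is epistatic to
    activating point mutations for the genes modeled here) and the conflict
    is recorded in the perturbation set.
    """
    network = network or build_gc_network()
    rules = tuple(rules) if rules is not None else default_mapping()
    index = mapping_index(rules)
    levels: dict[str, set[int]] = {}
    for lesion in filter_lesions(lesions, rules):
        component, level = interpret_lesion(lesion, index[lesion.gene], network)
        levels.setdefault(component, set()).add(level)
    clamps: dict[str, int] = {}
    conflicts: list[str] = []
    for component in sorted(levels):
        values = levels[component]
        if len(values) > 1:
            clamps[component] = 0  # LOF wins
            conflicts.append(
                f"{component}: conflicting GOF/LOF clamps {sorted(values)}; kept LOF"
            )
            log.warning("patient %s: %s", patient_id, conflicts[-1])
        else:
            clamps[component] = values.pop()
    return PerturbationSet(patient_id, clamps, tuple(conflicts))
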