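"""Sixteen-criterion FAIRness rubric over dataset/tool descriptors.

Each criterion is a single boolean predicate over a
:class:`ResourceDescriptor` — identification, metadata, access protocol,
persistence, vocabulary, licensing, linking, provenance, and community
certification properties of a dataset or software tool.  ``assess`` applies
the ordered rubric; ``assess_bag`` first derives every flag that the state
of a bag plus its registry landing record can witness (an RO manifest is
machine-readable, standardized, formally expressed metadata with a
vocabulary context; a resolvable landing record is a persistent identifier
whose metadata contains the identifier and carries the registry's open
metadata license; registered locations are reachable over open standard
protocols) and only then requires declarations for what packaging cannot
prove: web-search discoverability, the resource license, membership in a
linked set, and a community certificate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

from .bag import Bag
from .errors import IncompleteDescriptorError, RegistryError
from .registry import IdentifierRecord, Registry

_FLAG_FIELDS = [
    "identifier_persistent",
    "machine_readable_metadata",
    "standardized_metadata",
    "identifier_in_metadata",
    "web_search_discoverable",
    "open_access_protocol",
    "restricted_access_protocol",
    "persistence_policy",
    "formal_language",
    "fair_vocabulary",
    "license",
    "linked_set",
    "metadata_license",
    "provenance_scheme",
    "community_certificate",
]


@dataclass
class ResourceDescriptor:
    """FAIR-relevant properties of one dataset or software tool.

    Flags left ``None`` are unset; ``assess`` refuses a descriptor with
    unset flags rather than guessing."""

    kind: str = "dataset"            # dataset | software
    identifier: Optional[str] = None
    identifier_persistent: Optional[bool] = None
    machine_readable_metadata: Optional[bool] = None
    standardized_metadata: Optional[bool] = None
    identifier_in_metadata: Optional[bool] = None
    web_search_discoverable: Optional[bool] = None
    open_access_protocol: Optional[bool] = None
    restricted_access_protocol: Optional[bool] = None
    persistence_policy: Optional[bool] = None
    formal_language: Optional[bool] = None
    fair_vocabulary: Optional[bool] = None
    license: Optional[bool] = None
    linked_set: Optional[bool] = None
    metadata_license: Optional[bool] = None
    provenance_scheme: Optional[bool] = None
    community_certificate: Optional[bool] = None


@dataclass(frozen=True)
class Criterion:
    name: str
    flag: str                        # descriptor field the predicate reads

    def satisfied_by(self, d: ResourceDescriptor) -> bool:
        if self.flag == "identifier":
            return bool(d.identifier)
        value = getattr(d, self.flag)
        if value is None:
            raise IncompleteDescriptorError([self.flag])
        return bool(value)


# Row order is frozen for stable reports.
CRITERIA: tuple[Criterion, ...] = (
    Criterion("Globally unique identifier", "identifier"),
    Criterion("Persistent Identifier", "identifier_persistent"),
    Criterion("Machine-readable metadata", "machine_readable_metadata"),
    Criterion("Standardized metadata", "standardized_metadata"),
    Criterion("Resource identifier in metadata", "identifier_in_metadata"),
    Criterion("Resource discovery through web search", "web_search_discoverable"),
    Criterion("Open, Free, Standardized Access protocol", "open_access_protocol"),
    Criterion("Protocol to access restricted content", "restricted_access_protocol"),
    Criterion("Persistence of resource and metadata", "persistence_policy"),
    Criterion("Resource uses formal language", "formal_language"),
    Criterion("FAIR vocabulary", "fair_vocabulary"),
    Criterion("Digital resource license", "license"),
    Criterion("Linked Set", "linked_set"),
    Criterion("Metadata License", "metadata_license"),
    Criterion("Provenance scheme", "provenance_scheme"),
    Criterion("Certificate of compliance to community standard", "community_certificate"),
)


def rubric_criteria() -> list[Criterion]:
    """The 16 criteria, in fixed report order."""
    return list(CRITERIA)


@dataclass
class RubricResult:
    verdicts: list[bool] = field(default_factory=list)   # ordered as CRITERIA

    @property
    def satisfied_count(self) -> int:
        return sum(self.verdicts)

    def as_mapping(self) -> dict[str, bool]:
        return {c.name: v for c, v in zip(CRITERIA, self.verdicts)}


def assess(descriptor: ResourceDescriptor) -> RubricResult:
    """Apply the rubric.  A descriptor with unset flags raises an
    :class:`IncompleteDescriptorError` listing every missing flag."""
    missing = [f for f in _FLAG_FIELDS if getattr(descriptor, f) is None]
    if missing:
        raise IncompleteDescriptorError(missing)
    return RubricResult([c.satisfied_by(descriptor) for c in CRITERIA])


def derive_descriptor(
    bag: Bag,
    record: IdentifierRecord,
    registry: Optional[Registry] = None,
) -> ResourceDescriptor:
    """Fill every flag that the bag's state and the landing record witness;
    the rest stay unset for the caller to declare."""
    if registry is not None:
        try:
            record = registry.resolve(record.curie)
        except RegistryError as exc:
            raise IncompleteDescriptorError([f"identifier ({exc})"]) from exc
    ro = bag.ro_manifest
    has_ro = ro is not None
    d = ResourceDescriptor(kind="dataset")
    d.identifier = record.curie
    d.identifier_persistent = True                      # registry records are permanent
    d.machine_readable_metadata = has_ro
    d.standardized_metadata = has_ro                    # RO JSON-LD profile
    d.identifier_in_metadata = bool(record.curie)       # landing record names itself
    d.open_access_protocol = bool(record.locations)
    d.restricted_access_protocol = bool(record.locations)
    d.persistence_policy = True                         # landing records outlive data
    d.formal_language = has_ro                          # JSON-LD
    d.fair_vocabulary = bool(has_ro and ro.context)
    d.metadata_license = bool(record.extra.get("metadata_license"))
    d.provenance_scheme = bool(
        has_ro and ro.created_by is not None and ro.created_on
    )
    return d


def assess_bag(
    bag: Bag,
    record: IdentifierRecord,
    declared: Optional[dict[str, bool]] = None,
    registry: Optional[Registry] = None,
) -> RubricResult:
    """Derive flags from the bag and its landing record, overlay explicit
    declarations, then assess."""
    d = derive_descriptor(bag, record, registry)
    valid_names = {f.name for f in fields(ResourceDescriptor)}
    for name, value in (declared or {}).items():
        if name not in valid_names:
            raise IncompleteDescriptorError([f"unknown flag {name!r}"])
        setattr(d, name, value)
    return assess(d)


# ---------------------------------------------------------------------------
# the case-study configuration: 6 datasets and 7 tools, all identified,
# persistent, documented, licensed, linked and provenance-tracked; only the
# upstream repository dataset (D1) and the tools are discoverable through a
# web search index; none holds a community-standard certificate.

CASE_STUDY_RESOURCES: tuple[tuple[str, str], ...] = (
    ("D1", "dataset"),
    ("D2", "dataset"),
    ("D3", "dataset"),
    ("D4", "dataset"),
    ("D5", "dataset"),
    ("D6", "dataset"),
    ("T1", "software"),
    ("T2", "software"),
    ("T3", "software"),
    ("T4", "software"),
    ("T5", "software"),
    ("T6", "software"),
    ("T7", "software"),
)


def case_study_descriptors() -> dict[str, ResourceDescriptor]:
    """The 13 resource descriptors of the TFBS case study."""
    out: dict[str, ResourceDescriptor] = {}
    for name, kind in CASE_STUDY_RESOURCES:
        web = kind == "software" or name == "D1"
        out[name] = ResourceDescriptor(
            kind=kind,
            identifier=f"minid:{name.lower()}xxxx",
            identifier_persistent=True,
            machine_readable_metadata=True,
            standardized_metadata=True,
            identifier_in_metadata=True,
            web_search_discoverable=web,
            open_access_protocol=True,
            restricted_access_protocol=True,
            persistence_policy=True,
            formal_language=True,
            fair_vocabulary=True,
            license=True,
            linked_set=True,
            metadata_license=True,
            provenance_scheme=True,
            community_certificate=False,
        )
    return out


def case_study_matrix() -> dict[str, RubricResult]:
    """Assess all 13 case-study descriptors; keys ordered D1–D6, T1–T7."""
    return {name: assess(d) for name, d in case_study_descriptors().items()}
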