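"""Research Object manifests embedded in a bag's ``metadata/`` directory.

The RO manifest aggregates the bag's contents (local payload files by their
bag-relative path, remote references by their locator URI) and carries
attribution (``createdBy``/``createdOn``) plus annotations about aggregated
resources or the bag as a whole.  It is serialized as JSON-LD at
``metadata/manifest.json`` and covered by the tag manifests, so tampering
with metadata is caught by full bag validation exactly like payload damage.

The profile is deliberately minimal: a fixed context list and four top-level
keys. No nested provenance chains, no full ORE vocabulary.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Union

from .bag import Bag
from .errors import AbsentMetadataError, ConsistencyError

DEFAULT_CONTEXT = ["https://w3id.org/bundle/context"]

BAG_TARGET = "."  # annotation target meaning "the bag itself"


def _utc_seconds(ts: Optional[datetime]) -> str:
    ts = ts or datetime.now(timezone.utc)
    return ts.astimezone(timezone.utc).replace(microsecond=0).isoformat()


@dataclass
class Agent:
    name: str
    uri: Optional[str] = None

    def to_dict(self) -> dict:
        d = {"name": self.name}
        if self.uri:
            d["uri"] = self.uri
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Agent":
        return cls(name=d["name"], uri=d.get("uri"))


@dataclass
class Aggregate:
    """One aggregated resource: a bag-relative path or an external URI."""

    uri: str
    mediatype: Optional[str] = None
    digest: Optional[str] = None

    def to_dict(self) -> dict:
        d: dict = {"uri": self.uri}
        if self.mediatype:
            d["mediatype"] = self.mediatype
        if self.digest:
            d["digest"] = self.digest
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Aggregate":
        return cls(uri=d["uri"], mediatype=d.get("mediatype"), digest=d.get("digest"))


@dataclass
class Annotation:
    about: str          # an aggregate uri, or BAG_TARGET for the whole bag
    content: str        # bag-relative file under metadata/annotations/, or a URI

    def to_dict(self) -> dict:
        return {"about": self.about, "content": self.content}

    @classmethod
    def from_dict(cls, d: dict) -> "Annotation":
        return cls(about=d["about"], content=d["content"])


@dataclass
class RoManifest:
    context: list[str] = field(default_factory=lambda: list(DEFAULT_CONTEXT))
    created_on: str = ""
    created_by: Optional[Agent] = None
    aggregates: list[Aggregate] = field(default_factory=list)
    annotations: list[Annotation] = field(default_factory=list)

    def to_json_bytes(self) -> bytes:
        doc = {
            "@context": self.context,
            "createdOn": self.created_on,
            "createdBy": self.created_by.to_dict() if self.created_by else None,
            "aggregates": [a.to_dict() for a in self.aggregates],
            "annotations": [a.to_dict() for a in self.annotations],
        }
        return (json.dumps(doc, indent=2, sort_keys=True) + "\n").encode("utf-8")

    @classmethod
    def from_json_bytes(cls, raw: bytes) -> "RoManifest":
        doc = json.loads(raw.decode("utf-8"))
        return cls(
            context=list(doc.get("@context", [])),
            created_on=doc.get("createdOn", ""),
            created_by=Agent.from_dict(doc["createdBy"]) if doc.get("createdBy") else None,
            aggregates=[Aggregate.from_dict(a) for a in doc.get("aggregates", [])],
            annotations=[Annotation.from_dict(a) for a in doc.get("annotations", [])],
        )


def _aggregate_uris(bag: Bag) -> set[str]:
    uris = {e.path for e in bag.payload if e.present}
    uris.update(r.locator for r in bag.remotes)
    # remote targets are also addressable by their eventual payload path
    uris.update(r.target_path for r in bag.remotes)
    return uris


def build_manifest(
    bag: Bag,
    agent: Agent,
    annotations: Optional[list[Annotation]] = None,
    created_on: Optional[datetime] = None,
) -> RoManifest:
    """Build an RO manifest enumerating every payload entry and remote
    reference of *bag*, attach it, and return it.  The caller serializes via
    ``write_bag`` (which places it at metadata/manifest.json and registers it
    in the tag manifests)."""
    aggregates = []
    remote_targets = {r.target_path for r in bag.remotes}
    for e in sorted(bag.payload, key=lambda e: e.path):
        if e.path in remote_targets:
            continue
        digest = None
        if e.digests:
            alg = sorted(e.digests)[0]
            digest = f"{alg}:{e.digests[alg]}"
        aggregates.append(Aggregate(uri=e.path, digest=digest))
    for r in sorted(bag.remotes, key=lambda r: r.target_path):
        aggregates.append(Aggregate(uri=r.locator))

    valid_targets = _aggregate_uris(bag) | {BAG_TARGET}
    for ann in annotations or []:
        if ann.about not in valid_targets:
            raise ConsistencyError(
                f"annotation about non-aggregated target: {ann.about!r}"
            )

    manifest = RoManifest(
        created_on=_utc_seconds(created_on),
        created_by=agent,
        aggregates=aggregates,
        annotations=list(annotations or []),
    )
    bag.ro_manifest = manifest
    return manifest


def check_aggregation_consistency(bag: Bag) -> list[str]:
    """Cross-check the RO manifest against the bag's payload and remotes.

    Returns an empty list iff they are mutually consistent; otherwise one
    human-readable inconsistency per problem."""
    if bag.ro_manifest is None:
        raise AbsentMetadataError("bag has no RO manifest")
    manifest: RoManifest = bag.ro_manifest
    problems: list[str] = []

    known = _aggregate_uris(bag)
    aggregated: set[str] = set()
    for agg in manifest.aggregates:
        aggregated.add(agg.uri)
        if agg.uri.startswith("data/"):
            if agg.uri not in known:
                problems.append(f"aggregate refers to missing payload entry: {agg.uri}")
            elif bag.entry(agg.uri) is not None and bag.entry(agg.uri).present:
                if not (bag.root / agg.uri).is_file():
                    problems.append(f"aggregate refers to deleted payload file: {agg.uri}")

    remote_locators = {r.locator for r in bag.remotes}
    remote_targets = {r.target_path for r in bag.remotes}
    for e in bag.payload:
        if e.path in aggregated:
            continue
        if e.path in remote_targets:
            ref = bag.remote_for(e.path)
            if ref.locator not in aggregated:
                problems.append(f"unaggregated entry: {e.path}")
        else:
            problems.append(f"unaggregated entry: {e.path}")
    for loc in remote_locators:
        if loc not in aggregated and not any(
            r.target_path in aggregated for r in bag.remotes if r.locator == loc
        ):
            problems.append(f"unaggregated remote reference: {loc}")

    valid_targets = known | {BAG_TARGET}
    for ann in manifest.annotations:
        if ann.about not in valid_targets:
            problems.append(f"annotation about unknown target: {ann.about}")
    return problems


def attach_annotation(
    bag: Bag,
    about: str,
    content: Union[str, Path],
    name: Optional[str] = None,
) -> Bag:
    """Attach an annotation about *about* (an aggregate uri, payload path,
    remote locator, or "." for the bag itself).

    String content that is not an existing file is treated as a URI/free-text
    reference and stored inline in the manifest; an existing file is copied
    under ``metadata/annotations/`` so it is digested by the tag manifests."""
    if bag.ro_manifest is None:
        raise AbsentMetadataError("bag has no RO manifest; call build_manifest first")
    valid_targets = _aggregate_uris(bag) | {BAG_TARGET}
    if about not in valid_targets:
        raise ConsistencyError(f"annotation target does not resolve: {about!r}")

    content_path = Path(content) if not isinstance(content, Path) else content
    if content_path.is_file():
        ann_dir = bag.root / "metadata" / "annotations"
        ann_dir.mkdir(parents=True, exist_ok=True)
        dest = ann_dir / (name or content_path.name)
        shutil.copyfile(content_path, dest)
        ref = f"metadata/annotations/{dest.name}"
    else:
        ref = str(content)
    bag.ro_manifest.annotations.append(Annotation(about=about, content=ref))
    return bag
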