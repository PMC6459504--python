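"""Minting and resolution of checksum-bound persistent identifiers.

An identifier is a CURIE ``prefix:suffix`` (default prefix ``minid``, suffix
six lowercase base-36 characters).  Minting binds the identifier to a sha256
digest of the identified content and to an ordered list of storage locations;
resolving returns the full landing record, which is designed to outlive the
data itself — tombstoning a record marks the data gone but the metadata stays
resolvable.

Records persist in an append-only JSON-lines store (one file), so a registry
reopened from disk resolves identically to the one that minted.  Landing
records render in machine (JSON) or human (HTML) form — the two faces of the
content-negotiation contract a landing page honors.
"""

from __future__ import annotations

import hashlib
import html
import json
import random
import re
import string
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Union

from .errors import (
    CurieParseError,
    ImmutableRecordError,
    InputError,
    NotFoundError,
    RegistryError,
)

SUFFIX_ALPHABET = string.digits + string.ascii_lowercase  # base 36
SUFFIX_LENGTH = 6
DEFAULT_PREFIX = "minid"
METADATA_LICENSE = "CC0-1.0"  # registry policy: landing metadata is openly licensed

_CURIE_RE = re.compile(r"^(?P<prefix>[A-Za-z][A-Za-z0-9._-]*):(?P<suffix>[A-Za-z0-9]+)$")


def parse_curie(text: str) -> tuple[str, str]:
    m = _CURIE_RE.match(text)
    if not m:
        raise CurieParseError(f"malformed CURIE: {text!r}")
    return m.group("prefix"), m.group("suffix")


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        while chunk := fh.read(1 << 16):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class IdentifierRecord:
    """A landing record: everything an identifier resolves to."""

    curie: str
    title: str
    creator: str
    created: str                       # RFC 3339, UTC, second precision
    checksum: tuple[str, str]          # (algorithm, lowercase hex digest)
    locations: list[str] = field(default_factory=list)
    status: str = "active"             # active | tombstoned
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "curie": self.curie,
            "title": self.title,
            "creator": self.creator,
            "created": self.created,
            "checksum": {"algorithm": self.checksum[0], "digest": self.checksum[1]},
            "locations": list(self.locations),
            "status": self.status,
            "extra": dict(self.extra),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IdentifierRecord":
        return cls(
            curie=d["curie"],
            title=d["title"],
            creator=d["creator"],
            created=d["created"],
            checksum=(d["checksum"]["algorithm"], d["checksum"]["digest"]),
            locations=list(d["locations"]),
            status=d.get("status", "active"),
            extra=dict(d.get("extra", {})),
        )


class Registry:
    """Append-only local identifier registry.

    Every state change appends one JSON line to the store file; the latest
    line per CURIE wins on load, so history is retained and a reopened
    registry resolves exactly like the live one.
    """

    def __init__(
        self,
        store_path: Union[str, Path],
        prefix: str = DEFAULT_PREFIX,
        seed: Optional[int] = None,
    ):
        self.store_path = Path(store_path)
        self.prefix = prefix
        self._rng = random.Random(seed)
        self._records: dict[str, IdentifierRecord] = {}
        if self.store_path.exists():
            self._load()

    def _load(self) -> None:
        with open(self.store_path, encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    rec = IdentifierRecord.from_dict(json.loads(line))
                    self._records[rec.curie] = rec

    def _append(self, record: IdentifierRecord) -> None:
        self.store_path.parent.mkdir(parents=True, exist_ok=True)
        with open(self.store_path, "a", encoding="utf-8") as fh:
            fh.write(json.dumps(record.to_dict(), sort_keys=True) + "\n")
        self._records[record.curie] = record

    def _new_suffix(self) -> str:
        for _ in range(100):
            suffix = "".join(self._rng.choice(SUFFIX_ALPHABET) for _ in range(SUFFIX_LENGTH))
            if f"{self.prefix}:{suffix}" not in self._records:
                return suffix
        raise RegistryError("could not find an unused suffix after 100 attempts")

    # -- operations ---------------------------------------------------------

    def mint(
        self,
        content: Optional[Union[str, Path]] = None,
        digest: Optional[tuple[str, str]] = None,
        title: str = "",
        creator: str = "",
        locations: Optional[list[str]] = None,
        now: Optional[datetime] = None,
        extra: Optional[dict] = None,
    ) -> IdentifierRecord:
        """Mint a new identifier for *content* (a file, hashed with sha256)
        or an explicit *(algorithm, digest)* pair.  Identifiers name dataset
        instances, not content: minting the same bytes twice yields two
        distinct CURIEs with equal checksums."""
        if digest is None:
            if content is None:
                raise InputError("mint requires content or an explicit digest")
            content = Path(content)
            if not content.is_file():
                raise InputError(f"no such content file: {content}")
            digest = ("sha256", sha256_file(content))
        created = (now or datetime.now(timezone.utc)).astimezone(timezone.utc)
        merged_extra = {"metadata_license": METADATA_LICENSE}
        merged_extra.update(extra or {})
        record = IdentifierRecord(
            curie=f"{self.prefix}:{self._new_suffix()}",
            title=title,
            creator=creator,
            created=created.replace(microsecond=0).isoformat(),
            checksum=(digest[0], digest[1].lower()),
            locations=list(locations or []),
            extra=merged_extra,
        )
        self._append(record)
        return record

    def resolve(self, curie: str) -> IdentifierRecord:
        parse_curie(curie)
        rec = self._records.get(curie)
        if rec is None:
            raise NotFoundError(f"unknown identifier: {curie}")
        return rec

    def add_location(self, curie: str, url: str) -> IdentifierRecord:
        rec = self.resolve(curie)
        if rec.status == "tombstoned":
            raise ImmutableRecordError(f"{curie} is tombstoned")
        if url in rec.locations:            # idempotent
            return rec
        updated = IdentifierRecord.from_dict(rec.to_dict())
        updated.locations.append(url)
        self._append(updated)
        return updated

    def tombstone(self, curie: str) -> IdentifierRecord:
        """Mark the data gone; the landing record stays resolvable."""
        rec = self.resolve(curie)
        if rec.status == "tombstoned":
            return rec
        updated = IdentifierRecord.from_dict(rec.to_dict())
        updated.status = "tombstoned"
        self._append(updated)
        return updated

    def verify_content(self, curie: str, local_copy: Union[str, Path]) -> bool:
        """True iff the local copy's digest matches the minted checksum.

        Works for tombstoned records too: the checksum outlives the data."""
        rec = self.resolve(curie)
        local_copy = Path(local_copy)
        if not local_copy.is_file():
            raise InputError(f"unreadable file: {local_copy}")
        alg, expected = rec.checksum
        h = hashlib.new(alg)
        with open(local_copy, "rb") as fh:
            while chunk := fh.read(1 << 16):
                h.update(chunk)
        return h.hexdigest() == expected


def render_record(record: IdentifierRecord, format: str = "machine") -> str:
    """Render a landing record.

    ``machine`` is a JSON document carrying every field (parseable back into
    a field-equal record); ``human`` is a small HTML landing page listing
    title, creator, date, checksum, status and one link per location."""
    if format == "machine":
        return json.dumps(record.to_dict(), indent=2, sort_keys=True)
    if format != "human":
        raise InputError(f"unknown render format: {format!r}")
    alg, digest = record.checksum
    links = "\n".join(
        f'    <li><a href="{html.escape(loc, quote=True)}">{html.escape(loc)}</a></li>'
        for loc in record.locations
    )
    return f"""<!DOCTYPE html>
<html>
<head><title>{html.escape(record.curie)}</title></head>
<body>
  <h1>{html.escape(record.title) or html.escape(record.curie)}</h1>
  <dl>
    <dt>Identifier</dt><dd>{html.escape(record.curie)}</dd>
    <dt>Creator</dt><dd>{html.escape(record.creator)}</dd>
    <dt>Created</dt><dd>{html.escape(record.created)}</dd>
    <dt>Checksum ({html.escape(alg)})</dt><dd>{html.escape(digest)}</dd>
    <dt>Status</dt><dd>{html.escape(record.status)}</dd>
  </dl>
  <h2>Locations</h2>
  <ul>
{links}
  </ul>
</body>
</html>
"""


def parse_machine_record(text: str) -> IdentifierRecord:
    return IdentifierRecord.from_dict(json.loads(text))
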