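"""Materialize holey bags: resolve fetch entries, download, verify, expand.

A fetch entry's locator is either a plain URL or an identifier CURIE; CURIEs
are resolved through the registry to the landing record's ordered location
list, and candidates are tried in that order until one verifies.  Fixity is
checked *before* a file is placed at its target path (verify-then-place), so
no partially verified bytes ever occupy the payload; corrupt downloads are
quarantined by digest for post-mortem.

``materialize_recursive`` handles bags of bags: a fetched payload entry that
is itself a serialized bag (declared via the registry record's content-type,
or sniffed by the presence of bagit.txt at the archive root) is expanded and
materialized in turn, up to a depth bound, and the report lists the tree of
inner bags with their validation states.

Supported transports are ``file://`` and ``http(s)://`` with a bounded
retry; anything else is reported unavailable, never fatal.
"""

from __future__ import annotations

import fnmatch
import hashlib
import os
import tempfile
import time
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .bag import Bag, RemoteReference, ValidationReport, is_bag_archive, read_bag, validate_bag
from .errors import RegistryError
from .registry import Registry, parse_curie

URL_SCHEMES = ("http", "https", "file", "ftp")
BAG_CONTENT_TYPES = ("bag+zip", "bag+tgz")


def is_identifier_locator(locator: str) -> bool:
    """A locator is a CURIE when it has no ``://`` and its prefix is not a
    plain URL scheme (``minid:b9q119`` yes, ``https://...`` no)."""
    if "://" in locator:
        return False
    try:
        prefix, _ = parse_curie(locator)
    except RegistryError:
        return False
    return prefix.lower() not in URL_SCHEMES


@dataclass
class PlanEntry:
    ref: RemoteReference
    candidates: list[str]
    expected_digests: dict[str, str]
    expected_length: Optional[int]
    curie: Optional[str] = None
    note: Optional[str] = None       # e.g. unresolvable identifier


@dataclass
class FetchPlan:
    bag: Bag
    entries: list[PlanEntry] = field(default_factory=list)


@dataclass
class EntryResult:
    target_path: str
    outcome: str                     # fetched-verified | fetched-corrupt | unavailable | skipped
    chosen_url: Optional[str] = None
    bytes_fetched: int = 0
    failures: list[str] = field(default_factory=list)


@dataclass
class FetchResult:
    entries: list[EntryResult] = field(default_factory=list)

    @property
    def bytes_fetched(self) -> int:
        return sum(e.bytes_fetched for e in self.entries)

    @property
    def all_verified(self) -> bool:
        return all(e.outcome in ("fetched-verified", "skipped") for e in self.entries)

    def outcome_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries:
            counts[e.outcome] = counts.get(e.outcome, 0) + 1
        return counts


def plan_fetch(
    bag: Bag,
    registry: Optional[Registry] = None,
    selector: Optional[str] = None,
) -> FetchPlan:
    """Build the fetch plan for every non-present payload entry (optionally
    restricted by a glob over target paths).  CURIE locators are resolved to
    the landing record's locations, in registry order; the record's checksum
    joins the expected digests."""
    plan = FetchPlan(bag=bag)
    for ref in bag.remotes:
        entry = bag.entry(ref.target_path)
        if entry is None or entry.present:
            continue
        if selector and not fnmatch.fnmatch(ref.target_path, selector):
            continue
        digests = dict(entry.digests)
        curie = None
        note = None
        if is_identifier_locator(ref.locator):
            curie = ref.locator
            if registry is None:
                candidates: list[str] = []
                note = "identifier locator but no registry supplied"
            else:
                try:
                    record = registry.resolve(ref.locator)
                    candidates = list(record.locations)
                    alg, digest = record.checksum
                    digests.setdefault(alg, digest)
                except RegistryError as exc:
                    candidates = []
                    note = f"unresolvable identifier: {exc}"
        else:
            candidates = [ref.locator]
        plan.entries.append(
            PlanEntry(
                ref=ref,
                candidates=candidates,
                expected_digests=digests,
                expected_length=ref.length_bytes,
                curie=curie,
                note=note,
            )
        )
    return plan


def _download(url: str, dest: Path, retries: int, retry_delay: float) -> int:
    last_exc: Optional[Exception] = None
    for attempt in range(retries):
        try:
            with urllib.request.urlopen(url) as resp, open(dest, "wb") as out:
                n = 0
                while chunk := resp.read(1 << 16):
                    out.write(chunk)
                    n += len(chunk)
            return n
        except (urllib.error.URLError, OSError, ValueError) as exc:
            last_exc = exc
            if attempt + 1 < retries:
                time.sleep(retry_delay * (2 ** attempt))
    raise IOError(f"download failed after {retries} attempts: {url}: {last_exc}")


def fetch_all(
    plan: FetchPlan,
    retries: int = 3,
    retry_delay: float = 0.1,
    quarantine_dir: Optional[Path] = None,
) -> FetchResult:
    """Execute a fetch plan: each entry's candidates are tried in order until
    one download verifies against every expected digest and the declared
    length.  Re-running on a completed bag fetches zero bytes."""
    bag = plan.bag
    result = FetchResult()
    quarantine = Path(quarantine_dir) if quarantine_dir else bag.root / "quarantine"

    for pe in plan.entries:
        target = bag.root / pe.ref.target_path
        if target.is_file():
            result.entries.append(EntryResult(pe.ref.target_path, "skipped"))
            continue
        er = EntryResult(pe.ref.target_path, "unavailable")
        if pe.note:
            er.failures.append(pe.note)
        saw_corrupt = False
        for url in pe.candidates:
            fd, tmp_name = tempfile.mkstemp(dir=bag.root, prefix=".fetch-")
            os.close(fd)
            tmp = Path(tmp_name)
            try:
                n = _download(url, tmp, retries, retry_delay)
            except IOError as exc:
                er.failures.append(str(exc))
                tmp.unlink(missing_ok=True)
                continue
            problems = []
            if pe.expected_length is not None and n != pe.expected_length:
                problems.append(f"length mismatch: declared {pe.expected_length}, got {n}")
            hashers = {alg: hashlib.new(alg) for alg in pe.expected_digests}
            with open(tmp, "rb") as fh:
                while chunk := fh.read(1 << 16):
                    for h in hashers.values():
                        h.update(chunk)
            for alg, expected in pe.expected_digests.items():
                observed = hashers[alg].hexdigest()
                if observed != expected:
                    problems.append(f"{alg} mismatch: expected {expected}, got {observed}")
            if problems:
                saw_corrupt = True
                er.failures.append(f"{url}: " + "; ".join(problems))
                quarantine.mkdir(parents=True, exist_ok=True)
                qname = hashlib.sha256(tmp.read_bytes()).hexdigest()
                os.replace(tmp, quarantine / qname)
                continue
            target.parent.mkdir(parents=True, exist_ok=True)
            os.replace(tmp, target)       # verify-then-place, atomically
            er.outcome = "fetched-verified"
            er.chosen_url = url
            er.bytes_fetched = n
            entry = bag.entry(pe.ref.target_path)
            entry.present = True
            entry.size_bytes = n
            break
        else:
            if saw_corrupt:
                er.outcome = "fetched-corrupt"
        result.entries.append(er)
    return result


@dataclass
class MaterializationNode:
    """One bag (or unexpanded bag archive) in a recursive materialization."""

    location: Path
    curie: Optional[str] = None
    expanded: bool = True
    validation: Optional[ValidationReport] = None
    fetch: Optional[FetchResult] = None
    children: list["MaterializationNode"] = field(default_factory=list)

    @property
    def all_valid(self) -> bool:
        ok = self.validation.valid if self.validation else not self.expanded
        return ok and all(c.all_valid for c in self.children)

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


def _looks_like_bag(path: Path, curie: Optional[str], registry: Optional[Registry]) -> bool:
    if curie and registry is not None:
        try:
            record = registry.resolve(curie)
            if record.extra.get("content-type") in BAG_CONTENT_TYPES:
                return True
        except RegistryError:
            pass
    return is_bag_archive(path)


def materialize_recursive(
    bag: Bag,
    registry: Optional[Registry] = None,
    max_depth: int = 1,
    selector: Optional[str] = None,
    retries: int = 3,
    retry_delay: float = 0.1,
) -> MaterializationNode:
    """Fetch a bag's remote entries, then expand and materialize any payload
    entry that is itself a serialized bag, recursively up to *max_depth*
    levels of bags (the outer bag is level 1, so ``max_depth=1`` fetches
    inner bag archives without expanding them)."""
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    return _materialize(bag, registry, max_depth, 1, selector, retries, retry_delay)


def _materialize(
    bag: Bag,
    registry: Optional[Registry],
    max_depth: int,
    depth: int,
    selector: Optional[str],
    retries: int,
    retry_delay: float,
) -> MaterializationNode:
    plan = plan_fetch(bag, registry, selector)
    fetch = fetch_all(plan, retries=retries, retry_delay=retry_delay)
    node = MaterializationNode(
        location=bag.root, fetch=fetch, validation=validate_bag(bag, mode="full")
    )

    curie_by_target = {
        pe.ref.target_path: pe.curie for pe in plan.entries if pe.curie
    }
    for entry in bag.payload:
        if not entry.present:
            continue
        path = bag.root / entry.path
        curie = curie_by_target.get(entry.path)
        if not _looks_like_bag(path, curie, registry):
            continue
        if depth >= max_depth:
            node.children.append(
                MaterializationNode(location=path, curie=curie, expanded=False)
            )
            continue
        # expand outside data/ so the extracted tree never shadows the outer
        # bag's payload enumeration
        inner = read_bag(path, extract_to=bag.root / "expanded" / path.stem)
        child = _materialize(
            inner, registry, max_depth, depth + 1, None, retries, retry_delay
        )
        child.curie = curie
        node.children.append(child)
    return node
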