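"""Create, serialize, read, and validate BDBags.

A BDBag is a BagIt bag (declaration ``bagit.txt``, payload under ``data/``,
checksum manifests, tag files) extended with two conventions: remote payload
references carried in ``fetch.txt`` as ``(URL, LENGTH, FILENAME)`` triples,
and a Research Object manifest embedded at ``metadata/manifest.json``.  A bag
whose payload is partly remote is *holey*: structurally valid, but incomplete
until the references are materialized.

The module is deliberately file-oriented: a :class:`Bag` mirrors an on-disk
bag directory, ``write_bag`` serializes it (directory, zip, or tgz layout)
and ``read_bag`` parses any of the three layouts back into a structurally
equal object.
"""

from __future__ import annotations

import hashlib
import shutil
import tarfile
import tempfile
import zipfile
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Optional

from .errors import (
    BagParseError,
    ConfigurationError,
    ConflictError,
    InputError,
    NotABagError,
)

BAGIT_VERSION = "1.0"
BAGIT_ENCODING = "UTF-8"
DEFAULT_ALGORITHMS = ("md5", "sha256")
SUPPORTED_ALGORITHMS = ("md5", "sha1", "sha256", "sha512")

_CHUNK = 1 << 16


def compute_digests(path: Path, algorithms: Iterable[str]) -> dict[str, str]:
    """Stream a file once and return lowercase hex digests for *algorithms*."""
    algorithms = list(algorithms)
    for alg in algorithms:
        if alg not in SUPPORTED_ALGORITHMS:
            raise ConfigurationError(f"unsupported checksum algorithm: {alg!r}")
    hashers = {alg: hashlib.new(alg) for alg in algorithms}
    with open(path, "rb") as fh:
        while chunk := fh.read(_CHUNK):
            for h in hashers.values():
                h.update(chunk)
    return {alg: h.hexdigest() for alg, h in hashers.items()}


def _check_payload_path(path: str) -> str:
    p = path.replace("\\", "/")
    if not p.startswith("data/") or p != str(Path(p).as_posix()) or ".." in p.split("/"):
        raise InputError(f"payload path must be normalized and under data/: {path!r}")
    return p


@dataclass
class PayloadEntry:
    """One payload stream of a bag, local (present) or referenced remotely."""

    path: str
    size_bytes: Optional[int]
    digests: dict[str, str]
    present: bool = True

    def __post_init__(self) -> None:
        self.path = _check_payload_path(self.path)
        self.digests = {a: d.lower() for a, d in self.digests.items()}


@dataclass
class RemoteReference:
    """A fetch.txt triple: locator (URL or CURIE), declared length, target path."""

    locator: str
    length_bytes: Optional[int]
    target_path: str

    def __post_init__(self) -> None:
        self.target_path = _check_payload_path(self.target_path)
        if self.length_bytes is not None and self.length_bytes < 0:
            raise InputError("remote reference length must be non-negative")


@dataclass
class TagFileEntry:
    """A non-payload file covered by the tag manifests."""

    path: str
    digests: dict[str, str]


@dataclass
class BagInfo:
    """Ordered label → value pairs of bag-info.txt."""

    pairs: dict[str, str] = field(default_factory=dict)

    def get(self, label: str, default: Optional[str] = None) -> Optional[str]:
        return self.pairs.get(label, default)


@dataclass
class ValidationReport:
    structural_ok: bool
    complete: bool
    fixity_errors: list[tuple[str, str, str, str]] = field(default_factory=list)
    missing_entries: list[str] = field(default_factory=list)
    extra_files: list[str] = field(default_factory=list)
    oxum_ok: bool = True
    messages: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return (
            self.structural_ok
            and self.complete
            and not self.fixity_errors
            and not self.extra_files
        )


@dataclass
class Bag:
    """In-memory mirror of an on-disk BDBag.

    ``root`` locates the bag but does not take part in structural equality,
    so a round-trip through any serialization layout compares equal.
    """

    root: Path = field(compare=False)
    payload: list[PayloadEntry] = field(default_factory=list)
    remotes: list[RemoteReference] = field(default_factory=list)
    tag_files: list[TagFileEntry] = field(default_factory=list)
    bag_info: BagInfo = field(default_factory=BagInfo)
    ro_manifest: object = None  # fairbag.ro.RoManifest, optional
    version: str = BAGIT_VERSION
    encoding: str = BAGIT_ENCODING

    @property
    def is_holey(self) -> bool:
        return any(not e.present for e in self.payload)

    @property
    def is_complete(self) -> bool:
        return not self.is_holey

    @property
    def algorithms(self) -> list[str]:
        algs: set[str] = set()
        for e in self.payload:
            algs.update(e.digests)
        for t in self.tag_files:
            algs.update(t.digests)
        return sorted(algs) or list(DEFAULT_ALGORITHMS)

    def entry(self, path: str) -> Optional[PayloadEntry]:
        for e in self.payload:
            if e.path == path:
                return e
        return None

    def remote_for(self, target_path: str) -> Optional[RemoteReference]:
        for r in self.remotes:
            if r.target_path == target_path:
                return r
        return None

    def payload_oxum(self) -> Optional[tuple[int, int]]:
        """(octets, streams) over local and remote entries; None if any
        remote length is unknown (the Oxum of a holey bag counts the complete
        dataset it represents, so an unknown length makes it undefined)."""
        total = 0
        for e in self.payload:
            if e.size_bytes is None:
                return None
            total += e.size_bytes
        return total, len(self.payload)

    def _sort(self) -> None:
        self.payload.sort(key=lambda e: e.path)
        self.remotes.sort(key=lambda r: r.target_path)
        self.tag_files.sort(key=lambda t: t.path)


# ---------------------------------------------------------------------------
# fetch.txt dialect: three space-separated fields per line; LENGTH is a
# decimal integer or "-"; CR, LF and "%" in the filename are percent-encoded.

def _encode_fetch_path(path: str) -> str:
    return path.replace("%", "%25").replace("\r", "%0D").replace("\n", "%0A")


def _decode_fetch_path(text: str) -> str:
    return text.replace("%0A", "\n").replace("%0D", "\r").replace("%25", "%")


def format_fetch_line(ref: RemoteReference) -> str:
    length = "-" if ref.length_bytes is None else str(ref.length_bytes)
    return f"{ref.locator} {length} {_encode_fetch_path(ref.target_path)}"


def parse_fetch_line(line: str, lineno: int = 0) -> RemoteReference:
    parts = line.rstrip("\n").split(" ", 2)
    if len(parts) != 3 or not all(parts):
        raise BagParseError(f"fetch.txt line {lineno}: expected 3 fields, got {line!r}")
    locator, length_text, path_text = parts
    if length_text == "-":
        length: Optional[int] = None
    else:
        try:
            length = int(length_text)
        except ValueError:
            raise BagParseError(
                f"fetch.txt line {lineno}: bad LENGTH field {length_text!r}"
            ) from None
        if length < 0:
            raise BagParseError(f"fetch.txt line {lineno}: negative length")
    return RemoteReference(locator, length, _decode_fetch_path(path_text))


# ---------------------------------------------------------------------------
# creation

def create_bag(
    source_tree: Path,
    info: Optional[dict[str, str]] = None,
    algorithms: Iterable[str] = DEFAULT_ALGORITHMS,
    now: Optional[datetime] = None,
) -> Bag:
    """Turn *source_tree* in place into a bag: its files move under ``data/``,
    digests are computed for every requested algorithm, and the tag files are
    written.  The result is a valid, complete bag."""
    source_tree = Path(source_tree)
    algorithms = list(algorithms)
    if not algorithms:
        raise ConfigurationError("at least one checksum algorithm is required")
    for alg in algorithms:
        if alg not in SUPPORTED_ALGORITHMS:
            raise ConfigurationError(f"unsupported checksum algorithm: {alg!r}")
    if not source_tree.is_dir():
        raise InputError(f"source tree does not exist or is unreadable: {source_tree}")

    # move existing contents under data/ (two-step through a temp name so a
    # top-level file literally named "data" cannot collide)
    staging = Path(tempfile.mkdtemp(dir=source_tree, prefix=".bagstage-"))
    for child in sorted(source_tree.iterdir()):
        if child != staging:
            shutil.move(str(child), staging / child.name)
    data_dir = source_tree / "data"
    staging.rename(data_dir)

    payload = []
    for f in sorted(p for p in data_dir.rglob("*") if p.is_file()):
        rel = f.relative_to(source_tree).as_posix()
        payload.append(
            PayloadEntry(rel, f.stat().st_size, compute_digests(f, algorithms))
        )

    pairs = dict(info or {})
    pairs.setdefault(
        "Bagging-Date",
        (now or datetime.now(timezone.utc)).strftime("%Y-%m-%d"),
    )
    bag = Bag(root=source_tree, payload=payload, bag_info=BagInfo(pairs))
    if not any(e.digests for e in payload):
        # empty bag: remember the requested algorithms for the manifest files
        bag._requested_algorithms = algorithms  # type: ignore[attr-defined]
    write_bag(bag, layout="directory")
    return bag


def add_remote_reference(
    bag: Bag, ref: RemoteReference, digests: dict[str, str]
) -> Bag:
    """Record a remote payload file: a non-present entry plus a fetch line.

    At least one digest is required — a reference whose fixity cannot be
    verified after download is rejected."""
    if not digests:
        raise InputError(f"remote reference {ref.target_path!r} needs at least one digest")
    existing = bag.entry(ref.target_path)
    if existing is not None:
        raise ConflictError(f"payload entry already exists: {ref.target_path!r}")
    if bag.remote_for(ref.target_path) is not None:
        raise ConflictError(f"fetch entry already exists: {ref.target_path!r}")
    bag.payload.append(
        PayloadEntry(ref.target_path, ref.length_bytes, dict(digests), present=False)
    )
    bag.remotes.append(ref)
    bag._sort()
    return bag


# ---------------------------------------------------------------------------
# serialization

def _tag_file_paths(root: Path) -> list[str]:
    """Every non-payload, non-tagmanifest file of a bag directory."""
    out = []
    for f in sorted(root.rglob("*")):
        if not f.is_file():
            continue
        rel = f.relative_to(root).as_posix()
        if rel.startswith("data/") or rel.startswith("tagmanifest-"):
            continue
        out.append(rel)
    return out


def write_bag(bag: Bag, layout: str = "directory", dest: Optional[Path] = None) -> Path:
    """Serialize *bag*.  ``directory`` writes the canonical tree at
    ``bag.root``; ``zip``/``tgz`` additionally produce an archive holding a
    single top-level directory named after the bag."""
    if layout not in ("directory", "zip", "tgz"):
        raise ConfigurationError(f"unknown layout: {layout!r}")
    root = bag.root
    root.mkdir(parents=True, exist_ok=True)
    (root / "data").mkdir(exist_ok=True)
    bag._sort()

    algorithms = bag.algorithms
    requested = getattr(bag, "_requested_algorithms", None)
    if requested:
        algorithms = sorted(set(algorithms) | set(requested))

    (root / "bagit.txt").write_text(
        f"BagIt-Version: {bag.version}\nTag-File-Character-Encoding: {bag.encoding}\n",
        encoding="utf-8",
    )

    fetch_path = root / "fetch.txt"
    if bag.remotes:
        fetch_path.write_text(
            "".join(format_fetch_line(r) + "\n" for r in bag.remotes), encoding="utf-8"
        )
    elif fetch_path.exists():
        fetch_path.unlink()

    # payload manifests: every entry appears in each manifest for which it
    # carries a digest (and must carry at least one)
    for e in bag.payload:
        if not e.digests:
            raise InputError(f"payload entry {e.path!r} has no digest")
    for alg in algorithms:
        lines = [
            f"{e.digests[alg]}  {e.path}\n" for e in bag.payload if alg in e.digests
        ]
        (root / f"manifest-{alg}.txt").write_text("".join(lines), encoding="utf-8")

    oxum = bag.payload_oxum()
    pairs = dict(bag.bag_info.pairs)
    if oxum is not None:
        pairs["Payload-Oxum"] = f"{oxum[0]}.{oxum[1]}"
    else:
        pairs.pop("Payload-Oxum", None)
    bag.bag_info = BagInfo(pairs)
    (root / "bag-info.txt").write_text(
        "".join(f"{k}: {v}\n" for k, v in pairs.items()), encoding="utf-8"
    )

    if bag.ro_manifest is not None:
        meta = root / "metadata"
        meta.mkdir(exist_ok=True)
        (meta / "manifest.json").write_bytes(bag.ro_manifest.to_json_bytes())

    # tag manifests cover every non-payload file, including the metadata dir
    tag_paths = _tag_file_paths(root)
    tag_entries = [
        TagFileEntry(rel, compute_digests(root / rel, algorithms)) for rel in tag_paths
    ]
    for alg in algorithms:
        lines = [f"{t.digests[alg]}  {t.path}\n" for t in tag_entries]
        (root / f"tagmanifest-{alg}.txt").write_text("".join(lines), encoding="utf-8")
    bag.tag_files = tag_entries

    if layout == "directory":
        return root
    if dest is None:
        dest = root.parent / (root.name + (".zip" if layout == "zip" else ".tgz"))
    dest = Path(dest)
    # archives carry fixed timestamps so identical bag content serializes to
    # identical bytes (archive digests are minted; determinism keeps them stable)
    entries = sorted(root.rglob("*"))
    if layout == "zip":
        with zipfile.ZipFile(dest, "w", zipfile.ZIP_DEFLATED) as zf:
            for p in entries:
                arcname = f"{root.name}/{p.relative_to(root).as_posix()}"
                if p.is_dir():
                    zf.writestr(zipfile.ZipInfo(arcname + "/", (1980, 1, 1, 0, 0, 0)), b"")
                elif p.is_file():
                    zi = zipfile.ZipInfo(arcname, date_time=(1980, 1, 1, 0, 0, 0))
                    zi.compress_type = zipfile.ZIP_DEFLATED
                    zf.writestr(zi, p.read_bytes())
    else:
        import gzip

        with open(dest, "wb") as raw:
            with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz:
                with tarfile.open(fileobj=gz, mode="w") as tf:
                    for p in entries:
                        ti = tarfile.TarInfo(
                            f"{root.name}/{p.relative_to(root).as_posix()}"
                        )
                        ti.mtime = 0
                        if p.is_dir():
                            ti.type = tarfile.DIRTYPE
                            ti.mode = 0o755
                            tf.addfile(ti)
                        elif p.is_file():
                            ti.size = p.stat().st_size
                            with open(p, "rb") as fh:
                                tf.addfile(ti, fh)
    return dest


# ---------------------------------------------------------------------------
# reading

def _extract_archive(location: Path, extract_to: Optional[Path]) -> Path:
    target = Path(extract_to) if extract_to else Path(tempfile.mkdtemp(prefix="fairbag-"))
    target.mkdir(parents=True, exist_ok=True)
    if zipfile.is_zipfile(location):
        with zipfile.ZipFile(location) as zf:
            zf.extractall(target)
    elif tarfile.is_tarfile(location):
        with tarfile.open(location) as tf:
            tf.extractall(target, filter="data")
    else:
        raise NotABagError(f"not a bag directory or archive: {location}")
    tops = [p for p in target.iterdir() if p.is_dir()]
    if len(tops) != 1:
        raise BagParseError(
            f"archive must contain exactly one top-level bag directory: {location}"
        )
    return tops[0]


def is_bag_archive(location: Path) -> bool:
    """Structural sniff: does the archive hold <top>/bagit.txt?"""
    location = Path(location)
    try:
        if zipfile.is_zipfile(location):
            with zipfile.ZipFile(location) as zf:
                names = zf.namelist()
        elif tarfile.is_tarfile(location):
            with tarfile.open(location) as tf:
                names = tf.getnames()
        else:
            return False
    except (OSError, tarfile.TarError, zipfile.BadZipFile):
        return False
    return any(n.split("/")[1:] == ["bagit.txt"] for n in names)


def read_bag(location: Path, extract_to: Optional[Path] = None) -> Bag:
    """Parse a bag from a directory, zip, or tgz into a :class:`Bag`."""
    location = Path(location)
    if not location.exists():
        raise InputError(f"no such bag location: {location}")
    root = location if location.is_dir() else _extract_archive(location, extract_to)

    bagit = root / "bagit.txt"
    if not bagit.is_file():
        raise NotABagError(f"missing bagit.txt: {root}")
    decl = {}
    for line in bagit.read_text(encoding="utf-8").splitlines():
        if ":" in line:
            k, v = line.split(":", 1)
            decl[k.strip()] = v.strip()
    version = decl.get("BagIt-Version", BAGIT_VERSION)
    encoding = decl.get("Tag-File-Character-Encoding", BAGIT_ENCODING)

    manifest_files = sorted(root.glob("manifest-*.txt"))
    if not manifest_files:
        raise NotABagError(f"no payload manifest files: {root}")

    digests_by_path: dict[str, dict[str, str]] = {}
    for mf in manifest_files:
        alg = mf.name[len("manifest-"):-len(".txt")]
        for lineno, line in enumerate(mf.read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip():
                continue
            try:
                digest, path = line.split(None, 1)
            except ValueError:
                raise BagParseError(f"{mf.name} line {lineno}: malformed entry") from None
            digests_by_path.setdefault(path.strip(), {})[alg] = digest.lower()

    remotes = []
    fetch_path = root / "fetch.txt"
    if fetch_path.is_file():
        for lineno, line in enumerate(
            fetch_path.read_text(encoding="utf-8").splitlines(), 1
        ):
            if line.strip():
                remotes.append(parse_fetch_line(line, lineno))
    remote_by_target = {r.target_path: r for r in remotes}

    payload = []
    for path, digs in sorted(digests_by_path.items()):
        local = root / path
        if local.is_file():
            payload.append(PayloadEntry(path, local.stat().st_size, digs, present=True))
        else:
            ref = remote_by_target.get(path)
            length = ref.length_bytes if ref else None
            payload.append(PayloadEntry(path, length, digs, present=False))

    pairs: dict[str, str] = {}
    info_path = root / "bag-info.txt"
    if info_path.is_file():
        last = None
        for line in info_path.read_text(encoding="utf-8").splitlines():
            if line[:1] in (" ", "\t") and last:
                pairs[last] += " " + line.strip()
            elif ":" in line:
                k, v = line.split(":", 1)
                pairs[k.strip()] = v.strip()
                last = k.strip()

    tag_files = []
    tag_digests: dict[str, dict[str, str]] = {}
    for tmf in sorted(root.glob("tagmanifest-*.txt")):
        alg = tmf.name[len("tagmanifest-"):-len(".txt")]
        for line in tmf.read_text(encoding="utf-8").splitlines():
            if line.strip():
                digest, path = line.split(None, 1)
                tag_digests.setdefault(path.strip(), {})[alg] = digest.lower()
    for path, digs in sorted(tag_digests.items()):
        tag_files.append(TagFileEntry(path, digs))

    ro = None
    ro_path = root / "metadata" / "manifest.json"
    if ro_path.is_file():
        from .ro import RoManifest

        ro = RoManifest.from_json_bytes(ro_path.read_bytes())

    bag = Bag(
        root=root,
        payload=payload,
        remotes=remotes,
        tag_files=tag_files,
        bag_info=BagInfo(pairs),
        ro_manifest=ro,
        version=version,
        encoding=encoding,
    )
    bag._sort()
    return bag


# ---------------------------------------------------------------------------
# validation

def validate_bag(bag: Bag, mode: str = "full") -> ValidationReport:
    """Validate a bag on disk.

    ``structural`` checks layout only; ``fast`` adds presence and the
    Payload-Oxum; ``full`` additionally recomputes every recorded digest of
    every present payload and tag file.  All findings are reported, nothing
    raises."""
    if mode not in ("full", "fast", "structural"):
        raise ConfigurationError(f"unknown validation mode: {mode!r}")
    root = bag.root
    messages: list[str] = []
    structural_ok = True

    if not (root / "bagit.txt").is_file():
        structural_ok = False
        messages.append("missing bagit.txt")
    if not any(root.glob("manifest-*.txt")):
        structural_ok = False
        messages.append("no payload manifests")
    if not (root / "data").is_dir():
        structural_ok = False
        messages.append("missing data/ directory")
    for ref in bag.remotes:
        if bag.entry(ref.target_path) is None:
            structural_ok = False
            messages.append(f"fetch entry without payload entry: {ref.target_path}")

    missing = [e.path for e in bag.payload if not (root / e.path).is_file()]
    known = {e.path for e in bag.payload}
    extra = []
    data_dir = root / "data"
    if data_dir.is_dir():
        for f in sorted(data_dir.rglob("*")):
            if f.is_file():
                rel = f.relative_to(root).as_posix()
                if rel not in known:
                    extra.append(rel)

    oxum_ok = True
    if mode in ("fast", "full"):
        declared = bag.bag_info.get("Payload-Oxum")
        actual = bag.payload_oxum()
        if actual is None:
            oxum_ok = False
            messages.append("Payload-Oxum unverifiable: remote entry with unknown length")
        elif declared is None:
            oxum_ok = False
            messages.append("Payload-Oxum missing from bag-info.txt")
        elif declared != f"{actual[0]}.{actual[1]}":
            oxum_ok = False
            messages.append(
                f"Payload-Oxum mismatch: declared {declared}, actual {actual[0]}.{actual[1]}"
            )

    fixity_errors: list[tuple[str, str, str, str]] = []
    if mode == "full":
        for e in bag.payload:
            local = root / e.path
            if local.is_file() and e.digests:
                observed = compute_digests(local, list(e.digests))
                for alg, expected in e.digests.items():
                    if observed[alg] != expected:
                        fixity_errors.append((e.path, alg, expected, observed[alg]))
        for t in bag.tag_files:
            local = root / t.path
            if not local.is_file():
                structural_ok = False
                messages.append(f"missing tag file: {t.path}")
                continue
            observed = compute_digests(local, list(t.digests))
            for alg, expected in t.digests.items():
                if observed[alg] != expected:
                    fixity_errors.append((t.path, alg, expected, observed[alg]))

    return ValidationReport(
        structural_ok=structural_ok,
        complete=not missing,
        fixity_errors=fixity_errors,
        missing_entries=missing,
        extra_files=extra,
        oxum_ok=oxum_ok,
        messages=messages,
    )
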