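"""ENCODE-style metadata manifests → holey bags, summaries, pipeline plans.

This is the encode2bag-style conversion stage plus the dataset bookkeeping
around it.  A metadata table (one row per downloadable file, with accession,
tissue term, biosample, replicate, size, md5, URL) is parsed, filtered,
partitioned by tissue, and turned into per-group holey bags — bags that
carry one fetch line and one md5 manifest entry per file, plus the query
that selected the rows, recorded verbatim as an annotation so the selection
is reproducible even after the upstream portal's contents drift.  Each bag
gets a minted identifier; a partition additionally produces an outer "bag of
bags" whose fetch locators are the per-group CURIEs.

The planner reproduces the downstream fan-out arithmetic of a footprinting
pipeline: per-tissue input bags, per-{tissue, seed} alignment bags, one
merged alignment file per {biosample, seed}, and per-{tissue, seed, method}
footprint files.
"""

from __future__ import annotations

import json
import re
import tempfile
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .bag import Bag, RemoteReference, add_remote_reference, create_bag, write_bag
from .errors import ConflictError, InputError, ManifestFormatError
from .registry import IdentifierRecord, Registry
from .ro import BAG_TARGET, Agent, attach_annotation, build_manifest

# Column names of an ENCODE-portal-style metadata export; a caller whose
# export uses different labels passes a replacement mapping.
DEFAULT_COLUMNS: dict[str, str] = {
    "file_accession": "File accession",
    "experiment_accession": "Experiment accession",
    "assay": "Assay",
    "tissue": "Biosample term name",
    "biosample_id": "Biosample accession",
    "replicate_id": "Technical replicate",
    "file_format": "File format",
    "size_bytes": "Size",
    "md5": "md5sum",
    "url": "File download URL",
}

_INT_RE = re.compile(r"^\d+$")
_MD5_RE = re.compile(r"^[0-9a-f]{32}$")


@dataclass
class ManifestRow:
    file_accession: str
    experiment_accession: str
    assay: str
    tissue: str
    biosample_id: str
    replicate_id: str
    file_format: str
    size_bytes: int
    md5: str
    url: str


@dataclass
class GroupSummary:
    group_key: str
    n_biosamples: int
    n_replicates: int
    n_files: int
    total_bytes: int


@dataclass
class QueryRecord:
    """The filter that selected a set of rows, recorded verbatim in every
    bag the converter produces."""

    predicates: dict[str, str]
    executed_at: str
    source: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "predicates": self.predicates,
                "executed_at": self.executed_at,
                "source": self.source,
            },
            indent=2,
            sort_keys=True,
        )


def make_query_record(
    predicates: dict[str, str],
    source: str,
    now: Optional[datetime] = None,
) -> QueryRecord:
    ts = (now or datetime.now(timezone.utc)).astimezone(timezone.utc)
    return QueryRecord(
        predicates=dict(predicates),
        executed_at=ts.replace(microsecond=0).isoformat(),
        source=source,
    )


# ---------------------------------------------------------------------------
# parsing and filtering

def parse_manifest(
    tsv: Union[str, Path],
    columns: Optional[dict[str, str]] = None,
) -> list[ManifestRow]:
    """Parse a tab-separated metadata table into typed rows.

    Strict by design: a missing required column, a duplicate file accession,
    a non-integer size (no silent coercion of thousands separators), a
    malformed md5, or an empty tissue/biosample/replicate all raise a
    :class:`ManifestFormatError` naming the offending column or line."""
    columns = columns or DEFAULT_COLUMNS
    tsv = Path(tsv)
    if not tsv.is_file():
        raise InputError(f"no such manifest: {tsv}")
    with open(tsv, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        header = header_line.split("\t")
        missing = [c for c in columns.values() if c not in header]
        if missing:
            raise ManifestFormatError(f"missing required column(s): {', '.join(missing)}")
        idx = {f: header.index(c) for f, c in columns.items()}

        rows: list[ManifestRow] = []
        problems: list[str] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(header):
                problems.append(f"line {lineno}: expected {len(header)} columns, got {len(cells)}")
                continue
            raw = {f: cells[i].strip() for f, i in idx.items()}
            if raw["file_accession"] in seen:
                raise ManifestFormatError(
                    f"line {lineno}: duplicate file accession {raw['file_accession']!r}"
                )
            seen.add(raw["file_accession"])
            if not _INT_RE.match(raw["size_bytes"]):
                problems.append(
                    f"line {lineno}: size is not a plain decimal integer: {raw['size_bytes']!r}"
                )
                continue
            if not _MD5_RE.match(raw["md5"].lower()):
                problems.append(f"line {lineno}: malformed md5: {raw['md5']!r}")
                continue
            empty = [f for f in ("tissue", "biosample_id", "replicate_id") if not raw[f]]
            if empty:
                problems.append(f"line {lineno}: empty field(s): {', '.join(empty)}")
                continue
            rows.append(
                ManifestRow(
                    file_accession=raw["file_accession"],
                    experiment_accession=raw["experiment_accession"],
                    assay=raw["assay"],
                    tissue=raw["tissue"],
                    biosample_id=raw["biosample_id"],
                    replicate_id=raw["replicate_id"],
                    file_format=raw["file_format"],
                    size_bytes=int(raw["size_bytes"]),
                    md5=raw["md5"].lower(),
                    url=raw["url"],
                )
            )
    if problems:
        raise ManifestFormatError("malformed rows:\n" + "\n".join(problems))
    return rows


def filter_rows(
    rows: Sequence[ManifestRow],
    assay: Optional[str] = None,
    tissue: Optional[str] = None,
    file_format: Optional[str] = None,
) -> list[ManifestRow]:
    """Rows satisfying every given predicate, order preserved.  An empty
    predicate set is the identity; an empty result is legal."""
    out = []
    for r in rows:
        if assay is not None and r.assay != assay:
            continue
        if tissue is not None and r.tissue != tissue:
            continue
        if file_format is not None and r.file_format != file_format:
            continue
        out.append(r)
    return out


def query_predicates(
    assay: Optional[str] = None,
    tissue: Optional[str] = None,
    file_format: Optional[str] = None,
) -> dict[str, str]:
    preds = {}
    if assay is not None:
        preds["assay"] = assay
    if tissue is not None:
        preds["tissue"] = tissue
    if file_format is not None:
        preds["file_format"] = file_format
    return preds


# ---------------------------------------------------------------------------
# summaries

def summarize(
    rows: Sequence[ManifestRow], key: str = "tissue"
) -> tuple[list[GroupSummary], GroupSummary]:
    """Per-group biosample/replicate/file/byte counts plus a totals row
    (column sums over the groups)."""
    if not rows:
        return [], GroupSummary("total", 0, 0, 0, 0)
    df = pd.DataFrame(
        {
            "group": [getattr(r, key) for r in rows],
            "biosample": [r.biosample_id for r in rows],
            "replicate": [f"{r.biosample_id}\t{r.replicate_id}" for r in rows],
            "size": [r.size_bytes for r in rows],
        }
    )
    grouped = df.groupby("group", sort=True)
    summaries = [
        GroupSummary(
            group_key=name,
            n_biosamples=int(g["biosample"].nunique()),
            n_replicates=int(g["replicate"].nunique()),
            n_files=int(len(g)),
            total_bytes=int(g["size"].sum()),
        )
        for name, g in grouped
    ]
    totals = GroupSummary(
        group_key="total",
        n_biosamples=sum(s.n_biosamples for s in summaries),
        n_replicates=sum(s.n_replicates for s in summaries),
        n_files=sum(s.n_files for s in summaries),
        total_bytes=sum(s.total_bytes for s in summaries),
    )
    return summaries, totals


# ---------------------------------------------------------------------------
# conversion to bags

def _slug(text: str) -> str:
    return re.sub(r"[^a-z0-9]+", "-", text.lower()).strip("-") or "group"


def _target_path(row: ManifestRow) -> str:
    ext = re.sub(r"[^a-z0-9.]+", "", row.file_format.lower()) or "dat"
    return f"data/{row.file_accession}.{ext}"


def _rows_tsv(rows: Sequence[ManifestRow], columns: dict[str, str]) -> str:
    fields = list(columns)
    lines = ["\t".join(columns[f] for f in fields)]
    for r in rows:
        lines.append("\t".join(str(getattr(r, f)) for f in fields))
    return "\n".join(lines) + "\n"


def rows_to_holey_bag(
    rows: Sequence[ManifestRow],
    registry: Registry,
    title: str,
    query: QueryRecord,
    out_dir: Union[str, Path],
    agent: Optional[Agent] = None,
    now: Optional[datetime] = None,
    layout: str = "zip",
) -> tuple[Bag, IdentifierRecord]:
    """Convert rows into one holey bag: one fetch line and one md5 manifest
    entry per file, the source rows and the query recorded as annotations,
    the serialized archive minted in the registry.

    The bag holds references only, so its size is a few kB regardless of the
    volume of data it describes."""
    if not rows:
        raise InputError("rows_to_holey_bag needs at least one row")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=False)
    agent = agent or Agent(name="fairbag")
    bag = create_bag(out_dir, info={"External-Description": title}, now=now)

    targets: set[str] = set()
    for row in rows:
        target = _target_path(row)
        if target in targets:
            raise ConflictError(f"colliding target path from accession: {target}")
        targets.add(target)
        add_remote_reference(
            bag,
            RemoteReference(row.url, row.size_bytes, target),
            {"md5": row.md5},
        )

    build_manifest(bag, agent, created_on=now)
    with tempfile.TemporaryDirectory() as tmp:
        qfile = Path(tmp) / "query.json"
        qfile.write_text(query.to_json(), encoding="utf-8")
        attach_annotation(bag, BAG_TARGET, qfile)
        mfile = Path(tmp) / "source-manifest.tsv"
        mfile.write_text(_rows_tsv(rows, DEFAULT_COLUMNS), encoding="utf-8")
        attach_annotation(bag, BAG_TARGET, mfile)
    write_bag(bag, layout="directory")

    archive = write_bag(bag, layout=layout)
    record = registry.mint(
        content=archive,
        title=title,
        creator=agent.name,
        locations=[archive.resolve().as_uri()],
        now=now,
        extra={"content-type": f"bag+{layout}"},
    )
    return bag, record


def partition_and_bag(
    rows: Sequence[ManifestRow],
    registry: Registry,
    out_dir: Union[str, Path],
    key: str = "tissue",
    query: Optional[QueryRecord] = None,
    agent: Optional[Agent] = None,
    now: Optional[datetime] = None,
    layout: str = "zip",
) -> tuple[dict[str, tuple[Bag, IdentifierRecord]], Bag, IdentifierRecord]:
    """One holey bag per distinct *key* value, plus an outer bag of bags
    whose fetch locators are the per-group CURIEs (itself minted)."""
    if not rows:
        raise InputError("partition_and_bag needs at least one row")
    out_dir = Path(out_dir)
    agent = agent or Agent(name="fairbag")
    query = query or make_query_record({}, source="partition", now=now)

    groups: dict[str, list[ManifestRow]] = {}
    for r in rows:
        groups.setdefault(getattr(r, key), []).append(r)

    inner: dict[str, tuple[Bag, IdentifierRecord]] = {}
    for name in sorted(groups):
        gquery = QueryRecord(
            predicates={**query.predicates, key: name},
            executed_at=query.executed_at,
            source=query.source,
        )
        inner[name] = rows_to_holey_bag(
            groups[name],
            registry,
            title=f"{key}={name}",
            query=gquery,
            out_dir=out_dir / _slug(name),
            agent=agent,
            now=now,
            layout=layout,
        )

    outer_root = out_dir / "bag-of-bags"
    outer_root.mkdir(parents=True, exist_ok=False)
    outer = create_bag(
        outer_root, info={"External-Description": f"bag of {len(inner)} bags by {key}"}, now=now
    )
    ext = "zip" if layout == "zip" else "tgz"
    for name in sorted(inner):
        _, record = inner[name]
        archive = out_dir / f"{_slug(name)}.{ext}"
        add_remote_reference(
            outer,
            RemoteReference(record.curie, archive.stat().st_size, f"data/{_slug(name)}.{ext}"),
            {record.checksum[0]: record.checksum[1]},
        )
    build_manifest(outer, agent, created_on=now)
    with tempfile.TemporaryDirectory() as tmp:
        qfile = Path(tmp) / "query.json"
        qfile.write_text(query.to_json(), encoding="utf-8")
        attach_annotation(outer, BAG_TARGET, qfile)
    write_bag(outer, layout="directory")
    outer_archive = write_bag(outer, layout=layout)
    outer_record = registry.mint(
        content=outer_archive,
        title=f"bag of bags by {key}",
        creator=agent.name,
        locations=[outer_archive.resolve().as_uri()],
        now=now,
        extra={"content-type": f"bag+{layout}"},
    )
    return inner, outer, outer_record


# ---------------------------------------------------------------------------
# pipeline fan-out planning

@dataclass
class PipelinePlan:
    """The expected product inventory of the footprinting pipeline, derived
    purely from group summaries × seed lengths × footprint methods."""

    tissues: list[str]
    seeds: list[int]
    methods: list[str]
    biosamples_per_tissue: dict[str, int]
    products: dict[str, list[dict]] = field(default_factory=dict)

    @property
    def n_input_bags(self) -> int:
        return len(self.tissues)

    @property
    def n_alignment_bags(self) -> int:
        return len(self.tissues) * len(self.seeds)

    @property
    def n_merged_alignment_files(self) -> int:
        return sum(self.biosamples_per_tissue.values()) * len(self.seeds)

    @property
    def n_footprint_files(self) -> int:
        return len(self.tissues) * len(self.seeds) * len(self.methods)

    def to_dict(self) -> dict:
        return {
            "tissues": self.tissues,
            "seeds": self.seeds,
            "methods": self.methods,
            "counts": {
                "input_bags": self.n_input_bags,
                "alignment_bags": self.n_alignment_bags,
                "merged_alignment_files": self.n_merged_alignment_files,
                "footprint_files": self.n_footprint_files,
            },
            "products": self.products,
        }


def plan_products(
    summaries: Sequence[GroupSummary],
    seeds: Sequence[int],
    methods: Sequence[str],
) -> PipelinePlan:
    """Enumerate every expected pipeline product and its lineage.

    Alignment runs once per {tissue, seed}; merging yields one alignment
    file per {biosample, seed}; footprinting yields one file per
    {tissue, seed, method}."""
    if not seeds or not methods:
        raise InputError("plan_products needs at least one seed and one method")
    tissues = [s.group_key for s in summaries]
    nb = {s.group_key: s.n_biosamples for s in summaries}

    input_bags = [{"stage": "input", "tissue": t} for t in tissues]
    alignment_bags = [
        {"stage": "alignment", "tissue": t, "seed": s, "derived_from": f"input:{t}"}
        for t in tissues
        for s in seeds
    ]
    merged = [
        {
            "stage": "merged-alignment",
            "tissue": t,
            "seed": s,
            "n_files": nb[t],
            "derived_from": f"alignment:{t}:seed{s}",
        }
        for t in tissues
        for s in seeds
    ]
    footprints = [
        {
            "stage": "footprints",
            "tissue": t,
            "seed": s,
            "method": m,
            "derived_from": f"alignment:{t}:seed{s}",
        }
        for t in tissues
        for s in seeds
        for m in methods
    ]
    return PipelinePlan(
        tissues=tissues,
        seeds=list(seeds),
        methods=list(methods),
        biosamples_per_tissue=nb,
        products={
            "input_bags": input_bags,
            "alignment_bags": alignment_bags,
            "merged_alignment_files": merged,
            "footprint_files": footprints,
        },
    )
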