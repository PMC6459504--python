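"""Footprint × motif-hit interval intersection (candidate TFBS calling).

Footprints are short protected regions within open chromatin; motif hits
are position-weight-matrix occurrences in the reference genome.  A candidate
transcription-factor binding site is the nonempty coordinate overlap of a
footprint and a hit on the same chromosome.  All coordinates are 0-based
half-open (BED convention); any 1-based dialect must be converted at the
reader.  Overlap requires at least one shared base; strand plays no part in
the overlap test but is carried through to the output.

The intersection itself runs on per-chromosome interval trees; tests hold it
to exact agreement with a brute-force all-pairs scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from intervaltree import IntervalTree

from .errors import BedParseError, InputError


@dataclass(frozen=True)
class FootprintRecord:
    chrom: str
    start: int
    end: int
    method: str = ""
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise BedParseError("footprint with empty chromosome name")
        if self.start >= self.end:
            raise BedParseError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )


@dataclass(frozen=True)
class HitRecord:
    motif_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    p_value: float = 1.0
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.chrom:
            raise BedParseError("hit with empty chromosome name")
        if self.start >= self.end:
            raise BedParseError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if not 0.0 <= self.p_value <= 1.0:
            raise BedParseError(f"p-value outside [0, 1]: {self.p_value}")
        if self.strand not in ("+", "-", "."):
            raise BedParseError(f"bad strand: {self.strand!r}")


@dataclass(frozen=True)
class CandidateTFBS:
    motif_id: str
    chrom: str
    start: int                       # overlap interval, contained in both sources
    end: int
    footprint: FootprintRecord
    hit: HitRecord
    method: str


# ---------------------------------------------------------------------------
# BED I/O

def read_bed(path: Union[str, Path], method: str = "") -> list[FootprintRecord]:
    """Read a 3+ column BED of footprints (0-based half-open).  Column 4 is
    kept as the method label when present (overridable), column 5 as score."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"no such BED file: {path}")
    records = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise BedParseError(f"{path.name} line {lineno}: fewer than 3 columns")
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError:
            raise BedParseError(
                f"{path.name} line {lineno}: non-numeric coordinate"
            ) from None
        score = None
        if len(cols) >= 5 and cols[4] not in (".", ""):
            try:
                score = float(cols[4])
            except ValueError:
                raise BedParseError(f"{path.name} line {lineno}: bad score") from None
        try:
            records.append(
                FootprintRecord(
                    chrom=cols[0],
                    start=start,
                    end=end,
                    method=method or (cols[3] if len(cols) >= 4 else ""),
                    score=score,
                )
            )
        except BedParseError as exc:
            raise BedParseError(f"{path.name} line {lineno}: {exc}") from None
    return records


def write_bed(records: Sequence[FootprintRecord], path: Union[str, Path]) -> Path:
    path = Path(path)
    lines = []
    for r in sorted(records, key=lambda r: (r.chrom, r.start, r.end, r.method)):
        score = "." if r.score is None else format(r.score, "g")
        lines.append(f"{r.chrom}\t{r.start}\t{r.end}\t{r.method or '.'}\t{score}")
    path.write_text("".join(l + "\n" for l in lines), encoding="utf-8")
    return path


def read_hits(path: Union[str, Path]) -> list[HitRecord]:
    """Read a hits table: motif_id, chrom, start, end, strand, p_value, score
    (tab-separated, no header)."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"no such hits file: {path}")
    hits = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 7:
            raise BedParseError(f"{path.name} line {lineno}: expected 7 columns")
        try:
            hits.append(
                HitRecord(
                    motif_id=cols[0],
                    chrom=cols[1],
                    start=int(cols[2]),
                    end=int(cols[3]),
                    strand=cols[4],
                    p_value=float(cols[5]),
                    score=float(cols[6]),
                )
            )
        except ValueError:
            raise BedParseError(f"{path.name} line {lineno}: bad field") from None
        except BedParseError as exc:
            raise BedParseError(f"{path.name} line {lineno}: {exc}") from None
    return hits


def write_hits(hits: Sequence[HitRecord], path: Union[str, Path]) -> Path:
    path = Path(path)
    lines = [
        f"{h.motif_id}\t{h.chrom}\t{h.start}\t{h.end}\t{h.strand}\t{h.p_value:g}\t{h.score:g}"
        for h in sorted(hits, key=lambda h: (h.chrom, h.start, h.end, h.motif_id))
    ]
    path.write_text("".join(l + "\n" for l in lines), encoding="utf-8")
    return path


def write_candidates(candidates: Sequence[CandidateTFBS], path: Union[str, Path]) -> Path:
    """BED6+ output: overlap coordinates, motif_id in the name column, hit
    score and strand, then method and source intervals."""
    path = Path(path)
    lines = [
        "\t".join(
            [
                c.chrom,
                str(c.start),
                str(c.end),
                c.motif_id,
                format(c.hit.score, "g"),
                c.hit.strand,
                c.method or ".",
                str(c.footprint.start),
                str(c.footprint.end),
                str(c.hit.start),
                str(c.hit.end),
                format(c.hit.p_value, "g"),
            ]
        )
        for c in candidates
    ]
    path.write_text("".join(l + "\n" for l in lines), encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# intersection

def intersect_catalog(
    footprints: Sequence[FootprintRecord], hits: Sequence[HitRecord]
) -> list[CandidateTFBS]:
    """One candidate per (footprint, hit) pair sharing ≥1 base on the same
    chromosome, sorted by (chrom, start, motif_id).  Interval-tree driven;
    exact-equivalent to the all-pairs scan."""
    trees: dict[str, IntervalTree] = {}
    for h in hits:
        trees.setdefault(h.chrom, IntervalTree()).addi(h.start, h.end, h)

    out: list[CandidateTFBS] = []
    for fp in footprints:
        tree = trees.get(fp.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(fp.start, fp.end):
            h: HitRecord = iv.data
            start = max(fp.start, h.start)
            end = min(fp.end, h.end)
            out.append(
                CandidateTFBS(
                    motif_id=h.motif_id,
                    chrom=fp.chrom,
                    start=start,
                    end=end,
                    footprint=fp,
                    hit=h,
                    method=fp.method,
                )
            )
    out.sort(
        key=lambda c: (
            c.chrom,
            c.start,
            c.motif_id,
            c.end,
            c.footprint.start,
            c.footprint.end,
            c.hit.start,
            c.hit.end,
        )
    )
    return out


def brute_force_intersect(
    footprints: Sequence[FootprintRecord], hits: Sequence[HitRecord]
) -> list[CandidateTFBS]:
    """Quadratic all-pairs reference scan (the independent oracle for the
    tree-based implementation)."""
    out = []
    for fp in footprints:
        for h in hits:
            if fp.chrom == h.chrom and fp.start < h.end and h.start < fp.end:
                out.append(
                    CandidateTFBS(
                        motif_id=h.motif_id,
                        chrom=fp.chrom,
                        start=max(fp.start, h.start),
                        end=min(fp.end, h.end),
                        footprint=fp,
                        hit=h,
                        method=fp.method,
                    )
                )
    out.sort(
        key=lambda c: (
            c.chrom,
            c.start,
            c.motif_id,
            c.end,
            c.footprint.start,
            c.footprint.end,
            c.hit.start,
            c.hit.end,
        )
    )
    return out


# ---------------------------------------------------------------------------
# bagged, per-file intersection

def enumerate_footprint_files(node) -> list[tuple[str, Path]]:
    """Walk a materialization tree and list (label, path) for every BED
    payload file of every expanded inner bag (and of the root bag itself)."""
    out: list[tuple[str, Path]] = []
    for n in node.walk():
        if not n.expanded:
            continue
        root = Path(n.location)
        for bed in sorted(root.glob("data/**/*.bed")) + sorted(root.glob("data/*.bed")):
            label = f"{root.name}/{bed.relative_to(root / 'data').as_posix()}"
            if (label, bed) not in out:
                out.append((label, bed))
    return out


def intersect_per_bag(
    materialized,
    hits: Sequence[HitRecord],
    registry,
    out_dir: Union[str, Path],
    agent=None,
    now=None,
):
    """Intersect every footprint BED of a materialized bag-of-bags with the
    hits catalog: one candidate file per input footprint file, one output
    bag per source footprint bag, and an outer minted bag of bags over the
    output CURIEs.

    An unreadable footprint file is recorded as a per-file failure and the
    run continues.  Returns ``(outer_bag, outer_record, results)`` where
    *results* maps each input label to an outcome record."""
    from .bag import RemoteReference, add_remote_reference, create_bag, write_bag
    from .ro import Agent, build_manifest

    out_dir = Path(out_dir)
    agent = agent or Agent(name="fairbag")
    inputs = enumerate_footprint_files(materialized)

    # group candidate outputs by the inner bag they came from
    by_source: dict[str, list[tuple[str, Path]]] = {}
    for label, bed_path in inputs:
        by_source.setdefault(label.split("/", 1)[0], []).append((label, bed_path))

    results: dict[str, dict] = {}
    inner: list[tuple[str, object]] = []        # (slug, IdentifierRecord)
    for source in sorted(by_source):
        slug = source.replace(".", "-")
        bag_root = out_dir / f"tfbs-{slug}"
        bag_root.mkdir(parents=True, exist_ok=False)
        for label, bed_path in by_source[source]:
            name = label.split("/", 1)[-1].replace("/", "__").removesuffix(".bed")
            try:
                fps = read_bed(bed_path)
                candidates = intersect_catalog(fps, hits)
            except (BedParseError, InputError) as exc:
                results[label] = {"ok": False, "error": str(exc)}
                continue
            write_candidates(candidates, bag_root / f"{name}.candidates.bed")
            results[label] = {"ok": True, "n_candidates": len(candidates)}
        bag = create_bag(
            bag_root,
            info={"External-Description": f"candidate TFBSs from {source}"},
            now=now,
        )
        build_manifest(bag, agent, created_on=now)
        write_bag(bag, layout="directory")
        archive = write_bag(bag, layout="zip")
        record = registry.mint(
            content=archive,
            title=f"candidate TFBSs ({source})",
            creator=agent.name,
            locations=[archive.resolve().as_uri()],
            now=now,
            extra={"content-type": "bag+zip"},
        )
        inner.append((slug, record))

    outer_root = out_dir / "tfbs-bag-of-bags"
    outer_root.mkdir(parents=True, exist_ok=False)
    outer = create_bag(
        outer_root,
        info={"External-Description": "bag of candidate-TFBS bags"},
        now=now,
    )
    for slug, record in inner:
        archive = out_dir / f"tfbs-{slug}.zip"
        add_remote_reference(
            outer,
            RemoteReference(record.curie, archive.stat().st_size, f"data/tfbs-{slug}.zip"),
            {record.checksum[0]: record.checksum[1]},
        )
    build_manifest(outer, agent, created_on=now)
    write_bag(outer, layout="directory")
    outer_archive = write_bag(outer, layout="zip")
    outer_record = registry.mint(
        content=outer_archive,
        title="candidate TFBSs (all sources)",
        creator=agent.name,
        locations=[outer_archive.resolve().as_uri()],
        now=now,
        extra={"content-type": "bag+zip"},
    )
    return outer, outer_record, results
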