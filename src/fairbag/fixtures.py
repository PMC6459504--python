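"""Seeded synthetic fixtures: metadata manifests, payload stores, interval
sets, footprint bag trees, and a tamper utility.

The manifest generator emulates an ENCODE-portal metadata export
structurally — one row per downloadable file with accession, tissue term,
biosample, technical replicate, format, size, md5 and a download URL — with
every URL a ``file://`` link into a locally generated payload store, so the
whole packaging/materialization lifecycle runs with no network.  The bundled
``table1`` preset carries the 27 tissues of the DNase-seq case study with
their published biosample and replicate counts (193 biosamples, 1,355
replicates in total); each replicate contributes one FASTQ file.

Payload files are small (1–4 kB) regardless of the sizes real repositories
would serve; the manifest's size column always states the actual generated
size so length checks remain meaningful.  All generation is reproducible
from (spec, seed) alone.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Optional, Sequence, Union

from .errors import InputError

# (biosamples, replicates) per tissue of the case study's inventory
TABLE1_COUNTS: dict[str, tuple[int, int]] = {
    "adrenal gland": (3, 8),
    "blood vessel": (10, 129),
    "bone element": (1, 7),
    "brain": (29, 185),
    "bronchus": (2, 9),
    "esophagus": (2, 41),
    "extraembryonic": (11, 66),
    "eye": (8, 53),
    "gonad": (2, 7),
    "heart": (8, 69),
    "kidney": (8, 29),
    "large intestine": (5, 18),
    "liver": (3, 8),
    "lung": (7, 94),
    "lymphatic vessel": (2, 30),
    "lymphoblast": (21, 71),
    "mammary gland": (2, 5),
    "mouth": (4, 18),
    "muscle organ": (4, 13),
    "pancreas": (2, 13),
    "prostate gland": (2, 8),
    "skin": (48, 401),
    "spinal cord": (2, 34),
    "stomach": (1, 5),
    "thyroid gland": (3, 24),
    "tongue": (2, 8),
    "urinary bladder": (1, 2),
}


@dataclass
class FixtureSpec:
    seed: int = 0
    counts: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(TABLE1_COUNTS)
    )
    size_range: tuple[int, int] = (1024, 4096)
    assay: str = "DNase-seq"
    file_format: str = "fastq"


def table1_spec(seed: int = 0) -> FixtureSpec:
    """The preset mirroring the case study's 27-tissue inventory."""
    return FixtureSpec(seed=seed)


def _file_bytes(spec: FixtureSpec, accession: str) -> bytes:
    # content keyed by (seed, accession): identical whether or not the store
    # is written, and stable across processes (str seeding hashes via SHA-512)
    rng = random.Random(f"{spec.seed}:{accession}")
    size = rng.randint(*spec.size_range)
    return rng.randbytes(size)


def _distribute(total: int, bins: int) -> list[int]:
    """Split *total* replicates over *bins* biosamples, each getting >= 1."""
    if total < bins:
        raise InputError(f"cannot give {bins} biosamples at least one of {total} replicates")
    base, extra = divmod(total, bins)
    return [base + (1 if i < extra else 0) for i in range(bins)]


def generate_fixture_manifest(
    spec: FixtureSpec,
    out_dir: Union[str, Path],
    write_store: bool = True,
) -> tuple[Path, Path]:
    """Write ``manifest.tsv`` (and, unless skipped, the payload store it
    points into) under *out_dir*.  Returns (tsv path, store directory).

    md5 values always equal the digest of the (deterministically generated)
    file content, so fixity checks against the store succeed."""
    from .encode import DEFAULT_COLUMNS

    out_dir = Path(out_dir)
    store = out_dir / "store"
    out_dir.mkdir(parents=True, exist_ok=True)
    if write_store:
        store.mkdir(parents=True, exist_ok=True)

    fields = list(DEFAULT_COLUMNS)
    lines = ["\t".join(DEFAULT_COLUMNS[f] for f in fields)]
    file_no = 0
    bio_no = 0
    exp_no = 0
    for tissue, (n_bio, n_rep) in spec.counts.items():
        if n_bio <= 0 or n_rep <= 0:
            raise InputError(f"counts must be positive: {tissue}")
        for b, reps in enumerate(_distribute(n_rep, n_bio)):
            bio_no += 1
            exp_no += 1
            biosample = f"ENCBS{bio_no:05d}"
            experiment = f"ENCSR{exp_no:05d}"
            for r in range(1, reps + 1):
                file_no += 1
                accession = f"ENCFF{file_no:06d}"
                content = _file_bytes(spec, accession)
                filename = f"{accession}.{spec.file_format}"
                if write_store:
                    (store / filename).write_bytes(content)
                row = {
                    "file_accession": accession,
                    "experiment_accession": experiment,
                    "assay": spec.assay,
                    "tissue": tissue,
                    "biosample_id": biosample,
                    "replicate_id": f"1_{r}",
                    "file_format": spec.file_format,
                    "size_bytes": str(len(content)),
                    "md5": hashlib.md5(content).hexdigest(),
                    "url": (store.resolve() / filename).as_uri(),
                }
                lines.append("\t".join(row[f] for f in fields))

    tsv = out_dir / "manifest.tsv"
    tsv.write_text("".join(l + "\n" for l in lines), encoding="utf-8")
    return tsv, store


# ---------------------------------------------------------------------------
# intervals

def generate_intervals(
    out_dir: Union[str, Path],
    seed: int = 0,
    n_footprints: int = 100,
    n_hits: int = 100,
    chrom_sizes: Optional[dict[str, int]] = None,
    method: str = "hint",
):
    """Seeded random footprints and motif hits (0-based half-open, valid by
    construction), written as ``footprints.bed`` and ``hits.tsv``."""
    from .intervals import FootprintRecord, HitRecord, write_bed, write_hits

    if n_footprints < 0 or n_hits < 0:
        raise InputError("interval counts must be >= 0")
    chrom_sizes = chrom_sizes or {"chr1": 200_000, "chr2": 150_000}
    rng = random.Random(seed)
    chroms = sorted(chrom_sizes)

    footprints = []
    for _ in range(n_footprints):
        chrom = rng.choice(chroms)
        length = rng.randint(10, 60)
        start = rng.randrange(0, chrom_sizes[chrom] - length)
        footprints.append(
            FootprintRecord(
                chrom=chrom,
                start=start,
                end=start + length,
                method=method,
                score=round(rng.uniform(0, 100), 3),
            )
        )
    hits = []
    for i in range(n_hits):
        chrom = rng.choice(chroms)
        length = rng.randint(6, 20)
        start = rng.randrange(0, chrom_sizes[chrom] - length)
        hits.append(
            HitRecord(
                motif_id=f"MOTIF{rng.randint(1, 50):04d}",
                chrom=chrom,
                start=start,
                end=start + length,
                strand=rng.choice("+-."),
                p_value=round(10 ** -rng.uniform(2, 8), 12),
                score=round(rng.uniform(5, 30), 3),
            )
        )

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_bed(footprints, out_dir / "footprints.bed")
    write_hits(hits, out_dir / "hits.tsv")
    return footprints, hits


def generate_footprint_bag_tree(
    out_dir: Union[str, Path],
    registry,
    tissues: Sequence[str],
    seeds: Sequence[int] = (16, 20),
    methods: Sequence[str] = ("hint", "wellington"),
    n_per_file: int = 20,
    seed: int = 0,
    now: Optional[datetime] = None,
):
    """Build a holey bag of bags of footprint files: one inner bag per
    {tissue, seed} holding one BED per method, each inner bag archived and
    minted, the outer bag's fetch locators being the inner CURIEs.

    This emulates the footprint dataset a footprinting phase hands to the
    intersection stage.  Returns ``(outer_bag, outer_record)``."""
    from .bag import RemoteReference, add_remote_reference, create_bag, write_bag
    from .intervals import FootprintRecord
    from .intervals import write_bed
    from .ro import Agent, build_manifest

    out_dir = Path(out_dir)
    agent = Agent(name="fairbag-fixtures")
    rng = random.Random(seed)
    chrom_sizes = {"chr1": 200_000, "chr2": 150_000}
    chroms = sorted(chrom_sizes)

    inner: list[tuple[str, object, Path]] = []
    for tissue in tissues:
        for s in seeds:
            name = f"{tissue.replace(' ', '-')}-seed{s}"
            root = out_dir / name
            root.mkdir(parents=True, exist_ok=False)
            for m in methods:
                fps = []
                for _ in range(n_per_file):
                    chrom = rng.choice(chroms)
                    length = rng.randint(10, 60)
                    start = rng.randrange(0, chrom_sizes[chrom] - length)
                    fps.append(
                        FootprintRecord(chrom=chrom, start=start, end=start + length, method=m)
                    )
                write_bed(fps, root / f"{name}_{m}.bed")
            bag = create_bag(
                root, info={"External-Description": f"footprints {name}"}, now=now
            )
            build_manifest(bag, agent, created_on=now)
            write_bag(bag, layout="directory")
            archive = write_bag(bag, layout="zip")
            record = registry.mint(
                content=archive,
                title=f"footprints {name}",
                creator=agent.name,
                locations=[archive.resolve().as_uri()],
                now=now,
                extra={"content-type": "bag+zip"},
            )
            inner.append((name, record, archive))

    outer_root = out_dir / "footprints-bag-of-bags"
    outer_root.mkdir(parents=True, exist_ok=False)
    outer = create_bag(
        outer_root,
        info={"External-Description": "bag of footprint bags"},
        now=now,
    )
    for name, record, archive in inner:
        add_remote_reference(
            outer,
            RemoteReference(record.curie, archive.stat().st_size, f"data/{name}.zip"),
            {record.checksum[0]: record.checksum[1]},
        )
    build_manifest(outer, agent, created_on=now)
    write_bag(outer, layout="directory")
    outer_record = registry.mint(
        content=write_bag(outer, layout="zip"),
        title="footprint bag of bags",
        creator=agent.name,
        locations=[],
        now=now,
        extra={"content-type": "bag+zip"},
    )
    return outer, outer_record


# ---------------------------------------------------------------------------
# tampering

def tamper(path: Union[str, Path], offset: int) -> None:
    """Flip every bit of the byte at *offset* (an involution: tampering the
    same offset twice restores the original content)."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"no such file: {path}")
    size = path.stat().st_size
    if not 0 <= offset < size:
        raise InputError(f"offset {offset} out of range for {size}-byte file")
    with open(path, "r+b") as fh:
        fh.seek(offset)
        byte = fh.read(1)
        fh.seek(offset)
        fh.write(bytes([byte[0] ^ 0xFF]))
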