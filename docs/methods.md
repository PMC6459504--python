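# Methods

## What the package models

`fairbag` implements the data-lifecycle machinery of a large DNase-seq
footprinting study as a reusable library: packaging datasets so that their
contents are enumerated, checksummed, and optionally remote (BDBags);
naming dataset instances with checksum-bound persistent identifiers whose
landing records outlive the data; materializing reference-only bags —
including bags of bags — with fixity verified before placement; converting
repository metadata exports into per-tissue bags with the selecting query
recorded verbatim; planning the combinatorial fan-out of the downstream
pipeline; scoring resources against a 16-criterion FAIR rubric; and the
final analysis step, intersecting chromatin footprints with motif hits to
produce candidate transcription-factor binding sites.

The compute-heavy stages of the original workflow (read alignment, peak
calling, footprint inference, genome-wide motif scanning) are external
tools by design and are *not* reimplemented; their inputs and outputs are
what this package packages, names, moves, verifies, and intersects.

## Bags

A bag is a BagIt 1.0 directory: `bagit.txt` (version 1.0, UTF-8), payload
under `data/`, one `manifest-<alg>.txt` per checksum algorithm, tag
manifests covering every non-payload file (including the embedded metadata
directory), and `bag-info.txt`. Design choices that the BagIt family of
specifications leaves open:

* **Algorithms.** md5 and sha256 by default. Repository exports commonly
  supply md5 only, while the identifier registry standardizes on sha256;
  a payload entry must appear in at least one payload manifest, and full
  validation verifies every digest that is recorded.
* **Payload-Oxum** counts local *and* remote entries, because the Oxum of a
  holey bag should describe the complete dataset it represents. A remote
  entry with unknown length makes the Oxum undefined; it is then omitted
  from `bag-info.txt` and fast validation reports `oxum_ok=False` with a
  reason rather than guessing.
* **fetch.txt dialect**: one record per line, three space-separated fields;
  LENGTH is a decimal integer or `-` for unknown; CR, LF and `%` in target
  paths are percent-encoded. Parsing splits on the first two spaces only,
  so target paths containing spaces survive a round trip.
* **Serialization** is byte-stable: manifests sort lexicographically by
  path, and zip/tgz archives carry fixed timestamps (so re-serializing
  identical content yields an identical archive digest — which matters
  because archive digests are minted). Archives contain exactly one
  top-level directory named after the bag.
* **Validation modes**: `structural` (layout only), `fast` (adds presence
  and Oxum), `full` (recomputes every recorded digest of every present
  payload and tag file). All findings are reported in the
  `ValidationReport`; validation never raises. "Valid" means structurally
  sound, complete, no fixity errors, no unmanifested payload files; a holey
  bag is expected to be structurally valid but incomplete.

## Research Object metadata

The RO manifest at `metadata/manifest.json` is a deliberately minimal
JSON-LD profile: a fixed context list, `createdOn`/`createdBy`, an
aggregate per payload entry (bag-relative path) and per remote reference
(its locator URI), and annotations about aggregates or the bag itself.
Timestamps are UTC, second precision, RFC 3339. File-based annotation
content is copied under `metadata/annotations/` so the tag manifests digest
it — tampering with metadata is then caught by full validation exactly like
payload damage. No nested provenance chains and no full ORE/RO-Crate
vocabulary: the profile records who made the bag, when, of what, and what
was said about it.

## Identifiers

Identifiers are CURIEs `minid:<suffix>` with six-character lowercase
base-36 suffixes, collision-checked at mint time; prefix, alphabet and
length are registry configuration, and a seeded registry yields a
reproducible suffix sequence for tests. The suffix length and alphabet are
package decisions — landing-page conventions pin down the CURIE form but
not the suffix grammar.

A record binds the identifier to `(algorithm, digest)` — sha256 of the
identified content — plus title, creator, creation time, an *ordered* list
of locations, a status, and open metadata. The checksum is immutable after
minting; locations may only grow (idempotent re-adds); tombstoning marks
the data gone while the record stays resolvable, so verification of a
surviving copy still works. Persistence is an append-only JSON-lines store
(latest line per CURIE wins on load): a reopened registry resolves
identically, and history is retained. Identifiers name dataset *instances*,
not content — minting the same bytes twice yields distinct CURIEs with
equal checksums.

Rendering honors the two faces of a landing page: `machine` is a JSON
document carrying every field (parseable back into a field-equal record),
`human` a small HTML page listing title, creator, date, checksum, status,
and one link per location. A network resolver service is out of scope;
resolution is a library/CLI operation against the local store.

## Materialization

Fetch planning maps every non-present payload entry to an ordered candidate
list: a plain URL passes through; a CURIE locator resolves through the
registry to the landing record's locations, in registry order (no bandwidth
heuristics), with the record's checksum joining the expected digests. An
unresolvable identifier is recorded as unavailable, never fatal — a bag may
legitimately reference data its holder cannot (yet) access.

Downloads go to a temporary file and are verified — declared length and
*every* expected digest — before an atomic rename into the target path, so
no partially verified bytes ever occupy the payload. Corrupt downloads move
to a `quarantine/` directory named by their actual sha256 for post-mortem.
Candidates are tried in order until one verifies; outcomes are
`fetched-verified`, `fetched-corrupt`, `unavailable`, or `skipped` (already
present, so re-running a completed bag fetches zero bytes). Transports are
`file://` and `http(s)://` with three attempts and exponential backoff;
anything else is unavailable.

Recursive materialization treats a fetched payload entry as an inner bag
when its registry record declares content-type `bag+zip`/`bag+tgz`, or,
as a fallback, when the archive structurally contains `bagit.txt` at its
root. Inner bags are expanded under `expanded/` (outside `data/`, so the
extracted tree never pollutes the outer bag's payload enumeration) and
materialized in turn up to a depth bound: the outer bag is level 1, so
depth 1 fetches inner archives without expanding them. The report is a tree
of nodes carrying each bag's fetch outcomes and full-validation state; a
tampered inner bag is reported invalid without affecting its siblings.

## Manifest conversion and bookkeeping

The parser reads a tab-separated metadata export with a configurable
column mapping (defaults follow the ENCODE portal's labels). It is strict
on purpose: missing columns, duplicate file accessions, non-integer sizes
(`12,345` is an error, not 12345), malformed md5s, and empty
tissue/biosample/replicate fields are reported with line numbers rather
than coerced. Replicate identity is the `(biosample, technical replicate)`
pair; a replicate may span multiple files, counted at file level only.

Conversion produces holey bags: one fetch line and one md5 manifest entry
per row, target paths `data/<accession>.<format>`, the source rows and the
executing query stored as digested annotations, the serialized archive
minted with a `file://` location. Partitioning groups rows by tissue (the
organ term is taken as given — no ontology mapping), emits one bag per
group plus an outer bag of bags whose fetch locators are the per-group
CURIEs and whose digests are the minted archive checksums. With an injected
clock and a seeded registry the whole construction is byte-deterministic.

The planner turns group summaries × seed lengths × methods into a product
ledger: alignment runs once per {tissue, seed}; merging yields one
alignment file per {biosample, seed}; footprinting one file per
{tissue, seed, method}; each product records its lineage. For the bundled
27-tissue inventory with seeds {16, 20} and methods {HINT, Wellington}
this gives 54 alignment bags, 386 merged alignment files, and 108
footprint files. (Dataset inventories sometimes describe the footprint
stage as files-per-biosample instead; the planner follows the
per-{tissue, seed, method} count, which is the one the intersection stage
consumes.)

## FAIR rubric

Sixteen ordered criteria, each a single boolean predicate over a
`ResourceDescriptor`; the questionnaire behind each criterion is not
reproduced. `assess` refuses descriptors with unset flags, listing them.
`assess_bag` derives what packaging can witness: identifier and persistence
from the resolvable landing record; machine-readable, standardized,
formally-expressed metadata with a vocabulary from the RO manifest
(JSON-LD with a context); identifier-in-metadata from the landing record
naming its own CURIE (a bag archive cannot contain the identifier of its
own checksum); open and restricted access protocols from registered
locations reachable over standard protocols; metadata licensing from the
registry's policy of publishing landing records under CC0. Four flags
cannot be derived from packaging and must be declared: web-search
discoverability, the resource license, membership in a linked set, and a
community certificate. The bundled case-study configuration (6 datasets,
7 tools; only the upstream repository dataset and the tools web-indexed;
no certificates) yields a verdict matrix whose minimum satisfied count is
14 of 16.

## Interval intersection

Coordinates are 0-based half-open everywhere. A candidate TFBS is emitted
for every (footprint, hit) pair on the same chromosome sharing at least one
base — any-overlap, not containment, and strand plays no role in the
overlap test (the hit's strand is carried through to the output). Output is
BED6+ sorted by (chrom, start, motif_id, …) for byte-stable files. The
implementation builds one interval tree per chromosome over the hits and
queries each footprint; a quadratic all-pairs scan serves as the
independent oracle in tests, and the two must agree exactly. The
bag-level driver walks a materialized bag-of-bags, intersects every
footprint BED with the hits catalog (per-file failures are recorded and
the run continues), and packages the outputs as one bag per source bag
under a minted outer bag of bags.

## Synthetic fixtures

The fixture generator emulates an ENCODE-portal metadata export
structurally: per-tissue biosample and replicate counts, accession-styled
identifiers, per-file sizes, md5s, and `file://` URLs into a generated
payload store. The bundled `table1` preset carries the case study's
27-tissue inventory exactly — 193 biosamples, 1,355 replicates — with one
FASTQ file per replicate; replicates are distributed over biosamples as
evenly as possible (floor plus remainder to the leading biosamples, every
biosample ≥ 1). Payload files are 1–4 kB with contents keyed by
(seed, accession), so manifests are reproducible byte-for-byte and the
size/md5 columns always describe the true generated file — length and
fixity checks are therefore meaningful. The store can be skipped for
summary-only work without changing the manifest.

What the fixtures do *not* emulate: real file sizes (gigabytes), the
splitting of some replicates across multiple FASTQ files (each fixture
replicate is exactly one file, so file counts equal replicate counts),
sequence content, repository authentication, or network transport beyond
`file://`. Passing tests demonstrate the packaging, naming, verification,
bookkeeping, and intersection logic — not alignment or footprinting
science, and not behavior under repository-scale data volumes or flaky
wide-area networks.

Problem sizes used by the test and acceptance suites: the full 27-tissue
manifest (1,355 rows) for summaries, planning, and the 27-bag partition;
two-to-three-tissue manifests with generated stores for materialization;
random instances up to 500×500 intervals for the intersection oracle;
random file trees of up to six files for round-trip and fixity properties.

## Known limitations

* The registry is local; no n2t.net/identifiers.org integration, no
  DOI/ARK minting, and no HTTP resolver service.
* No parallel or authenticated transfer; `file://` and plain `http(s)://`
  only.
* The RO profile is minimal and not validated against external ontologies.
* BagIt features beyond the core-plus-`fetch.txt` profile (encryption,
  streaming archive readers, `.bagit` profiles) are out of scope.
* Rubric criteria are one-flag predicates; "protocol to access restricted
  content" is declared or derived from locations, never probed.
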