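# fairbag

Infrastructure for keeping big genomics analyses FAIR — findable,
accessible, interoperable, reusable — across every step of the data
lifecycle, not just at publication time. `fairbag` packages datasets as
**BDBags** (BagIt bags extended with remote references and embedded
Research Object metadata), binds them to **checksum-backed persistent
identifiers** with multi-location landing records, **materializes** holey
bags (including recursive bags of bags) with verify-then-place fixity,
converts **ENCODE-portal-style metadata manifests** into per-tissue bags
with recorded queries, plans the downstream pipeline **fan-out**, scores
resources against a 16-criterion **FAIR rubric**, and intersects DNase-seq
**footprints with motif hits** to call candidate transcription-factor
binding sites (TFBSs).

The package is written for data engineers and computational biologists who
run multi-stage, multi-terabyte workflows and need every intermediate
product to be independently identifiable, verifiable, and re-fetchable.

## The core machinery

* **Bag** — a BagIt 1.0 tree: declaration `bagit.txt`, payload under
  `data/`, payload manifests `manifest-<alg>.txt`, tag manifests, and
  `bag-info.txt` carrying `Payload-Oxum = <octets>.<streams>` over local
  *and* remote entries. A remote entry is one `fetch.txt` line
  `(URL|CURIE, LENGTH, FILENAME)`; a bag with unfetched entries is *holey*:
  structurally valid, incomplete, and typically a few kB no matter how much
  data it references.
* **Identifier** — a CURIE `minid:<suffix>` bound at mint time to a sha256
  digest of the content and an ordered list of storage locations. The
  landing record outlives the data (tombstoning keeps it resolvable), and
  any copy, from any location, can be verified against the minted checksum.
* **Materialization** — resolve each fetch entry (CURIEs through the
  registry), try candidate locations in order, verify digest and length
  *before* placing bytes at the target path, quarantine corrupt downloads,
  and recurse into payload entries that are themselves serialized bags.
* **Rubric** — 16 ordered boolean criteria (unique/persistent identifier,
  machine-readable/standardized metadata, access protocols, persistence,
  vocabulary, licensing, linked set, provenance, community certificate).
  Most flags are derived mechanically from a bag plus its landing record;
  what packaging cannot prove must be declared.
* **Intersection** — candidate TFBS = footprint ∩ motif hit with ≥ 1 shared
  base on the same chromosome, 0-based half-open coordinates throughout,
  interval-tree driven and exact-equivalent to the all-pairs scan.

## Worked example

Generate the bundled 27-tissue synthetic manifest (ENCODE-portal-shaped;
see `docs/methods.md` for what it does and does not emulate), summarize it,
and plan the pipeline fan-out:

```bash
$ fairbag fixtures manifest fx --seed 1 --no-store
$ fairbag summarize fx/manifest.tsv
group             biosamples  replicates  files  bytes
adrenal gland              3           8      8  20798
blood vessel              10         129    129  321116
bone element               1           7      7  16799
...
urinary bladder            1           2      2  4893
total                    193        1355   1355  3485048

$ fairbag plan fx/manifest.tsv --seeds 16,20 --methods hint,wellington
{
  "input_bags": 27,
  "alignment_bags": 54,
  "merged_alignment_files": 386,
  "footprint_files": 108
}
```

The summary reproduces the case-study inventory — 193 biosamples and 1,355
replicates across 27 tissues — and the plan is the fan-out arithmetic:
27 tissues × 2 alignment seed lengths = 54 alignment bags; 193 biosamples
× 2 seeds = 386 merged alignment files; 27 × 2 × 2 footprinting methods =
108 footprint files.

Convert one tissue into a holey bag (with a payload store this time), then
materialize and verify it:

```bash
$ fairbag fixtures manifest fxs --seed 2
$ fairbag convert fxs/manifest.tsv bags --tissue "urinary bladder" \
    --registry reg.jsonl --seed 7 --title "urinary bladder DNase-seq"
bag with 2 fetch entries minted as minid:k9p34y
$ fairbag validate bags
bags: structurally valid, holey (2 missing), 0 fixity error(s)
$ fairbag materialize bags --registry reg.jsonl
bags: {'fetched-verified': 2}
$ fairbag validate bags
bags: valid, complete, 0 fixity error(s)
```

The bag starts as references plus checksums (holey), and after
materialization every payload byte has been verified against the manifest
digests recorded at conversion time. The minted CURIE resolves to a landing
record (JSON or HTML) whose checksum verifies the serialized bag itself.

From the library, the same flows are
`fairbag.parse_manifest` / `summarize` / `plan_products`,
`rows_to_holey_bag` / `partition_and_bag`, `materialize_recursive`,
`Registry.mint` / `resolve` / `verify_content`, `assess_bag`, and
`intersect_catalog`.

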