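"""Fetch planning, verified downloads, recursive bag-of-bags expansion."""

from __future__ import annotations

import hashlib
from pathlib import Path

import pytest

from fairbag.bag import (
    RemoteReference,
    add_remote_reference,
    create_bag,
    validate_bag,
    write_bag,
)
from fairbag.fixtures import generate_footprint_bag_tree, tamper
from fairbag.materialize import (
    fetch_all,
    is_identifier_locator,
    materialize_recursive,
    plan_fetch,
)
from fairbag.registry import Registry
from fairbag.ro import Agent, build_manifest


def md5(data: bytes) -> str:
    return hashlib.md5(data).hexdigest()


@pytest.fixture
def store(tmp_path):
    """Three payload files served over file:// URLs."""
    d = tmp_path / "store"
    d.mkdir()
    files = {}
    for name in ("one.fastq", "two.fastq", "three.fastq"):
        data = f"@read-{name}\nACGT\n".encode() * 10
        (d / name).write_bytes(data)
        files[name] = data
    return d, files


def make_holey(tmp_path, store, now, name="holey") -> object:
    d, files = store
    root = tmp_path / name
    root.mkdir()
    bag = create_bag(root, now=now)
    for fname, data in sorted(files.items()):
        add_remote_reference(
            bag,
            RemoteReference((d / fname).resolve().as_uri(), len(data), f"data/{fname}"),
            {"md5": md5(data)},
        )
    write_bag(bag, layout="directory")
    return bag


class TestLocatorClassification:
    @pytest.mark.parametrize(
        "locator,expected",
        [
            ("minid:b9q119", True),
            ("ark:abc123", True),
            ("https://example.org/f", False),
            ("file:///store/f", False),
            ("not a locator", False),
        ],
    )
    def test_identifier_vs_url(self, locator, expected):
        assert is_identifier_locator(locator) is expected


class TestPlan:
    def test_plan_enumerates_all_missing_entries(self, tmp_path, store, now):
        bag = make_holey(tmp_path, store, now)
        plan = plan_fetch(bag)
        assert len(plan.entries) == 3

    def test_curie_resolves_to_locations_in_registry_order(
        self, tmp_path, store, registry, now
    ):
        d, files = store
        record = registry.mint(
            content=d / "one.fastq",
            locations=["file:///mirror/one", (d / "one.fastq").resolve().as_uri()],
        )
        root = tmp_path / "viaminid"
        root.mkdir()
        bag = create_bag(root, now=now)
        add_remote_reference(
            bag,
            RemoteReference(record.curie, len(files["one.fastq"]), "data/one.fastq"),
            {"md5": md5(files["one.fastq"])},
        )
        plan = plan_fetch(bag, registry)
        assert plan.entries[0].candidates == record.locations
        # the landing record's own checksum joins the expected digests
        assert plan.entries[0].expected_digests["sha256"] == record.checksum[1]

    def test_selector_restricts_plan(self, tmp_path, store, now):
        bag = make_holey(tmp_path, store, now)
        plan = plan_fetch(bag, selector="data/one*")
        assert [e.ref.target_path for e in plan.entries] == ["data/one.fastq"]

    def test_unresolvable_curie_recorded_not_fatal(self, tmp_path, store, registry, now):
        root = tmp_path / "bad"
        root.mkdir()
        bag = create_bag(root, now=now)
        add_remote_reference(
            bag, RemoteReference("minid:zzzzzz", 5, "data/gone"), {"md5": "0" * 32}
        )
        plan = plan_fetch(bag, registry)
        assert plan.entries[0].candidates == []
        assert "unresolvable" in plan.entries[0].note


class TestFetch:
    def test_full_materialization_ends_valid_and_complete(self, tmp_path, store, now):
        bag = make_holey(tmp_path, store, now)
        result = fetch_all(plan_fetch(bag), retry_delay=0)
        assert result.outcome_counts() == {"fetched-verified": 3}
        report = validate_bag(bag, mode="full")
        assert report.valid and report.complete

    def test_fallback_to_second_location_on_corrupt_first(
        self, tmp_path, store, registry, now
    ):
        d, files = store
        bad = tmp_path / "bad-copy.fastq"
        bad.write_bytes(files["one.fastq"][:-1] + b"X")
        good_url = (d / "one.fastq").resolve().as_uri()
        record = registry.mint(
            content=d / "one.fastq",
            locations=[bad.resolve().as_uri(), good_url],
        )
        root = tmp_path / "fallback"
        root.mkdir()
        bag = create_bag(root, now=now)
        add_remote_reference(
            bag,
            RemoteReference(record.curie, len(files["one.fastq"]), "data/one.fastq"),
            {"md5": md5(files["one.fastq"])},
        )
        result = fetch_all(plan_fetch(bag, registry), retry_delay=0)
        entry = result.entries[0]
        assert entry.outcome == "fetched-verified"
        assert entry.chosen_url == good_url

    def test_length_mismatch_not_placed(self, tmp_path, store, now):
        d, files = store
        root = tmp_path / "short"
        root.mkdir()
        bag = create_bag(root, now=now)
        data = files["one.fastq"]
        add_remote_reference(
            bag,
            RemoteReference((d / "one.fastq").resolve().as_uri(), len(data) + 1, "data/one.fastq"),
            {"md5": md5(data)},
        )
        result = fetch_all(plan_fetch(bag), retry_delay=0)
        assert result.entries[0].outcome == "fetched-corrupt"
        assert not (root / "data" / "one.fastq").exists()

    def test_corrupt_download_quarantined_by_digest(self, tmp_path, store, now):
        d, files = store
        root = tmp_path / "quarantine"
        root.mkdir()
        bag = create_bag(root, now=now)
        add_remote_reference(
            bag,
            RemoteReference(
                (d / "one.fastq").resolve().as_uri(),
                len(files["one.fastq"]),
                "data/one.fastq",
            ),
            {"md5": "0" * 32},
        )
        fetch_all(plan_fetch(bag), retry_delay=0)
        quarantined = list((root / "quarantine").iterdir())
        assert len(quarantined) == 1
        assert quarantined[0].name == hashlib.sha256(files["one.fastq"]).hexdigest()

    def test_rerun_on_complete_bag_fetches_zero_bytes(self, tmp_path, store, now):
        bag = make_holey(tmp_path, store, now)
        first = fetch_all(plan_fetch(bag), retry_delay=0)
        assert first.bytes_fetched > 0
        second = fetch_all(plan_fetch(bag), retry_delay=0)
        assert second.bytes_fetched == 0
        assert all(e.outcome == "skipped" for e in second.entries)

    def test_unavailable_url(self, tmp_path, now):
        root = tmp_path / "nowhere"
        root.mkdir()
        bag = create_bag(root, now=now)
        add_remote_reference(
            bag,
            RemoteReference("file:///does/not/exist", 5, "data/x"),
            {"md5": "0" * 32},
        )
        result = fetch_all(plan_fetch(bag), retries=1, retry_delay=0)
        assert result.entries[0].outcome == "unavailable"
        # the bag stays holey but structurally valid
        report = validate_bag(bag, mode="structural")
        assert report.structural_ok and not report.complete

    def test_materialized_manifests_equal_local_creation(self, tmp_path, store, now):
        """Digest-level equivalence: fetching content reproduces the payload
        manifests a locally created bag of the same files would have."""
        d, files = store
        bag = make_holey(tmp_path, store, now)
        fetch_all(plan_fetch(bag), retry_delay=0)
        local_src = tmp_path / "local"
        local_src.mkdir()
        for fname, data in files.items():
            (local_src / fname).write_bytes(data)
        local = create_bag(local_src, algorithms=["md5"], now=now)
        remote_md5 = {e.path: e.digests["md5"] for e in bag.payload}
        local_md5 = {e.path: e.digests["md5"] for e in local.payload}
        assert remote_md5 == local_md5


class TestRecursive:
    @pytest.fixture
    def bag_of_bags(self, tmp_path, registry, now):
        outer, record = generate_footprint_bag_tree(
            tmp_path / "tree",
            registry,
            tissues=["adrenal gland", "stomach", "urinary bladder"],
            seeds=[16],
            methods=["hint"],
            seed=3,
            now=now,
        )
        return outer, record

    def test_inner_bags_all_expand_and_validate(self, bag_of_bags, registry):
        outer, _ = bag_of_bags
        node = materialize_recursive(outer, registry, max_depth=2, retry_delay=0)
        assert node.validation.valid
        assert len(node.children) == 3
        assert all(c.expanded and c.validation.valid for c in node.children)
        assert node.all_valid

    def test_depth_one_fetches_but_does_not_expand(self, bag_of_bags, registry):
        outer, _ = bag_of_bags
        node = materialize_recursive(outer, registry, max_depth=1, retry_delay=0)
        assert node.validation.valid and node.validation.complete
        assert len(node.children) == 3
        assert all(not c.expanded for c in node.children)

    def test_tampered_inner_bag_isolated(self, tmp_path, registry, now):
        # build an inner bag whose payload was corrupted before archiving, so
        # the archive digest verifies but the inner bag's own fixity fails
        inner_root = tmp_path / "inner-bad"
        inner_root.mkdir()
        (inner_root / "x.bed").write_text("chr1\t0\t10\thint\t.\n")
        bad = create_bag(inner_root, now=now)
        tamper(inner_root / "data" / "x.bed", 0)
        archive = write_bag(bad, layout="zip")
        bad_record = registry.mint(
            content=archive,
            locations=[archive.resolve().as_uri()],
            now=now,
            extra={"content-type": "bag+zip"},
        )

        good_root = tmp_path / "inner-good"
        good_root.mkdir()
        (good_root / "y.bed").write_text("chr1\t5\t15\thint\t.\n")
        good = create_bag(good_root, now=now)
        good_archive = write_bag(good, layout="zip")
        good_record = registry.mint(
            content=good_archive,
            locations=[good_archive.resolve().as_uri()],
            now=now,
            extra={"content-type": "bag+zip"},
        )

        outer_root = tmp_path / "outer"
        outer_root.mkdir()
        outer = create_bag(outer_root, now=now)
        for name, rec, arch in (
            ("bad", bad_record, archive),
            ("good", good_record, good_archive),
        ):
            add_remote_reference(
                outer,
                RemoteReference(rec.curie, arch.stat().st_size, f"data/{name}.zip"),
                {rec.checksum[0]: rec.checksum[1]},
            )
        write_bag(outer, layout="directory")

        node = materialize_recursive(outer, registry, max_depth=2, retry_delay=0)
        by_curie = {c.curie: c for c in node.children}
        assert not by_curie[bad_record.curie].validation.valid
        assert by_curie[bad_record.curie].validation.fixity_errors
        assert by_curie[good_record.curie].validation.valid
        assert not node.all_valid
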