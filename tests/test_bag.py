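"""Bag creation, serialization layouts, fetch.txt dialect, validation."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fairbag.bag import (
    Bag,
    RemoteReference,
    add_remote_reference,
    create_bag,
    format_fetch_line,
    parse_fetch_line,
    read_bag,
    validate_bag,
    write_bag,
)
from fairbag.errors import (
    BagParseError,
    ConfigurationError,
    ConflictError,
    InputError,
    NotABagError,
)
from fairbag.fixtures import tamper

from conftest import make_tree


class TestCreate:
    def test_three_file_bag_is_valid_and_complete(self, simple_bag):
        assert len(simple_bag.payload) == 3
        for entry in simple_bag.payload:
            assert set(entry.digests) == {"md5", "sha256"}
        report = validate_bag(simple_bag, mode="full")
        assert report.valid and report.complete and not report.fixity_errors

    def test_empty_directory_bag(self, tmp_path, now):
        src = tmp_path / "empty"
        src.mkdir()
        bag = create_bag(src, now=now)
        assert bag.payload == []
        assert bag.bag_info.get("Payload-Oxum") == "0.0"
        assert validate_bag(bag, mode="full").structural_ok

    def test_nested_hierarchy_preserved(self, simple_bag):
        assert "data/nested/c.txt" in [e.path for e in simple_bag.payload]

    def test_unreadable_tree_rejected(self, tmp_path):
        with pytest.raises(InputError):
            create_bag(tmp_path / "does-not-exist")

    def test_unsupported_algorithm_rejected(self, tmp_path):
        src = tmp_path / "src"
        src.mkdir()
        with pytest.raises(ConfigurationError):
            create_bag(src, algorithms=["crc32"])


class TestRemoteReferences:
    def test_add_remote_makes_bag_holey(self, simple_bag):
        add_remote_reference(
            simple_bag,
            RemoteReference("https://example.org/f1.fastq.gz", 1024, "data/f1.fastq.gz"),
            {"md5": "d" * 32},
        )
        write_bag(simple_bag, layout="directory")
        report = validate_bag(simple_bag, mode="full")
        assert simple_bag.is_holey
        assert report.structural_ok and not report.complete
        assert report.missing_entries == ["data/f1.fastq.gz"]

    def test_curie_locator_round_trips_through_fetch_txt(self, simple_bag):
        add_remote_reference(
            simple_bag,
            RemoteReference("minid:b9q119", 10, "data/inner.zip"),
            {"sha256": "e" * 64},
        )
        write_bag(simple_bag, layout="directory")
        line = (simple_bag.root / "fetch.txt").read_text().splitlines()[0]
        assert line.split(" ")[0] == "minid:b9q119"
        again = read_bag(simple_bag.root)
        assert again.remotes == simple_bag.remotes

    def test_reference_only_bag_is_kilobytes(self, tmp_path, now):
        src = tmp_path / "refs-only"
        src.mkdir()
        bag = create_bag(src, now=now)
        for i in range(10):
            add_remote_reference(
                bag,
                RemoteReference(
                    f"https://example.org/big{i}", 10**12, f"data/big{i}.bam"
                ),
                {"md5": f"{i:032x}"},
            )
        archive = write_bag(bag, layout="zip")
        # ten terabyte-scale references serialize to a few kB of tag files
        assert archive.stat().st_size < 16_384

    def test_duplicate_target_rejected(self, simple_bag):
        ref = RemoteReference("https://example.org/x", 1, "data/x")
        add_remote_reference(simple_bag, ref, {"md5": "a" * 32})
        with pytest.raises(ConflictError):
            add_remote_reference(simple_bag, ref, {"md5": "a" * 32})

    def test_reference_without_digest_rejected(self, simple_bag):
        with pytest.raises(InputError):
            add_remote_reference(
                simple_bag, RemoteReference("https://e.org/y", 1, "data/y"), {}
            )


class TestFetchDialect:
    @pytest.mark.parametrize(
        "ref",
        [
            RemoteReference("https://example.org/a", 10, "data/a"),
            RemoteReference("minid:abc123", None, "data/b.zip"),
            RemoteReference("file:///store/c", 0, "data/odd%name"),
        ],
    )
    def test_line_round_trip(self, ref):
        assert parse_fetch_line(format_fetch_line(ref)) == ref

    def test_unknown_length_dash(self):
        ref = parse_fetch_line("https://e.org/x - data/x", 1)
        assert ref.length_bytes is None

    @pytest.mark.parametrize("bad", ["onlyonefield", "url notanumber data/x", "a b"])
    def test_malformed_line_names_lineno(self, bad):
        with pytest.raises(BagParseError, match="line 7"):
            parse_fetch_line(bad, 7)


class TestSerialization:
    @pytest.mark.parametrize("layout", ["directory", "zip", "tgz"])
    def test_round_trip_each_layout(self, simple_bag, tmp_path, layout):
        loc = write_bag(simple_bag, layout=layout)
        again = read_bag(loc, extract_to=tmp_path / f"x-{layout}")
        assert again == simple_bag
        assert validate_bag(again, mode="full").valid

    def test_fetch_txt_line_count(self, simple_bag):
        add_remote_reference(
            simple_bag,
            RemoteReference("https://e.org/one", 5, "data/one"),
            {"md5": "b" * 32},
        )
        write_bag(simple_bag, layout="directory")
        lines = (simple_bag.root / "fetch.txt").read_text().splitlines()
        assert len(lines) == 1

    def test_archive_has_single_top_level_dir(self, simple_bag, tmp_path):
        import zipfile

        archive = write_bag(simple_bag, layout="zip")
        with zipfile.ZipFile(archive) as zf:
            tops = {name.split("/")[0] for name in zf.namelist()}
        assert tops == {simple_bag.root.name}

    def test_read_non_bag_directory(self, tmp_path):
        plain = tmp_path / "plain"
        plain.mkdir()
        (plain / "stuff.txt").write_text("x")
        with pytest.raises(NotABagError):
            read_bag(plain)

    def test_read_missing_manifests(self, tmp_path):
        fake = tmp_path / "fake"
        fake.mkdir()
        (fake / "bagit.txt").write_text("BagIt-Version: 1.0\n")
        with pytest.raises(NotABagError):
            read_bag(fake)


class TestValidation:
    def test_payload_tamper_yields_exactly_one_fixity_error_per_algorithm(self, simple_bag):
        target = simple_bag.root / "data" / "a.txt"
        tamper(target, 0)
        report = validate_bag(simple_bag, mode="full")
        paths = {(p, alg) for p, alg, _, _ in report.fixity_errors}
        assert paths == {("data/a.txt", "md5"), ("data/a.txt", "sha256")}

    def test_tag_file_tamper_detected(self, simple_bag):
        tamper(simple_bag.root / "bag-info.txt", 0)
        report = validate_bag(simple_bag, mode="full")
        assert any(p == "bag-info.txt" for p, _, _, _ in report.fixity_errors)

    def test_added_file_reported_extra(self, simple_bag):
        (simple_bag.root / "data" / "sneaky.txt").write_text("new")
        report = validate_bag(simple_bag, mode="full")
        assert report.extra_files == ["data/sneaky.txt"]
        assert not report.valid

    def test_deleted_file_reported_missing(self, simple_bag):
        (simple_bag.root / "data" / "b.txt").unlink()
        report = validate_bag(simple_bag, mode="full")
        assert "data/b.txt" in report.missing_entries
        assert not report.complete

    def test_oxum_counts_remote_lengths(self, simple_bag):
        local = sum(e.size_bytes for e in simple_bag.payload)
        add_remote_reference(
            simple_bag,
            RemoteReference("https://e.org/r", 500, "data/r"),
            {"md5": "c" * 32},
        )
        write_bag(simple_bag, layout="directory")
        assert simple_bag.bag_info.get("Payload-Oxum") == f"{local + 500}.4"
        assert validate_bag(simple_bag, mode="fast").oxum_ok

    def test_unknown_remote_length_makes_oxum_unverifiable(self, simple_bag):
        add_remote_reference(
            simple_bag,
            RemoteReference("https://e.org/r", None, "data/r"),
            {"md5": "c" * 32},
        )
        write_bag(simple_bag, layout="directory")
        report = validate_bag(simple_bag, mode="fast")
        assert not report.oxum_ok
        assert any("unknown length" in m for m in report.messages)

    def test_structural_mode_skips_digests(self, simple_bag):
        tamper(simple_bag.root / "data" / "a.txt", 0)
        assert validate_bag(simple_bag, mode="structural").fixity_errors == []


class TestProperties:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n_files=st.integers(0, 6))
    def test_random_tree_round_trip(self, tmp_path_factory, seed, n_files):
        root = tmp_path_factory.mktemp("prop") / "tree"
        make_tree(root, seed=seed, n_files=n_files)
        bag = create_bag(root)
        for layout in ("zip", "tgz"):
            loc = write_bag(bag, layout=layout)
            again = read_bag(loc)
            assert again == bag
            report = validate_bag(again, mode="full")
            assert report.valid and report.complete
        oxum = bag.payload_oxum()
        assert oxum == (sum(e.size_bytes for e in bag.payload), len(bag.payload))

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_any_single_byte_tamper_detected(self, tmp_path_factory, seed):
        import random

        root = tmp_path_factory.mktemp("fixity") / "tree"
        make_tree(root, seed=seed, n_files=3)
        bag = create_bag(root)
        rng = random.Random(seed)
        victim = rng.choice([e.path for e in bag.payload])
        offset = rng.randrange((bag.root / victim).stat().st_size)
        tamper(bag.root / victim, offset)
        report = validate_bag(bag, mode="full")
        assert any(p == victim for p, _, _, _ in report.fixity_errors)
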