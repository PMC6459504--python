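"""Shared fixtures: seeded file trees, a registry, a frozen clock."""

from __future__ import annotations

import random
from datetime import datetime, timezone
from pathlib import Path

import pytest

from fairbag.bag import create_bag
from fairbag.registry import Registry

FROZEN_NOW = datetime(2024, 1, 15, 12, 0, 0, tzinfo=timezone.utc)


@pytest.fixture
def now() -> datetime:
    return FROZEN_NOW


@pytest.fixture
def registry(tmp_path: Path) -> Registry:
    return Registry(tmp_path / "registry.jsonl", seed=42)


def make_tree(root: Path, seed: int = 0, n_files: int = 3, max_depth: int = 2) -> list[Path]:
    """Write a small random file tree (seeded) and return the files."""
    rng = random.Random(seed)
    root.mkdir(parents=True, exist_ok=True)
    files = []
    for i in range(n_files):
        depth = rng.randint(0, max_depth)
        d = root
        for level in range(depth):
            d = d / f"dir{level}{rng.randint(0, 2)}"
        d.mkdir(parents=True, exist_ok=True)
        f = d / f"file{i}.bin"
        f.write_bytes(rng.randbytes(rng.randint(16, 2048)))
        files.append(f)
    return files


@pytest.fixture
def tree_factory(tmp_path: Path):
    counter = iter(range(1000))

    def _make(seed: int = 0, n_files: int = 3):
        root = tmp_path / f"tree{next(counter)}"
        make_tree(root, seed=seed, n_files=n_files)
        return root

    return _make


@pytest.fixture
def simple_bag(tmp_path: Path, now):
    """A complete 3-file bag with md5+sha256 digests."""
    src = tmp_path / "simple"
    src.mkdir()
    (src / "a.txt").write_text("alpha\n")
    (src / "b.txt").write_text("beta\n")
    sub = src / "nested"
    sub.mkdir()
    (sub / "c.txt").write_text("gamma\n")
    return create_bag(src, info={"External-Description": "three files"}, now=now)
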