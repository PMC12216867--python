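"""Packaged data resources (parameter tables, printed network weights).

Every resource ships with a SHA-256 recorded in ``data/MANIFEST.sha256`` and is
verified on first load; a mismatch raises :class:`ResourceError` rather than
silently serving a corrupted table.
"""

from __future__ import annotations

import hashlib
import json
from functools import lru_cache
from importlib import resources as _ilr
from pathlib import Path

import pandas as pd


class ResourceError(RuntimeError):
    """A packaged data file is missing or fails its checksum."""


def _data_dir() -> Path:
    return Path(str(_ilr.files("carbotherm").joinpath("data")))


@lru_cache(maxsize=1)
def _manifest() -> dict[str, str]:
    path = _data_dir() / "MANIFEST.sha256"
    if not path.exists():
        raise ResourceError(f"checksum manifest missing: {path}")
    out: dict[str, str] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        digest, name = line.split(maxsplit=1)
        out[name.strip()] = digest
    return out


@lru_cache(maxsize=None)
def resource_path(name: str) -> Path:
    """Return the verified path of packaged resource *name*."""
    path = _data_dir() / name
    if not path.exists():
        raise ResourceError(f"packaged resource missing: {name}")
    expected = _manifest().get(name)
    if expected is None:
        raise ResourceError(f"resource {name!r} not listed in checksum manifest")
    actual = hashlib.sha256(path.read_bytes()).hexdigest()
    if actual != expected:
        raise ResourceError(
            f"checksum mismatch for {name!r}: expected {expected}, got {actual}"
        )
    return path


def load_csv(name: str) -> pd.DataFrame:
    return pd.read_csv(resource_path(name))


def load_json(name: str) -> dict:
    with open(resource_path(name)) as fh:
        return json.load(fh)
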