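"""Run manifest: records exactly what produced a set of outputs.

A manifest captures the tool version, a stable hash of the scenario config,
content hashes of every input file, the seed, timestamps and the list of
output files — enough to verify that a rerun used identical inputs.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .config import ScenarioConfig


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(
    config: ScenarioConfig,
    input_paths: dict[str, str | Path | None],
    output_paths: list[str | Path],
    seed: int | None = None,
) -> dict:
    return {
        "tool": "cardioroi",
        "version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "seed": seed if seed is not None else config.psa.seed,
        "config_hash": config.config_hash(),
        "inputs": {
            name: {"path": str(p), "sha256": file_sha256(p)}
            for name, p in input_paths.items()
            if p is not None
        },
        "outputs": [str(p) for p in output_paths],
    }


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
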