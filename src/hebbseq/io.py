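"""Serialization of runs: time-series tables, matrix archives, manifests.

Every CLI run writes a JSON manifest listing the emitted files with
their SHA-256 hashes, the configuration hash, the seed and the package
version, so that any output can be traced back to (and reproduced from)
its exact inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_outputs", "Manifest"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class Manifest:
    config_hash: str
    seed: int
    version: str
    files: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "version": self.version,
                "files": self.files,
            },
            indent=2,
            sort_keys=True,
        )


def write_outputs(
    record: dict,
    out_dir: str | Path,
    config_hash: str = "",
    seed: int = 0,
) -> Manifest:
    """Write a record of named outputs and return the manifest.

    ``record`` maps file stems to objects: DataFrames become TSV files,
    ndarrays (or dicts of ndarrays) become ``.npz`` archives, and plain
    dicts/lists become JSON.  The manifest itself is written as
    ``manifest.json``.  Identical records written with identical
    config/seed produce bit-identical files.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config_hash=config_hash, seed=seed, version=__version__)

    for stem, obj in record.items():
        if isinstance(obj, pd.DataFrame):
            path = out / f"{stem}.tsv"
            obj.to_csv(path, sep="\t", index=False, float_format="%.10g")
        elif isinstance(obj, np.ndarray):
            path = out / f"{stem}.npz"
            np.savez(path, **{stem: obj})
        elif isinstance(obj, dict) and obj and all(
            isinstance(v, np.ndarray) for v in obj.values()
        ):
            path = out / f"{stem}.npz"
            np.savez(path, **obj)
        else:
            path = out / f"{stem}.json"
            path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
        manifest.files[path.name] = _sha256(path)

    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
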