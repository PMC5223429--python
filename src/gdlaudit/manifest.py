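"""Reproducibility metadata emitted alongside every report."""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional


def _sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _sha256_texts(texts) -> str:
    h = hashlib.sha256()
    for text in texts:
        h.update(text.encode("utf-8"))
    return h.hexdigest()


@dataclass
class RunManifest:
    """What produced a report: tool version, input hashes, seed, timestamp.

    Identical inputs yield an identical manifest apart from ``timestamp``.
    """

    version: str
    seed: Optional[int]
    input_hashes: dict = field(default_factory=dict)
    guideline_checksum: str = ""
    timestamp: str = ""

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "input_hashes": self.input_hashes,
            "guideline_checksum": self.guideline_checksum,
            "timestamp": self.timestamp,
        }

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2) + "\n", encoding="utf-8"
        )


def build_manifest(inputs=(), guideline_texts=(), seed=None) -> RunManifest:
    from . import __version__

    return RunManifest(
        version=__version__,
        seed=seed,
        input_hashes={Path(p).name: _sha256_file(p) for p in inputs},
        guideline_checksum=_sha256_texts(sorted(guideline_texts)),
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
    )
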