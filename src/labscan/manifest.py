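"""Run manifests: a machine-readable record of every CLI invocation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

from . import __version__


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    command: str
    config: dict = dataclasses.field(default_factory=dict)
    inputs: dict = dataclasses.field(default_factory=dict)  # path -> sha256
    seed: int | None = None
    counts: dict = dataclasses.field(default_factory=dict)
    warnings: list = dataclasses.field(default_factory=list)
    version: str = __version__
    timestamp: str = ""

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = file_digest(path)

    def write(self, path: str | Path) -> None:
        self.timestamp = datetime.now(timezone.utc).isoformat()
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
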