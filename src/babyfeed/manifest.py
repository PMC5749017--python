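"""Run manifests: config digest, seed, paths, and pipeline stage counts."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path


def config_digest(config_dict: dict) -> str:
    canon = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


@dataclass
class RunManifest:
    command: str
    seed: "int | None"
    config_hash: str
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def write(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(
                {
                    "command": self.command,
                    "seed": self.seed,
                    "config_hash": self.config_hash,
                    "inputs": self.inputs,
                    "outputs": self.outputs,
                    "counts": self.counts,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
        return path
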