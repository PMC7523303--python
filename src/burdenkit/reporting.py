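"""Run manifests: provenance and conservation audit for pipeline runs."""

from __future__ import annotations

import datetime as _dt
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """What a run saw and produced: config hash, input/output digests, seed,
    per-stage row counts and before/after weight totals."""

    config_path: str
    config_digest: str
    seed: int | None
    version: str = __version__
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    stages: dict[str, dict] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    @classmethod
    def begin(cls, config_path: str | Path, seed: int | None) -> "RunManifest":
        return cls(
            config_path=str(config_path),
            config_digest=file_digest(config_path),
            seed=seed,
            started=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        )

    def add_input(self, path: str | Path) -> None:
        self.inputs[Path(path).name] = file_digest(path)

    def add_output(self, path: str | Path) -> None:
        self.outputs[Path(path).name] = file_digest(path)

    def add_stage(self, name: str, **fields) -> None:
        self.stages[name] = dict(fields)

    def finish(self) -> None:
        self.finished = _dt.datetime.now(_dt.timezone.utc).isoformat()

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config_path,
            "config_sha256": self.config_digest,
            "seed": self.seed,
            "inputs_sha256": dict(sorted(self.inputs.items())),
            "outputs_sha256": dict(sorted(self.outputs.items())),
            "stages": self.stages,
            "started": self.started,
            "finished": self.finished,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
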