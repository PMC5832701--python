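"""Run-reproducibility manifests.

Every CLI run writes exactly one ``manifest.json`` into its output
directory recording the tool version, command, seed, full parameter set
and SHA-256 hashes of the inputs, so deterministic stages can be
reproduced bitwise from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .flight import FlightParams
from .io import sha256_file

MANIFEST_NAME = "manifest.json"


@dataclass
class RunManifest:
    command: str
    seed: int | None
    params: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)   # path -> sha256
    version: str = __version__
    created: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.UTC).isoformat())

    @classmethod
    def create(cls, command: str, seed: int | None,
               params: FlightParams | None = None,
               extra_params: dict | None = None,
               input_paths: list | None = None) -> "RunManifest":
        p = {}
        if params is not None:
            p.update({k: getattr(params, k)
                      for k in FlightParams.__dataclass_fields__})
        if extra_params:
            p.update(extra_params)
        inputs = {str(x): sha256_file(x) for x in (input_paths or [])}
        return cls(command=command, seed=seed, params=p, inputs=inputs)

    def write(self, outdir) -> Path:
        path = Path(outdir) / MANIFEST_NAME
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                   sort_keys=True) + "\n")
        return path

    @classmethod
    def load(cls, path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(**data)
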