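"""Run configuration and seed discipline.

One global integer seed lives in :class:`RunConfig`.  Every stochastic stage
derives its own generator with :func:`derive_rng`, keyed by an operation name,
so re-running one stage never perturbs the random stream of another.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

log = logging.getLogger("pneumotyper")


def derive_rng(seed: int, operation: str) -> np.random.Generator:
    """Deterministic per-operation generator from the global seed.

    The operation name is hashed (CRC-32) into the seed sequence, so each
    named stage gets an independent, reproducible stream.
    """
    key = zlib.crc32(operation.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def derive_int_seed(seed: int, operation: str) -> int:
    """A single derived integer seed (< 2**31) for APIs that want one."""
    return int(derive_rng(seed, operation).integers(0, 2**31 - 1))


@dataclass
class RunConfig:
    """Global seed plus per-module parameter dictionaries.

    Identical configs produce identical outputs for every pipeline stage.
    Module parameter defaults live in the modules themselves; entries here
    override them.
    """

    seed: int = 0
    outdir: Path = Path("pneumotyper_out")
    params: dict[str, dict[str, Any]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        seed = int(raw.pop("seed", 0))
        outdir = Path(raw.pop("outdir", "pneumotyper_out"))
        params = {str(k): dict(v or {}) for k, v in raw.items()}
        return cls(seed=seed, outdir=outdir, params=params)

    def module_params(self, module: str, **overrides: Any) -> dict[str, Any]:
        merged = dict(self.params.get(module, {}))
        merged.update({k: v for k, v in overrides.items() if v is not None})
        return merged

    def to_dict(self) -> dict[str, Any]:
        return {"seed": self.seed, "outdir": str(self.outdir), **self.params}

    def echo(self, module: str) -> None:
        """Log the resolved configuration before a stage computes."""
        log.info("resolved config for %s: %s", module, self.to_dict())
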