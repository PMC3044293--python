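"""Run configuration: the tunable hyperparameters, JSON-serializable.

Defaults follow the package's standard operating point: a strong anchor on
the query profile (kappa0 = 10x the number of genes, resolved at run time),
a prior bicluster spread at half the background spread (f_bcl = 0.5) with
moderate weight (nu0 = 10), a per-cell complexity threshold of log 2, and a
1% prior gene-membership probability.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path


@dataclass
class RunConfig:
    """Hyperparameters and run controls for one biclustering run.

    ``kappa0 = None`` resolves to 10x the number of genes in the matrix;
    ``sigma_floor = None`` resolves to 1e-3 x the median background sigma.
    """

    f_bcl: float = 0.5
    kappa0: float | None = None
    nu0: float = 10.0
    log_penalty: float = math.log(2.0)
    p_gene: float = 0.01
    trim_fraction: float = 0.1
    sigma_floor: float | None = None
    max_iter: int = 100
    tol: float = 1e-6
    rng_seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")
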