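"""Run configuration: one flat record of every tunable in the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

from .errors import DomainError, InputFormatError


@dataclass
class RunConfig:
    """All pipeline parameters in one place.

    Paths may stay None when a stage is not used. Thresholds are validated
    on construction; see the individual modules for semantics.
    """

    network_path: str | None = None
    expression_path: str | None = None
    annotation_path: str | None = None
    dag_path: str | None = None
    output_dir: str = "."
    # DCB constraint
    gamma: float = 0.5
    epsilon: float = 0.5
    d_min: int = 3
    min_size: int = 3
    # merging
    member_overlap: float = 0.75
    subspace_overlap: float = 0.75
    # ranking
    n_samples: int = 2000
    seed: int = 0
    # evaluation
    p_threshold: float = 0.05
    deep_level: int = 7
    core_level: int = 3
    correction: str = "bh"

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise DomainError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.epsilon < 0:
            raise DomainError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.d_min < 1 or self.min_size < 2:
            raise DomainError("d_min must be >= 1 and min_size >= 2")
        for name in ("member_overlap", "subspace_overlap"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise DomainError(f"{name} must be in (0, 1], got {v}")
        if self.n_samples < 1:
            raise DomainError(f"n_samples must be >= 1, got {self.n_samples}")
        if self.seed < 0:
            raise DomainError(f"seed must be a non-negative integer, got {self.seed}")
        if not 0.0 < self.p_threshold < 1.0:
            raise DomainError(f"p_threshold must be in (0, 1), got {self.p_threshold}")
        if self.deep_level < 0 or self.core_level < 0:
            raise DomainError("deep_level and core_level must be >= 0")
        if self.correction not in ("bh", "bonferroni"):
            raise DomainError(f"unknown correction {self.correction!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat key=value file (``#`` comments and blank lines ok)."""
        path = Path(path)
        types = {f.name: f.type for f in fields(cls)}
        kwargs: dict = {}
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise InputFormatError(
                        f"{path}:{lineno}: expected key=value, got {line!r}"
                    )
                key, value = (s.strip() for s in line.split("=", 1))
                if key not in types:
                    raise InputFormatError(f"{path}:{lineno}: unknown key {key!r}")
                ann = str(types[key])
                if value.lower() in ("none", ""):
                    kwargs[key] = None
                elif "int" in ann:
                    kwargs[key] = int(value)
                elif "float" in ann:
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)
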