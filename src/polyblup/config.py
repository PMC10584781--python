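"""Run configuration: trait, matrix method, thresholds, seeds.

Loaded from YAML for the CLI; every output written by the CLI records the
seed so runs are reproducible end to end.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml

__all__ = ["RunConfig"]

_METHODS = ("A2", "A4", "A4w", "G2", "G4")


@dataclass
class RunConfig:
    trait: str = "trait"
    matrix_method: str = "A4"
    w: Optional[float] = None          # required for A4w; no baked-in default
    maf_threshold: float = 0.05
    cv_folds: int = 10
    cv_repeats: int = 10
    rng_seed: int = 0
    reml_tol: float = 1e-8
    reml_max_iter: int = 200
    blend: float = 0.01                # identity blend for G matrices
    kii_convention: str = "matrix"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.matrix_method not in _METHODS:
            raise ValueError(f"matrix_method must be one of {_METHODS}")
        if self.w is not None and not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")
        if not 0.0 <= self.maf_threshold <= 0.5:
            raise ValueError("maf_threshold must lie in [0, 0.5]")
        if self.cv_folds < 2 or self.cv_repeats < 1:
            raise ValueError("cv_folds >= 2 and cv_repeats >= 1 required")
        if self.reml_tol <= 0 or self.reml_max_iter < 1:
            raise ValueError("invalid REML tolerances")
        if self.kii_convention not in ("matrix", "one-plus-f"):
            raise ValueError("kii_convention must be 'matrix' or 'one-plus-f'")
        if self.matrix_method == "A4w" and self.w is None:
            raise ValueError("A4w requires an explicit double-reduction w")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        return cls(**kwargs, extra=extra)

    def to_dict(self) -> dict:
        return asdict(self)
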