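"""Flat key=value run configuration, losslessly serializable.

A :class:`RunConfig` bundles the model parameters, time grid, solver choice
and sampling options of one run.  The on-disk format is a plain text file of
``key = value`` lines (``#`` comments and blank lines ignored), so a run
manifest is itself a valid configuration file.  Floats are written with
``repr`` so a round trip through disk is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

from .model import ModelParams, TimeGrid

__all__ = ["RunConfig", "SOLVERS"]

SOLVERS = (
    "whe",
    "gpc_whe",
    "gpc_whe_gaussian_only",
    "em",
    "exact_path",
    "nested_mc",
)


@dataclass
class RunConfig:
    # model
    a0: float = 0.5
    a1: float = 0.0
    eps: float = 0.01
    lam: float = 0.0
    x0: float = 0.5
    # grid
    dt: float = 0.05
    t_end: float = 40.0
    # solver
    solver: str = "whe"
    convention: str = "coefficient"
    # sampling
    n_paths: int = 10_000
    dt_mc: float = 0.01
    n_param_draws: int = 200
    seed: int | None = None
    # bookkeeping
    output_dir: str = "."
    preset: str | None = None

    def __post_init__(self) -> None:
        if self.solver not in SOLVERS:
            raise ValueError(f"solver must be one of {SOLVERS}, got {self.solver!r}")

    def model_params(self) -> ModelParams:
        return ModelParams(a0=self.a0, a1=self.a1, eps=self.eps, lam=self.lam, x0=self.x0)

    def time_grid(self) -> TimeGrid:
        return TimeGrid.from_horizon(self.dt, self.t_end)

    # -- flat text round trip ------------------------------------------------

    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            lines.append(f"{f.name} = {v!r}" if isinstance(v, float) else f"{f.name} = {v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        known = {f.name: f for f in fields(cls)}
        kwargs = {}
        for ln, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {ln}: expected 'key = value', got {raw!r}")
            key, val = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ValueError(f"line {ln}: unknown configuration key {key!r}")
            kwargs[key] = _coerce(key, val)
        return cls(**kwargs)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_text(), encoding="utf-8", newline="\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_text(Path(path).read_text(encoding="utf-8"))


_INT_KEYS = {"n_paths", "n_param_draws", "seed"}
_STR_KEYS = {"solver", "convention", "output_dir", "preset"}


def _coerce(key: str, val: str):
    if key in _STR_KEYS:
        return val
    if key in _INT_KEYS:
        return int(val)
    return float(val)
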