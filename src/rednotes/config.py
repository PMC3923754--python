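"""Run configuration, seeding, and reproducibility plumbing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "write_meta", "corpus_hash", "derive_seed"]


@dataclass
class RunConfig:
    """All pipeline defaults in one validated bundle.

    Notable defaults: the redundancy detector uses token 8-grams with a
    winnowing window of 4 and flags shared runs of at least 10 tokens; test
    notes must have a copied fraction of at most 0.15 to count as
    non-redundant; samplers run 2000 sweeps over 50 topics.
    """

    # fingerprinting
    k: int = 8
    window: int = 4
    min_span: int = 10
    # held-out certification
    max_test_redundancy: float = 0.15
    n_test_records: int = 0
    # sampler
    n_topics: int = 50
    n_iterations: int = 2000
    alpha: float | None = None
    beta: float = 0.01
    delta: float = 0.1
    # evaluation
    top_m: int = 20
    n_fold_iterations: int = 50
    runs: int = 3
    # reproducibility
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.min_span < self.k:
            raise ValueError("min_span must be >= k")
        if not (0.0 <= self.max_test_redundancy <= 1.0):
            raise ValueError("max_test_redundancy must be in [0, 1]")
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not (0.0 < self.delta < 1.0):
            raise ValueError("delta must lie strictly in (0, 1)")
        if self.top_m < 2:
            raise ValueError("top_m must be >= 2")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load YAML config (optional) and apply non-None keyword overrides."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    for key, val in overrides.items():
        if val is not None:
            data[key] = val
    return RunConfig.from_dict(data)


def derive_seed(seed: int, *indices: int) -> int:
    """Deterministic sub-seed below 2**31 from a base seed and indices."""
    h = hashlib.sha256(("/".join(map(str, (seed, *indices)))).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def corpus_hash(path: str | Path) -> str:
    """Stable content hash of an input file (first 16 hex chars)."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_meta(out_dir: str | Path, config: RunConfig, **extra) -> None:
    """Drop a ``meta.json`` snapshot (config, seed, input hashes) in out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"config": config.to_dict(), **extra}
    (out_dir / "meta.json").write_text(json.dumps(meta, indent=2), encoding="utf-8")
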