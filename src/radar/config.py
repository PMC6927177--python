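"""Run configuration with a flat ``key = value`` file format."""

from __future__ import annotations

from dataclasses import dataclass, fields, asdict
from pathlib import Path


@dataclass
class RunConfig:
    """Pipeline thresholds and optimizer settings.

    Defaults: 50-nt bins, mean-raw-IP filter at 15 reads, IP-depletion
    filter at mean enrichment 1.0, top 1% of bins for IP size factors,
    BH FDR cutoff 10%.
    """

    bin_size: int = 50
    min_ip: float = 15.0
    min_enrichment: float = 1.0
    top_frac: float = 0.01
    fdr_cutoff: float = 0.1
    strandness: str = "none"
    paired_end: bool = False
    min_mapq: int = 0
    tol: float = 1e-8
    max_iter: int = 1000
    keep_nonconverged: bool = False
    seed: int = 1

    def validate(self) -> None:
        if self.bin_size < 10:
            raise ValueError(f"bin_size must be >= 10, got {self.bin_size}")
        if self.min_ip < 0:
            raise ValueError("min_ip must be non-negative")
        if not 0 < self.top_frac <= 0.1:
            raise ValueError("top_frac must be in (0, 0.1]")
        if not 0 < self.fdr_cutoff < 1:
            raise ValueError("fdr_cutoff must be in (0, 1)")
        if self.strandness not in ("none", "forward", "reverse"):
            raise ValueError(f"invalid strandness {self.strandness!r}")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("invalid optimizer settings")

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            t = types[key]
            if t in ("bool", bool):
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif t in ("int", int):
                kwargs[key] = int(val)
            elif t in ("float", float):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def as_dict(self) -> dict:
        return asdict(self)
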