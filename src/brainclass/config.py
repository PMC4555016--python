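"""Run configuration: a single YAML file driving the whole pipeline.

CLI flags override file values; a config is validated before any image
is read so mistakes fail fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .crossval import ParamGrid
from .images import canonical_channel


def parse_fwhm_grid(text: str) -> tuple[float | None, ...]:
    """Parse a comma-separated FWHM list; 'none'/'0' means no smoothing."""
    out: list[float | None] = []
    for tok in str(text).split(","):
        tok = tok.strip().lower()
        if not tok:
            continue
        if tok in ("none", "0"):
            out.append(None)
        else:
            val = float(tok)
            if val <= 0:
                raise ValueError(f"FWHM values must be positive, got {tok!r}")
            out.append(val)
    if not out:
        raise ValueError("empty FWHM grid")
    return tuple(out)


def parse_tissues(text: str) -> tuple[str, ...]:
    tissues = tuple(canonical_channel(t) for t in str(text).split(",") if t.strip())
    if not tissues:
        raise ValueError("empty tissue grid")
    return tissues


@dataclass
class RunConfig:
    """Validated configuration for an end-to-end pipeline run."""

    table: Path
    out_dir: Path
    k: int = 20
    tissues: tuple[str, ...] = ("WB", "GM", "WM")
    fwhms: tuple[float | None, ...] = (None, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0)
    max_components: int | None = None
    seed: int = 0
    refit: str = "full"
    C: float = 1.0
    threshold: float = 0.5
    covariates: tuple[str, ...] = ()
    positive_label: int | str | None = None
    label_map: dict | None = None

    def __post_init__(self) -> None:
        self.table = Path(self.table)
        self.out_dir = Path(self.out_dir)
        if self.k < 2:
            raise ValueError("k must be >= 2")
        self.tissues = tuple(canonical_channel(t) for t in self.tissues)
        if not self.tissues or not self.fwhms:
            raise ValueError("parameter grids must be nonempty")
        if self.refit not in ("full", "half"):
            raise ValueError("refit must be 'full' or 'half'")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        if self.label_map is not None and len(set(self.label_map.values())) != 2:
            raise ValueError("label_map must code exactly two classes")

    @property
    def grid(self) -> ParamGrid:
        return ParamGrid(tissues=self.tissues, fwhms=self.fwhms,
                         max_components=self.max_components)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "fwhms" in raw and isinstance(raw["fwhms"], str):
            raw["fwhms"] = parse_fwhm_grid(raw["fwhms"])
        if "tissues" in raw and isinstance(raw["tissues"], str):
            raw["tissues"] = parse_tissues(raw["tissues"])
        if "covariates" in raw and isinstance(raw["covariates"], str):
            raw["covariates"] = tuple(
                c.strip() for c in raw["covariates"].split(",") if c.strip())
        return cls(**raw)
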