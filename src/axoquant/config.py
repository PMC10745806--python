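"""Pipeline configuration: every numeric constant in one place.

The config file is flat ``key = value`` text (``#`` comments allowed);
command-line flags override file values, which override the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    width_um: float = 25.0            # straightened band width
    min_collateral_um: float = 0.5    # strict minimum collateral length
    band_um: float = 5.0              # excised shaft band width
    bin_px: int = 4                   # transverse bin width in pixels
    dorsal_extent_um: float = 70.0    # dorsal/ventral boundary
    q: float = 0.05                   # FDR level
    fdr_method: str = "bky"           # 'bky' | 'bh'
    threshold_method: str = "otsu"    # 'otsu' | 'fixed'
    threshold_value: float | None = None
    pixel_size_x: float | None = None  # metadata override, µm/px
    pixel_size_y: float | None = None
    z_step: float | None = None
    trace_units: str = "px"           # 'px' | 'um'
    seed: int = 0

    def __post_init__(self):
        for name in ("width_um", "min_collateral_um", "band_um",
                     "dorsal_extent_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.bin_px < 1:
            raise ValueError("bin_px must be >= 1")
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")
        if self.band_um >= self.width_um:
            raise ValueError("band_um must be smaller than width_um")


def load_config(path=None, **overrides) -> PipelineConfig:
    """Build a config from an optional key=value file plus overrides.

    Overrides with value ``None`` are ignored so CLI flags can be passed
    through unconditionally.
    """
    values = {}
    if path is not None:
        text = Path(path).read_text()
        known = {f.name: f for f in fields(PipelineConfig)}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, _, val = (s.strip() for s in line.partition("="))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            values[key] = _coerce(val, known[key].type)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**values)


def _coerce(val: str, annotation: str):
    if val.lower() in ("none", ""):
        return None
    for caster in (int, float):
        name = caster.__name__
        if annotation == name or annotation.startswith(f"{name} "):
            return caster(val)
    if "float" in str(annotation):
        return float(val)
    return val
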