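"""Pipeline configuration with flat key=value file support."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path


@dataclass
class PipelineConfig:
    # tolerance iteration grids (ppm)
    carbon_grid: tuple[float, ...] = (0.2, 0.35, 0.5)
    nitrogen_grid: tuple[float, ...] = (0.3, 0.55, 0.8)
    # data-quality gate
    quality_threshold: float = 0.3
    # linking
    unmatched_penalty: float = 0.2
    # candidate domains / pentapeptides
    max_candidates: int = 12
    fragment_floor: float = 1e-8
    # belief propagation (damping/strength calibrated on clean synthetic runs)
    bp_max_iters: int = 300
    bp_damping: float = 0.3
    bp_message_tol: float = 1e-6
    link_strength: float = 50.0
    exclusion_penalty: float = 1e-3
    # assignment iteration
    max_rounds: int = 5
    offset_confidence: float = 0.85
    offset_min_atoms: int = 5
    offset_report_floor: float = 0.1
    # reporting / evaluation
    probability_cutoff: float = 0.6
    sidechain_cutoff: float = 0.5
    match_tol_carbon: float = 0.3
    match_tol_nitrogen: float = 0.5

    def validate(self) -> None:
        for grid in (self.carbon_grid, self.nitrogen_grid):
            if not grid or any(g <= 0 for g in grid):
                raise ValueError("tolerance grids must be positive and non-empty")
            if list(grid) != sorted(set(grid)):
                raise ValueError("tolerance grids must be strictly increasing")
        if not 0.0 <= self.probability_cutoff <= 1.0:
            raise ValueError("probability cutoff must be in [0, 1]")


def load_config(path) -> PipelineConfig:
    """Read a flat ``key = value`` file; unknown keys raise."""
    cfg = PipelineConfig()
    valid = {f.name: f.type for f in fields(PipelineConfig)}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#")[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key = value")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in valid:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        current = getattr(cfg, key)
        if isinstance(current, tuple):
            setattr(cfg, key, tuple(float(v) for v in value.replace(",", " ").split()))
        elif isinstance(current, bool):
            setattr(cfg, key, value.lower() in ("1", "true", "yes"))
        elif isinstance(current, int):
            setattr(cfg, key, int(value))
        else:
            setattr(cfg, key, float(value))
    cfg.validate()
    return cfg
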