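"""Analysis configuration.

All tunable thresholds of the CCFD quantification pipeline live here so a
run is fully described by one config object (serializable to/from YAML).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline parameters for CCFD grid-box quantification.

    Parameters
    ----------
    box_px
        Side of a grid box in pixels. 74 px at 12 µm/px is roughly
        0.9 x 0.9 mm (0.81 mm^2).
    max_invalid_frac
        A box is excluded when *more than* this fraction of its area is
        unavailable (masked, low-signal or registration-cropped).
    low_signal_db
        Margin above the median background signal (in dB, power convention
        10*log10) below which a pixel counts as low-signal.
    mdc_pct
        Minimal detectable change for a single grid box, in CCFD
        percentage points; changes with |delta| strictly above this are
        treated as real rather than test-retest variability.
    min_deficit_diam_um
        Flow-deficit components with equivalent circular diameter below
        this are removed (physiological intercapillary distance).
    gamma_grid
        Candidate exponents for attenuation compensation, evaluated
        exhaustively; ties resolve toward the smaller gamma.
    smooth_kernel_px, smooth_sigma
        Gaussian pre-filter applied to the sub-RPE reference slab before
        gamma optimization (stabilizes the objective against
        high-frequency noise).
    search_radius_px
        Half-width of the translation search window for registration.
    rng_seed
        Seed for any stochastic step (the quantification itself is
        deterministic; the seed feeds synthetic-data generation).
    """

    box_px: int = 74
    max_invalid_frac: float = 0.25
    low_signal_db: float = 5.0
    mdc_pct: float = 5.0
    min_deficit_diam_um: float = 24.0
    gamma_grid: tuple[float, ...] = tuple(np.round(np.arange(0.0, 5.0 + 1e-9, 0.1), 10))
    smooth_kernel_px: int = 13
    smooth_sigma: float = 15.0
    search_radius_px: int = 32
    min_eligible_px: int = 100
    zncc_min_peak: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("box_px", "low_signal_db", "mdc_pct", "min_deficit_diam_um",
                     "smooth_kernel_px", "smooth_sigma", "search_radius_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.max_invalid_frac <= 1.0):
            raise ValueError("max_invalid_frac must lie in [0, 1]")
        grid = tuple(float(g) for g in self.gamma_grid)
        if len(grid) == 0:
            raise ValueError("gamma_grid must be nonempty")
        if any(b < a for a, b in zip(grid, grid[1:])):
            raise ValueError("gamma_grid must be sorted ascending")
        if any(g < 0 for g in grid):
            raise ValueError("gamma values must be >= 0")
        object.__setattr__(self, "gamma_grid", grid)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["gamma_grid"] = [float(g) for g in self.gamma_grid]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "gamma_grid" in data:
            data["gamma_grid"] = tuple(data["gamma_grid"])
        return cls(**data)
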