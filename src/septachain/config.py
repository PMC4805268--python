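"""Parameter blocks and run configuration.

Every tunable of the analysis lives here as a pydantic model with the
package-wide default, so a single YAML/JSON file can drive an end-to-end
run. Unknown keys are rejected (``extra="forbid"``) to catch typos in
user configs early.

All length-like parameters are in micrometres; intensities are in the
arbitrary units of the camera (no rescaling is ever applied).
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ChainParams(_Block):
    """Chain segmentation and axis tracing (phase-contrast channel)."""

    threshold_method: Literal["otsu", "fixed"] = "otsu"
    fixed_threshold: Optional[float] = None
    smooth_um: float = 0.1  # Gaussian pre-smoothing of phase before thresholding
    dark_cells: bool = True  # phase-contrast polarity: cells darker than background
    min_area_um2: float = 1.0
    border_policy: Literal["exclude", "keep"] = "exclude"
    prune_um: float = 0.5
    smooth_window: int = 5


class StraightenParams(_Block):
    band_um: float = 1.6
    avg_rows: int = 3


class SeptumParams(_Block):
    min_prominence_frac: float = 0.15
    min_cell_length_um: float = 1.0
    pole_margin_um: float = 0.25
    profile_smooth_um: float = 0.1  # Gaussian smoothing of the profile before peak finding


class MetricsParams(_Block):
    # box_width_um=None -> chain mean diameter + 0.3 um, decided per chain
    box_width_um: Optional[float] = None
    background: Optional[float] = None  # None -> modal intensity of the frame
    subtract_background: bool = True
    histogram_bins: int = 40


class NucParams(_Block):
    smooth_sigma_um: float = 0.1
    min_separation_um: float = 0.5
    min_peak_frac: float = 0.2
    sampling_diameter_um: float = 0.66


class FixtureParams(_Block):
    """Synthetic ground-truthed image generation.

    Defaults mirror a typical widefield setup for chain-forming bacilli:
    0.066 um/px camera sampling, 1.0 um rod diameter, 3 um cells, septum
    signal 1.5x the lateral membrane signal, and read noise giving an
    amplitude signal-to-noise ratio near 10.
    """

    pixel_size: float = 0.066
    n_chains: int = 5
    cells_per_chain: int | tuple[int, int] = (2, 6)  # fixed, or inclusive uniform range
    cell_length_um: float = 3.0
    diameter_um: float = 1.0
    septum_contrast: float = 1.5  # septum amplitude / lateral membrane amplitude
    membrane_amplitude: float = 150.0
    blur_sigma_um: float = 0.1
    background: float = 100.0
    phase_background: float = 200.0
    phase_cell_level: float = 80.0
    dapi_amplitude: float = 400.0
    dapi_sigma_um: float = 0.15
    mixing_fraction: float = 0.5
    reporter_low: float = 80.0  # mixture-component mean amplitude above background
    reporter_high: float = 400.0
    reporter_low_sd: float = 8.0   # cell-to-cell spread within each component
    reporter_high_sd: float = 40.0
    noise_sigma: float = 15.0
    clearance_px: float = 4.0
    seed: int = 0


class RunConfig(_Block):
    """Top-level configuration for pipeline runs."""

    input: Optional[str] = None  # TIFF path; None -> generate a fixture
    channel_map: dict[str, int] = Field(default_factory=dict)
    pixel_size: Optional[float] = None
    edits: Optional[str] = None  # CSV of manual septum corrections
    output_dir: str = "septachain_out"
    seed: int = 0

    chain: ChainParams = Field(default_factory=ChainParams)
    straighten: StraightenParams = Field(default_factory=StraightenParams)
    septum: SeptumParams = Field(default_factory=SeptumParams)
    metrics: MetricsParams = Field(default_factory=MetricsParams)
    nuc: NucParams = Field(default_factory=NucParams)
    fixture: FixtureParams = Field(default_factory=FixtureParams)

    @field_validator("channel_map")
    @classmethod
    def _roles_known(cls, v: dict[str, int]) -> dict[str, int]:
        allowed = {"phase", "membrane", "dapi", "reporter"}
        bad = set(v) - allowed
        if bad:
            raise ValueError(f"unknown channel roles: {sorted(bad)}")
        return v


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON — YAML superset) run config."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)
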