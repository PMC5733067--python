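"""Pipeline configuration: validated settings for every stage, YAML-backed."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .preprocess import DEFAULT_SPECTRAL_RULES
from .tfr import BASELINE_WINDOW, BandWindow, default_band_windows

__all__ = ["PipelineConfig", "demo_config"]


@dataclass
class PipelineConfig:
    """Everything a full pipeline run needs, serializable to YAML.

    The scenario block configures the synthetic study (or is ignored when
    ``input_path`` points at recorded data); the analysis blocks mirror the
    processing stages.  ``contrasts`` selects which subject-level
    comparisons are tested: any of ``"A>bsl"``, ``"B>bsl"``, ``"A>B"`` with
    A/B the two condition names.
    """

    # synthetic scenario (used when input_path is None)
    scenario: dict = field(default_factory=dict)
    input_path: str | None = None

    # preprocessing
    amp_limit_uv: float = 100.0
    spectral_rules: list = field(default_factory=lambda: list(DEFAULT_SPECTRAL_RULES))
    reject: bool = True

    # forward model
    sphere_radius_mm: float = 90.0
    grid_radius_mm: float = 75.0
    grid_spacing_mm: float = 15.0
    n_channels: int = 128

    # inverse
    gamma: float = 1.0
    snr: float = 3.0

    # time-frequency
    bands: list[BandWindow] = field(default_factory=default_band_windows)
    baseline_window: tuple[float, float] = BASELINE_WINDOW
    orientation_rule: str = "dominant-svd"

    # statistics
    contrasts: list[str] = field(default_factory=lambda: ["A>B"])
    n_perm: int = 5000
    two_sided: bool = True
    perm_method: str = "auto"

    # reproducibility / outputs
    seed: int = 0
    out_dir: str = "sourcetf_out"

    def validate(self) -> None:
        for bw in self.bands:
            if not (bw.f_lo < bw.f_hi and bw.t_lo_ms < bw.t_hi_ms):
                raise ValueError(f"malformed band/window {bw.name}")
        if self.baseline_window[0] >= self.baseline_window[1]:
            raise ValueError("malformed baseline window")
        if self.grid_spacing_mm <= 0 or self.grid_radius_mm <= 0:
            raise ValueError("grid geometry must be positive")
        if self.grid_radius_mm >= self.sphere_radius_mm:
            raise ValueError("grid must lie strictly inside the head sphere")
        for c in self.contrasts:
            if c not in ("A>bsl", "B>bsl", "A>B"):
                raise ValueError(f"unknown contrast {c!r}")

    # -- YAML round trip ---------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["bands"] = [asdict(b) for b in self.bands]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "bands" in d:
            d["bands"] = [BandWindow(**b) for b in d["bands"]]
        if "baseline_window" in d:
            d["baseline_window"] = tuple(d["baseline_window"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def demo_config(seed: int = 0, out_dir: str = "sourcetf_out") -> PipelineConfig:
    """A desk-scale demonstration configuration.

    A reduced montage, coarse grid and small subject/trial counts keep the
    full pipeline (simulate -> preprocess -> inverse -> six band/window
    source maps -> permutation statistics) to well under a minute while
    exercising every stage; the analysis table itself is the standard
    six-cell default.
    """
    cfg = PipelineConfig(
        scenario={
            "n_subjects": 6,
            "n_trials": 12,
            "srate": 128.0,
            "n_background": 10,
            "background_amplitude": 5.0,
            "sensor_noise_sd": 1.0,
            "sources": [
                {
                    "position": (35.0, -20.0, 40.0),
                    "orientation": (0.0, 0.0, 1.0),
                    "band_center": 11.0,
                    "modulation": "erd",
                    "gain": 0.5,
                    "modulation_window": (0.45, 1.45),
                    "amplitude": 40.0,
                    "conditions": ("MI",),
                },
                {
                    "position": (-20.0, 30.0, 35.0),
                    "orientation": (1.0, 0.0, 0.0),
                    "band_center": 5.5,
                    "phase_lock_kappa": 2.0,
                    "reset_time": 0.4,
                    "amplitude": 25.0,
                    "conditions": ("MI",),
                },
            ],
        },
        n_channels=32,
        grid_spacing_mm=25.0,
        n_perm=256,
        perm_method="auto",
        seed=seed,
        out_dir=out_dir,
    )
    cfg.validate()
    return cfg
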