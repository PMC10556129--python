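"""Pipeline configuration: screening thresholds, ellipse level, MCMC settings."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .types import ValidationError


@dataclass
class PipelineConfig:
    """All tunable knobs of the screening/classification/mixing pipeline.

    Units: lipid yields in µg g⁻¹, δ13C quantities in ‰ VPDB, windows on
    dimensionless ratios, ``shellfish_srr_window`` in % of the SRR
    diastereomer among phytanic-acid diastereomers.
    """

    # screening
    lipid_yield_threshold: float = 5.0  # µg g⁻¹; sherds at or below are excluded
    shellfish_srr_window: tuple[float, float] = (20.0, 47.0)  # %SRR, closed
    shellfish_tmtd_window: tuple[float, float] = (0.34, 1.63)  # TMTD/phytanic
    alkanol_trace_threshold: float = 1.0  # relative abundance units
    palm_c12_threshold: float = 5.0  # relative abundance units for lauric acid
    aquatic_requires_both_apaas: bool = True  # C18 AND C20 homologues

    # isotopes
    ellipse_level: float = 0.68
    default_d13c_sd: float = 0.3  # ‰, typical GC-C-IRMS replicate precision
    suess_correction: float = 0.0  # ‰ added to reference centres (fossil-fuel shift)

    # mixing model
    sigma_model: float = 0.5  # ‰, residual model error per proxy
    grid_step: float = 0.05  # simplex lattice step of the grid oracle
    n_chains: int = 4
    n_iter: int = 4000  # retained iterations per chain
    n_burn: int = 2000  # burn-in iterations per chain (adaptive, discarded)
    proposal_scale: float = 0.5  # initial random-walk sd in ALR space
    seed: int = 0

    # stats
    report_u: str = "min"  # "min" -> min(U_x, U_y); "x" -> U of the first sample

    def validate(self) -> "PipelineConfig":
        if self.lipid_yield_threshold <= 0:
            raise ValidationError("lipid_yield_threshold must be > 0")
        if self.alkanol_trace_threshold <= 0:
            raise ValidationError("alkanol_trace_threshold must be > 0")
        if self.palm_c12_threshold <= 0:
            raise ValidationError("palm_c12_threshold must be > 0")
        if not (0 < self.ellipse_level < 1):
            raise ValidationError("ellipse_level must be in (0, 1)")
        for window, name in (
            (self.shellfish_srr_window, "shellfish_srr_window"),
            (self.shellfish_tmtd_window, "shellfish_tmtd_window"),
        ):
            if len(window) != 2 or not window[0] < window[1]:
                raise ValidationError(f"{name} must be an ordered [low, high] pair")
        if self.default_d13c_sd <= 0:
            raise ValidationError("default_d13c_sd must be > 0")
        if self.sigma_model < 0:
            raise ValidationError("sigma_model must be >= 0")
        if not (0 < self.grid_step <= 1):
            raise ValidationError("grid_step must be in (0, 1]")
        if self.n_chains < 2:
            raise ValidationError("n_chains must be >= 2 for split-Rhat")
        if self.n_iter < 1 or self.n_burn < 0:
            raise ValidationError("n_iter must be >= 1 and n_burn >= 0")
        if self.proposal_scale <= 0:
            raise ValidationError("proposal_scale must be > 0")
        if self.report_u not in ("min", "x"):
            raise ValidationError("report_u must be 'min' or 'x'")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["shellfish_srr_window"] = list(self.shellfish_srr_window)
        d["shellfish_tmtd_window"] = list(self.shellfish_tmtd_window)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("shellfish_srr_window", "shellfish_tmtd_window"):
            if key in kwargs:
                kwargs[key] = tuple(float(v) for v in kwargs[key])
        return cls(**kwargs).validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)
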