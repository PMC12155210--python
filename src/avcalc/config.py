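"""One configuration namespace for every pipeline threshold.

All clinically meaningful constants live here with their standard defaults —
the 130 HU calcium threshold and 1 mm^2 area rule, the 10 Ag valid-lesion
cutoff, the 36/45 HU noise gates, the HU window, the expansion distances and
the severity policy — so nothing is hidden in code.  Serializable to YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .geometry import ExpansionConfig
from .qc import QcThresholds
from .scoring import SeverityPolicy

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    hu_threshold: float = 130.0
    min_area_mm2: float = 1.0
    mass_calibration: float = 0.001  # scanner-specific; placeholder default
    window_hu: tuple[float, float] = (-300.0, 100.0)
    iso_spacing_mm: float = 1.0
    crop_shape: tuple[int, int, int] = (176, 176, 128)
    superior_is_above: bool = True  # dA side of the disk = scanner superior
    sector_mode: str = "anchor_rays"
    expansion: ExpansionConfig = field(default_factory=ExpansionConfig)
    qc: QcThresholds = field(default_factory=QcThresholds)
    severity: SeverityPolicy = field(default_factory=SeverityPolicy)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "expansion" in kwargs:
            kwargs["expansion"] = ExpansionConfig(**kwargs["expansion"])
        if "qc" in kwargs:
            kwargs["qc"] = QcThresholds(**kwargs["qc"])
        if "severity" in kwargs:
            sev = dict(kwargs["severity"])
            for k in ("bin_edges", "bin_labels"):
                if k in sev:
                    sev[k] = tuple(sev[k])
            kwargs["severity"] = SeverityPolicy(**sev)
        for k in ("window_hu", "crop_shape"):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)
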