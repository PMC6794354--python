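"""Pipeline configuration.

All defaults equal the published analysis parameters: 0.5-48 Hz band-pass,
+/-100 uV rejection, 95% PCA artifact variance, 0.5 Hz spectral resolution
with 50% overlapped Hanning windows, |PSI| > 2 edge threshold, and a 20%
quantile for each hub criterion.  Band edges are half-open [lo, hi) so the
five bands partition 0.5-48 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 48.0),
}


@dataclass
class PipelineConfig:
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS))
    filter_lo: float = 0.5          # Hz
    filter_hi: float = 48.0         # Hz
    reject_uv: float = 100.0        # rejection threshold, microvolts
    pca_var: float = 0.95           # artifact PCA variance fraction
    df: float = 0.5                 # spectral resolution, Hz
    overlap: float = 0.5            # Welch window overlap fraction
    psi_threshold: float = 2.0      # |PSI| edge threshold
    hub_quantile: float = 0.2       # extreme-quantile size per hub criterion
    apply_csd: bool = True          # surface-Laplacian step on/off
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.bands:
            raise ValueError("at least one band required")
        edges = sorted(self.bands.values())
        for (lo, hi) in edges:
            if not lo < hi:
                raise ValueError(f"band ({lo}, {hi}) has lo >= hi")
        for (_, hi1), (lo2, _) in zip(edges, edges[1:]):
            if lo2 < hi1:
                raise ValueError("bands overlap; they must be disjoint and ordered")
        if not 0.0 < self.filter_lo < self.filter_hi:
            raise ValueError("need 0 < filter_lo < filter_hi")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")
        if self.df <= 0:
            raise ValueError("df must be positive")
        if self.psi_threshold <= 0:
            raise ValueError("psi_threshold must be positive")
        if not 0.0 < self.hub_quantile <= 1.0:
            raise ValueError("hub_quantile must be in (0, 1]")
        if not 0.0 < self.pca_var <= 1.0:
            raise ValueError("pca_var must be in (0, 1]")
        if self.reject_uv <= 0:
            raise ValueError("reject_uv must be positive")

    def to_file(self, path: str | Path) -> None:
        obj = asdict(self)
        obj["bands"] = {k: list(v) for k, v in self.bands.items()}
        Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        obj = yaml.safe_load(Path(path).read_text())
        if "bands" in obj:
            obj["bands"] = {k: tuple(v) for k, v in obj["bands"].items()}
        return cls(**obj)
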