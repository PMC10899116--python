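"""Class codebook and configuration objects.

The seven-class codebook covers non-tumor tissue plus the six invasive
non-mucinous lung adenocarcinoma growth patterns of the IASLC grading
system.  Cribriform, micropapillary and solid are the high-grade patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

NON_TUMOR = 0
CLASS_NAMES = {
    0: "non_tumor",
    1: "lepidic",
    2: "papillary",
    3: "acinar",
    4: "cribriform",
    5: "micropapillary",
    6: "solid",
}
CLASS_IDS = {v: k for k, v in CLASS_NAMES.items()}
PATTERN_IDS = (1, 2, 3, 4, 5, 6)           # tumor growth patterns only
HIGH_GRADE_IDS = (4, 5, 6)                 # cribriform, micropapillary, solid
# clinical severity, most aggressive first (used to break predominance ties)
SEVERITY_ORDER = (6, 5, 4, 3, 2, 1)

N_CLASSES = 7
PATCH_SIZE = 768          # training/inference patch edge at x20
TILE_SIZE = 2000          # whole-slide tile edge at x20
MPP_X20 = 0.45            # microns per pixel at x20 equivalent
MASK_DOWNSAMPLE = 16      # x20 -> x1.25 for the analysis-resolution mask
MPP_ANALYSIS = MPP_X20 * MASK_DOWNSAMPLE   # ~7.2 um/px

#: width multiplier calibrated once so that the reference three-stream
#: network with first+second-order attention and pyramid pooling counts
#: 4.10 million trainable parameters (two decimals); frozen thereafter.
REFERENCE_WIDTH_MULTIPLIER = 1.67


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture switches; the ablation variants are reachable by name.

    ``fusion`` selects how the streams are combined: plain addition
    (``add``), first-order squeeze-gate attention plus addition (``fo``),
    second-order Gram-matrix attention (``so``), or both (``fo+so``, the
    reference model).  ``n_streams=1`` is the single-stream baseline.
    """

    n_streams: int = 3
    stream_scales: tuple = (10.0, 5.0, 2.5)
    fusion: str = "fo+so"
    width_multiplier: float = REFERENCE_WIDTH_MULTIPLIER
    ppm_bins: tuple = (1, 2, 3, 6)
    n_classes: int = N_CLASSES

    def __post_init__(self):
        if self.n_streams not in (1, 3):
            raise ValueError(f"n_streams must be 1 or 3, got {self.n_streams}")
        if self.fusion not in ("add", "fo", "so", "fo+so"):
            raise ValueError(f"unknown fusion mode {self.fusion!r}")
        if not self.ppm_bins:
            raise ValueError("ppm_bins must be non-empty")
        if any(b < 1 for b in self.ppm_bins):
            raise ValueError("ppm_bins must be positive")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")

    @property
    def use_fo(self) -> bool:
        return self.n_streams > 1 and self.fusion in ("fo", "fo+so")

    @property
    def use_so(self) -> bool:
        return self.n_streams > 1 and self.fusion in ("so", "fo+so")

    def with_width(self, width_multiplier: float) -> "NetworkConfig":
        return replace(self, width_multiplier=width_multiplier)

    def to_dict(self) -> dict:
        return {
            "n_streams": self.n_streams,
            "stream_scales": list(self.stream_scales),
            "fusion": self.fusion,
            "width_multiplier": self.width_multiplier,
            "ppm_bins": list(self.ppm_bins),
            "n_classes": self.n_classes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(
            n_streams=int(d["n_streams"]),
            stream_scales=tuple(d["stream_scales"]),
            fusion=str(d["fusion"]),
            width_multiplier=float(d["width_multiplier"]),
            ppm_bins=tuple(d["ppm_bins"]),
            n_classes=int(d["n_classes"]),
        )


@dataclass(frozen=True)
class TrainSchedule:
    """Step-wise Adam schedule: 1e-3 / 1e-4 / 1e-5 over epochs 1-10/11-50/51-60.

    ``scaled(total)`` keeps the three phases in the same 1:4:1 proportion for
    shortened runs.
    """

    epochs: int = 60
    batch_size: int = 8
    phase_ends: tuple = (10, 50, 60)
    phase_lrs: tuple = (1e-3, 1e-4, 1e-5)
    seed: int = 0

    def __post_init__(self):
        if len(self.phase_ends) != 3 or len(self.phase_lrs) != 3:
            raise ValueError("schedule must have exactly three phases")
        if list(self.phase_lrs) != sorted(self.phase_lrs, reverse=True):
            raise ValueError("learning rate must be non-increasing")
        if self.phase_ends[-1] != self.epochs:
            raise ValueError("last phase must end at the final epoch")

    def lr_at(self, epoch: int) -> float:
        """Learning rate for a 1-based epoch index."""
        for end, lr in zip(self.phase_ends, self.phase_lrs):
            if epoch <= end:
                return lr
        return self.phase_lrs[-1]

    def scaled(self, epochs: int, seed: int | None = None) -> "TrainSchedule":
        frac = epochs / self.epochs
        ends = [max(1, round(e * frac)) for e in self.phase_ends]
        for i in range(1, 3):                     # keep phases ordered
            ends[i] = max(ends[i], ends[i - 1] + 1)
        ends[2] = epochs
        ends[1] = min(ends[1], epochs)
        ends[0] = min(ends[0], ends[1])
        return TrainSchedule(epochs=epochs, batch_size=self.batch_size,
                             phase_ends=tuple(ends), phase_lrs=self.phase_lrs,
                             seed=self.seed if seed is None else seed)


@dataclass(frozen=True)
class AugmentPolicy:
    """Joint geometric + image-only color jitter used during training."""

    max_rotation_deg: float = 90.0
    max_shift_frac: float = 0.2
    zoom_range: tuple = (0.8, 1.2)
    saturation_range: tuple = (0.8, 2.0)
    hue_range: tuple = (-0.1, 0.1)
    color_aug_enabled: bool = True

    @classmethod
    def identity(cls) -> "AugmentPolicy":
        return cls(max_rotation_deg=0.0, max_shift_frac=0.0,
                   zoom_range=(1.0, 1.0), saturation_range=(1.0, 1.0),
                   hue_range=(0.0, 0.0), color_aug_enabled=False)


@dataclass(frozen=True)
class FilterThresholds:
    """Minimum component areas (mm^2) kept per class in postprocessing.

    Lepidic islands under 0.05 mm^2 and papillary/cribriform/solid islands
    under 0.015 mm^2 are relabeled to non-tumor; acinar and micropapillary
    are never filtered.
    """

    min_area_mm2: dict = field(default_factory=lambda: {
        CLASS_IDS["lepidic"]: 0.05,
        CLASS_IDS["papillary"]: 0.015,
        CLASS_IDS["cribriform"]: 0.015,
        CLASS_IDS["solid"]: 0.015,
    })

    def __post_init__(self):
        if any(v < 0 for v in self.min_area_mm2.values()):
            raise ValueError("area thresholds must be non-negative")
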