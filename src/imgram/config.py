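"""Pipeline configuration: every knob of the end-to-end method in one
validated, immutable object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Any

from .classify import ClassifierConfig

WEIGHTING_MODES = ("tf", "tf_rf")


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the encode -> n-gram -> weight -> select -> classify flow.

    Defaults follow the method's reference settings: orders {1, 2, 3},
    TF weighting, rank-sum filter at alpha = 0.05, all valid features
    retained, 10-fold cross-validation, RBF-SVM with C = 10 and
    gamma = 0.01.  Preprocessing is off by default.
    """

    orders: tuple[int, ...] = (1, 2, 3)
    weighting: str = "tf"
    alpha: float = 0.05
    fraction: float = 1.0
    n_folds: int = 10
    seed: int = 0
    scale: bool = True
    tf_per_order: bool = False
    correction: str | None = None
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    # optional preprocessing
    denoise: bool = False
    diffusion_iterations: int = 10
    diffusion_kappa: float = 30.0
    diffusion_dt: float = 0.2
    fill_border: bool = False
    white_threshold: int = 250

    def __post_init__(self):
        object.__setattr__(self, "orders", tuple(sorted(set(self.orders))))
        if not self.orders or not set(self.orders) <= {1, 2, 3}:
            raise ValueError(f"orders must be a nonempty subset of {{1,2,3}}, got {self.orders}")
        if self.weighting not in WEIGHTING_MODES:
            raise ValueError(f"weighting must be one of {WEIGHTING_MODES}, got {self.weighting!r}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.fraction <= 1:
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")
        if self.n_folds < 2:
            raise ValueError(f"n_folds must be >= 2, got {self.n_folds}")
        if self.correction not in (None, "bh"):
            raise ValueError(f"correction must be None or 'bh', got {self.correction!r}")
        if not 1 <= self.white_threshold <= 255:
            raise ValueError(f"white_threshold must be in [1, 255], got {self.white_threshold}")
        if self.diffusion_iterations < 0:
            raise ValueError("diffusion_iterations must be >= 0")
        if isinstance(self.classifier, dict):
            object.__setattr__(self, "classifier", ClassifierConfig(**self.classifier))

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["orders"] = list(self.orders)
        d["classifier"]["mlp_hidden"] = list(self.classifier.mlp_hidden)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "orders" in d:
            d["orders"] = tuple(d["orders"])
        if isinstance(d.get("classifier"), dict):
            c = dict(d["classifier"])
            if "mlp_hidden" in c:
                c["mlp_hidden"] = tuple(c["mlp_hidden"])
            d["classifier"] = ClassifierConfig(**c)
        return cls(**d)
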