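"""Pipeline configuration (YAML-backed).

All analysis constants live here as defaults rather than being hard-coded
in the stages: the band and filter, the univariate pre-reduction size
(4000), the per-modality sparse-selection counts (500 + 500), the bootstrap
parameters (L = 0.3 M0, l0 = 200), the SVM/SVR hyperparameters, and the
permutation count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .signal import BandpassSpec
from .synthgen import CohortConfig, high_snr_reduced_config


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    low_hz: float = 0.01
    high_hz: float = 0.08
    filter_order: int = 4
    ripple_db: float = 0.5
    init_alff: int = 4000
    n_alff: int = 500
    n_fc: int = 500
    l_frac: float = 0.3
    l0: int = 200
    svm_c: float = 1.0
    svr_c: float = 1.0
    epsilon: float = 0.1
    n_perm: int = 0
    modalities: tuple[str, ...] = ("hybrid",)
    scores: tuple[str, ...] = ("sas", "sds")
    seed: int = 0

    def validate(self) -> None:
        self.cohort.validate()
        self.bandpass_spec().validate()
        for name in ("init_alff", "n_alff", "n_fc", "l0"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def bandpass_spec(self) -> BandpassSpec:
        return BandpassSpec(low_hz=self.low_hz, high_hz=self.high_hz,
                            order=self.filter_order, ripple_db=self.ripple_db,
                            tr_seconds=self.cohort.tr_seconds)

    def mvpa_params(self) -> dict:
        return dict(init_alff=self.init_alff, n_alff=self.n_alff, n_fc=self.n_fc,
                    l_frac=self.l_frac, l0=self.l0)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d["modalities"] = list(self.modalities)
        d["scores"] = list(self.scores)
        return d

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        for key in ("modalities", "scores"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = PipelineConfig(**d)
        cfg.validate()
        return cfg

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return PipelineConfig.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @staticmethod
    def reduced(seed: int = 0) -> "PipelineConfig":
        """Desk-scale configuration: small high-SNR cohort, lighter bootstrap."""
        return PipelineConfig(
            cohort=high_snr_reduced_config(seed=seed),
            init_alff=500, n_alff=100, n_fc=100, l0=50,
            modalities=("hybrid", "alff", "fc"), seed=seed)
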