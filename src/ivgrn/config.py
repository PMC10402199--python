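"""Run configuration: every tunable of the pipeline, YAML round-trip,
validation with unknown-key rejection, and a stable content hash for
resumable runs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # input paths
    expression: str | None = None
    tpm: str | None = None          # GTEx mode only
    dosage: str | None = None
    variant_table: str | None = None
    annotation: str | None = None
    covariates: str | None = None
    outdir: str = "ivgrn_run"

    # preprocessing
    mode: str = "none"              # {gtex, tcga, none}; none = expression already log scale
    tpm_threshold: float = 0.1
    count_threshold: float = 6.0
    min_expressed_fraction: float = 0.20
    tcga_min_total: float = 2_500_000.0
    tcga_max_missing: float = 0.80
    logratio_trim: float = 0.30
    sum_trim: float = 0.05
    max_variant_missing: float = 0.10
    max_sample_missing: float = 0.10
    hwe_alpha: float = 1e-4
    hwe_test: str = "chisq"
    min_mac: int = 5
    n_pcs: int = 3

    # instrument discovery
    iv_alpha: float = 0.05
    flank: int = 1000
    max_instruments: int = 3
    max_instrument_corr: float = 0.3
    asum_alpha0: float = 0.1
    n_perm: int = 1000

    # network estimation
    isis_size: int | str = "auto"
    gamma: float = 1.0
    selection: str = "cv_1se"
    cv_folds: int = 10
    n_alphas: int = 40

    # bootstrap + partition
    n_bootstraps: int = 1000
    cutoff: float = 1.0

    # execution
    seed: int = 0
    n_jobs: int = 1

    _MODES = ("gtex", "tcga", "none")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"mode must be one of {self._MODES}, got {self.mode!r}")
        if not (0 < self.cutoff <= 1):
            raise ValueError("cutoff must be in (0, 1]")
        if self.n_bootstraps < 1:
            raise ValueError("n_bootstraps must be >= 1")
        if self.selection not in ("cv_1se", "cv_min", "bic"):
            raise ValueError(f"unknown selection rule {self.selection!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def spls_params(self) -> dict:
        return dict(isis_size=self.isis_size, gamma=self.gamma,
                    selection=self.selection, cv=self.cv_folds,
                    n_alphas=self.n_alphas, n_jobs=self.n_jobs, seed=self.seed)
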