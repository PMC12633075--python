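"""Schema-validated run configuration (YAML/JSON, unknown keys rejected)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BackendConfig(_Strict):
    name: str = "mock"
    identity_band: Tuple[float, float] = (0.3, 0.5)
    forward_noise: float = 0.05


class GenerationConfig(_Strict):
    protocol: str = "default"
    coverages: List[float] = [0.4, 0.6, 0.8, 1.0]
    temperatures: List[float] = [0.9, 1.0, 1.1]
    top_ks: List[Optional[int]] = [None, 40]
    top_ps: List[Optional[float]] = [0.9, 0.95]
    n_structures: int = Field(4, ge=1)
    multiplier: int = Field(3, ge=1)
    alpha: float = Field(1.0, ge=0)
    target_row_count: Optional[int] = None
    n_repeats: int = Field(1, ge=1)

    @field_validator("protocol")
    @classmethod
    def _protocol(cls, v: str) -> str:
        if v not in ("default", "shallow"):
            raise ValueError("protocol must be 'default' or 'shallow'")
        return v


class MutagenesisConfig(_Strict):
    enabled: bool = False
    fraction_of_rows: float = Field(0.2, ge=0, le=1)
    per_position_rate: float = Field(0.05, ge=0, le=1)
    matrix_name: str = "BLOSUM62"


class AssemblyConfig(_Strict):
    max_run: int = Field(6, ge=1)
    min_entropy_bits: float = Field(2.0, ge=0)
    max_digram_freq: float = Field(0.6, gt=0, le=1)
    redundancy_identity: Optional[float] = 0.95
    mutagenesis: MutagenesisConfig = MutagenesisConfig()
    msa_format: str = "a3m"
    max_seq: int = 16
    max_extra_seq: int = 32


class QualityConfig(_Strict):
    nad_threshold: float = Field(0.5, gt=0, le=1)
    coevolution: bool = False
    coevolution_pseudocount: float = Field(1.0, gt=0)


class RunConfig(_Strict):
    """Top-level configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "pseudomsa_out"
    log_level: str = "INFO"
    backend: BackendConfig = BackendConfig()
    generation: GenerationConfig = GenerationConfig()
    assembly: AssemblyConfig = AssemblyConfig()
    quality: QualityConfig = QualityConfig()

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.model_validate(data or {})

    def echo(self, out_dir: Path) -> Path:
        """Write the effective configuration next to the run outputs."""
        p = Path(out_dir) / "effective_config.yaml"
        p.write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))
        return p
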