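"""Pipeline configuration: one YAML-serializable object, one seed."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings.

    All stage randomness (simulation, GSEA permutations) flows from the
    single ``seed``, fanned out deterministically per stage, so rerunning the
    same config reproduces every output byte for byte.
    """

    # input mode
    simulate: bool = True
    counts_path: str | None = None
    expression_path: str | None = None
    gene_sets_path: str | None = None
    edges_path: str | None = None
    annotations_path: str | None = None

    # simulation conditions
    seed: int = 0
    n_patients: int = 32
    ne_high_fraction: float = 0.645
    n_genes: int = 2560
    effect_size: float = 2.0
    noise_sd: float = 1.0
    interaction_density: float = 0.002

    # phenotyping
    mad_c: float = 0.0
    macrophage_min_fraction: float = 0.5

    # enrichment
    gsea_metric: str = "signal_to_noise"
    gsea_weight: float = 1.0
    n_perm: int = 1000

    # differential expression / volcano
    de_shrink_var: bool = False
    volcano_p: str = "adjusted"  # or "raw"
    volcano_p_threshold: float = 0.05
    fc_low: float = 1.5
    fc_high: float = 2.0

    # network
    network_min_score: float = 0.4
    network_p_column: str = "p_adj"
    edges_per_node_mode: str = "ratio"

    # morphometry
    composition_mode: str = "ratio_of_sums"

    out_dir: str | None = None

    def __post_init__(self):
        if self.volcano_p not in ("adjusted", "raw"):
            raise ValueError("volcano_p must be 'adjusted' or 'raw'")
        for name in (
            "volcano_p_threshold", "fc_low", "fc_high", "network_min_score"
        ):
            if not float("-inf") < float(getattr(self, name)) < float("inf"):
                raise ValueError(f"{name} must be finite")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        if not self.simulate:
            for name in ("counts_path", "expression_path", "gene_sets_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} required when simulate is false")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: no such file: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the analysis-relevant configuration.

        ``out_dir`` is excluded so the same analysis written to two places
        carries the same provenance digest.
        """
        fields = asdict(self)
        fields.pop("out_dir", None)
        canon = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
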