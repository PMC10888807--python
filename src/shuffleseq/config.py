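"""Configuration for simulation and analysis stages.

Every numeric threshold used by an analysis stage is a named field of
:class:`Config`, so a single YAML/JSON file (plus a global seed) fully
specifies an end-to-end run. Unknown keys are rejected on load.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class Config:
    """All tunable parameters, with the experiment's published defaults.

    Genomic coordinates are 1-based inclusive in TSV tables and 0-based
    half-open in BED/BEDPE exports throughout the package.
    """

    # ---- global ----
    seed: int = 0

    # ---- insertion mapping ----
    levenshtein_budget: int = 6          # joint (bc1+bc2) edit-distance budget for clustering
    cluster_pair_offset: int = 4         # bp between paired (-,+) clusters (TTAA duplication)
    min_cluster_reads: int = 6           # clusters removed iff reads < this AND lengths < below
    min_unique_lengths: int = 3
    support_replicate: int = 2           # replicate whose counts feed the support filter
    parental_min_reads: float = 50.0     # exclusive; on depth-rescaled averaged counts
    parental_min_umis: float = 30.0      # exclusive

    # ---- bulk rearrangement calling ----
    rearrangement_min_umi: int = 2       # ">1 UMI"
    well_min_reads: int = 100_000
    cpm_scale: float = 1e6
    barcode_match_mode: str = "exact"    # "exact" or "levenshtein"

    # ---- single-cell genotyping ----
    chimera_min_share: float = 0.2
    umi_hamming: int = 1
    clonotype_min_umi_per_pair: int = 3
    min_cell_total_umi: int = 20
    min_pair_total_umi: int = 20
    n_pcs: int = 100
    knn_neighbors: int = 10
    leiden_resolution: float = 1.0
    rank_ratio_cut: float = 1.5
    min_max_detection_fraction: float = 0.5
    min_clonotype_pairs: int = 7         # ">6"
    jaccard_merge: float = 0.95
    jaccard_connect: float = 0.1
    jaccard_bulk: float = 0.05
    assign_min_recall: float = 0.1
    assign_min_precision: float = 0.75
    doublet_second_recall: float = 0.1
    assign_min_umi: int = 2
    qc_min_umi: int = 1000
    qc_mito_range: tuple[float, float] = (1.0, 12.0)   # percent
    qc_doublet_max: float = 0.4
    sc_norm_scale: float = 10_000.0

    # ---- simulator: genome ----
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000, "chr3": 1_000_000}
    )
    variant_spacing: float = 150.0       # mean bp between heterozygous SNVs
    haplotypes: tuple[str, str] = ("BL6", "CAST")

    # ---- simulator: clones and recombination ----
    n_clones: int = 100
    insertions_per_clone: int = 50
    cre_rate: float = 5.0                # mean recombination events per clone
    cis_decay_lambda: float = 200_000.0  # bp; cis pair weight ~ exp(-d/lambda)
    trans_rate: float = 0.1              # probability an event is inter-chromosomal

    # ---- simulator: read emission ----
    ivt_depth_per_side: int = 10
    ivt_read_len: int = 120
    ivt_flank_min: int = 30
    ivt_flank_max: int = 110
    ivt_err_rate: float = 0.001
    amplicon_dialect: str = "2-primer"
    molecules_per_cassette: int = 30
    umis_per_molecule: int = 2
    chimera_rate: float = 0.01
    amplicon_umi_len: int = 10
    sc_n_cells: int = 2000
    sc_capture_rate: float = 0.7
    sc_umi_depth: float = 6.0
    sc_ambient_rate: float = 0.02
    sc_doublet_rate: float = 0.03
    sc_cells_per_event: int = 1
    cell_bc_len: int = 16
    sc_umi_len: int = 12

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.cis_decay_lambda <= 0:
            raise ValueError("cis_decay_lambda must be > 0")
        for name in ("sc_capture_rate", "sc_ambient_rate", "sc_doublet_rate",
                     "chimera_rate", "trans_rate", "chimera_min_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.amplicon_dialect not in ("2-primer", "4-primer"):
            raise ValueError(f"unknown amplicon_dialect {self.amplicon_dialect!r}")
        if self.barcode_match_mode not in ("exact", "levenshtein"):
            raise ValueError(f"unknown barcode_match_mode {self.barcode_match_mode!r}")
        lo, hi = self.qc_mito_range
        if not 0 <= lo <= hi <= 100:
            raise ValueError("qc_mito_range must satisfy 0 <= lo <= hi <= 100")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["qc_mito_range"] = list(self.qc_mito_range)
        d["haplotypes"] = list(self.haplotypes)
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


_FIELDS = {f.name for f in dataclasses.fields(Config)}


def load_config(path: str | Path | None = None, **overrides: Any) -> Config:
    """Load a Config from YAML/JSON, applying keyword overrides on top.

    An empty or missing file yields all defaults; unknown keys raise.
    """
    data: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) if text.strip() else {}
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(loaded)
    data.update(overrides)
    unknown = set(data) - _FIELDS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "qc_mito_range" in data:
        data["qc_mito_range"] = tuple(data["qc_mito_range"])
    if "haplotypes" in data:
        data["haplotypes"] = tuple(data["haplotypes"])
    return Config(**data)


def save_config(config: Config, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


@dataclass
class RunManifest:
    """Provenance record emitted by every CLI run."""

    tool_version: str
    config_hash: str
    seed: int
    input_hashes: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def file_hash(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]
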