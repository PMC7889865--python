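"""Run configuration with the pipeline's free parameters.

Every default matches the method's published operating point: 50 kb
molecule split gap, alt-fraction 0.25 / quality 13 / 10th-90th-percentile
depth pruning, cluster merge support 3, block overlap support 5, parity
significance 0.99, 200 kb block threshold, 100 kb chunk length, coverage
factor 0.8, 100-mer uniqueness, 1 kb contig floor, MAPQ 20, 20 bp insertion
breakpoint tolerance and 50 bp SV size threshold.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


@dataclass(slots=True)
class RunConfig:
    split_gap: int = 50_000
    min_mapq_reads: int = 20
    min_alt_fraction: float = 0.25
    coverage_low_pct: float = 10.0
    coverage_high_pct: float = 90.0
    min_snp_qual: float = 13.0
    merge_support: int = 3
    overlap_support: int = 5
    alpha: float = 0.99
    block_threshold: int = 200_000
    chunk_len: int = 100_000
    search_window: int = 20_000
    factor: float = 0.8
    k_uniq: int = 100
    anchor_k: int = 100
    assembler_backend: str = "toy"
    assembler_k: int = 31
    assembler_min_kmer_count: int = 2
    external_cmd: str | None = None
    min_contig_len: int = 1000
    min_mapq: int = 20
    ins_tol: int = 20
    sv_min_size: int = 50
    align_pad: int = 150_000
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


#: The free parameters whose defaults are pinned to the published values,
#: asserted as a table by the test suite.
PUBLISHED_DEFAULTS: dict[str, float | int] = {
    "split_gap": 50_000,
    "min_alt_fraction": 0.25,
    "min_snp_qual": 13,
    "merge_support": 3,
    "overlap_support": 5,
    "alpha": 0.99,
    "block_threshold": 200_000,
    "chunk_len": 100_000,
    "factor": 0.8,
    "k_uniq": 100,
    "min_contig_len": 1000,
    "min_mapq": 20,
    "ins_tol": 20,
    "sv_min_size": 50,
}
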