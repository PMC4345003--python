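"""Pipeline configuration.

One config object drives a whole run. The two search-space strategies
differ only in their cis-window and pair constraints:

* ``cis_trans``: a probe needs one cis-eQTL (within 1 Mb of the probe
  midpoint) and one trans-eQTL (further away or on another chromosome);
  intra-chromosomal pairs must additionally be out of LD.
* ``cis_cis``: a probe needs two cis-eQTLs under a 10 Mb window; the two
  SNPs must be within 10 Mb of each other, at least 100 kb apart, and
  out of LD.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

CIS_TRANS = "cis_trans"
CIS_CIS = "cis_cis"

#: Default cis window per strategy (bp).
DEFAULT_CIS_WINDOW = {CIS_TRANS: 1_000_000, CIS_CIS: 10_000_000}


@dataclass
class PipelineConfig:
    strategy: str = CIS_TRANS
    maf_min: float = 0.2           # SNPs kept when MAF strictly greater
    miss_max: float = 0.2          # SNPs kept when missingness <= this
    hwe_alpha: float = 0.05        # SNPs dropped when HWE p below this
    iqr_top_fraction: float = 0.05  # fraction of most-variable probes kept
    fdr_threshold: float = 0.5     # liberal BH gate on marginal eQTLs
    ld_r2_max: float = 0.01        # intra-chromosomal pairs must be below
    min_cell_count: int = 10       # per 9-cell genotype combination
    cis_window: int | None = None  # bp; None = strategy default
    pair_min_distance: int = 100_000  # bp, cis_cis only
    n_pcs: int | str = "auto"      # "auto" = Tracy-Widom significant count
    alpha: float = 0.05            # family-wise level for Bonferroni / TW
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in (CIS_TRANS, CIS_CIS):
            raise ValueError(f"unknown strategy: {self.strategy!r}")
        if self.cis_window is None:
            self.cis_window = DEFAULT_CIS_WINDOW[self.strategy]
        for name in ("maf_min", "miss_max", "hwe_alpha", "iqr_top_fraction",
                     "fdr_threshold", "ld_r2_max", "alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.strategy == CIS_CIS and not self.cis_window > self.pair_min_distance:
            raise ValueError("cis_window must exceed pair_min_distance")
        if self.n_pcs != "auto" and (not isinstance(self.n_pcs, int) or self.n_pcs < 0):
            raise ValueError("n_pcs must be 'auto' or a non-negative integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
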