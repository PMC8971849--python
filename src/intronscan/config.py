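"""Shared configuration with range validation and YAML loading."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class Config:
    """Tunable parameters; defaults are the package's study conditions."""

    pseudocount: float = 1.0           # background-scaled Laplace pseudocount
    cutoff_margin: float = 1.0         # bits below the training minimum
    slack: float = 0.2                 # variable-region max-length slack
    n_shuffles: int = 500              # E-value calibration shuffles
    shuffle_len: int = 10_000          # nt per calibration shuffle
    both_strands: bool = True
    dedupe_identical: float = 0.02     # "identical" p-distance threshold
    dedupe_related: float = 0.10       # "closely related" threshold
    conflict_fraction: float = 0.95    # shared-conserved-position threshold
    conflict_coord_tol: int = 10       # +-nt for "same start/end"
    ambiguity_orders: float = 2.0      # E-value orders for unambiguity
    window_cap: int = 500              # level-1 "closely spaced" bound, nt
    level1_fp_per_mb: float = 10.0     # expected random hits/Mb, level 1
    mid_fp_per_mb: float = 0.1         # budget after the middle level(s)
    max_levels: int = 3
    extend_evalue_max: float = 1e-5    # best hits added per round
    extend_cap: int = 50
    min_tally_count: int = 5

    def validate(self) -> "Config":
        checks = [
            (self.pseudocount > 0, "pseudocount must be > 0"),
            (self.cutoff_margin >= 0, "cutoff_margin must be >= 0"),
            (0 <= self.slack <= 5, "slack must lie in [0, 5]"),
            (self.n_shuffles >= 10, "n_shuffles must be >= 10"),
            (self.shuffle_len >= 100, "shuffle_len must be >= 100"),
            (0 <= self.dedupe_identical <= 1, "dedupe_identical in [0, 1]"),
            (0 <= self.dedupe_related <= 1, "dedupe_related in [0, 1]"),
            (0 < self.conflict_fraction <= 1, "conflict_fraction in (0, 1]"),
            (self.conflict_coord_tol >= 0, "conflict_coord_tol must be >= 0"),
            (self.ambiguity_orders >= 0, "ambiguity_orders must be >= 0"),
            (self.window_cap > 0, "window_cap must be > 0"),
            (self.level1_fp_per_mb > 0, "level1_fp_per_mb must be > 0"),
            (self.mid_fp_per_mb > 0, "mid_fp_per_mb must be > 0"),
            (self.max_levels in (3, 4), "max_levels must be 3 or 4"),
            (self.extend_evalue_max > 0, "extend_evalue_max must be > 0"),
            (self.extend_cap >= 1, "extend_cap must be >= 1"),
            (self.min_tally_count >= 1, "min_tally_count must be >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)
        return self

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "Config":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc).validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
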