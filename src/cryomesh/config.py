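"""Analysis run configuration.

A single config object is the source of every analysis parameter whose
value is a methodological choice (fragment length, histogram bin width,
peak estimator, contact threshold).  Every output table embeds the config
hash so results computed under different choices cannot be pooled silently.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    fragment_length: float = 20.0  # nm
    bin_width: float = 5.0  # degrees
    peak_method: str = "kde"  # "kde" | "hist_mode"
    contact_threshold: float = 0.0  # nm; 0 = direct contact only
    seed: int = 0
    n_permutations: int = 10000
    genotype_overrides: dict = field(default_factory=dict)
    output_dir: str | None = None

    def __post_init__(self):
        for name in ("fragment_length", "bin_width", "n_permutations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.contact_threshold < 0:
            raise ValueError("contact_threshold must be >= 0")
        if self.peak_method not in ("kde", "hist_mode"):
            raise ValueError(f"unknown peak_method {self.peak_method!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(Path(path)) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @property
    def hash(self) -> str:
        """Short digest of the analysis-relevant parameters."""
        d = self.to_dict()
        d.pop("output_dir", None)  # where results go does not change them
        blob = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
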