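"""Pipeline configuration with the analysis defaults.

Every analysis parameter is surfaced as a named field; the defaults are the
standard choices for this analysis: band-pass 0.009-0.08 Hz, network
densities 5/10/15%, Louvain resolution gamma = 1 with 100 restarts,
group activation threshold z = 2.32, and 10,000 permutations.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .synth import CohortSpec

__all__ = ["PipelineConfig", "validate_config"]


@dataclass
class PipelineConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    band: tuple[float, float] = (0.009, 0.08)
    densities: tuple[float, ...] = (0.05, 0.10, 0.15)
    gamma: float = 1.0
    restarts: int = 100
    z_threshold: float = 2.32
    n_perm: int = 10_000
    fdr_method: str = "bh"
    n_null: int = 1000
    consensus: bool = False
    seed: int = 0
    out_dir: str = "netreconf_out"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        cohort_raw = raw.pop("cohort", {})
        for key in ("states", "encodings"):
            if key in cohort_raw:
                cohort_raw[key] = tuple(cohort_raw[key])
        cohort = CohortSpec(**cohort_raw)
        known = {f.name for f in fields(cls)} - {"cohort"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        if "densities" in raw:
            raw["densities"] = tuple(raw["densities"])
        return cls(cohort=cohort, **raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band"] = list(self.band)
        d["densities"] = list(self.densities)
        d["cohort"]["states"] = list(self.cohort.states)
        d["cohort"]["encodings"] = list(self.cohort.encodings)
        return d


def validate_config(config: PipelineConfig) -> list[str]:
    """Check all config invariants; returns a list of violations (empty if
    valid)."""
    errors: list[str] = []
    try:
        config.cohort.validate()
    except ValueError as exc:
        errors.append(str(exc))
    low, high = config.band
    if not (0 < low < high):
        errors.append("band: need 0 < low < high")
    nyquist = 0.5 / config.cohort.tr
    if high >= nyquist:
        errors.append(f"band: high cut {high} >= Nyquist {nyquist:.4f}")
    for d in config.densities:
        if not (0 < d <= 1):
            errors.append(f"densities: {d} outside (0, 1]")
    if not config.densities:
        errors.append("densities: at least one density required")
    if config.restarts < 1:
        errors.append("restarts must be >= 1")
    if config.n_perm < 100:
        errors.append("n_perm must be >= 100")
    if config.fdr_method not in ("bh", "storey"):
        errors.append("fdr_method must be 'bh' or 'storey'")
    if config.gamma <= 0:
        errors.append("gamma must be positive")
    return errors
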