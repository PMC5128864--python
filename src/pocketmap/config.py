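"""Run configuration shared by the pipeline stages and the CLI.

A flat key=value text file with CLI-flag overrides; precedence is
CLI > file > defaults, so every cutoff that shaped a result is auditable in
the run log.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

from .pockets import DEFAULT_CLUSTER_CUTOFF, DEFAULT_CONTACT_CUTOFF
from .tessellation import DEFAULT_R_MAX, DEFAULT_R_MIN

__all__ = ["RunConfig", "load_config_file"]


@dataclass
class RunConfig:
    """All tunable cutoffs and selections for a pipeline run.

    Units are Å throughout. ``occupation_cutoff`` defaults to the 1.6 Å
    alpha-atom-to-ligand-atom occupation criterion; the remaining defaults
    are package conventions, not literature constants.
    """

    r_min: float = DEFAULT_R_MIN
    r_max: float = DEFAULT_R_MAX
    cluster_cutoff: float = DEFAULT_CLUSTER_CUTOFF
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
    occupation_cutoff: float = 1.6
    salt_bridge_cutoff: float = 4.0
    cluster_method: str = "average"
    contact_mode: str = "alpha"
    heavy_only: bool = True
    receptor_sel: str = "chain A"
    ligand_sel: str = "chain B"
    frame_start: int = 0
    frame_stop: int = -1  # -1: all frames
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        for name in (
            "cluster_cutoff", "contact_cutoff", "occupation_cutoff",
            "salt_bridge_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.r_min > self.r_max:
            raise ValueError(f"r_min {self.r_min} > r_max {self.r_max}")
        if self.r_min < 0:
            raise ValueError("r_min must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_sources(cls, file_values: dict | None = None, **overrides) -> "RunConfig":
        """Build a config with precedence CLI overrides > file > defaults."""
        values: dict = {}
        if file_values:
            values.update(file_values)
        values.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name: f.type for f in fields(cls)}
        unknown = set(values) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**values)


_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def load_config_file(path) -> dict:
    """Parse a flat ``key = value`` config file; '#' starts a comment."""
    values: dict = {}
    float_keys = {
        "r_min", "r_max", "cluster_cutoff", "contact_cutoff",
        "occupation_cutoff", "salt_bridge_cutoff",
    }
    int_keys = {"frame_start", "frame_stop", "seed"}
    bool_keys = {"heavy_only"}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (t.strip() for t in line.split("=", 1))
            if key in float_keys:
                values[key] = float(value)
            elif key in int_keys:
                values[key] = int(value)
            elif key in bool_keys:
                values[key] = _BOOL[value.lower()]
            else:
                values[key] = value
    return values
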