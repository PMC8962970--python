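"""Run configuration with lossless TOML round-trip."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .cnlad import DenoiseConfig


@dataclass
class RunConfig:
    """Everything a reproducible run needs: pipeline tunables plus seed."""

    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    seed: int = 0
    out_dir: str = "."

    def to_toml(self, path: str | Path) -> None:
        lines = [f"seed = {self.seed}", f'out_dir = "{self.out_dir}"', "", "[denoise]"]
        for f in dataclasses.fields(DenoiseConfig):
            v = getattr(self.denoise, f.name)
            if v is None:
                continue  # absent key means "auto"
            if isinstance(v, bool):
                lines.append(f"{f.name} = {'true' if v else 'false'}")
            elif isinstance(v, (int, float)):
                lines.append(f"{f.name} = {v}")
            else:
                lines.append(f'{f.name} = "{v}"')
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        data = tomllib.loads(Path(path).read_text())
        known_top = {"seed", "out_dir", "denoise"}
        unknown = set(data) - known_top
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        dn = data.get("denoise", {})
        valid = {f.name for f in dataclasses.fields(DenoiseConfig)}
        bad = set(dn) - valid
        if bad:
            raise ValueError(f"unknown [denoise] keys: {sorted(bad)}")
        return cls(
            denoise=DenoiseConfig(**dn),
            seed=int(data.get("seed", 0)),
            out_dir=str(data.get("out_dir", ".")),
        )
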