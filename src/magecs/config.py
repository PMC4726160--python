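"""Design configuration: reagent sequences and conventions, from YAML.

The scaffold, repeat and USER-tail sequences are properties of the user's
constructs; the toolkit refuses to invent them.  A config file looks like::

    scaffold: GTTTTAGAGCTA...      # sgRNA scaffold (crRNA-repeat/tracrRNA fusion)
    repeat: GTTTTAGAGCTATGCT...    # 30-nt pre-crRNA array repeat
    tail_f: ACGTACGTAC             # 10-nt USER tails matching the backbone
    tail_r: TGCATGCATG
    oligo_size: 70
    window_size: 70
    replichore:
      ori: 3925744
      ter: 1590754
      convention: {1: "-", 2: "+"}
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .assembly import DEFAULT_OLIGO_SIZE
from .design import DEFAULT_WINDOW
from .seqmodel import InputError

__all__ = ["DesignConfig"]


@dataclass
class DesignConfig:
    scaffold: str | None = None
    repeat: str | None = None
    tail_f: str | None = None
    tail_r: str | None = None
    oligo_size: int = DEFAULT_OLIGO_SIZE
    window_size: int = DEFAULT_WINDOW
    ori: int | None = None
    ter: int | None = None
    strand_convention: dict[int, str] = field(
        default_factory=lambda: {1: "-", 2: "+"})
    phosphorothioate_5prime: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DesignConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        rep = raw.pop("replichore", None) or {}
        conv = rep.get("convention")
        cfg = cls(
            scaffold=raw.get("scaffold"),
            repeat=raw.get("repeat"),
            tail_f=raw.get("tail_f"),
            tail_r=raw.get("tail_r"),
            oligo_size=int(raw.get("oligo_size", DEFAULT_OLIGO_SIZE)),
            window_size=int(raw.get("window_size", DEFAULT_WINDOW)),
            ori=rep.get("ori"),
            ter=rep.get("ter"),
            phosphorothioate_5prime=int(raw.get("phosphorothioate_5prime", 0)),
        )
        if conv:
            cfg.strand_convention = {int(k): str(v) for k, v in conv.items()}
        return cfg

    def require(self, name: str) -> str:
        value = getattr(self, name)
        if not value:
            raise InputError(
                f"config value {name!r} is required for this operation and "
                "has no default (it is construct-specific)"
            )
        return value

    def to_yaml(self, path: str | Path) -> None:
        data: dict = {
            k: v for k, v in {
                "scaffold": self.scaffold,
                "repeat": self.repeat,
                "tail_f": self.tail_f,
                "tail_r": self.tail_r,
                "oligo_size": self.oligo_size,
                "window_size": self.window_size,
                "phosphorothioate_5prime": self.phosphorothioate_5prime,
            }.items() if v is not None
        }
        if self.ori is not None and self.ter is not None:
            data["replichore"] = {
                "ori": self.ori, "ter": self.ter,
                "convention": self.strand_convention,
            }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
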