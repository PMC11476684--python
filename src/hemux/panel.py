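"""Marker panel: the ordered list of protein markers shared by every module.

The panel order is the single source of truth — column ``m`` of every
expression / embedding / call matrix in this package refers to
``panel.names[m]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Default 16-marker colorectal-cancer CyCIF panel.
CRC_PANEL_NAMES = (
    "cytokeratin",
    "Ki-67",
    "CD3",
    "CD20",
    "CD45RO",
    "CD4",
    "CD8a",
    "CD68",
    "CD163",
    "FOXP3",
    "PD1",
    "PDL1",
    "CD31",
    "aSMA",
    "desmin",
    "CD45",
)


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered, unique marker identifiers (length ``M``)."""

    names: tuple[str, ...] = field(default=CRC_PANEL_NAMES)

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(names) == 0:
            raise ValueError("marker panel must be non-empty")
        if any(not n for n in names):
            raise ValueError("marker names must be non-empty strings")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate marker names: {dupes}")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown marker {name!r}; panel is {list(self.names)}"
            ) from None

    @classmethod
    def from_file(cls, path: str | Path) -> "MarkerPanel":
        """Load a panel from a YAML list or a plain one-name-per-line file."""
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if isinstance(loaded, dict) and "markers" in loaded:
            loaded = loaded["markers"]
        if isinstance(loaded, str):
            loaded = [ln.strip() for ln in text.splitlines() if ln.strip()]
        if not isinstance(loaded, list):
            raise ValueError(f"cannot interpret {path} as a marker list")
        return cls(tuple(str(n) for n in loaded))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(list(self.names)))
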