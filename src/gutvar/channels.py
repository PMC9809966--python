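"""Flow-cytometry channel sets.

The CytoFLEX S panel used throughout this package records 23 scatter and
fluorescence parameters per event; classifiers and the heterogeneity
statistic operate on all of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The 23-parameter CytoFLEX S panel (area/height pairs plus FSC width).
DEFAULT_CHANNEL_NAMES: tuple[str, ...] = (
    "FSC-A", "FSC-H", "SSC-A", "SSC-H",
    "FL1-A", "FL1-H",
    "FL2-orange-A", "FL2-orange-H",
    "FL3-red-A", "FL3-red-H",
    "FL4-A", "FL4-H",
    "APC-A750-A", "APC-A750H",
    "VSSC-A", "VSSC-H",
    "KO525-A", "KO252-H",
    "mCherry-A", "mCherry-H",
    "PI-A", "PI-H",
    "FSC-Width",
)


@dataclass(frozen=True)
class ChannelSet:
    """An ordered, duplicate-free collection of channel names."""

    names: tuple[str, ...] = field(default=DEFAULT_CHANNEL_NAMES)

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if not names:
            raise ValueError("ChannelSet must contain at least one channel")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate channel names: {dupes}")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None

    def validate_against(self, expected: "ChannelSet") -> None:
        """Raise if any expected channel is absent, naming the missing ones."""
        missing = [n for n in expected.names if n not in self.names]
        if missing:
            raise ValueError(f"missing channels: {missing}")

    def rename(self, alias_map: dict[str, str]) -> "ChannelSet":
        """Map instrument-specific names onto canonical ones."""
        return ChannelSet(tuple(alias_map.get(n, n) for n in self.names))


DEFAULT_CHANNELS = ChannelSet(DEFAULT_CHANNEL_NAMES)
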