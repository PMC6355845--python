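"""Facies class scheme for cold-water coral mound mapping.

Seven mapped facies plus an ``OTHER`` bucket (shadows, rare mobile fauna)
that is generated but excluded from training and accuracy metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ClassScheme", "DEFAULT_SCHEME"]


@dataclass(frozen=True)
class ClassScheme:
    """Ordered facies codes, display names, hierarchy tags and raster ids."""

    codes: tuple[str, ...] = ("LCN", "DC", "SPG", "HEMS", "HESDR", "CRUB", "PEB")
    excluded: str = "OTHER"
    display_names: dict = field(
        default_factory=lambda: {
            "LCN": "Live coral framework",
            "DC": "Dead coral framework",
            "SPG": "Sponges",
            "HEMS": "Hemipelagic sediments",
            "HESDR": "Hemipelagic sediments with dropstones",
            "CRUB": "Coral rubble",
            "PEB": "Pebbles",
            "OTHER": "Other / non-classified",
        }
    )
    hierarchy: dict = field(
        default_factory=lambda: {
            "LCN": "Biogenic",
            "DC": "Biogenic",
            "SPG": "Biogenic",
            "HEMS": "Sediment",
            "HESDR": "Sediment",
            "CRUB": "Sediment",
            "PEB": "Sediment",
            "OTHER": "Other",
        }
    )

    def __post_init__(self):
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("class codes must be unique")
        if self.excluded in self.codes:
            raise ValueError("the excluded code must not be a mapped class")

    @property
    def all_codes(self) -> tuple[str, ...]:
        """Mapped classes followed by the excluded bucket."""
        return self.codes + (self.excluded,)

    def id_of(self, code: str) -> int:
        """Raster label id: mapped classes are 1..K in order, excluded is K+1."""
        return self.all_codes.index(code) + 1

    def code_of(self, label_id: int) -> str:
        return self.all_codes[label_id - 1]

    @property
    def n_classes(self) -> int:
        return len(self.codes)


DEFAULT_SCHEME = ClassScheme()
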