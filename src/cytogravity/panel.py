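"""Mass-cytometry antibody panel configuration.

The default panel mirrors a 41-parameter immune-monitoring assay: 21 surface
(phenotyping) markers that drive the gating hierarchy, 14 functional markers
(signaling phospho-epitopes and activation markers) whose stimulated levels
constitute the response features, and 6 palladium barcode channels used for
combinatorial sample multiplexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

SURFACE = "surface"
FUNCTIONAL = "functional"
BARCODE = "barcode"

_CLASSES = (SURFACE, FUNCTIONAL, BARCODE)


@dataclass(frozen=True)
class Marker:
    """One antibody/isotope channel: a marker name, its metal tag, and its class."""

    name: str
    channel: str
    cls: str

    def __post_init__(self) -> None:
        if self.cls not in _CLASSES:
            raise ValueError(f"marker class must be one of {_CLASSES}, got {self.cls!r}")


@dataclass
class PanelConfig:
    """Channel inventory plus the arcsinh cofactor used for transformation.

    Parameters
    ----------
    markers
        Ordered list of :class:`Marker`. Marker names must be unique; the
        order defines the canonical channel order of event tables.
    cofactor
        Arcsinh scale factor (``asinh(x / cofactor)``); must be positive.
        The mass-cytometry community default is 5.
    """

    markers: list[Marker] = field(default_factory=list)
    cofactor: float = 5.0

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")
        if not self.cofactor > 0:
            raise ValueError(f"cofactor must be positive, got {self.cofactor}")

    def _names(self, cls: str) -> list[str]:
        return [m.name for m in self.markers if m.cls == cls]

    @property
    def surface_markers(self) -> list[str]:
        return self._names(SURFACE)

    @property
    def functional_markers(self) -> list[str]:
        return self._names(FUNCTIONAL)

    @property
    def barcode_markers(self) -> list[str]:
        return self._names(BARCODE)

    @property
    def channel_names(self) -> list[str]:
        return [m.name for m in self.markers]

    @property
    def n_channels(self) -> int:
        return len(self.markers)

    def marker_class(self, name: str) -> str:
        for m in self.markers:
            if m.name == name:
                return m.cls
        raise KeyError(f"marker {name!r} not in panel")

    def __contains__(self, name: str) -> bool:
        return any(m.name == name for m in self.markers)

    def to_yaml(self, path: str) -> None:
        payload = {
            "cofactor": float(self.cofactor),
            "markers": [
                {"name": m.name, "channel": m.channel, "class": m.cls}
                for m in self.markers
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PanelConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        markers = [
            Marker(m["name"], m["channel"], m["class"]) for m in payload["markers"]
        ]
        return cls(markers=markers, cofactor=float(payload["cofactor"]))


# (name, metal channel) pairs; channels are plausible CyTOF metal assignments.
_SURFACE = [
    ("CD45", "Y89Di"),
    ("CD7", "In113Di"),
    ("CD19", "Nd142Di"),
    ("CD45RA", "Nd143Di"),
    ("CD11c", "Nd144Di"),
    ("CD4", "Nd145Di"),
    ("CD8a", "Nd146Di"),
    ("CD14", "Gd160Di"),
    ("CD56", "Dy161Di"),
    ("FoxP3", "Dy162Di"),
    ("CD33", "Dy163Di"),
    ("CD123", "Dy164Di"),
    ("TCRgd", "Ho165Di"),
    ("CD27", "Er166Di"),
    ("CD16", "Er167Di"),
    ("CD61", "Er168Di"),
    ("CD127", "Tm169Di"),
    ("CD3", "Er170Di"),
    ("CD161", "Yb171Di"),
    ("CD24", "Yb172Di"),
    ("HLA-DR", "Yb174Di"),
]

_FUNCTIONAL = [
    ("CD25", "Pr141Di"),
    ("CD69", "Sm147Di"),
    ("pSTAT1", "Nd148Di"),
    ("pSTAT3", "Sm149Di"),
    ("pSTAT4", "Nd150Di"),
    ("pSTAT5", "Eu151Di"),
    ("pSTAT6", "Sm152Di"),
    ("pNFkB", "Eu153Di"),
    ("IkB", "Sm154Di"),
    ("pMAPKAPK2", "Gd155Di"),
    ("pP38", "Gd156Di"),
    ("prpS6", "Gd158Di"),
    ("pERK1/2", "Tb159Di"),
    ("pCREB", "Lu175Di"),
]

_BARCODE = [
    ("Pd102", "Pd102Di"),
    ("Pd104", "Pd104Di"),
    ("Pd105", "Pd105Di"),
    ("Pd106", "Pd106Di"),
    ("Pd108", "Pd108Di"),
    ("Pd110", "Pd110Di"),
]


def default_panel(cofactor: float = 5.0) -> PanelConfig:
    """The default 41-channel panel: 21 surface + 14 functional + 6 barcode."""
    markers = (
        [Marker(n, c, SURFACE) for n, c in _SURFACE]
        + [Marker(n, c, FUNCTIONAL) for n, c in _FUNCTIONAL]
        + [Marker(n, c, BARCODE) for n, c in _BARCODE]
    )
    return PanelConfig(markers=markers, cofactor=cofactor)
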