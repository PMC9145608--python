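"""Plate-layout configuration: wells, condition roles, channel assignments.

A layout names every well of a plate with its condition role, drug,
concentration (uM) and replicate index, plus the plate-wide channel map
(channel name -> stain). Condition roles:

* ``treated`` / ``untreated`` — the drug series and its normalisation anchor;
* ``CT`` — background control (untreated, secondary antibody only), anchors
  the marker gates;
* ``positive_control`` — e.g. a high-concentration topoisomerase-I-inhibitor
  well used to set exposures;
* ``single_stain:<marker>`` — one-marker wells for the channel-overlap check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

CORE_STAINS = {"hoechst", "pi", "calcein"}
ROLES = {"treated", "untreated", "CT", "positive_control"}


@dataclass
class WellSpec:
    address: str  # e.g. "A1"
    role: str  # see module docstring
    drug: str = ""
    concentration: float = 0.0  # uM
    replicate: int = 1


@dataclass
class PlateLayout:
    plate_id: str
    channels: dict[str, str]  # channel name -> stain/marker
    wells: list[WellSpec] = field(default_factory=list)

    @property
    def marker_channels(self) -> list[str]:
        """Channels that are DDR markers (not nuclear/viability stains)."""
        return [ch for ch in self.channels if ch not in CORE_STAINS]

    def wells_with_role(self, role: str) -> list[WellSpec]:
        return [w for w in self.wells if w.role == role]

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "plate_id": self.plate_id,
            "channels": dict(self.channels),
            "wells": [
                {
                    "address": w.address,
                    "role": w.role,
                    "drug": w.drug,
                    "concentration": w.concentration,
                    "replicate": w.replicate,
                }
                for w in self.wells
            ],
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlateLayout":
        text = Path(path).read_text()
        try:
            payload = yaml.safe_load(text)
        except yaml.YAMLError as err:
            mark = getattr(err, "problem_mark", None)
            where = f" at line {mark.line + 1}" if mark else ""
            raise ValueError(f"unparseable layout file {path}{where}: {err}") from err
        if not isinstance(payload, dict):
            raise ValueError(f"layout file {path} is not a mapping")
        wells = [WellSpec(**w) for w in payload.get("wells", [])]
        return cls(
            plate_id=str(payload.get("plate_id", "plate")),
            channels=dict(payload.get("channels", {})),
            wells=wells,
        )


def validate_layout(layout: PlateLayout) -> list[str]:
    """Return every invariant violation in the layout (empty list = valid)."""
    violations: list[str] = []

    seen: set[str] = set()
    for w in layout.wells:
        if w.address in seen:
            violations.append(f"duplicate well address {w.address!r}")
        seen.add(w.address)

    for w in layout.wells:
        base = w.role.split(":", 1)[0]
        if base not in ROLES and base != "single_stain":
            violations.append(f"well {w.address!r}: unknown role {w.role!r}")
        if w.concentration < 0:
            violations.append(
                f"well {w.address!r}: negative concentration {w.concentration}"
            )

    treated_drugs = {w.drug for w in layout.wells_with_role("treated")}
    has_untreated = bool(layout.wells_with_role("untreated"))
    for drug in sorted(treated_drugs):
        if not has_untreated:
            violations.append(
                f"treated series {drug!r} has no untreated well "
                "(normalisation undefined)"
            )

    if layout.marker_channels and not layout.wells_with_role("CT"):
        violations.append(
            "marker gating requested "
            f"(channels {layout.marker_channels}) but no CT well present"
        )

    if layout.wells and "hoechst" not in layout.channels:
        violations.append("no 'hoechst' channel assigned; segmentation impossible")

    for w in layout.wells:
        if w.role.startswith("single_stain:"):
            marker = w.role.split(":", 1)[1]
            if marker not in layout.marker_channels:
                violations.append(
                    f"well {w.address!r}: single-stain marker {marker!r} "
                    "not among plate channels"
                )

    return violations
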