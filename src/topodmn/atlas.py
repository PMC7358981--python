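"""Default mode network node atlas.

The DMN is modelled as a 26-node subgraph of the AAL90 parcellation:
13 homologous region pairs, one node per hemisphere. Nodes are kept in a
fixed canonical order (atlas row pairs, left before right, positions
0..25); every matrix in the package uses this ordering. In AAL90, odd
region indices are left-hemisphere and even indices right-hemisphere.

The atlas ships as a tab-separated data file so other parcellations can
be substituted without code changes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = ["Hemisphere", "Scope", "RoiNode", "load_atlas", "scope_indices"]


class Hemisphere(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class Scope(str, enum.Enum):
    """Which part of the network an analysis runs on."""

    BOTH = "both"
    LEFT = "left"
    RIGHT = "right"

    @classmethod
    def coerce(cls, value: "Scope | str") -> "Scope":
        if isinstance(value, Scope):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValueError(
                f"unknown scope {value!r}; expected one of "
                f"{[s.value for s in cls]}"
            ) from None


@dataclass(frozen=True)
class RoiNode:
    """One region of interest (a network node)."""

    aal_index: int
    abbreviation: str
    hemisphere: Hemisphere
    name: str

    def __post_init__(self) -> None:
        if not 1 <= self.aal_index <= 90:
            raise ValueError(f"aal_index {self.aal_index} outside 1..90")
        expected = Hemisphere.LEFT if self.aal_index % 2 == 1 else Hemisphere.RIGHT
        if self.hemisphere is not expected:
            raise ValueError(
                f"aal_index {self.aal_index} parity implies {expected.value}, "
                f"got {self.hemisphere.value}"
            )
        suffix = ".L" if self.hemisphere is Hemisphere.LEFT else ".R"
        if not self.abbreviation.endswith(suffix):
            raise ValueError(
                f"abbreviation {self.abbreviation!r} does not end in {suffix!r}"
            )


def _default_atlas_path() -> Path:
    return Path(str(resources.files("topodmn").joinpath("data/dmn_aal90.tsv")))


def load_atlas(path: str | Path | None = None) -> list[RoiNode]:
    """Load the ROI atlas, in canonical node order.

    Parameters
    ----------
    path
        Tab-separated file with header ``aal_index  abbreviation
        hemisphere  name``. Defaults to the packaged 26-node DMN atlas.
    """
    path = Path(path) if path is not None else _default_atlas_path()
    nodes: list[RoiNode] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["aal_index", "abbreviation", "hemisphere", "name"]:
            raise ValueError(f"unexpected atlas header in {path}: {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            idx, abbr, hemi, name = line.split("\t")
            nodes.append(RoiNode(int(idx), abbr, Hemisphere(hemi), name))
    seen = [n.aal_index for n in nodes]
    if len(set(seen)) != len(seen):
        raise ValueError("duplicate aal_index in atlas")
    return nodes


def scope_indices(scope: Scope | str, atlas: list[RoiNode] | None = None) -> list[int]:
    """Row positions (into the canonical node order) selected by *scope*."""
    scope = Scope.coerce(scope)
    if atlas is None:
        atlas = load_atlas()
    if scope is Scope.BOTH:
        return list(range(len(atlas)))
    hemi = Hemisphere.LEFT if scope is Scope.LEFT else Hemisphere.RIGHT
    return [i for i, node in enumerate(atlas) if node.hemisphere is hemi]
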