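"""Electrode montage handling.

A montage is a table of lead names with 2-D scalp coordinates on the unit
disk (azimuthal-equidistant projection, nasion at the top, left ear at
negative x).  The package ships a 63-lead 10-10 montage derived from the
standard spherical electrode positions; any montage can be supplied as a
CSV with columns ``lead_name, x, y``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 17 posterior leads (parietal, parieto-occipital, occipital) whose
#: spectrograms are stacked into the model's input tensor, in the fixed
#: order used throughout the package (left-to-right within each row,
#: posterior rows last).
POSTERIOR_17 = (
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)

#: Frequency band (Hz) conventionally called alpha; the default location of
#: the class-dependent power modulation in the synthetic generator.
ALPHA_BAND = (8.0, 13.0)


@dataclass(frozen=True)
class Montage:
    """Lead names with unit-disk scalp coordinates."""

    lead_names: tuple[str, ...]
    coords: np.ndarray  # (n_leads, 2), inside the unit disk
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (len(self.lead_names), 2):
            raise ValueError(
                f"coords shape {coords.shape} does not match "
                f"{len(self.lead_names)} lead names"
            )
        if np.any(np.hypot(coords[:, 0], coords[:, 1]) > 1.0 + 1e-9):
            raise ValueError("montage coordinates must lie inside the unit disk")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(
            self, "_index", {name: i for i, name in enumerate(self.lead_names)}
        )

    def __len__(self) -> int:
        return len(self.lead_names)

    def index_of(self, names: "list[str] | tuple[str, ...]") -> np.ndarray:
        """Row indices of ``names``, raising on any absent lead."""
        missing = [n for n in names if n not in self._index]
        if missing:
            raise KeyError(f"leads not in montage: {missing}")
        return np.array([self._index[n] for n in names], dtype=int)

    def subset(self, names: "list[str] | tuple[str, ...]") -> "Montage":
        idx = self.index_of(names)
        return Montage(tuple(names), self.coords[idx])

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"lead_name": self.lead_names,
             "x": self.coords[:, 0],
             "y": self.coords[:, 1]}
        ).to_csv(path, index=False)


def load_montage(path) -> Montage:
    """Read a montage CSV with columns ``lead_name, x, y``."""
    df = pd.read_csv(path)
    required = {"lead_name", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"montage CSV must have columns {sorted(required)}")
    return Montage(
        tuple(str(n) for n in df["lead_name"]),
        df[["x", "y"]].to_numpy(dtype=float),
    )


def default_montage() -> Montage:
    """The packaged 63-lead 10-10 montage."""
    ref = importlib.resources.files("wavefusion.data").joinpath("montage_63.csv")
    with importlib.resources.as_file(ref) as path:
        return load_montage(path)


def posterior_montage() -> Montage:
    """The 17 posterior leads of the default montage."""
    return default_montage().subset(POSTERIOR_17)
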