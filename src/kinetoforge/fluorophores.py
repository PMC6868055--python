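"""Labeled 3D point-emitter sets and their on-disk formats.

A :class:`FluorophoreSet` is the common currency between the structural
models (spindle/kinetochore geometry, polymer snapshots) and the image
renderer: a table of point emitters with nm coordinates, a color-channel
label and a photon-scale intensity.

Two interchange formats are supported: a flat CSV (``x_nm,y_nm,z_nm,
channel,intensity``) and a point-fluorophore XML dialect (one element per
emitter with position attributes, grouped by channel) compatible with
external renderers that consume per-fluorophore position lists.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["FluorophoreSet", "concat"]


@dataclass
class FluorophoreSet:
    """A set of point emitters in 3D.

    Parameters
    ----------
    xyz : (n, 3) float array
        Emitter positions in nm.
    channels : (n,) array of str
        Color-channel label per emitter (e.g. ``"green"``, ``"red"``).
    intensity : (n,) float array, optional
        Relative photon yield per emitter; defaults to 1.0 each.
    provenance : dict
        Free-form snapshot of the generating model parameters and seed.
    """

    xyz: np.ndarray
    channels: np.ndarray
    intensity: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        n = len(self.xyz)
        self.channels = np.asarray(self.channels, dtype=object).reshape(-1)
        if len(self.channels) == 1 and n > 1:
            self.channels = np.repeat(self.channels, n)
        if self.intensity is None:
            self.intensity = np.ones(n, dtype=float)
        else:
            self.intensity = np.asarray(self.intensity, dtype=float).reshape(-1)
        if not (len(self.channels) == len(self.intensity) == n):
            raise ValueError("xyz, channels and intensity lengths disagree")
        if n and not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite fluorophore coordinate")
        if n and np.any(self.intensity <= 0):
            raise ValueError("fluorophore intensity must be > 0")

    def __len__(self) -> int:
        return len(self.xyz)

    def select_channel(self, channel: str) -> "FluorophoreSet":
        m = self.channels == channel
        return FluorophoreSet(self.xyz[m], self.channels[m],
                              self.intensity[m], dict(self.provenance))

    def restrict_channels(self, allowed: Iterable[str]) -> "FluorophoreSet":
        allowed = set(allowed)
        m = np.array([c in allowed for c in self.channels], dtype=bool)
        return FluorophoreSet(self.xyz[m], self.channels[m],
                              self.intensity[m], dict(self.provenance))

    # ------------------------------------------------------------------ CSV
    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({
            "x_nm": self.xyz[:, 0], "y_nm": self.xyz[:, 1],
            "z_nm": self.xyz[:, 2], "channel": self.channels,
            "intensity": self.intensity,
        })
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FluorophoreSet":
        df = pd.read_csv(path)
        required = {"x_nm", "y_nm", "z_nm", "channel", "intensity"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"fluorophore CSV missing columns: {sorted(missing)}")
        return cls(df[["x_nm", "y_nm", "z_nm"]].to_numpy(float),
                   df["channel"].astype(str).to_numpy(object),
                   df["intensity"].to_numpy(float),
                   {"source": str(path)})

    # ------------------------------------------------------------------ XML
    def to_xml(self, path: str | Path) -> None:
        """Write the per-channel point-fluorophore XML dialect."""
        root = ET.Element("SimulatedFluorescence")
        for ch in sorted(set(self.channels)):
            sub = self.select_channel(ch)
            model = ET.SubElement(root, "FluorophoreModel", channel=str(ch))
            for (x, y, z), inten in zip(sub.xyz, sub.intensity):
                ET.SubElement(model, "Fluorophore",
                              x=repr(float(x)), y=repr(float(y)),
                              z=repr(float(z)), intensity=repr(float(inten)))
        ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")

    @classmethod
    def from_xml(cls, path: str | Path) -> "FluorophoreSet":
        root = ET.parse(path).getroot()
        xyz, chans, inten = [], [], []
        for model in root.iter("FluorophoreModel"):
            ch = model.get("channel")
            if ch is None:
                raise ValueError("FluorophoreModel element lacks 'channel' attribute")
            for f in model.iter("Fluorophore"):
                try:
                    xyz.append((float(f.get("x")), float(f.get("y")), float(f.get("z"))))
                    inten.append(float(f.get("intensity", "1.0")))
                except (TypeError, ValueError) as exc:
                    raise ValueError("malformed Fluorophore element: "
                                     "expected numeric x, y, z attributes") from exc
                chans.append(ch)
        return cls(np.array(xyz, dtype=float).reshape(-1, 3),
                   np.array(chans, dtype=object), np.array(inten, dtype=float),
                   {"source": str(path)})


def concat(sets: Iterable[FluorophoreSet],
           provenance: Mapping | None = None) -> FluorophoreSet:
    """Concatenate fluorophore sets into one, keeping channel labels."""
    sets = [s for s in sets if len(s)]
    if not sets:
        return FluorophoreSet(np.empty((0, 3)), np.empty(0, dtype=object),
                              np.empty(0), dict(provenance or {}))
    return FluorophoreSet(
        np.vstack([s.xyz for s in sets]),
        np.concatenate([s.channels for s in sets]),
        np.concatenate([s.intensity for s in sets]),
        dict(provenance or {}),
    )
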