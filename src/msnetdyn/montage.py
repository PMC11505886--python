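"""Synthetic 2-D scalp layout with named regions.

A deterministic sunflower-spiral layout on the unit disk stands in for a
10-10 electrode cap: it works for any channel count and gives every channel
a 2-D coordinate plus a coarse anatomical region label, which is all that
region-level statements ("left-frontal", "occipital") require.
Orientation convention: +y is anterior (nose), +x is the subject's right.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

REGIONS = (
    "frontal-left",
    "frontal-medial",
    "frontal-right",
    "central",
    "parietal",
    "occipital",
)


def _region(x: float, y: float) -> str:
    if y > 0.3:
        if x < -0.18:
            return "frontal-left"
        if x > 0.18:
            return "frontal-right"
        return "frontal-medial"
    if y > -0.15:
        return "central"
    if y > -0.55:
        return "parietal"
    return "occipital"


def scalp_montage(n_channels: int) -> pd.DataFrame:
    """Channel position table: columns x, y, region, label (index = channel).

    Channels are placed on a sunflower spiral so that any ``n_channels`` >= 8
    covers the disk roughly uniformly; the layout is a pure function of the
    channel count.
    """
    if n_channels < 8:
        raise ValueError("too few channels to express topographies")
    i = np.arange(n_channels)
    r = np.sqrt((i + 0.5) / n_channels)
    th = i * GOLDEN_ANGLE
    x = r * np.cos(th)
    y = r * np.sin(th)
    regions = [_region(xi, yi) for xi, yi in zip(x, y)]
    counters: dict = {}
    labels = []
    for reg in regions:
        counters[reg] = counters.get(reg, 0) + 1
        prefix = "".join(w[0].upper() for w in reg.split("-"))
        labels.append(f"{prefix}{counters[reg]}")
    return pd.DataFrame({"x": x, "y": y, "region": regions, "label": labels})


def region_channels(montage: pd.DataFrame, region: str) -> np.ndarray:
    """Indices of channels whose region starts with ``region``.

    ``region_channels(m, "frontal")`` matches all three frontal strips.
    """
    mask = montage["region"].str.startswith(region)
    return np.flatnonzero(mask.to_numpy())
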