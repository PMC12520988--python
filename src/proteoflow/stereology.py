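"""Stereological point counting of tissue composition.

A systematic square grid (default spacing 62.25 um, so each point stands
for spacing^2 = 3875 um^2 of tissue) is overlaid on a classified section
image; every grid intersection is classified as myocardium, fibrosis or
adipose tissue by the pixel it falls in, and the per-section area fraction
of each component is the classified point count over the total points
assessed.  Background pixels (label 0 by default) fall outside the tissue
and are excluded from the total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

TISSUE_CLASSES = ("myocardium", "fibrosis", "adipose")
DEFAULT_SPACING_UM = 62.25


@dataclass
class GridCounts:
    """Per-section grid-point counts for the three tissue classes."""

    counts: pd.DataFrame          # sections x classes
    spacing_um: float = DEFAULT_SPACING_UM
    group: str = ""
    empty_sections: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.spacing_um <= 0:
            raise ValueError("grid spacing must be > 0")
        missing = set(TISSUE_CLASSES) - set(self.counts.columns)
        if missing:
            raise ValueError(f"counts lack classes: {sorted(missing)}")
        if (self.counts < 0).any().any():
            raise ValueError("counts must be >= 0")

    @property
    def totals(self) -> pd.Series:
        return self.counts[list(TISSUE_CLASSES)].sum(axis=1)

    @property
    def point_area_um2(self) -> float:
        return self.spacing_um ** 2


def overlay_grid(label_image: np.ndarray, pixel_size_um: float,
                 spacing_um: float = DEFAULT_SPACING_UM,
                 class_labels: dict[int, str] | None = None,
                 background: int = 0, section: str = "section_1",
                 random_offset: bool = False, seed: int = 0,
                 group: str = "") -> GridCounts:
    """Count grid points per tissue class on an integer label image.

    Points sit at (spacing/2 + i*spacing, spacing/2 + j*spacing) in um from
    the top-left origin (or at a uniform random offset within one grid cell
    when ``random_offset`` for unbiased stereology).  Each point takes the
    class of the pixel it falls in; background points are excluded from the
    total.
    """
    img = np.asarray(label_image)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("label image must be a non-empty 2-D array")
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be > 0")
    if spacing_um < pixel_size_um:
        raise ValueError("grid spacing must be at least one pixel")
    if class_labels is None:
        class_labels = {1: "myocardium", 2: "fibrosis", 3: "adipose"}
    h_um = img.shape[0] * pixel_size_um
    w_um = img.shape[1] * pixel_size_um
    if random_offset:
        rng = np.random.default_rng(seed)
        off_y, off_x = rng.uniform(0.0, spacing_um, size=2)
    else:
        off_y = off_x = spacing_um / 2.0
    ys = np.arange(off_y, h_um, spacing_um)
    xs = np.arange(off_x, w_um, spacing_um)
    rows = np.minimum((ys / pixel_size_um).astype(int), img.shape[0] - 1)
    cols = np.minimum((xs / pixel_size_um).astype(int), img.shape[1] - 1)
    labels = img[np.ix_(rows, cols)].ravel()
    counts = {c: 0 for c in TISSUE_CLASSES}
    for lab in labels:
        if lab == background:
            continue
        name = class_labels.get(int(lab))
        if name is None:
            raise ValueError(f"unmapped pixel label {int(lab)}")
        counts[name] += 1
    table = pd.DataFrame([counts], index=pd.Index([section], name="section"),
                         columns=list(TISSUE_CLASSES))
    empty = [section] if sum(counts.values()) == 0 else []
    return GridCounts(table, spacing_um=spacing_um, group=group, empty_sections=empty)


def read_points_table(path) -> GridCounts:
    """Pre-classified points TSV (section, x, y, class) -> per-section counts."""
    df = pd.read_csv(path, sep="\t")
    for col in ("section", "class"):
        if col not in df.columns:
            raise ValueError(f"points table needs a {col!r} column")
    bad = sorted(set(df["class"]) - set(TISSUE_CLASSES))
    if bad:
        raise ValueError(f"unknown tissue classes: {bad}")
    counts = (df.groupby(["section", "class"]).size().unstack(fill_value=0)
              .reindex(columns=list(TISSUE_CLASSES), fill_value=0))
    counts.index.name = "section"
    return GridCounts(counts)


def count_proportions(counts: GridCounts, exact: bool = False) -> pd.DataFrame:
    """Per-section proportion of each tissue class (counts / total).

    With ``exact`` the division is done in rational arithmetic, so each
    row sums to exactly 1.
    """
    totals = counts.totals
    if (totals < 1).any():
        empty = list(totals.index[totals < 1])
        raise ValueError(f"section(s) with zero assessed points: {empty}")
    if exact:
        data = [[Fraction(int(counts.counts.at[s, c]), int(totals[s]))
                 for c in TISSUE_CLASSES] for s in counts.counts.index]
        return pd.DataFrame(data, index=counts.counts.index, columns=list(TISSUE_CLASSES))
    return counts.counts[list(TISSUE_CLASSES)].div(totals, axis=0)


def summarize_composition(counts: GridCounts, groups=None) -> pd.DataFrame:
    """Median and IQR of each class proportion, overall or per group."""
    props = count_proportions(counts)
    if groups is not None:
        props = props.assign(_group=pd.Series(groups).reindex(props.index))
        grouped = props.groupby("_group")
        out = grouped.quantile([0.25, 0.5, 0.75]).unstack(level=-1)
        out.index.name = "group"
        return out
    return props.quantile([0.25, 0.5, 0.75]).T.rename(
        columns={0.25: "q1", 0.5: "median", 0.75: "q3"})
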