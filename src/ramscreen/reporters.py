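"""Quantitative arithmetic around reporter experiments.

Covers dual-luciferase normalization and fold induction, the
background-contamination model that converts a fold induction into a
labeling purity, ensemble-overlap percentages, cube-count density and
total-cell estimates from confocal stacks, and the three-point smoothing
used for longitudinal in vivo luminescence series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class LuciferaseMeasurement:
    """One firefly/renilla reading from a dual-luciferase assay."""

    firefly: float
    renilla: float
    condition: str = ""
    replicate: int | str = 0

    @property
    def relative(self) -> float:
        return relative_luciferase(self.firefly, self.renilla)


@dataclass(frozen=True)
class CellCountFrame:
    """Cell counts from one imaging field.

    n_markedA is the reporter-labeled population (e.g. RAM+), n_markedB the
    reference marker (e.g. FOS+, NPAS4+, GluR2/3+ or SST+), n_double the
    doubly labeled cells.  n_total (e.g. DAPI+ or EGFP+) is optional.
    """

    n_markedA: int
    n_double: int
    n_markedB: int | None = None
    n_total: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_markedA, self.n_double) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_double > self.n_markedA:
            raise ValueError("n_double exceeds n_markedA")
        if self.n_markedB is not None and self.n_double > self.n_markedB:
            raise ValueError("n_double exceeds n_markedB")
        if self.n_total is not None:
            for n in (self.n_markedA, self.n_markedB or 0, self.n_double):
                if n > self.n_total:
                    raise ValueError("marked counts exceed n_total")


def relative_luciferase(firefly: float, renilla: float) -> float:
    """Firefly signal normalized to the renilla transfection control."""
    if renilla <= 0:
        raise ValueError(f"renilla signal must be positive, got {renilla}")
    return firefly / renilla


def fold_induction(stimulated: float, unstimulated: float) -> float:
    """Ratio of normalized reporter signal, stimulated over unstimulated."""
    if unstimulated <= 0:
        raise ValueError(
            f"unstimulated signal must be positive, got {unstimulated}"
        )
    return stimulated / unstimulated


def labeling_purity(fold: float) -> float:
    """Percent of labeled cells attributable to the designated experience.

    Model: baseline (home-cage) labeling persists unchanged under the
    experience, so it makes up fraction 1/f of the induced count and

        purity = 100 * (1 - 1/f).

    A 5-fold induction implies 80% purity, 37-fold implies 97%; the 2-3-fold
    induction typical of earlier activity-labeling systems implies 50-67%.
    """
    if fold < 1:
        raise ValueError(f"fold induction must be >= 1, got {fold}")
    return 100.0 * (1.0 - 1.0 / fold)


def overlap_percentage(frame: CellCountFrame) -> float:
    """Percent of the labeled (A) population that also carries marker B."""
    if frame.n_markedA == 0:
        raise ValueError("no marked-A cells; overlap undefined")
    return 100.0 * frame.n_double / frame.n_markedA


def density_total_estimate(
    cells_counted: int,
    cube_volume: float,
    layer_area: float,
    thickness: float,
) -> tuple[float, float]:
    """(density, total): cells/um^3 in a counting cube, scaled to a layer.

    ``cells_counted`` excludes, by upstream counting convention, cells
    touching three of the six cube faces.  total = density * layer_area *
    thickness.
    """
    for name, v in (("cells_counted", cells_counted),
                    ("cube_volume", cube_volume),
                    ("layer_area", layer_area),
                    ("thickness", thickness)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    density = cells_counted / cube_volume
    return density, density * layer_area * thickness


def smooth3(series) -> np.ndarray:
    """Centered 3-point moving average; endpoints average their 2 available points."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("series must be 1-D with at least 3 points")
    return (
        pd.Series(x).rolling(window=3, center=True, min_periods=1).mean().to_numpy()
    )
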