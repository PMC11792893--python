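"""Domain types and CSV I/O for stomatal coordinate tables.

Coordinates are stored in mm with the origin at the lower-left corner of the
imaged window (x rightward, y upward); guard-cell lengths are in μm.  The
default window is the 0.386 mm² square field used throughout the package
(side 0.6213... mm).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Side length (mm) of the default square imaging window of area 0.386 mm².
DEFAULT_WINDOW_SIDE = math.sqrt(0.386)

#: Default CSV column names; override via the ``schema`` mapping.
DEFAULT_SCHEMA = {
    "plant_id": "plant_id",
    "leaf_id": "leaf_id",
    "surface": "surface",
    "treatment": "treatment",
    "x": "x_mm",
    "y": "y_mm",
    "length": "length_um",
    "window_width": "window_width_mm",
    "window_height": "window_height_mm",
}

SURFACES = ("abaxial", "adaxial")


class SchemaError(ValueError):
    """A required column is missing or a schema mapping is malformed."""


class ValidationError(ValueError):
    """A record violates a geometric or bookkeeping invariant."""


@dataclass(frozen=True)
class SurfaceRecord:
    """One imaged (or synthetic) leaf surface.

    Parameters
    ----------
    surface_id : str
        Unique identifier, conventionally ``"{plant}:{leaf}:{surface}"``.
    xy : (n, 2) ndarray of float
        Stomatal centroid coordinates in mm.
    lengths : (n,) ndarray of float, optional
        Guard-cell lengths in μm; ``None`` when unmeasured.
    window : (float, float)
        Width and height of the imaged window in mm.
    """

    surface_id: str
    plant_id: str = ""
    leaf_id: str = ""
    surface: str = "abaxial"
    treatment: str = ""
    window: tuple[float, float] = (DEFAULT_WINDOW_SIDE, DEFAULT_WINDOW_SIDE)
    xy: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        xy = np.atleast_2d(np.asarray(self.xy, dtype=float))
        if xy.size == 0:
            xy = np.empty((0, 2))
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ValidationError(f"{self.surface_id}: xy must be (n, 2), got {xy.shape}")
        object.__setattr__(self, "xy", xy)
        w, h = self.window
        if not (w > 0 and h > 0):
            raise ValidationError(f"{self.surface_id}: window area must be positive, got {self.window}")
        if self.surface not in SURFACES:
            raise ValidationError(f"{self.surface_id}: surface must be one of {SURFACES}, got {self.surface!r}")
        eps = 1e-12
        bad = np.where(
            (xy[:, 0] < -eps) | (xy[:, 0] > w + eps) | (xy[:, 1] < -eps) | (xy[:, 1] > h + eps)
        )[0]
        if bad.size:
            i = int(bad[0])
            raise ValidationError(
                f"{self.surface_id}: stomate {i} at ({xy[i, 0]:.4f}, {xy[i, 1]:.4f}) mm "
                f"lies outside the {w:.4f} x {h:.4f} mm window"
            )
        if self.lengths is not None:
            lengths = np.asarray(self.lengths, dtype=float)
            if lengths.shape != (xy.shape[0],):
                raise ValidationError(
                    f"{self.surface_id}: lengths shape {lengths.shape} does not match {xy.shape[0]} stomata"
                )
            if np.any(~np.isnan(lengths) & (lengths <= 0)):
                raise ValidationError(f"{self.surface_id}: stomatal lengths must be positive")
            object.__setattr__(self, "lengths", lengths)
        if xy.shape[0] == 0:
            logger.info("surface %s has zero stomata", self.surface_id)

    @property
    def n(self) -> int:
        """Number of stomata in the window."""
        return int(self.xy.shape[0])

    @property
    def window_area(self) -> float:
        """Window area A_leaf in mm²."""
        return float(self.window[0] * self.window[1])

    def with_lengths(self, lengths: np.ndarray) -> "SurfaceRecord":
        return replace(self, lengths=np.asarray(lengths, dtype=float))


@dataclass(frozen=True)
class PairedSurfaces:
    """Abaxial and adaxial records of the same leaf in one coordinate frame."""

    leaf_id: str
    abaxial: SurfaceRecord
    adaxial: SurfaceRecord

    def __post_init__(self) -> None:
        if self.abaxial.surface != "abaxial" or self.adaxial.surface != "adaxial":
            raise ValidationError(f"pair {self.leaf_id}: surfaces mislabelled")
        if not np.allclose(self.abaxial.window, self.adaxial.window):
            raise ValidationError(
                f"pair {self.leaf_id}: window dimensions differ "
                f"({self.abaxial.window} vs {self.adaxial.window})"
            )


@dataclass(frozen=True)
class DispersionResult:
    """Nearest-neighbour dispersion summary for one surface.

    ``dispersion_index`` rescales the nearest-neighbour index so that the
    median of the random null maps to 0 and the median of the conditioned
    triangular-lattice ideal maps to 1; observed surfaces may fall outside
    [0, 1].
    """

    surface_id: str
    nni_observed: float
    nni_random_median: float
    nni_ideal_median: float
    dispersion_index: float
    p_raw: float
    n_sim: int
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p_raw <= 1):
            raise ValidationError(f"{self.surface_id}: p_raw must be in (0, 1], got {self.p_raw}")
        if self.p_adjusted is not None and not (0 < self.p_adjusted <= 1):
            raise ValidationError(f"{self.surface_id}: p_adjusted must be in (0, 1]")
        if self.n_sim < 1:
            raise ValidationError(f"{self.surface_id}: n_sim must be >= 1")
        if not np.isfinite(self.dispersion_index):
            raise ValidationError(f"{self.surface_id}: dispersion index not finite")


def stomatal_density(record: SurfaceRecord) -> float:
    """Stomatal density D_S in mm⁻²: count over window area."""
    return record.n / record.window_area


def read_surfaces(path, schema: Mapping[str, str] | None = None) -> list[SurfaceRecord]:
    """Read a stomatal coordinate table into one record per (leaf, surface).

    The CSV carries one row per stomate; rows whose x and y are both empty
    act as placeholders for surfaces with zero stomata.  ``schema`` remaps
    logical column names (keys of :data:`DEFAULT_SCHEMA`) onto the file's
    actual headers.
    """
    cols = dict(DEFAULT_SCHEMA)
    if schema:
        unknown = set(schema) - set(cols)
        if unknown:
            raise SchemaError(f"unknown schema keys: {sorted(unknown)}")
        cols.update(schema)
    df = pd.read_csv(path, float_precision="round_trip")
    required = [cols[k] for k in ("plant_id", "leaf_id", "surface", "x", "y",
                                  "window_width", "window_height")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    records: list[SurfaceRecord] = []
    keys = [cols["plant_id"], cols["leaf_id"], cols["surface"]]
    for (plant, leaf, surf), grp in df.groupby(keys, sort=True):
        widths = grp[cols["window_width"]].unique()
        heights = grp[cols["window_height"]].unique()
        if len(widths) != 1 or len(heights) != 1:
            raise ValidationError(f"{plant}:{leaf}:{surf}: inconsistent window dimensions within surface")
        x = grp[cols["x"]].to_numpy(dtype=float)
        y = grp[cols["y"]].to_numpy(dtype=float)
        empty = np.isnan(x) & np.isnan(y)
        if empty.any() and not empty.all():
            raise ValidationError(f"{plant}:{leaf}:{surf}: mixed empty and real coordinate rows")
        if empty.all():
            xy = np.empty((0, 2))
            lengths = None
        else:
            xy = np.column_stack([x, y])
            lengths = None
            if cols["length"] in grp.columns:
                lvals = grp[cols["length"]].to_numpy(dtype=float)
                if not np.all(np.isnan(lvals)):
                    lengths = lvals
        treatment = ""
        if cols["treatment"] in grp.columns:
            treatment = str(grp[cols["treatment"]].iloc[0])
        records.append(
            SurfaceRecord(
                surface_id=f"{plant}:{leaf}:{surf}",
                plant_id=str(plant),
                leaf_id=str(leaf),
                surface=str(surf),
                treatment=treatment,
                window=(float(widths[0]), float(heights[0])),
                xy=xy,
                lengths=lengths,
            )
        )
    return records


def write_surfaces(records: Iterable[SurfaceRecord], path) -> None:
    """Write records to the CSV schema read by :func:`read_surfaces`."""
    rows = []
    for rec in records:
        if rec.n == 0:
            rows.append(
                {
                    "plant_id": rec.plant_id, "leaf_id": rec.leaf_id,
                    "surface": rec.surface, "treatment": rec.treatment,
                    "x_mm": np.nan, "y_mm": np.nan, "length_um": np.nan,
                    "window_width_mm": rec.window[0], "window_height_mm": rec.window[1],
                }
            )
            continue
        for i in range(rec.n):
            rows.append(
                {
                    "plant_id": rec.plant_id, "leaf_id": rec.leaf_id,
                    "surface": rec.surface, "treatment": rec.treatment,
                    "x_mm": rec.xy[i, 0], "y_mm": rec.xy[i, 1],
                    "length_um": np.nan if rec.lengths is None else rec.lengths[i],
                    "window_width_mm": rec.window[0], "window_height_mm": rec.window[1],
                }
            )
    columns = ["plant_id", "leaf_id", "surface", "treatment", "x_mm", "y_mm",
               "length_um", "window_width_mm", "window_height_mm"]
    # %.17g round-trips IEEE doubles exactly, so write -> read is lossless
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False,
                                               float_format="%.17g")


def pair_surfaces(records: Sequence[SurfaceRecord]) -> list[PairedSurfaces]:
    """Match abaxial and adaxial records of the same leaf into pairs.

    Leaves lacking one surface are reported via the module logger and
    dropped; duplicated (leaf, surface) combinations raise.  The result is
    sorted by leaf key, so input order does not matter.
    """
    by_leaf: dict[tuple[str, str], dict[str, SurfaceRecord]] = {}
    for rec in records:
        key = (rec.plant_id, rec.leaf_id)
        slot = by_leaf.setdefault(key, {})
        if rec.surface in slot:
            raise ValidationError(f"duplicate record for leaf {key}, surface {rec.surface}")
        slot[rec.surface] = rec
    pairs: list[PairedSurfaces] = []
    for key in sorted(by_leaf):
        slot = by_leaf[key]
        if len(slot) == 2:
            pairs.append(PairedSurfaces(leaf_id=f"{key[0]}:{key[1]}",
                                        abaxial=slot["abaxial"], adaxial=slot["adaxial"]))
        else:
            (surf,) = slot
            logger.warning("leaf %s unpaired: only %s surface present", key, surf)
    return pairs
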