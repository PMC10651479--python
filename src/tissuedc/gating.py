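"""Event-cleaning gates for deformability-cytometry tables.

Debris removal follows the published analysis gates: drop everything below
25 µm² cross-sectional area, everything with convex-hull/contour area ratio
above 1.1 or bounding-box aspect ratio above 2, and additionally require
area ratio ≤ 1.05 for small cells (< 60 µm²), whose rough fragments would
otherwise pass. Fluorescence positivity is thresholded on an unstained
control from the same tissue. Doublets (two attached cells imaged as one)
are flagged by their elongation and size but kept out of the cleaned
single-cell pool by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import ParameterError, SchemaError

__all__ = ["GateConfig", "apply_debris_gates", "fluorescence_gate", "flag_doublets"]

REQUIRED_GATE_COLUMNS = ("area_um2", "area_ratio", "aspect_ratio")

#: Gate labels, in evaluation order; an event records the first failing rule.
LABEL_KEPT = "kept"
LABEL_DEBRIS_AREA = "debris:area"
LABEL_AREA_RATIO = "debris:area_ratio"
LABEL_ASPECT = "debris:aspect"
LABEL_SMALL_AREA_RATIO = "debris:small_area_ratio"


@dataclass
class GateConfig:
    """Thresholds for debris, small-cell, doublet and fluorescence gates.

    ``min_area`` is the acquisition-side floor (events below it are never
    recorded); ``debris_area`` is the analysis-side debris cut and the
    effective keep threshold. Ratio gates written "1:1.1" / "1:2" in protocol
    shorthand are upper bounds on area_ratio and aspect_ratio.
    """

    min_area: float = 20.0
    debris_area: float = 25.0
    max_area_ratio: float = 1.1
    max_area_ratio_small: float = 1.05
    small_cell_area: float = 60.0
    max_aspect: float = 2.0
    analysis_min_area: float | None = None
    doublet_min_aspect: float = 2.0
    doublet_min_area: float = 50.0
    fluorescence_thresholds: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.min_area <= self.debris_area <= self.small_cell_area:
            raise ParameterError(
                "need 0 < min_area <= debris_area <= small_cell_area, got "
                f"{self.min_area}, {self.debris_area}, {self.small_cell_area}"
            )
        if self.max_area_ratio_small > self.max_area_ratio:
            raise ParameterError("max_area_ratio_small must be <= max_area_ratio")
        if self.max_aspect <= 1:
            raise ParameterError("max_aspect must be > 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GateConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _require_columns(events: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in events.columns]
    if missing:
        raise SchemaError(f"event table is missing required columns: {missing}")


def apply_debris_gates(events: pd.DataFrame, cfg: GateConfig | None = None
                       ) -> tuple[pd.DataFrame, pd.Series]:
    """Partition events into kept cells and debris.

    Returns ``(kept, labels)`` where ``labels`` (aligned with the input)
    records "kept" or the first failing rule. An event is kept iff::

        area >= debris_area
        and area_ratio <= max_area_ratio
        and aspect_ratio <= max_aspect
        and (area >= small_cell_area or area_ratio <= max_area_ratio_small)

    with an optional extra floor ``analysis_min_area`` (e.g. 60 µm² for the
    tumour analyses, below which samples are mostly immune cells and debris).
    """
    cfg = cfg or GateConfig()
    cfg.validate()
    _require_columns(events, REQUIRED_GATE_COLUMNS)

    area = events["area_um2"].to_numpy(dtype=float)
    ratio = events["area_ratio"].to_numpy(dtype=float)
    aspect = events["aspect_ratio"].to_numpy(dtype=float)

    floor = cfg.debris_area
    if cfg.analysis_min_area is not None:
        floor = max(floor, cfg.analysis_min_area)

    labels = np.full(len(events), LABEL_KEPT, dtype=object)
    small_fail = (area < cfg.small_cell_area) & (ratio > cfg.max_area_ratio_small)
    # later assignments overwrite, so order from last rule to first
    labels[small_fail] = LABEL_SMALL_AREA_RATIO
    labels[aspect > cfg.max_aspect] = LABEL_ASPECT
    labels[ratio > cfg.max_area_ratio] = LABEL_AREA_RATIO
    labels[area < floor] = LABEL_DEBRIS_AREA

    labels = pd.Series(labels, index=events.index, name="gate_label")
    kept = events.loc[labels == LABEL_KEPT]
    return kept, labels


def fluorescence_gate(events: pd.DataFrame, control: pd.DataFrame,
                      channel: str, quantile: float = 0.99
                      ) -> tuple[float, pd.DataFrame]:
    """Positivity gate thresholded on an unstained control.

    The threshold is the given quantile of the control's fluorescence maxima
    for ``channel``; positives are events strictly above it. Returns
    ``(threshold, positive subset)``.
    """
    if len(control) == 0:
        raise ParameterError("unstained control table is empty")
    if not 0.0 < quantile <= 1.0:
        raise ParameterError(f"quantile must be in (0, 1], got {quantile}")
    col = channel if channel in events.columns else f"fl_{channel}_max"
    for table, name in ((events, "events"), (control, "control")):
        if col not in table.columns:
            raise SchemaError(f"channel column {col!r} missing from {name} table")
    threshold = float(control[col].quantile(quantile))
    positives = events.loc[events[col] > threshold]
    return threshold, positives


def flag_doublets(events: pd.DataFrame, cfg: GateConfig | None = None) -> pd.Series:
    """Flag probable cell doublets by elongation and size.

    A doublet candidate exceeds ``doublet_min_aspect`` in aspect ratio and
    ``doublet_min_area`` in cross-sectional area. Flags are informational:
    they never change debris-gate labels.
    """
    cfg = cfg or GateConfig()
    _require_columns(events, ("area_um2", "aspect_ratio"))
    flags = ((events["aspect_ratio"] > cfg.doublet_min_aspect)
             & (events["area_um2"] > cfg.doublet_min_area))
    return flags.rename("is_doublet_flag")
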