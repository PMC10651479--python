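"""Synthetic deformability-cytometry data with known ground truth.

Real measurements push tissue-derived cells through a microfluidic
constriction and record, for every cell, a brightfield image and a handful of
physical-phenotype features (cross-sectional area, deformation, aspect ratio,
convex-hull area ratio, brightness statistics, optional fluorescence maxima).
This module emulates such measurements phenomenologically: per-event feature
tables drawn from parametric marginals, whole matched-pair cohorts with
biological replicate variability, inflammation mixtures with a CD45-positive
low-deformation leukocyte subpopulation, and rasterized single-cell frames
with analytic ground-truth contours.

No hydrodynamics is simulated; distributions are chosen to reproduce the
qualitative orderings seen in dissociated healthy vs. pathological tissue
(tumours: larger, more deformed, rougher-outlined, more heterogeneous cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import GeometryError, ParameterError

__all__ = [
    "SubpopulationSpec",
    "PopulationSpec",
    "CohortSpec",
    "RenderSpec",
    "SampleRecord",
    "sample_events",
    "sample_cohort",
    "inflammation_cohort",
    "render_event_image",
    "healthy_colon",
    "tumour_colon",
]

#: Deformation is drawn from a beta distribution rescaled to this range; RT-DC
#: deformation of intact cells rarely exceeds ~0.3, so [0, 0.5] keeps the
#: domain invariant deformation < 1 exact while leaving headroom.
DEFORMATION_SCALE = 0.5

#: Events below this cross-sectional area are generated as debris fragments.
DEBRIS_AREA_UM2 = 25.0


@dataclass(frozen=True)
class FluorescenceSpec:
    """Log-normal fluorescence-maximum model for one antibody channel.

    A fraction ``pos_fraction`` of cells is stained-positive with log-normal
    median ``pos_median``; the rest emit a dim autofluorescence mode around
    ``neg_median``. Both share log-scale sigma ``sigma``.
    """

    pos_fraction: float = 0.0
    pos_median: float = 3000.0
    neg_median: float = 80.0
    sigma: float = 0.4

    def validate(self) -> None:
        if not 0.0 <= self.pos_fraction <= 1.0:
            raise ParameterError(f"pos_fraction must be in [0,1], got {self.pos_fraction}")
        if self.pos_median <= 0 or self.neg_median <= 0 or self.sigma <= 0:
            raise ParameterError("fluorescence medians and sigma must be positive")


@dataclass(frozen=True)
class SubpopulationSpec:
    """Marginal feature distributions for one cell subpopulation.

    Parameters
    ----------
    weight
        Mixture weight among non-debris, non-doublet cells.
    area_median, area_sigma
        Log-normal cross-sectional area: median in µm², sigma on log scale.
    deformation_mean, deformation_conc
        Mean and concentration of a beta distribution on [0, 0.5]
        (mean in absolute deformation units).
    area_ratio_excess
        Gamma-distributed excess over 1 of convex-hull/contour area ratio.
    aspect_excess
        Gamma-distributed excess over 1 of the bounding-box aspect ratio.
    brightness_mean, brightness_sigma
        Normal model of the per-cell average brightness, camera units.
    brightness_sd_mean
        Typical within-cell SD of brightness (gamma-distributed per event).
    fluorescence
        Mapping channel name -> FluorescenceSpec.
    """

    weight: float = 1.0
    area_median: float = 80.0
    area_sigma: float = 0.45
    deformation_mean: float = 0.08
    deformation_conc: float = 30.0
    area_ratio_excess: float = 0.03
    aspect_excess: float = 0.15
    brightness_mean: float = 110.0
    brightness_sigma: float = 8.0
    brightness_sd_mean: float = 12.0
    fluorescence: dict[str, FluorescenceSpec] = field(default_factory=dict)

    def validate(self) -> None:
        if self.weight < 0:
            raise ParameterError(f"subpopulation weight must be >= 0, got {self.weight}")
        if self.area_median <= 0 or self.area_sigma <= 0:
            raise ParameterError("area_median and area_sigma must be positive")
        if not 0.0 < self.deformation_mean < DEFORMATION_SCALE:
            raise ParameterError(
                f"deformation_mean must lie in (0, {DEFORMATION_SCALE}), got {self.deformation_mean}"
            )
        if self.deformation_conc <= 0:
            raise ParameterError("deformation_conc must be positive")
        if self.area_ratio_excess < 0 or self.aspect_excess < 0:
            raise ParameterError("ratio excesses must be >= 0")
        if self.brightness_sigma <= 0 or self.brightness_sd_mean <= 0:
            raise ParameterError("brightness sigma/sd parameters must be positive")
        for fl in self.fluorescence.values():
            fl.validate()


@dataclass(frozen=True)
class PopulationSpec:
    """Mixture of cell subpopulations plus debris and doublet contamination."""

    subpopulations: tuple[SubpopulationSpec, ...] = (SubpopulationSpec(),)
    debris_fraction: float = 0.15
    doublet_fraction: float = 0.03

    def validate(self) -> None:
        if not self.subpopulations:
            raise ParameterError("at least one subpopulation is required")
        for sub in self.subpopulations:
            sub.validate()
        total = sum(s.weight for s in self.subpopulations)
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"subpopulation weights must sum to 1, got {total}")
        for name, frac in (("debris_fraction", self.debris_fraction),
                           ("doublet_fraction", self.doublet_fraction)):
            if not 0.0 <= frac <= 1.0:
                raise ParameterError(f"{name} must be in [0,1], got {frac}")
        if self.debris_fraction + self.doublet_fraction > 1.0:
            raise ParameterError("debris_fraction + doublet_fraction must be <= 1")

    @property
    def channels(self) -> tuple[str, ...]:
        names: list[str] = []
        for sub in self.subpopulations:
            for ch in sub.fluorescence:
                if ch not in names:
                    names.append(ch)
        return tuple(names)


@dataclass(frozen=True)
class CohortSpec:
    """A matched-pair cohort: one pathological and one healthy sample per subject.

    ``area_jitter_cv`` and ``deformation_jitter_sd`` model biological
    replicate variability: each sample's subpopulation area medians are scaled
    by a common log-normal factor and its deformation means are shifted by a
    common Gaussian offset, mimicking animal-to-animal / patient-to-patient
    spread.
    """

    n_pairs: int = 16
    healthy: PopulationSpec = field(default_factory=lambda: healthy_colon())
    disease: PopulationSpec = field(default_factory=lambda: tumour_colon())
    events_per_sample: tuple[int, int] = (2000, 10000)
    pairing: bool = True
    area_jitter_cv: float = 0.10
    deformation_jitter_sd: float = 0.012

    def validate(self) -> None:
        if self.n_pairs < 0:
            raise ParameterError("n_pairs must be >= 0")
        lo, hi = self.events_per_sample
        if lo < 1 or hi < lo:
            raise ParameterError(f"invalid events_per_sample range {self.events_per_sample}")
        if self.area_jitter_cv < 0 or self.deformation_jitter_sd < 0:
            raise ParameterError("jitter parameters must be >= 0")
        self.healthy.validate()
        self.disease.validate()


@dataclass(frozen=True)
class RenderSpec:
    """Rasterization parameters for a single-cell brightfield frame.

    The cell outline is a superellipse |x/a|^p + |y/b|^p = 1 (p=2 gives an
    ellipse), centred in a frame of ``frame_shape`` = (height, width) pixels
    matching the instrument's 250x80 px region of interest. Intensity ramps
    linearly from ``intensity_center`` at the cell centre to
    ``intensity_edge`` at the boundary on top of a noisy background.
    """

    frame_shape: tuple[int, int] = (80, 250)
    pixel_size: float = 0.34
    semi_axis_x: float = 12.0
    semi_axis_y: float = 10.0
    exponent: float = 2.0
    intensity_center: float = 120.0
    intensity_edge: float = 70.0
    background_mean: float = 40.0
    background_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.frame_shape
        if h < 8 or w < 8:
            raise ParameterError(f"frame too small: {self.frame_shape}")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")
        if self.semi_axis_x <= 0 or self.semi_axis_y <= 0:
            raise ParameterError("semi-axes must be positive")
        if self.exponent < 1:
            raise ParameterError("superellipse exponent must be >= 1")
        if self.semi_axis_x > w / 2 - 2 or self.semi_axis_y > h / 2 - 2:
            raise GeometryError(
                f"shape ({self.semi_axis_x} x {self.semi_axis_y} px) does not fit "
                f"inside frame {self.frame_shape} with a 2 px margin"
            )
        for v in (self.intensity_center, self.intensity_edge, self.background_mean):
            if not 0 <= v <= 255:
                raise ParameterError("intensities must lie in camera range [0, 255]")
        if self.background_sigma < 0:
            raise ParameterError("background_sigma must be >= 0")


@dataclass
class SampleRecord:
    """One biopsy measurement: an event table plus acquisition metadata."""

    sample_id: str
    events: pd.DataFrame
    tissue: str = "colon"
    condition: str | None = None
    pairing_id: str | None = None
    pixel_size: float = 0.34
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.events)


# ---------------------------------------------------------------------------
# preset populations


def healthy_colon(channels: Sequence[str] = ()) -> PopulationSpec:
    """Healthy colon: epithelial-dominated, moderate size and deformation."""
    fl = {ch: FluorescenceSpec(pos_fraction=0.1 if ch == "cd45" else 0.7)
          for ch in channels}
    return PopulationSpec(
        subpopulations=(SubpopulationSpec(weight=1.0, fluorescence=fl),),
        debris_fraction=0.15,
        doublet_fraction=0.03,
    )


def tumour_colon(channels: Sequence[str] = (),
                 area_factor: float = 1.3,
                 deformation_shift: float = 0.05) -> PopulationSpec:
    """Tumour colon: larger, more deformed, rougher and more heterogeneous cells.

    Defaults encode the generator's disease effect: area median scaled by
    1.3, deformation mean shifted by +0.05, wider spreads and a higher
    area-ratio excess.
    """
    base = SubpopulationSpec()
    fl = {ch: FluorescenceSpec(pos_fraction=0.15 if ch == "cd45" else 0.6)
          for ch in channels}
    tumour = replace(
        base,
        area_median=base.area_median * area_factor,
        area_sigma=base.area_sigma * 1.25,
        deformation_mean=base.deformation_mean + deformation_shift,
        deformation_conc=base.deformation_conc * 0.6,
        area_ratio_excess=base.area_ratio_excess * 1.7,
        aspect_excess=base.aspect_excess * 1.2,
        fluorescence=fl,
    )
    return PopulationSpec(subpopulations=(tumour,),
                          debris_fraction=0.18, doublet_fraction=0.04)


def leukocyte_subpop(deformation_mean: float = 0.04,
                     weight: float = 1.0) -> SubpopulationSpec:
    """Small, stiff (low-deformation) CD45-positive leukocyte population."""
    return SubpopulationSpec(
        weight=weight,
        area_median=45.0,
        area_sigma=0.25,
        deformation_mean=deformation_mean,
        deformation_conc=60.0,
        area_ratio_excess=0.02,
        aspect_excess=0.08,
        brightness_mean=100.0,
        brightness_sigma=6.0,
        fluorescence={"cd45": FluorescenceSpec(pos_fraction=0.97)},
    )


def epithelial_subpop(weight: float = 1.0) -> SubpopulationSpec:
    """Colon epithelial population, CD45-negative (autofluorescence only)."""
    return SubpopulationSpec(
        weight=weight,
        fluorescence={"cd45": FluorescenceSpec(pos_fraction=0.0)},
    )


# ---------------------------------------------------------------------------
# event sampling


def _beta_params(mean: float, conc: float) -> tuple[float, float]:
    m = mean / DEFORMATION_SCALE
    return m * conc, (1.0 - m) * conc


def _draw_fluorescence(rng: np.random.Generator, spec: FluorescenceSpec,
                       n: int) -> np.ndarray:
    pos = rng.random(n) < spec.pos_fraction
    median = np.where(pos, spec.pos_median, spec.neg_median)
    return np.exp(np.log(median) + spec.sigma * rng.standard_normal(n))


def _draw_subpop(rng: np.random.Generator, sub: SubpopulationSpec, n: int,
                 channels: Sequence[str]) -> dict[str, np.ndarray]:
    a, b = _beta_params(sub.deformation_mean, sub.deformation_conc)
    out = {
        "area_um2": np.exp(np.log(sub.area_median)
                           + sub.area_sigma * rng.standard_normal(n)),
        "deformation": DEFORMATION_SCALE * rng.beta(a, b, n),
        "area_ratio": 1.0 + rng.gamma(2.0, sub.area_ratio_excess / 2.0, n),
        "aspect_ratio": 1.0 + rng.gamma(2.0, sub.aspect_excess / 2.0, n),
        "brightness_avg": sub.brightness_mean
        + sub.brightness_sigma * rng.standard_normal(n),
        "brightness_sd": rng.gamma(4.0, sub.brightness_sd_mean / 4.0, n),
    }
    for ch in channels:
        fl = sub.fluorescence.get(ch, FluorescenceSpec(pos_fraction=0.0))
        out[f"fl_{ch}_max"] = _draw_fluorescence(rng, fl, n)
    return out


def _draw_debris(rng: np.random.Generator, n: int,
                 channels: Sequence[str]) -> dict[str, np.ndarray]:
    # small fragments with rough, concave outlines
    out = {
        "area_um2": rng.uniform(4.0, DEBRIS_AREA_UM2, n),
        "deformation": DEFORMATION_SCALE * rng.beta(4.0, 12.0, n),
        "area_ratio": 1.0 + rng.gamma(2.0, 0.15, n),
        "aspect_ratio": 1.0 + rng.gamma(2.0, 0.25, n),
        "brightness_avg": 90.0 + 15.0 * rng.standard_normal(n),
        "brightness_sd": rng.gamma(4.0, 5.0, n),
    }
    for ch in channels:
        out[f"fl_{ch}_max"] = _draw_fluorescence(
            rng, FluorescenceSpec(pos_fraction=0.0), n)
    return out


def _draw_doublets(rng: np.random.Generator, sub: SubpopulationSpec, n: int,
                   channels: Sequence[str]) -> dict[str, np.ndarray]:
    # two touching cells imaged as one: ~double area, elongated (aspect > 2)
    single = _draw_subpop(rng, sub, n, channels)
    out = dict(single)
    out["area_um2"] = single["area_um2"] * rng.uniform(1.7, 2.0, n)
    out["aspect_ratio"] = 2.0 + rng.gamma(2.0, 0.3, n)
    out["area_ratio"] = 1.0 + rng.gamma(2.0, 0.06, n)
    return out


def sample_events(spec: PopulationSpec, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` per-cell events from a population mixture.

    Returns a DataFrame with the canonical feature columns plus ground-truth
    bookkeeping: ``subpop_id`` (index into ``spec.subpopulations``, -1 for
    debris/doublets), ``is_debris`` and ``is_doublet``. Deterministic for a
    fixed ``(spec, n, seed)``.
    """
    spec.validate()
    if n < 0:
        raise ParameterError(f"n must be >= 0, got {n}")
    rng = np.random.default_rng(seed)
    channels = spec.channels

    n_sub = len(spec.subpopulations)
    weights = np.array([s.weight for s in spec.subpopulations])
    cell_frac = 1.0 - spec.debris_fraction - spec.doublet_fraction
    probs = np.concatenate([weights * cell_frac,
                            [spec.debris_fraction, spec.doublet_fraction]])
    category = rng.choice(n_sub + 2, size=n, p=probs / probs.sum())

    columns = ["area_um2", "deformation", "area_ratio", "aspect_ratio",
               "brightness_avg", "brightness_sd"]
    columns += [f"fl_{ch}_max" for ch in channels]
    data = {c: np.empty(n) for c in columns}
    subpop_id = np.full(n, -1, dtype=np.int64)
    is_debris = np.zeros(n, dtype=bool)
    is_doublet = np.zeros(n, dtype=bool)

    for k in range(n_sub + 2):
        idx = np.flatnonzero(category == k)
        if idx.size == 0:
            continue
        if k < n_sub:
            drawn = _draw_subpop(rng, spec.subpopulations[k], idx.size, channels)
            subpop_id[idx] = k
        elif k == n_sub:
            drawn = _draw_debris(rng, idx.size, channels)
            is_debris[idx] = True
        else:
            # doublets inherit the phenotype of the heaviest subpopulation
            heaviest = int(np.argmax(weights))
            drawn = _draw_doublets(rng, spec.subpopulations[heaviest],
                                   idx.size, channels)
            is_doublet[idx] = True
        for c in columns:
            data[c][idx] = drawn[c]

    # position of the event in the channel, µm (flow axis x, lateral y)
    data["pos_x"] = rng.uniform(0.0, 85.0, n)
    data["pos_y"] = rng.normal(0.0, 2.0, n)
    frame = pd.DataFrame(data)
    frame["subpop_id"] = subpop_id
    frame["is_debris"] = is_debris
    frame["is_doublet"] = is_doublet
    return frame


def _jitter(spec: PopulationSpec, rng: np.random.Generator,
            area_cv: float, deform_sd: float) -> PopulationSpec:
    """Per-sample biological variability: common shifts of the marginals."""
    if area_cv == 0 and deform_sd == 0:
        return spec
    area_factor = float(np.exp(rng.normal(0.0, area_cv)))
    deform_shift = float(rng.normal(0.0, deform_sd))
    subs = []
    for sub in spec.subpopulations:
        new_mean = float(np.clip(sub.deformation_mean + deform_shift,
                                 0.01, DEFORMATION_SCALE - 0.02))
        subs.append(replace(sub, area_median=sub.area_median * area_factor,
                            deformation_mean=new_mean))
    return replace(spec, subpopulations=tuple(subs))


def sample_cohort(spec: CohortSpec, seed: int) -> list[SampleRecord]:
    """Generate a matched-pair cohort of ``2 * n_pairs`` samples.

    Each pair shares a ``pairing_id`` and consists of one ``healthy`` and one
    ``disease`` sample; event counts are drawn uniformly from
    ``events_per_sample``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    lo, hi = spec.events_per_sample
    records: list[SampleRecord] = []
    for p in range(spec.n_pairs):
        pair_id = f"pair{p:03d}" if spec.pairing else None
        for condition, pop in (("healthy", spec.healthy), ("disease", spec.disease)):
            jittered = _jitter(pop, rng, spec.area_jitter_cv,
                               spec.deformation_jitter_sd)
            n_events = int(rng.integers(lo, hi + 1))
            sub_seed = int(rng.integers(0, 2**31 - 1))
            events = sample_events(jittered, n_events, sub_seed)
            records.append(SampleRecord(
                sample_id=f"s{p:03d}_{condition}",
                events=events,
                condition=condition,
                pairing_id=pair_id,
            ))
    return records


def inflammation_cohort(n_samples: int, leukocyte_fractions: Sequence[float],
                        seed: int,
                        events_per_sample: tuple[int, int] = (2000, 10000),
                        ) -> list[SampleRecord]:
    """Colitis-like samples: epithelium mixed with stiff CD45+ leukocytes.

    ``leukocyte_fractions`` gives, per sample, the weight of a low-deformation
    CD45-positive subpopulation; fractions are recycled over ``n_samples``.
    The CD45 fluorescence channel is always populated so downstream
    positivity gating is exercised.
    """
    if n_samples < 0:
        raise ParameterError("n_samples must be >= 0")
    fracs = list(leukocyte_fractions)
    if not fracs:
        raise ParameterError("at least one leukocyte fraction is required")
    for f in fracs:
        if not 0.0 <= f <= 1.0:
            raise ParameterError(f"leukocyte fraction must be in [0,1], got {f}")
    rng = np.random.default_rng(seed)
    lo, hi = events_per_sample
    records = []
    for i in range(n_samples):
        f = fracs[i % len(fracs)]
        subs: list[SubpopulationSpec] = []
        if f < 1.0:
            subs.append(epithelial_subpop(weight=1.0 - f))
        if f > 0.0:
            subs.append(leukocyte_subpop(weight=f))
        pop = PopulationSpec(subpopulations=tuple(subs),
                             debris_fraction=0.12, doublet_fraction=0.02)
        n_events = int(rng.integers(lo, hi + 1))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        records.append(SampleRecord(
            sample_id=f"colitis{i:03d}",
            events=sample_events(pop, n_events, sub_seed),
            condition=f"leuko{f:.2f}",
            metadata={"leukocyte_fraction": f},
        ))
    return records


# ---------------------------------------------------------------------------
# image rendering


def superellipse_contour(spec: RenderSpec, n_vertices: int = 512) -> np.ndarray:
    """Analytic boundary polygon of the rendered cell, (x, y) pixel coords."""
    h, w = spec.frame_shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    e = 2.0 / spec.exponent
    x = cx + spec.semi_axis_x * np.sign(np.cos(t)) * np.abs(np.cos(t)) ** e
    y = cy + spec.semi_axis_y * np.sign(np.sin(t)) * np.abs(np.sin(t)) ** e
    return np.column_stack([x, y])


def _polygon_area_perimeter(poly: np.ndarray) -> tuple[float, float]:
    x, y = poly[:, 0], poly[:, 1]
    xs, ys = np.roll(x, -1), np.roll(y, -1)
    area = 0.5 * abs(np.sum(x * ys - xs * y))
    perim = float(np.sum(np.hypot(xs - x, ys - y)))
    return float(area), perim


def render_event_image(spec: RenderSpec) -> tuple[np.ndarray, np.ndarray, dict]:
    """Rasterize one cell and return ``(frame, truth_contour, truth_features)``.

    ``frame`` is a (height, width) float array in camera units; the truth
    contour is the analytic superellipse polygon (512 vertices, pixel
    coordinates) and ``truth_features`` holds the analytically computed
    physical phenotype of that polygon (area in µm², deformation, aspect and
    area ratios, interior brightness mean/SD for the noise-free profile).
    """
    spec.validate()
    h, w = spec.frame_shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    u = (np.abs((xx - cx) / spec.semi_axis_x) ** spec.exponent
         + np.abs((yy - cy) / spec.semi_axis_y) ** spec.exponent) ** (1.0 / spec.exponent)
    inside = u <= 1.0

    rng = np.random.default_rng(spec.seed)
    frame = np.full((h, w), spec.background_mean, dtype=float)
    if spec.background_sigma > 0:
        frame += rng.normal(0.0, spec.background_sigma, size=(h, w))
    profile = spec.intensity_center + (spec.intensity_edge - spec.intensity_center) * u
    frame[inside] = profile[inside]
    np.clip(frame, 0.0, 255.0, out=frame)

    contour = superellipse_contour(spec)
    # dense polygon for near-exact geometry of the smooth boundary
    dense = superellipse_contour(spec, n_vertices=4096)
    area_px, perim_px = _polygon_area_perimeter(dense)
    deformation = 1.0 - 2.0 * np.sqrt(np.pi * area_px) / perim_px
    extents = dense.max(axis=0) - dense.min(axis=0)
    aspect = float(max(extents) / min(extents))

    interior = profile[inside]
    truth = {
        "area_um2": area_px * spec.pixel_size**2,
        "area_px": area_px,
        "perimeter_px": perim_px,
        "deformation": float(deformation),
        "aspect_ratio": aspect,
        "area_ratio": 1.0,
        "brightness_avg": float(interior.mean()),
        "brightness_sd": float(interior.std()),
    }
    return frame, contour, truth
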