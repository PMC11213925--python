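"""Synthetic layered-epithelium fixtures with a planted transformation signal.

Slides are generated as horizontal tissue bands (background, keratin,
epithelial, basal, connective) with sinusoidally undulating boundaries.
Nuclei are placed by a per-region homogeneous Poisson process and rendered as
32-vertex polygonised ellipses with class-specific size distributions:
basal-epithelial nuclei in the basal band, epithelial nuclei in the
epithelial band, and "other" (connective/inflammatory) nuclei both in the
connective tissue and — at lower intensity — inside the epithelium,
emulating peri- and intra-epithelial lymphocytes.

Transforming slides carry the planted signal the pipeline is meant to
detect: their "other"-nucleus intensities are scaled by
``other_multiplier`` (default 4) in both compartments and their
epithelial-family nuclei are enlarged by ``size_multiplier`` (default 1.25).
Survival times for transforming slides are exponential (rate = baseline x
hazard ratio) truncated to the follow-up window; non-transforming slides get
uniform censoring times.  ``simulate_survival`` additionally provides a
textbook proportional-hazards simulator for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .io import (
    BinaryGrade,
    CohortTable,
    LayerMask,
    NucleusClass,
    NucleusRecord,
    SlideRecord,
    WHOGrade,
)

MM2_PER_PX = (0.5 / 1000.0) ** 2  # at 0.50 mpp
MAX_NUCLEI_PER_SLIDE = 1_000_000


@dataclass
class SimulationParams:
    """Study conditions for the synthetic cohort (densities in nuclei/mm^2)."""

    n_slides: int = 60
    slide_width: int = 1280
    slide_height: int = 1280
    mpp: float = 0.50
    # band geometry (px): top background margin, then keratin/epithelium/basal
    background_margin: int = 80
    keratin_thickness: int = 80
    epithelium_thickness: int = 440
    basal_thickness: int = 60
    undulation_amplitude: float = 40.0
    undulation_period: float = 512.0
    # Poisson intensities per class and region
    epithelial_density: float = 2500.0
    basal_density: float = 4000.0
    other_density_connective: float = 800.0
    other_density_epithelium: float = 120.0
    # nucleus morphology (um): mean radius per class, lognormal axis ratio
    radius_um: dict = field(
        default_factory=lambda: {"epithelial": 3.5, "basal_epithelial": 2.8, "other": 2.2}
    )
    radius_cv: float = 0.15
    axis_ratio_log_mean: float = np.log(1.5)
    axis_ratio_log_sd: float = 0.15
    # planted transformation effect
    other_multiplier: float = 4.0
    size_multiplier: float = 1.25
    # labels and survival
    prevalence: float = 0.5
    baseline_rate: float = 0.05  # events per year
    hazard_ratio: float = 8.0
    followup_years: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be > 0")
        for name in ("epithelial_density", "basal_density",
                     "other_density_connective", "other_density_epithelium"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _band_mask(params: SimulationParams, phase: float) -> np.ndarray:
    """Label image of undulating horizontal bands."""
    w, h = params.slide_width, params.slide_height
    x = np.arange(w)
    und = params.undulation_amplitude * np.sin(
        2 * np.pi * x / params.undulation_period + phase
    )
    b0 = params.background_margin + und  # top of keratin
    b1 = b0 + params.keratin_thickness
    b2 = b1 + params.epithelium_thickness
    b3 = b2 + params.basal_thickness
    rows = np.arange(h)[:, None]
    labels = np.select(
        [rows < b0, rows < b1, rows < b2, rows < b3],
        [io.LAYER_BACKGROUND, io.LAYER_KERATIN, io.LAYER_EPITHELIUM, io.LAYER_BASAL],
        default=io.LAYER_OTHER_TISSUE,
    )
    return labels.astype(np.uint8)


def _ellipse_contour(
    cx: float, cy: float, a_px: float, b_px: float, theta: float, n_vertices: int = 32
) -> tuple[tuple[float, float], ...]:
    t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    ex = a_px * np.cos(t)
    ey = b_px * np.sin(t)
    xs = cx + ex * np.cos(theta) - ey * np.sin(theta)
    ys = cy + ex * np.sin(theta) + ey * np.cos(theta)
    return tuple(zip(xs.tolist(), ys.tolist()))


def _place_nuclei(
    labels: np.ndarray,
    region_codes: tuple[int, ...],
    density_per_mm2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform Poisson point sample over the pixels of a mask region."""
    rows, cols = np.nonzero(np.isin(labels, region_codes))
    if rows.size == 0 or density_per_mm2 == 0:
        return np.zeros((0, 2))
    expected = density_per_mm2 * rows.size * MM2_PER_PX
    if expected > MAX_NUCLEI_PER_SLIDE:
        raise ValueError(f"intensity implies ~{expected:.0f} nuclei per slide")
    n = rng.poisson(expected)
    idx = rng.integers(0, rows.size, size=n)
    jitter = rng.random((n, 2))
    return np.column_stack([cols[idx] + jitter[:, 0], rows[idx] + jitter[:, 1]])


def generate_slide(
    params: SimulationParams, label: int, rng: np.random.Generator
) -> tuple[LayerMask, list[NucleusRecord]]:
    """One synthetic slide: layer mask plus typed, polygonised nuclei."""
    labels = _band_mask(params, phase=rng.uniform(0, 2 * np.pi))
    other_scale = params.other_multiplier if label else 1.0
    size_scale = params.size_multiplier if label else 1.0

    placements = [
        (NucleusClass.EPITHELIAL, (io.LAYER_EPITHELIUM,), params.epithelial_density, size_scale),
        (NucleusClass.BASAL_EPITHELIAL, (io.LAYER_BASAL,), params.basal_density, size_scale),
        (NucleusClass.OTHER, (io.LAYER_OTHER_TISSUE,),
         params.other_density_connective * other_scale, 1.0),
        (NucleusClass.OTHER, (io.LAYER_BASAL, io.LAYER_EPITHELIUM, io.LAYER_KERATIN),
         params.other_density_epithelium * other_scale, 1.0),
    ]

    records: list[NucleusRecord] = []
    nucleus_id = 0
    w, h = params.slide_width, params.slide_height
    for cls, codes, density, scale in placements:
        pts = _place_nuclei(labels, codes, density, rng)
        base_key = "other" if cls is NucleusClass.OTHER else cls.value
        mean_r_um = params.radius_um[base_key if base_key in params.radius_um else "other"]
        for cx, cy in pts:
            r_um = mean_r_um * scale * max(
                rng.normal(1.0, params.radius_cv), 0.3
            )
            ratio = float(np.exp(rng.normal(params.axis_ratio_log_mean,
                                            params.axis_ratio_log_sd)))
            r_px = r_um / params.mpp
            a_px = r_px * np.sqrt(ratio)
            b_px = r_px / np.sqrt(ratio)
            # keep the whole contour inside the slide (coords must be >= 0)
            cx = float(np.clip(cx, a_px, w - a_px - 1e-6))
            cy = float(np.clip(cy, a_px, h - a_px - 1e-6))
            records.append(
                NucleusRecord(
                    nucleus_id=nucleus_id,
                    centroid=(cx, cy),
                    contour=_ellipse_contour(cx, cy, a_px, b_px,
                                             rng.uniform(0, np.pi)),
                    model_class=cls,
                )
            )
            nucleus_id += 1
    return LayerMask(labels=labels, resolution_mpp=params.mpp), records


def _survival_time(
    label: int, params: SimulationParams, rng: np.random.Generator
) -> float:
    """Event time (transforming) or censoring time (non-transforming)."""
    if label:
        rate = params.baseline_rate * params.hazard_ratio
        # inverse-CDF exponential truncated to the follow-up window
        u = rng.uniform(0, 1 - np.exp(-rate * params.followup_years))
        return float(-np.log(1 - u) / rate)
    return float(rng.uniform(1.0, params.followup_years))


def _grades(label: int, rng: np.random.Generator) -> tuple[WHOGrade, BinaryGrade]:
    grades = [WHOGrade.MILD, WHOGrade.MODERATE, WHOGrade.SEVERE]
    if label:
        who = grades[rng.choice(3, p=[0.15, 0.30, 0.55])]
        binary = BinaryGrade.HIGH_RISK if rng.random() < 0.75 else BinaryGrade.LOW_RISK
    else:
        who = grades[rng.choice(3, p=[0.55, 0.30, 0.15])]
        binary = BinaryGrade.HIGH_RISK if rng.random() < 0.25 else BinaryGrade.LOW_RISK
    return who, binary


def simulate_cohort(
    params: SimulationParams,
) -> tuple[CohortTable, dict[str, tuple[LayerMask, list[NucleusRecord]]]]:
    """Generate the whole cohort in memory (deterministic per seed)."""
    root = np.random.default_rng(params.seed)
    slide_seeds = root.integers(0, 2**31 - 1, size=params.n_slides)
    meta_rng = np.random.default_rng(root.integers(0, 2**31 - 1))

    slides: list[SlideRecord] = []
    data: dict[str, tuple[LayerMask, list[NucleusRecord]]] = {}
    patient_counter = 0
    pending_patient: str | None = None
    for i in range(params.n_slides):
        rng = np.random.default_rng(slide_seeds[i])
        label = int(meta_rng.random() < params.prevalence)
        mask, nuclei = generate_slide(params, label, rng)
        slide_id = f"slide_{i:03d}"
        # ~10% of patients contribute two consecutive slides
        if pending_patient is not None:
            patient_id, pending_patient = pending_patient, None
        else:
            patient_id = f"patient_{patient_counter:03d}"
            patient_counter += 1
            if meta_rng.random() < 0.1 and i + 1 < params.n_slides:
                pending_patient = patient_id
        who, binary = _grades(label, meta_rng)
        slides.append(
            SlideRecord(
                slide_id=slide_id,
                patient_id=patient_id,
                transformed=label,
                time_to_event=_survival_time(label, params, meta_rng),
                who_grade=who,
                binary_grade=binary,
                age=float(np.round(meta_rng.normal(60, 10), 1)),
                sex=int(meta_rng.random() < 0.5),
                site=int(meta_rng.integers(0, 5)),
            )
        )
        data[slide_id] = (mask, nuclei)
    return CohortTable(slides=slides), data


def generate_cohort(params: SimulationParams, out_dir: str | Path) -> CohortTable:
    """Generate the cohort and write masks, nuclei JSON and cohort CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort, data = simulate_cohort(params)
    for slide_id, (mask, nuclei) in data.items():
        io.write_layer_mask(out_dir / f"{slide_id}_mask.png", mask)
        io.write_nuclei(out_dir / f"{slide_id}_nuclei.json", nuclei, mpp=params.mpp)
    io.write_cohort(out_dir / "cohort.csv", cohort)
    return cohort


def simulate_survival(
    n: int,
    hazard_ratio: float = 3.0,
    baseline_rate: float = 0.1,
    censor_horizon: float = 15.0,
    seed: int = 0,
) -> "np.recarray":
    """Proportional-hazards simulator for parameter-recovery checks.

    A binary covariate x ~ Bernoulli(0.5); event times exponential with rate
    ``baseline_rate * hazard_ratio**x``; administrative censoring at
    ``censor_horizon``.  Returns a recarray with fields time, event, x.
    """
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, size=n)
    rate = baseline_rate * hazard_ratio ** x
    t = rng.exponential(1.0 / rate)
    event = (t <= censor_horizon).astype(int)
    time = np.minimum(t, censor_horizon)
    out = np.rec.fromarrays([time, event, x], names=("time", "event", "x"))
    return out
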