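"""Seeded synthetic-cohort generator for longitudinal liquid biopsies.

The generator emulates the statistical structure of the target data:

* per-patient 1–5 collection timepoints per modality with median 3,
  drawn independently per modality so the two time grids mismatch;
* fluorescence-like composite crops — DAPI nucleus in blue, CEP8
  puncta in red, and a CD31-style membrane ring in green for CECs;
* positive serum-marker trajectories with label-dependent
  multiplicative trends.

The response signal lives in the *dynamics*: responders' nuclei shrink
and marker levels fall over treatment, non-responders' grow and rise.
Baseline cell counts carry no label information by construction, so a
count-based classifier is beatable exactly where dynamic modelling
should win. ``effect_size = 0`` removes the label linkage entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import (CellClass, CellImage, CellObservation, Cohort,
                     MarkerPanel, MarkerObservation, PatientRecord,
                     RecistLabel, ResponseLabel)

__all__ = ["SynthConfig", "GridFixture", "generate_cohort",
           "render_cell_image", "compose_grid_fixture"]

# P(T = t) for t = 1..5; median 3, mimicking "median 3, IQR 1–4".
_TIMEPOINT_PMF = np.array([0.22, 0.18, 0.25, 0.20, 0.15])

# Per-marker lognormal baseline parameters (log-mean, log-sd), loosely
# spanning the scale spread of AFP/CEA/CA19-9/CA72-4/CA125/NSE assays.
_MARKER_LOGMU = np.array([1.5, 1.0, 3.0, 1.2, 2.8, 2.2])
_MARKER_LOGSD = np.array([0.8, 0.6, 1.0, 0.7, 0.9, 0.5])


@dataclass(frozen=True)
class SynthConfig:
    n_patients: int = 90
    responder_frac: float = 0.59
    timepoints_range: tuple = (1, 5)
    image_size: int = 64
    cells_per_tp_mean: float = 3.0
    effect_size: float = 2.0
    marker_noise_sd: float = 0.25
    time_span_days: float = 400.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if not 0.0 < self.responder_frac < 1.0:
            raise ValueError("responder_frac must be in (0,1)")
        lo, hi = self.timepoints_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid timepoints_range")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.image_size < 8:
            raise ValueError("image_size too small")


@dataclass
class GridFixture:
    """A grid-arranged scan plus ground-truth crop boxes.

    Boxes are (row, col, h, w), 0-based, half-open; pairwise disjoint.
    """

    image: np.ndarray
    boxes: list


def _quantize(px: np.ndarray) -> np.ndarray:
    """Snap pixels to the 8-bit grid so PNG round-trips are exact."""
    return np.round(np.clip(px, 0.0, 1.0) * 255.0) / 255.0


def render_cell_image(size: int, nucleus_radius: float, spot_count: int,
                      cell_class: CellClass, rng: np.random.Generator) -> CellImage:
    """Render one composite fluorescence-like cell crop.

    Blue channel: an elliptical nucleus (axis ratio drawn near 1);
    red channel: `spot_count` bright puncta inside the nucleus;
    green channel: a membrane ring, present only for CECs.
    Background carries additive Gaussian noise in every channel.
    """
    if not 0 < nucleus_radius < size / 2:
        raise ValueError(f"nucleus_radius {nucleus_radius} out of (0, {size / 2})")
    if spot_count < 0:
        raise ValueError("spot_count must be >= 0")

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = size / 2 + rng.uniform(-2, 2)
    cx = size / 2 + rng.uniform(-2, 2)
    axis_ratio = rng.uniform(0.8, 1.0)
    theta = rng.uniform(0, np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    r2 = (u / nucleus_radius) ** 2 + (v / (nucleus_radius * axis_ratio)) ** 2

    img = np.zeros((size, size, 3))
    # nucleus: bright core with a soft edge whose half-maximum falls on
    # the nominal ellipse boundary (r2 = 1)
    img[:, :, 2] = 0.85 * np.clip(1.5 - r2, 0.0, 1.0)

    # CEP8 puncta strictly inside the nucleus
    for _ in range(spot_count):
        rad = np.sqrt(rng.uniform(0, 0.55))
        ang = rng.uniform(0, 2 * np.pi)
        su = rad * nucleus_radius * np.cos(ang)
        sv = rad * nucleus_radius * axis_ratio * np.sin(ang)
        sx = cx + su * ct - sv * st
        sy = cy + su * st + sv * ct
        d2 = (xx - sx) ** 2 + (yy - sy) ** 2
        img[:, :, 0] += 0.9 * np.exp(-d2 / (2 * 1.5 ** 2))

    if cell_class is CellClass.CEC:
        ring = np.exp(-((np.sqrt(r2) - 1.25) ** 2) / (2 * 0.12 ** 2))
        img[:, :, 1] = 0.7 * ring

    img += rng.normal(0.0, 0.02, size=img.shape)
    return CellImage(pixels=_quantize(img), cell_class=cell_class)


def _draw_times(rng: np.random.Generator, T: int, span: float) -> np.ndarray:
    """Visit times: first draw early in treatment, then sub-3-month gaps.

    Mirrors real collection schedules (first biopsy within ~3 months,
    follow-ups at intervals under 3 months); rescaled into the span if
    the walk overshoots.
    """
    t0 = rng.uniform(0.0, 90.0)
    gaps = rng.uniform(15.0, 90.0, size=max(T - 1, 0))
    times = t0 + np.concatenate([[0.0], np.cumsum(gaps)])
    if times[-1] > span:
        times = times * (span / times[-1])
    return times


def _draw_timepoint_count(rng: np.random.Generator, lo: int, hi: int) -> int:
    support = np.arange(lo, hi + 1)
    if (lo, hi) == (1, 5):
        pmf = _TIMEPOINT_PMF
    else:
        pmf = np.ones(len(support)) / len(support)
    return int(rng.choice(support, p=pmf))


def generate_cohort(config: SynthConfig) -> Cohort:
    """Generate a labelled synthetic cohort (bit-reproducible per seed)."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.timepoints_range
    span = config.time_span_days
    es = config.effect_size

    patients = []
    for i in range(config.n_patients):
        responder = rng.random() < config.responder_frac
        s_y = -1.0 if responder else 1.0
        recist = (RecistLabel.PR if responder else RecistLabel.SD)

        # --- cell-image stream -------------------------------------
        t_cells = _draw_times(rng, _draw_timepoint_count(rng, lo, hi), span)
        base_radius = config.image_size * rng.uniform(0.14, 0.2)
        base_spots = rng.integers(2, 5)
        cell_series = []
        for t in t_cells:
            n_cells = 1 + rng.poisson(max(config.cells_per_tp_mean - 1, 0.0))
            ctc_frac = rng.uniform(0.3, 0.7)
            trend = np.exp(s_y * es * t / span)
            images = []
            for _ in range(n_cells):
                noise = rng.lognormal(0.0, 0.1)
                radius = float(np.clip(base_radius * trend * noise,
                                       2.0, config.image_size / 2 - 1))
                spots = max(0, int(np.round(base_spots * trend
                                            * rng.lognormal(0.0, 0.15))))
                cls = CellClass.CTC if rng.random() < ctc_frac else CellClass.CEC
                images.append(render_cell_image(config.image_size, radius,
                                                spots, cls, rng))
            cell_series.append(CellObservation(t_days=float(t), images=images))

        # --- marker stream (independent time grid) ------------------
        t_mark = _draw_times(rng, _draw_timepoint_count(rng, lo, hi), span)
        baselines = np.exp(rng.normal(_MARKER_LOGMU, _MARKER_LOGSD))
        marker_series = []
        for t in t_mark:
            eps = rng.normal(0.0, config.marker_noise_sd, size=len(baselines))
            vals = baselines * np.exp(s_y * es * t / span + eps)
            marker_series.append(MarkerObservation(
                t_days=float(t),
                panel=MarkerPanel(tuple(np.maximum(vals, 0.0)))))

        patients.append(PatientRecord(
            patient_id=f"SP{i:04d}",
            cell_series=cell_series,
            marker_series=marker_series,
            label=(ResponseLabel.RESPONDER if responder
                   else ResponseLabel.NON_RESPONDER),
            rec_label=recist))
    return Cohort(patients=patients, name=f"synthetic-seed{config.seed}")


def compose_grid_fixture(cells: list, n_rows: int, n_cols: int,
                         margin: int = 8) -> GridFixture:
    """Tile cell crops row-major with black gutters; return ground truth.

    Box (i, j) has top-left ``(margin + i*(h+margin), margin + j*(w+margin))``.
    All crops must share one size.
    """
    if len(cells) > n_rows * n_cols:
        raise ValueError(f"{len(cells)} cells exceed {n_rows}x{n_cols} grid")
    if not cells:
        h = w = 32
        canvas = np.zeros((margin + n_rows * (h + margin),
                           margin + n_cols * (w + margin), 3))
        return GridFixture(image=canvas, boxes=[])
    h, w = cells[0].pixels.shape[:2]
    canvas = np.zeros((margin + n_rows * (h + margin),
                       margin + n_cols * (w + margin), 3))
    boxes = []
    for k, cell in enumerate(cells):
        i, j = divmod(k, n_cols)
        r0 = margin + i * (h + margin)
        c0 = margin + j * (w + margin)
        canvas[r0:r0 + h, c0:c0 + w] = cell.pixels
        boxes.append((r0, c0, h, w))
    return GridFixture(image=canvas, boxes=boxes)
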