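"""Seeded synthetic crystallogram studies with the assay's statistical structure.

The renderer is a stylised branching-walk texture generator, not a physical
model of CuCl2 dendrite growth: the analysis pipeline uses plate images only
as texture carriers, so what matters is that the generated studies carry the
statistical structure the evaluation layer is built to detect:

* day-to-day texture baseline variation and a day-specific evaporation time
  (LBI around 13.5-15 h, BRAD around 17-26 h);
* a verum/control treatment signal split into two spatial components — a
  reproducible contrast gain in the 70-90 % annulus and a centre-zone
  (r < 65 %) third-moment asymmetry from positively skewed bright speckles —
  plus a day-modulated gain in the 50-70 % annulus (day x treatment
  interaction);
* a linear processing-order drift and per-plate replicate noise, both acting
  on the relative fine-noise amplitude (a structural texture parameter that
  survives the global Gaussian grey normalisation);
* peripheral crystallisations — ramifications growing inward from the rim —
  when evaporation time exceeds its threshold (about 19 h).

All randomness is drawn from per-plate streams keyed by (lab, day,
processing order, plate replicate), so a plate's image is insensitive to
unrelated design edits and the full study is a pure function of
(design, configs, seed).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from .design import CONTROL, VERUM, ExperimentDesign, PlateRecord
from .imageprep import GreyImage

__all__ = [
    "EffectConfig",
    "EvaporationModel",
    "PlateGeometry",
    "simulate_evaporation",
    "render_crystallogram",
    "peripheral_branch_count",
    "simulate_seedling_weights",
    "generate_study",
    "iter_study_images",
]


@dataclass(frozen=True)
class EffectConfig:
    """Synthetic effect magnitudes.

    ``treatment_effect`` is a dimensionless multiplier on the verum texture
    signal (0 = null configuration).  ``day_sd``, ``noise_sd`` and
    ``order_slope`` act on the relative fine-noise amplitude;
    ``day_by_treatment_sd`` scales the day-modulated (interaction) component
    of the treatment signal; ``evap_coeff`` couples evaporation time to
    texture roughness (per hour).  ``peripheral_threshold`` is the
    evaporation time (h) above which rim-origin ramifications appear.
    ``granulation_base`` sets the centre-zone speckle amplitude relative to
    the plate contrast and ``granulation_sd`` the log-normal plate-to-plate
    spread of that amplitude (the asymmetry channel).
    """

    treatment_effect: float = 0.15
    day_sd: float = 0.03
    day_by_treatment_sd: float = 0.6
    order_slope: float = 0.0
    lab_offsets: tuple[float, ...] = (0.0, 0.0)
    noise_sd: float = 0.03
    evap_coeff: float = 0.16
    peripheral_threshold: float = 19.0
    granulation_base: float = 1.3
    granulation_sd: float = 0.45

    def __post_init__(self) -> None:
        for name in ("day_sd", "day_by_treatment_sd", "noise_sd", "granulation_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def null(cls, **kw) -> "EffectConfig":
        return cls(treatment_effect=0.0, **kw)


@dataclass(frozen=True)
class EvaporationModel:
    """Evaporation-time model: per-lab base hours with bounded day variation.

    The per-day mean is ``base + U(-day_spread, +day_spread)`` and plates
    scatter around it with Gaussian SD ``replicate_sd`` — the day effect
    dominates the replicate effect, as observed.  Defaults reproduce the
    reported per-day mean ranges (LBI 13.5-15 h, BRAD 17-26 h).
    """

    lab_base: dict[str, float] = field(
        default_factory=lambda: {"LBI": 14.25, "BRAD": 21.5}
    )
    day_spread: dict[str, float] = field(
        default_factory=lambda: {"LBI": 0.75, "BRAD": 4.5}
    )
    replicate_sd: float = 0.15

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.lab_base.values()):
            raise ValueError("lab_base hours must be positive")
        if any(s < 0 for s in self.day_spread.values()) or self.replicate_sd < 0:
            raise ValueError("spreads must be >= 0")


@dataclass(frozen=True)
class PlateGeometry:
    """Image size and crystallised-disc diameter in pixels."""

    size: int = 512
    plate_diameter_px: int = 460

    def __post_init__(self) -> None:
        if self.plate_diameter_px <= 0 or self.size <= 0:
            raise ValueError("degenerate geometry: size and diameter must be > 0")
        if self.plate_diameter_px > self.size:
            raise ValueError("plate disc must fit inside the image")


REDUCED_GEOMETRY = PlateGeometry(size=128, plate_diameter_px=116)


# ---------------------------------------------------------------------------
# Seed plumbing
# ---------------------------------------------------------------------------

def _lab_key(lab: str) -> int:
    return zlib.crc32(lab.encode())


def _day_rng(seed: int, lab: str, day: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_lab_key(lab), day, 0xDA))
    )


def _group_index(record: PlateRecord) -> int:
    if record.processing_order is not None:
        return record.processing_order
    # uncoded design: stable surrogate from group identity
    return _lab_key(f"{record.truth}:{record.internal_replicate}") % 997 + 10


def _plate_rng(seed: int, record: PlateRecord) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(
            seed,
            spawn_key=(
                _lab_key(record.lab),
                record.day,
                _group_index(record),
                record.plate_replicate or 0,
            ),
        )
    )


# ---------------------------------------------------------------------------
# Evaporation times and seedling weights
# ---------------------------------------------------------------------------

def simulate_evaporation(
    design: ExperimentDesign,
    model: EvaporationModel = EvaporationModel(),
    seed: int = 0,
) -> ExperimentDesign:
    """Fill ``evaporation_time`` on every plate of the design.

    Times are nearly constant within a day; treatment groups are
    exchangeable (the day mean is drawn once per day, before any group
    assignment enters).
    """
    for lab, day in design.days():
        base = model.lab_base.get(lab)
        spread = model.day_spread.get(lab)
        if base is None or spread is None:
            raise ValueError(f"no evaporation model entry for lab {lab!r}")
        rng = _day_rng(seed, lab, day)
        day_mean = base + rng.uniform(-spread, spread)
        for r in design.day_slots(lab, day):
            jitter = _plate_rng(seed, r).normal(0.0, model.replicate_sd) \
                if model.replicate_sd > 0 else 0.0
            r.evaporation_time = float(max(0.1, day_mean + jitter))
    design.audit_log.append(f"simulated evaporation times, seed={seed}")
    return design


def simulate_seedling_weights(
    design: ExperimentDesign,
    mean_mg: float = 30.0,
    offset_percent: float = 2.7,
    sd_mg: float = 1.2,
    seed: int = 0,
    labs: tuple[str, str] = ("LBI", "BRAD"),
) -> pd.DataFrame:
    """Average seedling weight per extract group (one data point per group).

    The second lab's seedlings are heavier by ``offset_percent`` (the study
    observed BRAD seedlings 2.7 % heavier than LBI).
    """
    if sd_mg < 0:
        raise ValueError("sd_mg must be >= 0")
    rows = []
    for lab, day in design.days():
        recs = [r for r in design.day_slots(lab, day) if not r.is_reference]
        groups = sorted({_group_index(r) for r in recs})
        rng = _day_rng(seed + 0x5EED, lab, day)
        lab_mean = mean_mg * (1.0 + offset_percent / 100.0 * (lab == labs[1]))
        for g in groups:
            w = lab_mean + (rng.normal(0.0, sd_mg) if sd_mg > 0 else 0.0)
            rows.append(dict(lab=lab, day=day, group=g, weight_mg=float(w)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def peripheral_branch_count(
    evaporation_time: float, threshold: float, radius_px: float
) -> int:
    """Number of rim-origin ramifications; 0 at or below the threshold."""
    excess = max(0.0, evaporation_time - threshold)
    return int(0.09 * radius_px * excess)


def _deposit_walks(
    img: np.ndarray,
    y0: np.ndarray,
    x0: np.ndarray,
    theta0: np.ndarray,
    n_steps: int,
    sigma_theta: float,
    amp: np.ndarray,
    rng: np.random.Generator,
    centre: tuple[float, float],
    r_max: float,
) -> None:
    """Accumulate random-walk polylines (unit steps) into ``img`` in place."""
    k = len(theta0)
    if k == 0 or n_steps == 0:
        return
    theta = theta0[:, None] + rng.normal(0.0, sigma_theta, (k, n_steps)).cumsum(axis=1)
    y = y0[:, None] + np.sin(theta).cumsum(axis=1)
    x = x0[:, None] + np.cos(theta).cumsum(axis=1)
    taper = 1.0 - 0.45 * np.arange(n_steps) / n_steps
    a = np.broadcast_to(amp[:, None] * taper, y.shape)
    iy = np.round(y).astype(int)
    ix = np.round(x).astype(int)
    h, w = img.shape
    cy, cx = centre
    ok = (iy >= 0) & (iy < h) & (ix >= 0) & (ix < w)
    ok &= (iy - cy) ** 2 + (ix - cx) ** 2 <= r_max**2
    np.add.at(img, (iy[ok], ix[ok]), a[ok])


def render_crystallogram(
    record: PlateRecord,
    effects: EffectConfig = EffectConfig(),
    geometry: PlateGeometry = PlateGeometry(),
    seed: int = 0,
    truth: str | None = None,
    lab_index: int | None = None,
) -> GreyImage:
    """Render one plate as a stylised dendritic texture.

    ``truth`` overrides ``record.truth`` (needed when rendering a blinded
    design; the generator plays the role of nature and knows the
    assignment).  Same (record, effects, geometry, seed) gives bit-identical
    pixels.
    """
    truth = truth if truth is not None else record.truth
    if record.evaporation_time is None:
        raise ValueError("record has no evaporation_time; simulate it first")
    if truth is None and effects.treatment_effect != 0.0:
        raise ValueError("treatment identity unknown but treatment_effect != 0")

    n = geometry.size
    R = geometry.plate_diameter_px / 2.0
    cy = cx = (n - 1) / 2.0
    day_rng = _day_rng(seed, record.lab, record.day)
    eps_day = day_rng.normal(0.0, effects.day_sd) if effects.day_sd > 0 else 0.0
    m_day = (
        day_rng.normal(0.0, effects.day_by_treatment_sd)
        if effects.day_by_treatment_sd > 0
        else 0.0
    )
    rng = _plate_rng(seed, record)

    if lab_index is None:
        lab_index = 0 if record.lab == "LBI" else 1
    lab_off = effects.lab_offsets[lab_index % len(effects.lab_offsets)]
    order = record.processing_order if record.processing_order is not None else 3.5
    rho = (
        1.0
        + eps_day
        + effects.evap_coeff * (record.evaporation_time - 14.0)
        + effects.order_slope * (order - 3.5)
        + lab_off
        + (rng.normal(0.0, effects.noise_sd) if effects.noise_sd > 0 else 0.0)
    )
    rho = float(np.clip(rho, 0.15, 4.0))

    # -- dendritic branch layer -------------------------------------------
    layer = np.zeros((n, n))
    ang = rng.uniform(0, 2 * np.pi)
    rad = 0.08 * R * np.sqrt(rng.uniform())
    ny, nx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)

    # Bipolar deposits: crystal ridges brighten, interstitial shadows darken.
    # Zero-mean amplitudes keep the baseline grey distribution symmetric, so
    # the third-moment (asymmetry) channel belongs to the speckle component
    # alone and does not leak roughness (evaporation/day) variation.
    # Exact sign balance (paired +/- amplitudes) keeps the layer's third
    # moment near zero; a binomial sign draw would leave a net imbalance of
    # order sqrt(n_br) branches, swamping the speckle asymmetry channel.
    n_br = 2 * max(4, int(0.21 * R))
    steps = int(1.15 * R)
    theta0 = rng.uniform(0, 2 * np.pi, n_br)
    mag = 95.0 * rng.uniform(0.55, 1.0, n_br // 2)
    sign = np.repeat((1.0, -1.0), n_br // 2)
    amp = sign * np.concatenate((mag, mag))
    _deposit_walks(
        layer, np.full(n_br, ny), np.full(n_br, nx), theta0, steps, 0.045,
        amp, rng, (cy, cx), 0.995 * R,
    )
    # Short side branchlets anchored on the main branches; amplitudes are
    # paired across the +/- parent halves so the branchlet population is
    # sign-balanced too.
    m_half = 2 * n_br
    b_half = rng.integers(0, n_br // 2, m_half)
    b_idx = np.concatenate((b_half, b_half + n_br // 2))
    m_side = 2 * m_half
    s_idx = rng.integers(int(0.15 * steps), steps, m_side)
    base_theta = theta0[b_idx] + 0.045 * rng.normal(0, np.sqrt(s_idx))
    side_theta = base_theta + rng.choice((-1.0, 1.0), m_side) * rng.uniform(
        0.5, 1.1, m_side
    )
    ay = ny + s_idx * np.sin(base_theta)
    ax = nx + s_idx * np.cos(base_theta)
    side_mag = 0.8 * 95.0 * rng.uniform(0.5, 1.0, m_half)
    _deposit_walks(
        layer, ay, ax, side_theta, max(2, int(0.12 * R)), 0.08,
        sign[b_idx] * np.concatenate((side_mag, side_mag)),
        rng, (cy, cx), 0.995 * R,
    )

    # peripheral crystallisations for prolonged evaporation
    n_rim = peripheral_branch_count(
        record.evaporation_time, effects.peripheral_threshold, R
    )
    if n_rim > 0:
        phi = rng.uniform(0, 2 * np.pi, n_rim)
        ry = cy + 0.99 * R * np.sin(phi)
        rx = cx + 0.99 * R * np.cos(phi)
        inward = phi + np.pi + rng.normal(0, 0.2, n_rim)
        rim_mag = 95.0 * rng.uniform(0.6, 1.0, n_rim)
        rim_sign = np.where(np.arange(n_rim) % 2 == 0, 1.0, -1.0)
        rim_mag[1::2] = rim_mag[0 : n_rim - n_rim % 2 : 2]  # pair magnitudes
        _deposit_walks(
            layer, ry, rx, inward, max(2, int(0.30 * R)), 0.07,
            rim_sign * rim_mag, rng, (cy, cx), 0.998 * R,
        )

    layer = gaussian_filter(layer, 1.1)

    # fine-grained noise, relative amplitude rho (structural roughness)
    noise = gaussian_filter(rng.normal(size=(n, n)), 0.45)
    noise *= 11.0 * rho / noise.std()

    img = 110.0 + layer + noise

    yy, xx = np.ogrid[:n, :n]
    r_grid = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    disc = r_grid <= R

    # Centre-zone granulation: soft bright droplets on every plate; verum
    # amplifies them.  A single plate-level strength sets the amplitude of
    # all droplets (individual droplets vary only slightly around it), so
    # the level-sum asymmetry variables (third moment, diagonal moment)
    # move together across plates.  Because the droplets are smooth blobs,
    # they add high-level mass with small pixel-to-pixel gradients and so
    # leave the gradient-based roughness variables (inertia, inverse
    # difference moment, difference statistics) to the fine-noise channel.
    # The verum amplification is mostly variance-neutral: the droplet count
    # falls as 1/sqrt(boost) while the amplitude rises with boost, so the
    # third moment grows much faster with the treatment than the droplets'
    # contribution to the total plate variance (a fully variance-coupled
    # boost would leak into every region through the global grey
    # normalisation).
    boost = 1.0 + 3.0 * effects.treatment_effect if truth == VERUM else 1.0
    n_sp = max(6, int(round(0.004 * np.pi * R**2 / boost**0.5)))
    sr = 0.65 * R * np.sqrt(rng.uniform(size=n_sp))
    sa = rng.uniform(0, 2 * np.pi, n_sp)
    sy = np.round(cy + sr * np.sin(sa)).astype(int)
    sx = np.round(cx + sr * np.cos(sa)).astype(int)
    plate_mult = float(np.exp(rng.normal(0.0, effects.granulation_sd)))
    scale = effects.granulation_base * float(img[disc].std()) * boost * plate_mult
    sp_amp = scale * rng.uniform(0.9, 1.1, n_sp)
    sp_sigma = 0.9
    sp_layer = np.zeros_like(img)
    np.add.at(sp_layer, (sy, sx), sp_amp * (2.0 * np.pi * sp_sigma**2))
    img += gaussian_filter(sp_layer, sp_sigma)

    # annulus-local treatment gains (verum only)
    if truth == VERUM and effects.treatment_effect != 0.0:
        mu = img[disc].mean()
        g_main = 0.55 * effects.treatment_effect * (1.0 + rng.normal(0.0, 0.05))
        ann = disc & (r_grid >= 0.70 * R) & (r_grid < 0.90 * R)
        img[ann] = mu + (1.0 + g_main) * (img[ann] - mu)
        g_int = effects.treatment_effect * m_day
        ann2 = disc & (r_grid >= 0.50 * R) & (r_grid < 0.70 * R)
        img[ann2] = mu + (1.0 + g_int) * (img[ann2] - mu)

    img[~disc] = 10.0
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return GreyImage(img, centre=(cy, cx), plate_diameter_px=float(geometry.plate_diameter_px))


# ---------------------------------------------------------------------------
# Whole-study generation
# ---------------------------------------------------------------------------

def _record_truth(design: ExperimentDesign, record: PlateRecord) -> str | None:
    if record.truth is not None:
        return record.truth
    if record.code is not None:
        entry = design._truth_map.get((record.lab, record.day, record.code))
        if entry is not None:
            return entry[0]
    return None


def iter_study_images(
    design: ExperimentDesign,
    effects: EffectConfig = EffectConfig(),
    geometry: PlateGeometry = PlateGeometry(),
    seed: int = 0,
):
    """Yield (record, truth, image) for every usable treatment plate.

    Renders in memory; reference-standard slots are scheduling placeholders
    and are not rendered.
    """
    for r in design.treatment_records():
        truth = _record_truth(design, r)
        yield r, truth, render_crystallogram(r, effects, geometry, seed, truth=truth)


def generate_study(
    design: ExperimentDesign,
    effects: EffectConfig = EffectConfig(),
    evap_model: EvaporationModel = EvaporationModel(),
    geometry: PlateGeometry = PlateGeometry(),
    out_dir: str | Path = "study",
    seed: int = 0,
    force: bool = False,
) -> Path:
    """Write a full synthetic study: PNG images, metadata CSV, manifest.

    One grey PNG per non-discarded treatment plate, a metadata CSV
    row-aligned with the image files, and a JSON manifest carrying the seed
    and configurations for full reproducibility.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    (out / "images").mkdir(exist_ok=True)

    if any(r.evaporation_time is None for r in design.treatment_records()):
        simulate_evaporation(design, evap_model, seed)

    files = []
    for r, truth, img in iter_study_images(design, effects, geometry, seed):
        fname = f"{r.record_id}.png"
        try:
            Image.fromarray(img.pixels).save(out / "images" / fname)
        except OSError as exc:
            raise OSError(f"failed writing {out / 'images' / fname}: {exc}") from exc
        files.append(fname)

    meta = design.to_frame()
    meta = meta[(meta["truth"] != "reference") & (~meta["discarded"])].reset_index(
        drop=True
    )
    meta["image"] = files
    meta.to_csv(out / "metadata.csv", index=False)

    manifest = dict(
        seed=seed,
        n_images=len(files),
        geometry=asdict(geometry),
        effects=asdict(effects),
        evaporation=dict(
            lab_base=evap_model.lab_base,
            day_spread=evap_model.day_spread,
            replicate_sd=evap_model.replicate_sd,
        ),
        scheme=design.scheme,
        blinded=design.coded and not design.decoded,
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    design.audit_log.append(f"generated study at {out} ({len(files)} images)")
    return out
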