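"""End-to-end orchestration: generate or ingest a study, extract texture
features, and emit the evaluation report tables.

The blinded workflow mirrors the assay: ``run_generate`` writes a coded
study (images + metadata + separate coding key), ``run_analyze`` extracts
features and blinded summaries without ever seeing truth labels, and
``run_decode`` reveals the code and emits the treatment-level statistical
reports (main-effect/interaction ANOVA tables, per-ROI localisation,
variable grouping, Holm flags, processing-order diagnostic and correction).
Decoding refuses to run before analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design as dz
from . import evaluation as ev
from .imageprep import GreyImage, ROISpec, STANDARD_ROIS, gaussian_normalize, roi_mask, read_image, to_grey
from .synthesis import (
    EffectConfig,
    EvaporationModel,
    PlateGeometry,
    generate_study,
    iter_study_images,
    simulate_evaporation,
)
from .texture import FEATURE_NAMES, CoocParams, features_for_rois

log = logging.getLogger("cresstex")

__all__ = [
    "RunConfig",
    "study_feature_table",
    "texture_reports",
    "run_generate",
    "run_analyze",
    "run_decode",
]

EFFECT_COLUMNS = (
    "day",
    "treatment",
    "replicate",
    "day:treatment",
    "day:replicate",
    "treatment:replicate",
    "day:treatment:replicate",
)
_FACTORS = ["day", "treatment", "replicate"]
SEGMENT_ROIS = tuple(r for r in STANDARD_ROIS if (r.inner_pct, r.outer_pct) != (0, 100))
FULL_ROI = ROISpec(0, 100)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable run configuration (YAML round-trip)."""

    n_labs: int = 2
    days_per_lab: tuple[int, ...] = (7, 8)
    n_treatments: int = 2
    n_internal: int = 3
    n_plate_reps: int = 6
    n_reference: int = 7
    scheme: str = "manual_emulated"
    geometry: PlateGeometry = field(default_factory=PlateGeometry)
    effects: EffectConfig = field(default_factory=EffectConfig)
    evaporation: EvaporationModel = field(default_factory=EvaporationModel)
    cooc: CoocParams = field(default_factory=CoocParams)
    rois: tuple[ROISpec, ...] = STANDARD_ROIS
    alpha: float = 0.05
    normalize: str = "linear"
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"] = asdict(self.geometry)
        d["effects"] = asdict(self.effects)
        d["evaporation"] = dict(
            lab_base=dict(self.evaporation.lab_base),
            day_spread=dict(self.evaporation.day_spread),
            replicate_sd=self.evaporation.replicate_sd,
        )
        d["cooc"] = dict(
            displacement=self.cooc.displacement,
            levels=self.cooc.levels,
            directions=[list(x) for x in self.cooc.directions],
        )
        d["rois"] = [[r.inner_pct, r.outer_pct] for r in self.rois]
        d["days_per_lab"] = list(self.days_per_lab)
        d["effects"]["lab_offsets"] = list(self.effects.lab_offsets)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["geometry"] = PlateGeometry(**d.get("geometry", {}))
        eff = dict(d.get("effects", {}))
        if "lab_offsets" in eff:
            eff["lab_offsets"] = tuple(eff["lab_offsets"])
        d["effects"] = EffectConfig(**eff)
        d["evaporation"] = EvaporationModel(**d.get("evaporation", {}))
        cooc = dict(d.get("cooc", {}))
        if "directions" in cooc:
            cooc["directions"] = tuple(tuple(x) for x in cooc["directions"])
        d["cooc"] = CoocParams(**cooc)
        if d.get("rois"):
            d["rois"] = tuple(ROISpec(a, b) for a, b in d["rois"])
        else:
            d["rois"] = STANDARD_ROIS
        d["days_per_lab"] = tuple(d.get("days_per_lab", (7, 8)))
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# In-memory study -> tidy feature table
# ---------------------------------------------------------------------------

def _plate_features(
    img: GreyImage,
    rois: tuple[ROISpec, ...],
    params: CoocParams,
    normalize: str | None,
) -> pd.DataFrame:
    if normalize:
        disc = roi_mask(img, FULL_ROI)
        img = gaussian_normalize(img, disc, method=normalize)
    return features_for_rois(img, rois, params)


def study_feature_table(
    design: dz.ExperimentDesign,
    effects: EffectConfig = EffectConfig(),
    geometry: PlateGeometry = PlateGeometry(),
    params: CoocParams = CoocParams(),
    rois: tuple[ROISpec, ...] = (FULL_ROI,),
    seed: int = 0,
    normalize: str | None = "linear",
    include_truth: bool = True,
) -> pd.DataFrame:
    """Render a study in memory and return the tidy per-plate feature table.

    One row per (plate, ROI).  ``include_truth`` attaches the unblinded
    treatment label (simulation-side convenience; the file-based analyze
    step never sees it).  Evaporation times must already be simulated.
    """
    frames = []
    for rec, truth, img in iter_study_images(design, effects, geometry, seed):
        feats = _plate_features(img, rois, params, normalize)
        feats.insert(0, "lab", rec.lab)
        feats.insert(1, "day", rec.day)
        feats.insert(2, "code", rec.code)
        feats.insert(3, "replicate", rec.internal_replicate)
        feats.insert(4, "plate_replicate", rec.plate_replicate)
        feats.insert(5, "processing_order", rec.processing_order)
        feats.insert(6, "evaporation_h", rec.evaporation_time)
        if include_truth:
            feats.insert(7, "treatment", truth)
        frames.append(feats)
    if not frames:
        raise ValueError("design has no usable plates")
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Statistical report layer (needs truth labels)
# ---------------------------------------------------------------------------

def _anova_row(sub: pd.DataFrame, var: str) -> tuple[dict, dict, ev.AnovaTable]:
    factors = [f for f in _FACTORS if sub[f].nunique() > 1]
    tab = ev.factorial_anova(sub, var, factors)
    ps = {c: np.nan for c in EFFECT_COLUMNS}
    fs = {c: np.nan for c in EFFECT_COLUMNS}
    for eff in tab.effects:
        ps[eff] = tab.p(eff)
        fs[eff] = tab.F(eff)
    return ps, fs, tab


def texture_reports(
    feat_long: pd.DataFrame,
    alpha: float = 0.05,
    order_mode: str = "ratio",
    variables: tuple[str, ...] = FEATURE_NAMES,
) -> dict:
    """Full evaluation of a decoded feature table.

    Returns a dict with the layered report tables:

    ``table1`` / ``table1_F``
        Whole-plate (ROI 0-100 %) day x treatment x replicate ANOVA p / F
        per texture variable.
    ``holm``
        Step-down-corrected rejection flags over the whole table1 family
        (all effects x all variables, the conservative independent-tests
        assumption).
    ``table2``
        Treatment main effect and day:treatment interaction p per annular
        segment, localising the signal.
    ``groups``
        Between-plate correlation grouping of the variables, with their
        evaporation-time correlations (whole plate).
    ``order_p``
        Control-group processing-order diagnostic p per variable.
    ``table4``
        Uncorrected vs order-corrected ANOVA p for variables flagged by the
        diagnostic at ``alpha``.
    """
    if "treatment" not in feat_long.columns:
        raise ValueError("feature table carries no treatment labels (still blinded?)")
    full = feat_long[feat_long["roi"] == FULL_ROI.label]
    if full.empty:
        raise ValueError("no whole-plate (0-100%) rows in feature table")

    p_rows, f_rows, order_p = {}, {}, {}
    for var in variables:
        ps, fs, _ = _anova_row(full, var)
        p_rows[var], f_rows[var] = ps, fs
        ctrl = full[full["treatment"] == dz.CONTROL]
        order_p[var] = ev.processing_order_test(
            ctrl, var, day_col="day", order_col="processing_order", mode=order_mode
        )
    table1 = pd.DataFrame(p_rows).T[list(EFFECT_COLUMNS)]
    table1_F = pd.DataFrame(f_rows).T[list(EFFECT_COLUMNS)]

    flat = table1.to_numpy().ravel()
    valid = ~np.isnan(flat)
    rej = np.zeros(flat.size, bool)
    if valid.any():
        rej[valid], _ = ev.holm_correction(flat[valid], alpha=alpha)
    holm = pd.DataFrame(
        rej.reshape(table1.shape), index=table1.index, columns=table1.columns
    )

    seg_rows = {}
    for var in variables:
        row = {}
        for roi in sorted(set(feat_long["roi"]) - {FULL_ROI.label}):
            sub = feat_long[feat_long["roi"] == roi]
            ps, _, _ = _anova_row(sub, var)
            row[f"treatment {roi}"] = ps["treatment"]
            row[f"day:treatment {roi}"] = ps["day:treatment"]
        seg_rows[var] = row
    table2 = pd.DataFrame(seg_rows).T

    groups = ev.correlate_and_group(
        full[list(variables)].reset_index(drop=True),
        full["evaporation_h"].to_numpy(),
    )

    order_p = pd.Series(order_p, name="order_p")
    flagged = [v for v in variables if order_p[v] < alpha]
    t4_rows = {}
    for var in flagged:
        corrected, _slope = ev.order_correction(
            full[var].to_numpy(), full["processing_order"].to_numpy()
        )
        sub = full.copy()
        sub[var] = corrected
        ps_u = p_rows[var]
        ps_c, _, _ = _anova_row(sub, var)
        t4_rows[var] = {
            **{f"{c}": ps_u[c] for c in EFFECT_COLUMNS},
            **{f"{c} corrected": ps_c[c] for c in EFFECT_COLUMNS},
        }
    table4 = pd.DataFrame(t4_rows).T

    return dict(
        table1=table1,
        table1_F=table1_F,
        holm=holm,
        table2=table2,
        groups=groups,
        order_p=order_p,
        table4=table4,
    )


# ---------------------------------------------------------------------------
# Disk-based orchestration
# ---------------------------------------------------------------------------

def run_generate(config: RunConfig, out_dir: str | Path, force: bool = False) -> Path:
    """Build, code and render a full synthetic study on disk.

    Writes images/, metadata.csv, manifest.json, the resolved config, and
    the coding key as a separate JSON file (for the code holder).
    """
    d = dz.build_design(
        n_labs=config.n_labs,
        days_per_lab=config.days_per_lab,
        n_treatments=config.n_treatments,
        n_internal=config.n_internal,
        n_plate_reps=config.n_plate_reps,
        n_reference=config.n_reference,
    )
    dz.randomize_and_code(d, scheme=config.scheme, seed=config.seed)
    simulate_evaporation(d, config.evaporation, config.seed)
    out = generate_study(
        d, config.effects, config.evaporation, config.geometry,
        out_dir=out_dir, seed=config.seed, force=force,
    )
    d.save_coding_key(out / "coding_key.json")
    config.save(out / "config.yaml")
    log.info("generated study with %d plates at %s", d.n_usable, out)
    return out


def run_analyze(
    config: RunConfig, study_dir: str | Path, out_dir: str | Path | None = None,
    force: bool = False,
) -> Path:
    """Extract per-plate, per-ROI texture features from a study on disk.

    Blinded stage: outputs carry treatment codes, never truth labels.
    Raises if any metadata row lacks its image file.
    """
    study = Path(study_dir)
    out = Path(out_dir) if out_dir else study / "report"
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"report directory {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)

    meta = pd.read_csv(study / "metadata.csv", dtype={"code": "string"})
    missing = [
        row.image for row in meta.itertuples()
        if not (study / "images" / row.image).exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing image files for metadata rows: {missing}")
    manifest = json.loads((study / "manifest.json").read_text())
    diam = float(manifest["geometry"]["plate_diameter_px"])

    frames = []
    for row in meta.itertuples():
        arr = to_grey(read_image(study / "images" / row.image))
        img = GreyImage(arr, centre=((arr.shape[0] - 1) / 2, (arr.shape[1] - 1) / 2),
                        plate_diameter_px=diam)
        feats = _plate_features(img, config.rois, config.cooc, config.normalize)
        feats.insert(0, "lab", row.lab)
        feats.insert(1, "day", row.day)
        feats.insert(2, "code", row.code)
        feats.insert(3, "replicate", row.internal_replicate)
        feats.insert(4, "plate_replicate", row.plate_replicate)
        feats.insert(5, "processing_order", row.processing_order)
        feats.insert(6, "evaporation_h", row.evaporation_h)
        frames.append(feats)
    features = pd.concat(frames, ignore_index=True)
    features.to_csv(out / "features.csv", index=False)

    evap_summary = (
        meta.groupby(["lab", "day"])["evaporation_h"].agg(["mean", "std", "count"])
    )
    evap_summary.to_csv(out / "evaporation_by_day.csv")
    (out / "analyze_manifest.json").write_text(
        json.dumps(
            dict(n_plates=len(meta), n_rows=len(features),
                 rois=[r.label for r in config.rois], decoded=False),
            indent=2,
        )
    )
    log.info("analyzed %d plates -> %s", len(meta), out)
    return out


def run_decode(
    report_dir: str | Path,
    key: dict | str | Path,
    alpha: float = 0.05,
    order_mode: str = "ratio",
) -> Path:
    """Reveal the code and emit the treatment-level statistical reports.

    Refuses if the analysis stage has not been run (enforces
    analyze-before-decode ordering).  Re-running with the same key simply
    rewrites the same tables (idempotent).
    """
    report = Path(report_dir)
    feat_path = report / "features.csv"
    if not feat_path.exists():
        raise FileNotFoundError(
            "premature decode: run the analysis stage first (features.csv missing)"
        )
    if not isinstance(key, dict):
        key = json.loads(Path(key).read_text())

    features = pd.read_csv(feat_path, dtype={"code": "string"})
    def lookup(row):
        try:
            return key[f"{row.lab}:{row.day}"][str(row.code)]
        except KeyError as exc:
            raise ValueError(f"coding key has no entry for {row.lab}:{row.day} "
                             f"code {row.code}") from exc
    features["treatment"] = [lookup(r) for r in features.itertuples()]

    reports = texture_reports(features, alpha=alpha, order_mode=order_mode)
    features.to_csv(report / "features_decoded.csv", index=False)
    reports["table1"].to_csv(report / "anova_main_effects.csv")
    reports["table1_F"].to_csv(report / "anova_main_effects_F.csv")
    reports["holm"].to_csv(report / "holm_flags.csv")
    reports["table2"].to_csv(report / "anova_by_roi.csv")
    reports["order_p"].to_csv(report / "processing_order_p.csv")
    if len(reports["table4"]):
        reports["table4"].to_csv(report / "order_corrected_comparison.csv")
    g = reports["groups"]
    pd.DataFrame(
        dict(label=pd.Series(g.labels), r_evap=g.evap_corr)
    ).to_csv(report / "variable_groups.csv")
    g.corr.to_csv(report / "variable_correlations.csv")
    (report / "decode_manifest.json").write_text(
        json.dumps(dict(decoded=True, alpha=alpha, order_mode=order_mode), indent=2)
    )
    log.info("decoded report at %s", report)
    return report
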