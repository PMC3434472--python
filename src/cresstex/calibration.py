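"""Simulation experiments over the full pipeline.

Each experiment generates many reduced synthetic studies (small plates, few
days) end to end — design, blinding, evaporation, rendering, normalisation,
GLCM features, factorial ANOVA — and measures an operating characteristic:
the type-I error of the treatment test under the null, F-statistic growth
and spatial localisation under injected effects, the power of the
processing-order diagnostic and the behaviour of the linear order
correction, and the correlation-group structure of the texture variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import design as dz
from . import evaluation as ev
from .imageprep import ROISpec
from .pipeline import FULL_ROI, study_feature_table
from .synthesis import (
    REDUCED_GEOMETRY,
    EffectConfig,
    EvaporationModel,
    PlateGeometry,
    simulate_evaporation,
)
from .texture import CoocParams

__all__ = [
    "small_study",
    "simulate_null_rejection_rate",
    "simulate_effect_recovery",
    "simulate_order_power",
    "grouping_structure",
]

_FAST_PARAMS = CoocParams(levels=64)


def small_study(
    n_days: int = 4,
    n_plate_reps: int = 2,
    seed: int = 0,
    scheme: str = "manual_emulated",
    lab: str = "BRAD",
) -> dz.ExperimentDesign:
    """A reduced single-lab study design, coded and with evaporation times."""
    d = dz.build_design(
        n_labs=1, days_per_lab=(n_days,), n_treatments=2, n_internal=3,
        n_plate_reps=n_plate_reps, n_reference=0, labs=(lab,),
    )
    dz.randomize_and_code(d, scheme=scheme, seed=seed)
    simulate_evaporation(d, EvaporationModel(), seed=seed)
    return d


def _treatment_p_and_f(
    feats: pd.DataFrame, variable: str
) -> tuple[float, float]:
    tab = ev.factorial_anova(feats, variable, ["day", "treatment", "replicate"])
    return tab.p("treatment"), tab.F("treatment")


def simulate_null_rejection_rate(
    n_studies: int = 500,
    seed: int = 0,
    n_days: int = 4,
    n_plate_reps: int = 2,
    geometry: PlateGeometry = REDUCED_GEOMETRY,
    variable: str = "entropy",
    alpha: float = 0.05,
) -> dict:
    """Treatment-effect rejection rate over null studies (no injected effect).

    Returns the rate, its binomial 3-SE band around alpha, and the p-values.
    """
    ps = np.empty(n_studies)
    for i in range(n_studies):
        d = small_study(n_days, n_plate_reps, seed=seed * 1_000_003 + i)
        feats = study_feature_table(
            d, EffectConfig.null(), geometry, _FAST_PARAMS,
            rois=(FULL_ROI,), seed=seed * 1_000_003 + i,
        )
        ps[i], _ = _treatment_p_and_f(feats, variable)
    rate = float((ps < alpha).mean())
    se = float(np.sqrt(alpha * (1 - alpha) / n_studies))
    return dict(rate=rate, alpha=alpha, se=se, band=(alpha - 3 * se, alpha + 3 * se),
                pvalues=ps)


def simulate_effect_recovery(
    effect_sizes: tuple[float, ...] = (0.1, 0.2, 0.4),
    n_studies: int = 12,
    seed: int = 0,
    n_days: int = 4,
    n_plate_reps: int = 2,
    geometry: PlateGeometry = REDUCED_GEOMETRY,
    centre_variable: str = "cluster_shade",
    annulus_variable: str = "inertia",
) -> dict:
    """Recovery of injected treatment effects and their spatial localisation.

    For each effect magnitude, renders studies and records the treatment F
    for the whole plate.  At the largest magnitude the per-ROI signed
    standardised verum-control differences localise the two components:
    the centre-asymmetry variable rises most inside 70 % radius, and the
    annulus-contrast variable rises in the 70-90 % annulus while its
    grey-normalisation shadow depresses it in the other regions (the sign
    pattern, unlike the raw F magnitudes, is robust to the complementary
    variance shift that global normalisation imposes).
    """
    rois = (
        ROISpec(0, 70),
        ROISpec(70, 90),
        ROISpec(90, 100),
        FULL_ROI,
    )
    home_roi = {centre_variable: rois[0], annulus_variable: rois[1]}
    median_F: dict[str, dict[float, float]] = {v: {} for v in home_roi}
    roi_d: dict[str, dict[str, list[float]]] = {
        centre_variable: {r.label: [] for r in rois},
        annulus_variable: {r.label: [] for r in rois},
    }
    for k, eff_size in enumerate(effect_sizes):
        eff = EffectConfig(treatment_effect=eff_size, day_by_treatment_sd=0.0)
        fs: dict[str, list[float]] = {v: [] for v in home_roi}
        for i in range(n_studies):
            s = seed * 7_654_321 + k * 10_000 + i
            d = small_study(n_days, n_plate_reps, seed=s)
            feats = study_feature_table(d, eff, geometry, _FAST_PARAMS,
                                        rois=rois, seed=s)
            for var, home in home_roi.items():
                sub = feats[feats["roi"] == home.label]
                _, F = _treatment_p_and_f(sub, var)
                fs[var].append(F)
            if k == len(effect_sizes) - 1:
                for var in roi_d:
                    for r in rois:
                        sub = feats[feats["roi"] == r.label]
                        verum = sub[sub["treatment"] == dz.VERUM][var]
                        ctrl = sub[sub["treatment"] == dz.CONTROL][var]
                        sd = sub[var].std()
                        roi_d[var][r.label].append(
                            float((verum.mean() - ctrl.mean()) / sd)
                        )
        for var in home_roi:
            median_F[var][eff_size] = float(np.median(fs[var]))
    roi_median_d = {
        var: {lbl: float(np.median(v)) for lbl, v in d_.items()}
        for var, d_ in roi_d.items()
    }
    return dict(median_F=median_F, roi_median_d=roi_median_d,
                centre_variable=centre_variable, annulus_variable=annulus_variable)


def simulate_order_power(
    slopes: tuple[float, ...] = (0.0, 0.05, 0.1, 0.2),
    n_studies: int = 25,
    seed: int = 0,
    n_days: int = 4,
    n_plate_reps: int = 2,
    geometry: PlateGeometry = REDUCED_GEOMETRY,
    variable: str = "inertia",
    alpha: float = 0.05,
) -> dict:
    """Power of the processing-order diagnostic and effect of the correction.

    For each injected order slope (per order unit, on the relative
    fine-noise amplitude): the control-group day-normalised one-way ANOVA
    rejection rate, the same rate after linear order correction, and the
    maximum absolute refitted slope after correction.
    """
    power: dict[float, float] = {}
    power_corrected: dict[float, float] = {}
    max_resid_slope = 0.0
    for k, slope in enumerate(slopes):
        eff = EffectConfig.null(order_slope=slope)
        rej = np.zeros(n_studies, bool)
        rej_c = np.zeros(n_studies, bool)
        for i in range(n_studies):
            s = seed * 33_554_467 + k * 10_000 + i
            d = small_study(n_days, n_plate_reps, seed=s)
            feats = study_feature_table(d, eff, geometry, _FAST_PARAMS,
                                        rois=(FULL_ROI,), seed=s)
            ctrl = feats[feats["treatment"] == dz.CONTROL]
            p = ev.processing_order_test(ctrl, variable)
            rej[i] = p < alpha
            corrected, _ = ev.order_correction(
                feats[variable].to_numpy(), feats["processing_order"].to_numpy()
            )
            feats_c = feats.assign(**{variable: corrected})
            _, refit_slope = ev.order_correction(
                feats_c[variable].to_numpy(), feats_c["processing_order"].to_numpy()
            )
            max_resid_slope = max(max_resid_slope, abs(refit_slope))
            ctrl_c = feats_c[feats_c["treatment"] == dz.CONTROL]
            rej_c[i] = ev.processing_order_test(ctrl_c, variable) < alpha
        power[slope] = float(rej.mean())
        power_corrected[slope] = float(rej_c.mean())
    return dict(power=power, power_corrected=power_corrected,
                max_residual_slope=max_resid_slope, variable=variable, alpha=alpha)


def grouping_structure(
    n_studies: int = 8,
    seed: int = 0,
    n_days: int = 6,
    n_plate_reps: int = 2,
    geometry: PlateGeometry = REDUCED_GEOMETRY,
    treatment_effect: float = 0.3,
    r_group: float = 0.6,
    r_evap: float = 0.46,
) -> dict:
    """Correlation-group structure of the variables on effect-bearing studies.

    Pools the plates of several independent studies (correlation noise on a
    single study is large relative to the grouping thresholds) and computes
    the cluster_shade/diagonal_moment correlation, their evaporation-time
    correlations, the group-II analogue block's internal and evaporation
    correlations, and the threshold grouping of the pooled table.
    """
    group2 = ("inertia", "entropy", "energy", "inverse_different_moment",
              "sum_entropy", "difference_entropy", "sum_variance")
    tables = []
    for i in range(n_studies):
        s = seed * 48_271 + i
        d = small_study(n_days, n_plate_reps, seed=s)
        eff = EffectConfig(treatment_effect=treatment_effect)
        tables.append(study_feature_table(d, eff, geometry, _FAST_PARAMS,
                                          rois=(FULL_ROI,), seed=s))
    feats = pd.concat(tables, ignore_index=True)
    g = ev.correlate_and_group(
        feats[["cluster_shade", "diagonal_moment", *group2]],
        feats["evaporation_h"].to_numpy(),
        r_group=r_group, r_evap=r_evap,
    )
    pairs = [abs(g.corr.loc[a, b])
             for ai, a in enumerate(group2) for b in group2[ai + 1:]]
    return dict(
        group1_internal_r=float(abs(g.corr.loc["cluster_shade", "diagonal_moment"])),
        group1_evap_r=float(max(abs(g.evap_corr["cluster_shade"]),
                                abs(g.evap_corr["diagonal_moment"]))),
        group2_evap_r=float(np.median([abs(g.evap_corr[v]) for v in group2])),
        group2_internal_r=float(np.median(pairs)),
        grouping=g,
        r_group=r_group,
        r_evap=r_evap,
    )
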