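"""End-to-end orchestration: volumes -> growth fits -> sex/confound tests,
and labels/meshes -> surface metrics -> expansion maps.

A :class:`RunConfig` is validated up front; every stage logs what it ran,
and reports embed a hash of the configuration plus the package version so
a rerun with the same seed reproduces the report byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import DataError, ParameterError
from .growth_models import derived_descriptors, fit_percent_of_adult, select_model
from .mixed_effects import confound_screen, residual_effect_analysis
from .surface_morphometry import (
    extract_midcortical_surface,
    surface_metrics,
)
from .expansion_mapping import (
    expansion_to_reference,
    fit_expansion_trajectories,
    mean_expansion_difference,
)
from .synthetic_data import (
    DEFAULT_REGION_MODELS,
    make_growing_mesh_sequence,
    make_phantom_labelmap,
    simulate_cohort,
)
from .volumetrics import ANALYSIS_REGIONS, compartment_volumes

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_volumetric_analysis", "run_surface_analysis"]

_SIGMOID = {"logistic3", "logistic4", "gompertz"}


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    input_table: str | None = None  # CSV path; None -> simulate a cohort
    regions: tuple[str, ...] = tuple(DEFAULT_REGION_MODELS)
    covariate: str = "sex"
    confounds: tuple[str, ...] = ()
    bonferroni_m: int = 7
    alpha: float = 0.05
    adult_volumes: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str | None = None

    def validate(self, known_regions=None) -> None:
        if self.bonferroni_m < 1:
            raise ParameterError("bonferroni_m must be >= 1")
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must be in (0, 1)")
        known = set(known_regions or set(DEFAULT_REGION_MODELS) | set(ANALYSIS_REGIONS))
        unknown = set(self.regions) - known
        if unknown:
            raise ParameterError(f"unknown regions in config: {sorted(unknown)}")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _round_floats(obj, ndigits=10):
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    return obj


def run_volumetric_analysis(config: RunConfig) -> dict:
    """Per-region model selection, descriptors, and covariate inference.

    Returns the report dictionary; when ``config.out_dir`` is set, writes
    ``volumetric_report.json`` and a coefficient TSV there as well.
    """
    config.validate()
    if config.input_table is not None:
        table = pd.read_csv(config.input_table)
        logger.info("loaded %s (%d rows)", config.input_table, len(table))
    else:
        table = simulate_cohort(seed=config.seed)
        logger.info("simulated default cohort with seed %d", config.seed)
    missing = set(config.regions) - set(table["region"].unique())
    if missing:
        raise DataError(f"regions missing from the table: {sorted(missing)}")

    report: dict = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "seed": config.seed,
        "regions": {},
    }
    coef_rows = []
    for region in config.regions:
        sub = table[table["region"] == region]
        selection = select_model(sub["age_days"], sub["value"])
        block = {
            "model_selection": {
                "winner": selection.winner,
                "bic_table": {f: (None if not np.isfinite(b) else b)
                              for f, b in selection.bic_table.items()},
            },
            "fit": selection.best_fit.as_dict(),
        }
        if selection.winner in _SIGMOID:
            d = derived_descriptors(selection.best_fit)
            block["descriptors"] = {
                "t_mid": d.t_mid, "r_max": d.r_max, "asymptote": d.asymptote,
            }
        res = residual_effect_analysis(
            table, region, selection, covariate=config.covariate,
            m_comparisons=config.bonferroni_m, alpha=config.alpha,
        )
        block["covariate_analysis"] = {
            "covariate": config.covariate,
            "betas": res.lmm.betas.tolist(),
            "ses": res.lmm.ses.tolist(),
            "df": res.lmm.satterthwaite_df.tolist(),
            "p": res.lmm.p_values.tolist(),
            "p_bonferroni": res.bonferroni_adjusted_p.tolist(),
            "significant": res.significant_after_correction.tolist(),
        }
        coef_rows.append(res.summary_frame())
        if config.confounds:
            screens = confound_screen(table, region, selection,
                                      list(config.confounds),
                                      m_comparisons=config.bonferroni_m)
            block["confound_p_values"] = {
                r.covariate: r.lmm.p_values.tolist() for r in screens
            }
        if region in config.adult_volumes:
            adult = config.adult_volumes[region]
            pct = 100.0 * sub["value"].to_numpy() / adult
            pfit = fit_percent_of_adult(sub["age_days"].to_numpy(), pct)
            block["percent_of_adult"] = {
                "adult_ml": adult,
                "Rg": pfit.params[1],
                "tmid": pfit.params[2],
                "max_rate_pct_per_day": 25.0 * pfit.params[1],
            }
        report["regions"][region] = block
        logger.info("region %s: winner=%s", region, selection.winner)

    report = _round_floats(report)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "volumetric_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
        pd.concat(coef_rows).to_csv(out / "coefficients.tsv", sep="\t")
    return report


def run_surface_analysis(
    config: RunConfig,
    fold_amplitudes: tuple[float, ...] = (0.0, 0.4, 0.8, 1.2, 1.6),
    hemisphere: str = "both",
) -> dict:
    """Surface metrics on a phantom sequence plus expansion trajectory maps.

    Phantom label volumes with increasing fold amplitude stand in for the
    age series; a synthetic growing mesh sequence provides the vertex
    correspondence for expansion maps.
    """
    config.validate()
    ages = [85, 97, 110, 122, 135][: len(fold_amplitudes)]
    per_age = []
    k_values = []
    for age, amp in zip(ages, fold_amplitudes):
        kind = "folded_shell" if amp > 0 else "concentric_shells"
        vol, truth = make_phantom_labelmap(kind, fold_amplitude=amp,
                                           seed=config.seed)
        mesh = extract_midcortical_surface(vol, hemisphere)
        vols = compartment_volumes(vol)
        metrics = surface_metrics(mesh, vols["cortical_plate"])
        k_values.append(metrics.k_star)
        per_age.append({
            "age_days": age,
            "fold_amplitude_mm": amp,
            "surface_area_cm2": metrics.surface_area_cm2,
            "k_star": metrics.k_star,
            "thickness_mm": metrics.thickness_mm,
            "truth_mid_sa_cm2": truth["mid_surface_area_mm2"] / 100.0,
        })

    cset, truth = make_growing_mesh_sequence(seed=config.seed)
    ref = cset.ages[0]
    maps = expansion_to_reference(cset, ref)
    traj = fit_expansion_trajectories(maps, reference_age=ref)
    fetal_ages = [a for a in cset.ages if a <= 165]
    mean_diffs = {
        f"{int(a)}": mean_expansion_difference(maps[ref], maps[a])
        for a in fetal_ages[1:]
    }
    report = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "seed": config.seed,
        "hemisphere": hemisphere,
        "per_age_metrics": per_age,
        "k_star_monotone": bool(np.all(np.diff(k_values) > 0)),
        "expansion": {
            "reference_age": ref,
            "trajectory_summary": traj.summary(),
            "mean_expansion_difference_from_reference": mean_diffs,
        },
    }
    report = _round_floats(report)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "surface_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
    return report
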