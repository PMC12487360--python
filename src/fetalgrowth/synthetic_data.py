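"""Synthetic cohorts, label-map phantoms, and growing mesh sequences.

Everything the analysis pipeline consumes can be generated here with known
ground truth:

* :func:`simulate_cohort` emulates the mixed-longitudinal fetal imaging
  design — 50 fetuses (28 female), 105 scans clustered at the seven target
  ages G85..G155 with a few days of jitter — and draws region volumes from
  sigmoidal generative models (published trajectory parameters by default)
  with a per-subject random intercept and additive measurement noise;
* :func:`make_phantom_labelmap` builds concentric-shell (optionally
  rippled) label images whose compartment volumes and mid-cortical surface
  area are known analytically;
* :func:`make_growing_mesh_sequence` grows an icosphere through a smooth,
  logistic-in-time areal expansion field with exact vertex correspondence.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from scipy.integrate import quad

from .exceptions import GeometryError, ParameterError
from .expansion_mapping import CorrespondenceSet
from .growth_models import FAMILIES, eval_model, gompertz_from_descriptors
from .surface_morphometry import CorticalMesh
from .volumetrics import LabelVolume

__all__ = [
    "CohortDesign",
    "GenerativeRegionModel",
    "DEFAULT_REGION_MODELS",
    "simulate_cohort",
    "make_phantom_labelmap",
    "make_growing_mesh_sequence",
]

#: target gestational ages (days post-conception) of the template cohort
TARGET_AGES = (85, 97, 110, 122, 135, 147, 155)
#: number of scans contributing to each age template
SCANS_PER_AGE = (31, 5, 20, 6, 28, 6, 9)


@dataclass(frozen=True)
class CohortDesign:
    """Mixed-longitudinal sampling plan (cross-sectional + repeated scans)."""

    n_subjects: int = 50
    n_female: int = 28
    target_ages: tuple[int, ...] = TARGET_AGES
    scans_per_age: tuple[int, ...] = SCANS_PER_AGE
    age_jitter_sd: float = 2.3  # template mean-age SDs are ~1-2.4 days
    age_jitter_max: float = 7.0
    max_scans_per_subject: int = 4

    def __post_init__(self):
        if len(self.target_ages) != len(self.scans_per_age):
            raise ParameterError("one scan count per target age is required")
        if sum(self.scans_per_age) < self.n_subjects:
            raise ParameterError("every subject needs at least one scan")
        if self.n_female > self.n_subjects:
            raise ParameterError("n_female exceeds n_subjects")


@dataclass(frozen=True)
class GenerativeRegionModel:
    """Ground-truth growth model for one region.

    ``params`` maps sex ("F"/"M") to the family parameter vector; regions
    without a sex effect use identical vectors.  ``subject_sd_frac`` scales
    the random-intercept SD by the model value at the median target age;
    ``noise_sd_frac`` scales the i.i.d. measurement noise by the
    age-specific model value.  ``sex_age_slope_delta`` adds an extra
    ``delta * (age - 85)`` to male trajectories for controlled recovery
    experiments.
    """

    family: str
    params: dict = field(default_factory=dict)
    subject_sd_frac: float = 0.04
    noise_sd_frac: float = 0.02
    sex_age_slope_delta: float = 0.0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ParameterError(f"unknown family {self.family!r}")
        if self.subject_sd_frac < 0 or self.noise_sd_frac < 0:
            raise ParameterError("noise fractions must be non-negative")

    def value(self, sex: str, age) -> np.ndarray:
        v = eval_model(self.family, self.params[sex], age)
        if sex == "M" and self.sex_age_slope_delta:
            v = v + self.sex_age_slope_delta * (np.asarray(age, dtype=float) - 85.0)
        return v


def _gompertz(asymptote, r_max, t_mid):
    return list(gompertz_from_descriptors(asymptote, r_max, t_mid))


#: published fetal growth trajectory parameters (volumes in mL, ages in days)
DEFAULT_REGION_MODELS: dict[str, GenerativeRegionModel] = {
    "whole_brain": GenerativeRegionModel(
        "logistic3", {"M": [48.5, 0.0566, 113], "F": [48.0, 0.0533, 116]}),
    "cortical_plate": GenerativeRegionModel(
        "logistic3", {"M": [24.1, 0.0589, 120], "F": [24.0, 0.0561, 123]}),
    "cerebellum": GenerativeRegionModel(
        "logistic3", {"M": [3.78, 0.0499, 141], "F": [3.10, 0.0533, 137]}),
    # the published 4PL table omits the t=0 offset B; 2.0 mL is a realistic
    # nascent-white-matter value extrapolated to conception
    "nascent_white_matter": GenerativeRegionModel(
        "logistic4", {s: [14.3, 2.0, 0.109, 108] for s in "FM"}),
    "subcortical_gray": GenerativeRegionModel(
        "gompertz", {s: _gompertz(4.55, 0.0552, 111) for s in "FM"}),
    "brainstem": GenerativeRegionModel(
        "gompertz", {s: _gompertz(3.19, 0.0166, 135) for s in "FM"}),
    # U-shaped ventricular trajectory: minimum 0.35 mL at G110, 0.45 mL at G85
    "ventricles": GenerativeRegionModel(
        "quadratic", {s: [2.286, -0.0352, 1.6e-4] for s in "FM"}),
}

_CONFOUND_LEVELS = {
    "scanner": ("v1", "v2"),
    "recon": ("btk", "deconv"),
    "resolution": (0.5, 0.6),
    "sequence": ("haste", "ssfse"),
}


def _allocate_scans(design: CohortDesign, rng: np.random.Generator):
    """Assign scan slots (age groups) to subjects: every subject scanned at
    least once, at most ``max_scans_per_subject`` times, never twice in the
    same age group."""
    slots = np.repeat(np.arange(len(design.target_ages)), design.scans_per_age)
    rng.shuffle(slots)
    n = design.n_subjects
    assignments: list[set[int]] = [set() for _ in range(n)]
    # first pass: one scan each
    for subj in range(n):
        assignments[subj].add(int(slots[subj]))
    # remaining slots: random subjects with capacity and a free age group
    for slot in slots[n:]:
        order = rng.permutation(n)
        placed = False
        for subj in order:
            if (len(assignments[subj]) < design.max_scans_per_subject
                    and int(slot) not in assignments[subj]):
                assignments[subj].add(int(slot))
                placed = True
                break
        if not placed:  # pathological designs only
            spare = int(np.argmin([len(a) for a in assignments]))
            assignments[spare].add(int(slot))
    return assignments


def simulate_cohort(
    design: CohortDesign | None = None,
    models: dict[str, GenerativeRegionModel] | None = None,
    seed: int = 0,
    confounds: bool = True,
) -> pd.DataFrame:
    """Simulate a long-format measurement table for the cohort design.

    Each observation is ``family(params_sex, age) + subject_intercept +
    noise``; the returned frame has columns ``subject, sex, age_days,
    region, value`` plus (optionally) the acquisition confound columns
    ``scanner, recon, scan_number, resolution, sequence``.
    """
    design = design or CohortDesign()
    models = models or DEFAULT_REGION_MODELS
    rng = np.random.default_rng(seed)

    sexes = np.array(["F"] * design.n_female
                     + ["M"] * (design.n_subjects - design.n_female))
    rng.shuffle(sexes)
    assignments = _allocate_scans(design, rng)
    median_age = float(np.median(design.target_ages))

    # per-subject random intercepts on a unit scale; rescaled per region
    unit_intercepts = rng.standard_normal(design.n_subjects)

    rows = []
    for subj in range(design.n_subjects):
        subject_id = f"S{subj:03d}"
        sex = str(sexes[subj])
        groups = sorted(assignments[subj])
        scan_confounds = {
            name: rng.choice(levels, size=len(groups))
            for name, levels in _CONFOUND_LEVELS.items()
        } if confounds else {}
        for scan_idx, g in enumerate(groups):
            jitter = float(np.clip(rng.normal(0.0, design.age_jitter_sd),
                                   -design.age_jitter_max, design.age_jitter_max))
            age = design.target_ages[g] + jitter
            for region, model in models.items():
                mean_val = float(model.value(sex, age))
                anchor = float(model.value(sex, median_age))
                subject_sd = model.subject_sd_frac * abs(anchor)
                noise_sd = model.noise_sd_frac * abs(mean_val)
                value = (mean_val
                         + subject_sd * unit_intercepts[subj]
                         + noise_sd * rng.standard_normal())
                row = {
                    "subject": subject_id,
                    "sex": sex,
                    "age_days": age,
                    "target_age": design.target_ages[g],
                    "region": region,
                    "value": value,
                    "scan_number": scan_idx + 1,
                }
                for name in _CONFOUND_LEVELS:
                    if confounds:
                        row[name] = scan_confounds[name][scan_idx]
                rows.append(row)
    frame = pd.DataFrame(rows)
    return frame.sort_values(["subject", "age_days", "region"],
                             kind="stable").reset_index(drop=True)


# -- phantoms --------------------------------------------------------------

_SHELL_LABELS = (4, 6, 3, 2, 1)  # ventricle core, subcortical, subplate, plate, CSF


def _sphere_volume(r):
    return 4.0 / 3.0 * math.pi * r**3


def make_phantom_labelmap(
    kind: str = "concentric_shells",
    radii: tuple[float, ...] = (5.0, 10.0, 15.0, 17.0, 20.0),
    voxel_mm: float = 0.5,
    fold_amplitude: float = 0.0,
    n_folds: int = 6,
    margin_mm: float = 2.0,
    seed: int = 0,
) -> tuple[LabelVolume, dict]:
    """Concentric-shell (or rippled-shell) label phantom with analytic truth.

    The innermost sphere is labelled ventricles (4), then subcortical gray
    (6), subplate (3), cortical plate (2), and extra-axial CSF (1) outside.
    The ``folded_shell`` variant perturbs the cortical-shell boundaries by
    an axisymmetric ripple ``r + amplitude*cos(n_folds*theta)``; compartment
    volumes and the mid-cortical surface area of the perturbed shell are
    computed by exact 1-D quadrature and recorded in the truth dictionary.
    """
    if kind not in ("concentric_shells", "folded_shell"):
        raise ParameterError(f"unknown phantom kind {kind!r}")
    radii = tuple(float(r) for r in radii)
    if len(radii) != 5 or np.any(np.diff(radii) <= 0):
        raise GeometryError("five strictly increasing radii are required")
    amp = float(fold_amplitude) if kind == "folded_shell" else 0.0
    shell_gap = min(radii[3] - radii[2], radii[2] - radii[1], radii[4] - radii[3])
    if amp >= shell_gap:
        raise GeometryError("fold amplitude must stay below the shell margin")

    extent = radii[-1] + margin_mm
    n_vox = int(math.ceil(2.0 * extent / voxel_mm))
    if (radii[-1] + amp) * 2.0 > n_vox * voxel_mm:
        raise GeometryError("radii exceed the voxel grid")
    coords = (np.arange(n_vox) + 0.5) * voxel_mm - extent
    x, y, z = np.meshgrid(coords, coords, coords, indexing="ij")
    r = np.sqrt(x**2 + y**2 + z**2)
    theta = np.arccos(np.divide(z, r, out=np.zeros_like(z), where=r > 0))

    def boundary(radius, rippled):
        return radius + amp * np.cos(n_folds * theta) if rippled else radius

    # ripple the inner and outer cortical-plate boundaries coherently so the
    # shell keeps its thickness while folding
    bounds = [
        boundary(radii[0], False),
        boundary(radii[1], False),
        boundary(radii[2], amp > 0),
        boundary(radii[3], amp > 0),
        boundary(radii[4], False),
    ]
    # boundaries are ordered pointwise because the amplitude is below the gap
    labels = np.zeros_like(r, dtype=np.int16)
    prev = np.zeros_like(r)
    for lab, bnd in zip(_SHELL_LABELS, bounds):
        labels[(r >= prev) & (r < bnd)] = lab
        prev = np.broadcast_to(bnd, r.shape).copy() if np.ndim(bnd) else np.full_like(r, bnd)

    def rippled_volume(r_in_const, r_out_const, rip_in, rip_out):
        def integrand(t):
            ri = r_in_const + (amp * math.cos(n_folds * t) if rip_in else 0.0)
            ro = r_out_const + (amp * math.cos(n_folds * t) if rip_out else 0.0)
            return (ro**3 - ri**3) * math.sin(t)
        val, _ = quad(integrand, 0.0, math.pi, limit=200)
        return 2.0 * math.pi / 3.0 * val

    rip = amp > 0
    truth_volumes_mm3 = {
        "ventricles": _sphere_volume(radii[0]),
        "subcortical_gray": _sphere_volume(radii[1]) - _sphere_volume(radii[0]),
        "nascent_white_matter": rippled_volume(radii[1], radii[2], False, rip),
        "cortical_plate": rippled_volume(radii[2], radii[3], rip, rip),
        "extra_axial_csf": rippled_volume(radii[3], radii[4], rip, False),
    }
    truth_volumes_mm3["whole_brain"] = sum(
        truth_volumes_mm3[k] for k in
        ("ventricles", "subcortical_gray", "nascent_white_matter", "cortical_plate")
    )
    truth_volumes_mm3["icv"] = (truth_volumes_mm3["whole_brain"]
                                + truth_volumes_mm3["extra_axial_csf"])

    r_mid = 0.5 * (radii[2] + radii[3])

    def sa_integrand(t):
        rho = r_mid + amp * math.cos(n_folds * t)
        drho = -amp * n_folds * math.sin(n_folds * t)
        return rho * math.sin(t) * math.sqrt(rho**2 + drho**2)

    sa_mid, _ = quad(sa_integrand, 0.0, math.pi, limit=400)
    truth = {
        "kind": kind,
        "radii_mm": radii,
        "fold_amplitude_mm": amp,
        "n_folds": n_folds,
        "voxel_mm": voxel_mm,
        "volumes_ml": {k: v / 1000.0 for k, v in truth_volumes_mm3.items()},
        "mid_surface_radius_mm": r_mid,
        "mid_surface_area_mm2": 2.0 * math.pi * sa_mid,
        "shell_thickness_mm": radii[3] - radii[2],
    }
    vol = LabelVolume(labels=labels, voxel_dims=np.full(3, voxel_mm))
    return vol, truth


# -- growing mesh sequences ------------------------------------------------

def make_growing_mesh_sequence(
    ages=(85, 97, 110, 122, 135, 147, 155, 1770),
    subdivisions: int = 3,
    base_radius_mm: float = 10.0,
    expansion_range: tuple[float, float] = (6.0, 11.0),
    rg: float = 0.07,
    tmid: float = 120.0,
    uniform: bool = False,
    seed: int = 0,
) -> tuple[CorrespondenceSet, dict]:
    """Grow an icosphere by a smooth logistic-in-time areal expansion field.

    The target areal expansion of vertex ``v`` relative to the first age is
    ``g_v(t) = 1 + (a_v - 1) * l(t)`` with ``l`` a logistic ramp (0 at the
    reference age, 1 at maturity) and ``a_v`` varying smoothly from
    ``expansion_range[0]`` at the +z pole (frontal) to ``expansion_range[1]``
    at the -z pole (occipital); radii scale as ``sqrt(g_v)``.  Vertex
    correspondence is exact by construction.  The truth record stores the
    analytic per-vertex expansion field at every age.
    """
    ages = tuple(float(a) for a in ages)
    if np.any(np.diff(ages) <= 0):
        raise GeometryError("ages must be strictly increasing")
    lo, hi = expansion_range
    if lo <= 0 or hi < lo:
        raise GeometryError("expansion range must be positive and ordered")

    base = trimesh.creation.icosphere(subdivisions=subdivisions,
                                      radius=base_radius_mm)
    verts = np.asarray(base.vertices)
    faces = np.asarray(base.faces)
    unit = verts / np.linalg.norm(verts, axis=1, keepdims=True)

    if uniform:
        a_v = np.full(len(verts), 0.5 * (lo + hi))
    else:
        # occipital-high (-z) to frontal-low (+z) gradient
        a_v = lo + (hi - lo) * (1.0 - unit[:, 2]) / 2.0

    t0 = ages[0]

    def ramp(t):
        raw = 1.0 / (1.0 + math.exp(-rg * (t - tmid)))
        raw0 = 1.0 / (1.0 + math.exp(-rg * (t0 - tmid)))
        return (raw - raw0) / (1.0 - raw0)

    meshes = []
    truth_fields = {}
    for t in ages:
        g = 1.0 + (a_v - 1.0) * ramp(t)
        if np.any(g <= 0):
            raise GeometryError("expansion field must stay positive")
        scaled = unit * (base_radius_mm * np.sqrt(g))[:, None]
        mesh = CorticalMesh(scaled, faces)
        if not mesh.to_trimesh().is_winding_consistent:
            raise GeometryError("grown mesh self-intersects or is degenerate")
        meshes.append(mesh)
        truth_fields[t] = g
    cset = CorrespondenceSet(ages=ages, meshes=tuple(meshes),
                             provenance="synthetic_known")
    truth = {
        "expansion_fields": truth_fields,
        "asymptotic_expansion": a_v,
        "rg": rg,
        "tmid": tmid,
        "reference_age": t0,
    }
    return cset, truth
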