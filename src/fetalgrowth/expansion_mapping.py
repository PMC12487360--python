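"""Vertex-wise cortical surface-area expansion and trajectory maps.

Given a sequence of meshes in vertex correspondence across ages (imported
from a surface-registration pipeline, or synthetic with known ground
truth), the per-vertex expansion factor between two ages is the ratio of
corresponding vertex areas.  Forward (young->old) and reverse (old->young,
inverted) estimates are averaged; with exact index correspondence the two
coincide and the average is the exact ratio.  Expansion of every age
relative to a reference (typically the youngest fetal age) yields per-age
maps; fitting a three-parameter logistic through each vertex's expansion
trajectory produces spatial maps of the asymptotic expansion ``A``, the
maximal expansion rate ``Rg``, and the age of fastest expansion ``tmid``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import DataError, ParameterError
from .growth_models import GrowthCurveModel
from .surface_morphometry import CorticalMesh, vertex_areas

logger = logging.getLogger(__name__)

__all__ = [
    "CorrespondenceSet",
    "ExpansionTrajectoryMaps",
    "vertex_expansion",
    "expansion_to_reference",
    "fit_expansion_trajectories",
    "mean_expansion_difference",
]

#: post-conception age (days) assigned to the post-pubertal adult time point
#: (165-day term + ~4.4 years); configurable wherever it is used
DEFAULT_ADULT_AGE_DAYS = 1770.0


@dataclass
class CorrespondenceSet:
    """Age-ordered meshes sharing vertex count and index correspondence."""

    ages: tuple[float, ...]
    meshes: tuple[CorticalMesh, ...]
    provenance: str = "synthetic_known"

    def __post_init__(self):
        if len(self.ages) != len(self.meshes):
            raise DataError("ages and meshes must pair up")
        if len(self.ages) >= 2 and np.any(np.diff(self.ages) <= 0):
            raise DataError("ages must be strictly increasing")
        ns = {m.n_vertices for m in self.meshes}
        if len(ns) > 1:
            raise DataError(f"meshes disagree on vertex count: {sorted(ns)}")

    @property
    def n_vertices(self) -> int:
        return self.meshes[0].n_vertices

    def mesh_at(self, age: float) -> CorticalMesh:
        try:
            return self.meshes[self.ages.index(age)]
        except ValueError:
            raise ParameterError(f"age {age} not in correspondence set {self.ages}")


@dataclass
class ExpansionTrajectoryMaps:
    """Per-vertex logistic expansion parameters relative to a reference age."""

    A_map: np.ndarray
    Rg_map: np.ndarray
    tmid_map: np.ndarray
    reference_age: float
    convergence_mask: np.ndarray

    def summary(self, percentiles=(5, 50, 95)) -> dict:
        ok = self.convergence_mask
        out = {"n_vertices": int(ok.size), "n_converged": int(ok.sum())}
        for name, arr in (("A", self.A_map), ("Rg", self.Rg_map),
                          ("tmid", self.tmid_map)):
            vals = np.percentile(arr[ok], percentiles) if ok.any() else \
                np.full(len(percentiles), np.nan)
            out[name] = dict(zip((f"p{p}" for p in percentiles), vals.tolist()))
        return out


def vertex_expansion(young: CorticalMesh, old: CorticalMesh,
                     combine: str = "arithmetic") -> np.ndarray:
    """Per-vertex area expansion factors between corresponding meshes.

    Vertices with zero young *and* old area are excluded (NaN) and flagged.
    ``combine`` chooses how the forward and reverse-direction estimates are
    averaged ("arithmetic" or "geometric").
    """
    if young.n_vertices != old.n_vertices:
        raise DataError("meshes must share vertex count")
    if combine not in ("arithmetic", "geometric"):
        raise ParameterError(f"unknown combine mode {combine!r}")
    a_young, _ = vertex_areas(young)
    a_old, _ = vertex_areas(old)
    valid = (a_young > 0) & (a_old > 0)
    if not valid.all():
        logger.warning("%d vertices with zero area excluded from expansion",
                       int((~valid).sum()))
    forward = np.divide(a_old, a_young, out=np.full_like(a_old, np.nan),
                        where=valid)
    # reverse direction measures shrinkage old->young; invert to expansion
    shrink = np.divide(a_young, a_old, out=np.full_like(a_old, np.nan),
                       where=valid)
    reverse = 1.0 / shrink
    if combine == "arithmetic":
        return 0.5 * (forward + reverse)
    return np.sqrt(forward * reverse)


def expansion_to_reference(cset: CorrespondenceSet, reference_age: float,
                           combine: str = "arithmetic") -> dict[float, np.ndarray]:
    """Expansion map of every age relative to the reference age.

    The reference maps to exactly 1 at every vertex.
    """
    if reference_age not in cset.ages:
        raise ParameterError(f"reference age {reference_age} not in {cset.ages}")
    ref = cset.mesh_at(reference_age)
    out: dict[float, np.ndarray] = {}
    for age, mesh in zip(cset.ages, cset.meshes):
        if age == reference_age:
            out[age] = np.ones(cset.n_vertices)
        else:
            out[age] = vertex_expansion(ref, mesh, combine=combine)
    return out


def fit_expansion_trajectories(
    maps: dict[float, np.ndarray] | np.ndarray,
    ages=None,
    reference_age: float | None = None,
    a_max: float = 50.0,
) -> ExpansionTrajectoryMaps:
    """Independent logistic3 fit of expansion vs age at every vertex.

    Parameters
    ----------
    maps : dict of age -> N-vector, or array of shape (n_ages, N)
        Per-age expansion maps relative to the reference age.
    ages : sequence of float, required when ``maps`` is an array
        Ages (days) including the adult time point.
    reference_age : float, optional
        Recorded on the output; defaults to the youngest age.
    a_max : float
        Upper bound for the asymptotic expansion parameter.

    Vertices where the optimizer fails are masked, not fitted.
    """
    if isinstance(maps, dict):
        ages = np.array(sorted(maps), dtype=float)
        data = np.vstack([maps[a] for a in ages])
    else:
        if ages is None:
            raise ParameterError("ages are required with array input")
        ages = np.asarray(ages, dtype=float)
        data = np.asarray(maps, dtype=float)
    if data.shape[0] != ages.size:
        raise DataError("one expansion map per age is required")
    if ages.size < 4:
        raise DataError("trajectory fitting needs at least 4 ages")
    if reference_age is None:
        reference_age = float(ages.min())

    n = data.shape[1]
    A = np.full(n, np.nan)
    Rg = np.full(n, np.nan)
    tmid = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)
    model = GrowthCurveModel("logistic3", bounds={"A": (1e-12, a_max)})
    for v in range(n):
        y = data[:, v]
        if not np.all(np.isfinite(y)):
            continue
        fit = model.fit(ages, y)
        if fit.converged_ and not _at_bounds(fit):
            A[v], Rg[v], tmid[v] = fit.params_
            ok[v] = True
    if not ok.all():
        logger.info("%d/%d vertices masked (non-converged or invalid)",
                    int((~ok).sum()), n)
    return ExpansionTrajectoryMaps(A_map=A, Rg_map=Rg, tmid_map=tmid,
                                   reference_age=reference_age,
                                   convergence_mask=ok)


def _at_bounds(fit: GrowthCurveModel, rtol: float = 1e-6) -> bool:
    """True when a free logistic3 parameter sits on its box bound."""
    table = {"A": (1e-12, fit.bounds["A"][1]), "Rg": (1e-9, 1.0),
             "tmid": (0.0, 400.0)}
    for name, val in zip(("A", "Rg", "tmid"), fit.params_):
        lo, hi = table[name]
        span = max(hi - lo, 1e-300)
        if (val - lo) / span < rtol or (hi - val) / span < rtol:
            return True
    return False


def mean_expansion_difference(map_a, map_b, weights=None) -> float:
    """Area-weighted mean of ``map_b - map_a`` (reference-age vertex areas)."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise DataError("expansion maps must share shape")
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != a.shape:
        raise DataError("weights must match the maps")
    ok = np.isfinite(a) & np.isfinite(b)
    return float(np.average(b[ok] - a[ok], weights=w[ok]))
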