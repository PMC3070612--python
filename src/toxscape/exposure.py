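"""Spatial-interaction exposure models.

Six families estimate the impact ``k_ij`` of release site *i* (volume
``t_i``) on region *j* at centroid distance ``d_ij``:

* ``containment`` — ``t^alpha`` if the site lies inside the region, else 0;
* ``buffer`` — ``t^alpha`` within a threshold distance ``T`` of the site;
* ``power`` — gravity-model decay ``t^alpha / d^theta`` (with a distance
  floor ``d_floor`` to tame the singularity at d = 0);
* ``exponential`` — ``t^alpha * exp(-theta d)``;
* ``cutter`` — quadratic decay ``t^alpha (1 - (d/T)^2)^theta`` with a hard
  cutoff at ``T``;
* ``external`` — a precomputed per-region risk score (RSEI-style) passed
  through unchanged.

Per-site impacts are summed into the cumulative impact ``K_j = sum_i k_ij``
on each region.  The module also provides release-set filtering, the log10
volume transform, and the decomposition of each region's impact into the
share originating from metropolitan (urban) source counties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .containers import (
    METRO_MAX_CODE,
    ConfigurationError,
    DecaySpec,
    Region,
    ReleaseSite,
)
from .geometry import distance_matrix

__all__ = [
    "RELEASE_SETS",
    "DEFAULT_DISTANCE_FLOOR",
    "VOLUME_FLOOR",
    "ImpactResult",
    "select_releases",
    "transform_volumes",
    "impact_containment",
    "impact_buffer",
    "impact_power",
    "impact_exponential",
    "impact_cutter",
    "cumulative_impact",
    "urban_source_share",
]

#: Distance floor (miles) for the power family; the gravity kernel is
#: singular at d = 0 and region centroids can coincide with site locations.
DEFAULT_DISTANCE_FLOOR = 1.0

#: Volumes at or below this (pounds) are floored before the log10 transform
#: so effective volumes stay positive.
VOLUME_FLOOR = 10.0

#: Release-set labels -> chemical-class labels included.  Set 1 is every
#: carcinogenic release; set 2 restricts to chemicals that induce lung
#: cancer; set 3 adds generic compound-category releases of those chemicals.
RELEASE_SETS = {
    "all_carcinogen": ("all_carcinogen", "lung_carcinogen", "lung_compound"),
    "lung_carcinogen": ("lung_carcinogen",),
    "lung_compound": ("lung_carcinogen", "lung_compound"),
}


def select_releases(sites: Sequence[ReleaseSite], release_set: str) -> list:
    """Filter sites to one of the three release sets.

    ``all_carcinogen`` keeps everything; ``lung_carcinogen`` keeps only sites
    labeled as lung carcinogens; ``lung_compound`` keeps lung carcinogens
    plus their compound-category releases.  An empty result triggers a
    warning, not an error.
    """
    if release_set not in RELEASE_SETS:
        raise ValueError(
            f"unknown release set {release_set!r}; expected one of {sorted(RELEASE_SETS)}"
        )
    keep = set(RELEASE_SETS[release_set])
    out = [s for s in sites if s.chemical_class in keep]
    if sites and not out:
        warnings.warn(f"release set {release_set!r} selected no sites", stacklevel=2)
    return out


def transform_volumes(volumes: np.ndarray, log10_flag: bool) -> np.ndarray:
    """Effective release volumes: identity, or log10 with a floor at 10 lb.

    Volumes of one pound or less would map to nonpositive logs, so volumes
    below :data:`VOLUME_FLOOR` are floored at 10 before the transform (each
    affected site is reported in a warning).
    """
    volumes = np.asarray(volumes, dtype=float)
    if (volumes <= 0).any():
        raise ValueError("release volumes must be positive")
    if not log10_flag:
        return volumes
    n_floored = int((volumes < VOLUME_FLOOR).sum())
    if n_floored:
        warnings.warn(
            f"{n_floored} volume(s) below {VOLUME_FLOOR} floored before log10 transform",
            stacklevel=2,
        )
    return np.log10(np.maximum(volumes, VOLUME_FLOOR))


# ---------------------------------------------------------------------------
# scalar kernels (vector-friendly: t and d may be arrays)
# ---------------------------------------------------------------------------

def impact_containment(t, same_region, spec: DecaySpec):
    """``t^alpha`` where the site's containing region is the target region."""
    return np.where(same_region, np.power(t, spec.alpha), 0.0)


def impact_buffer(t, d, spec: DecaySpec):
    """``t^alpha`` within the threshold distance T (boundary included)."""
    if spec.threshold is None:
        raise ConfigurationError("buffer family requires threshold T")
    return np.where(np.asarray(d) <= spec.threshold, np.power(t, spec.alpha), 0.0)


def impact_power(t, d, spec: DecaySpec, d_floor: float = DEFAULT_DISTANCE_FLOOR):
    """Gravity kernel ``t^alpha / max(d, d_floor)^theta``."""
    d_eff = np.maximum(np.asarray(d, dtype=float), d_floor)
    return np.power(t, spec.alpha) / np.power(d_eff, spec.theta)


def impact_exponential(t, d, spec: DecaySpec):
    """Exponential decay ``t^alpha * exp(-theta d)``; equals ``t^alpha`` at d = 0."""
    return np.power(t, spec.alpha) * np.exp(-spec.theta * np.asarray(d, dtype=float))


def impact_cutter(t, d, spec: DecaySpec):
    """Quadratic decay ``t^alpha (1 - (d/T)^2)^theta`` for d <= T, else 0.

    Anchored at ``t^alpha`` for d = 0, nonincreasing on [0, T], and zero
    beyond the threshold.  As theta -> 0+ the kernel converges pointwise to
    the buffer kernel with the same T on d < T.
    """
    if spec.threshold is None:
        raise ConfigurationError("cutter family requires threshold T")
    d = np.asarray(d, dtype=float)
    frac = np.clip(1.0 - (d / spec.threshold) ** 2, 0.0, None)
    return np.where(d <= spec.threshold, np.power(t, spec.alpha) * frac**spec.theta, 0.0)


@dataclass
class ImpactResult:
    """Cumulative impact ``K_j`` per region, with the per-site breakdown.

    ``per_site[i, j]`` is site *i*'s impact on region *j* when retained
    (instances above the retention cap drop it to save memory); then
    ``K_j = sum_i per_site[i, j]`` exactly.
    """

    K: np.ndarray
    region_ids: list
    spec: DecaySpec
    release_set: Optional[str] = None
    per_site: Optional[np.ndarray] = None
    site_ids: Optional[list] = None


def _impact_matrix(
    t_eff: np.ndarray,
    D: np.ndarray,
    same_region: np.ndarray,
    spec: DecaySpec,
    d_floor: float,
) -> np.ndarray:
    t = t_eff[:, None]
    if spec.family == "containment":
        return impact_containment(t, same_region, spec)
    if spec.family == "buffer":
        return impact_buffer(t, D, spec)
    if spec.family == "power":
        return impact_power(t, D, spec, d_floor)
    if spec.family == "exponential":
        return impact_exponential(t, D, spec)
    if spec.family == "cutter":
        return impact_cutter(t, D, spec)
    raise ConfigurationError(f"no per-site kernel for family {spec.family!r}")


def cumulative_impact(
    sites: Sequence[ReleaseSite],
    regions: Sequence[Region],
    spec: DecaySpec,
    release_set: Optional[str] = None,
    coords: str = "planar",
    d_floor: float = DEFAULT_DISTANCE_FLOOR,
    per_site_cap: int = 4_000_000,
) -> ImpactResult:
    """Cumulative impact ``K_j = sum_i k_ij`` of the selected releases.

    Parameters
    ----------
    release_set : str, optional
        One of the labels in :data:`RELEASE_SETS`; filters sites first.
    per_site_cap : int
        Retain the per-site matrix (needed for the urban-share
        decomposition) only when ``n_sites * n_regions`` stays at or below
        this cap.
    """
    region_ids = [r.id for r in regions]
    if spec.family == "external":
        risks = [r.external_risk for r in regions]
        if any(v is None for v in risks):
            missing = [r.id for r in regions if r.external_risk is None][:5]
            raise ConfigurationError(
                f"external family requires external_risk on every region; missing for {missing}"
            )
        K = np.asarray(risks, dtype=float)
        return ImpactResult(K=K, region_ids=region_ids, spec=spec, release_set=release_set)

    if release_set is not None:
        sites = select_releases(sites, release_set)
    n_sites, n_regions = len(sites), len(regions)
    if n_sites == 0:
        return ImpactResult(
            K=np.zeros(n_regions),
            region_ids=region_ids,
            spec=spec,
            release_set=release_set,
            per_site=np.zeros((0, n_regions)),
            site_ids=[],
        )
    volumes = np.array([s.volume for s in sites], dtype=float)
    t_eff = transform_volumes(volumes, spec.log10_volumes)
    D = distance_matrix(sites, regions, coords)
    rid_index = {rid: j for j, rid in enumerate(region_ids)}
    same = np.zeros((n_sites, n_regions), dtype=bool)
    for i, s in enumerate(sites):
        j = rid_index.get(s.region_id)
        if j is None:
            raise ValueError(f"site {s.id!r} references unknown region {s.region_id!r}")
        same[i, j] = True
    k = _impact_matrix(t_eff, D, same, spec, d_floor)
    if not np.isfinite(k).all():
        bad = np.argwhere(~np.isfinite(k))[0]
        raise FloatingPointError(
            f"non-finite impact for site {sites[bad[0]].id!r} under {spec.label()}"
        )
    K = k.sum(axis=0)
    keep = n_sites * n_regions <= per_site_cap
    return ImpactResult(
        K=K,
        region_ids=region_ids,
        spec=spec,
        release_set=release_set,
        per_site=k if keep else None,
        site_ids=[s.id for s in sites] if keep else None,
    )


def urban_source_share(
    impact: ImpactResult,
    sites: Sequence[ReleaseSite],
    regions: Sequence[Region],
) -> np.ndarray:
    """Percent of each region's cumulative impact from urban source counties.

    A source is urban when its containing region carries a rural-urban
    continuum code of 0-3 (metropolitan).  Regions with zero cumulative
    impact get NaN (the share is undefined there), never 0.
    """
    if impact.per_site is None:
        raise ValueError("urban_source_share requires the per-site impact matrix")
    site_by_id = {s.id: s for s in sites}
    metro_region = {r.id: r.rural_urban_code <= METRO_MAX_CODE for r in regions}
    urban_mask = np.array(
        [metro_region[site_by_id[sid].region_id] for sid in impact.site_ids], dtype=bool
    )
    urban_total = impact.per_site[urban_mask].sum(axis=0) if len(urban_mask) else np.zeros_like(impact.K)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = 100.0 * urban_total / impact.K
    share = np.where(impact.K > 0, share, np.nan)
    return share
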