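"""Core value types: regions, release sites, and decay specifications.

A :class:`Region` is the areal analysis unit (a county analog): it carries a
centroid, a USDA rural-urban continuum code (0-9; codes 0-3 are metropolitan),
named covariates, and an age-adjusted outcome rate.  A :class:`ReleaseSite` is
a point emission source with a positive release volume.  A :class:`DecaySpec`
names one of the six spatial-interaction families and its parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Mapping, Optional

import math

__all__ = ["Region", "ReleaseSite", "DecaySpec", "FAMILIES", "METRO_MAX_CODE"]

#: The six exposure families, in the order the comparison tables report them.
FAMILIES = ("containment", "buffer", "power", "exponential", "cutter", "external")

#: Rural-urban continuum codes 0..3 designate counties in metropolitan areas.
METRO_MAX_CODE = 3


class ConfigurationError(ValueError):
    """Raised for invalid model or scenario configuration."""


@dataclass(frozen=True)
class Region:
    """One areal unit (county analog).

    Parameters
    ----------
    id : hashable
        Unique region identifier.
    x, y : float
        Centroid coordinates.  Planar units (declared miles) by default; if
        the data were read from lon/lat columns the distance engine switches
        to great-circle distances.
    rural_urban_code : int
        USDA rural-urban continuum code, 0-9.
    outcome : float
        Age-adjusted outcome rate (e.g. deaths per 100,000).  May be NaN
        while a synthetic scenario is under construction.
    covariates : mapping of str to float
        Named covariate values.
    external_risk : float, optional
        Precomputed external risk score (RSEI stand-in), used by the
        ``external`` exposure family.
    """

    id: object
    x: float
    y: float
    rural_urban_code: int
    outcome: float = math.nan
    covariates: Mapping[str, float] = field(default_factory=dict)
    external_risk: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= int(self.rural_urban_code) <= 9):
            raise ValueError(
                f"region {self.id!r}: rural_urban_code must be in 0..9, "
                f"got {self.rural_urban_code}"
            )
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"region {self.id!r}: centroid must be finite")
        object.__setattr__(self, "covariates", MappingProxyType(dict(self.covariates)))

    @property
    def is_metro(self) -> bool:
        """Whether the region is metropolitan (code 0-3)."""
        return self.rural_urban_code <= METRO_MAX_CODE

    def with_outcome(self, outcome: float) -> "Region":
        return replace(self, covariates=dict(self.covariates), outcome=outcome)

    def with_external_risk(self, value: float) -> "Region":
        return replace(self, covariates=dict(self.covariates), external_risk=value)


@dataclass(frozen=True)
class ReleaseSite:
    """One point emission source.

    ``volume`` is the release volume in pounds (or abstract mass units) and
    must be positive.  ``region_id`` names the containing region; containment
    is resolved through this column, not point-in-polygon, so the pipeline
    runs without polygon data.
    """

    id: object
    x: float
    y: float
    region_id: object
    volume: float
    chemical_class: str = "all_carcinogen"

    def __post_init__(self) -> None:
        if not (self.volume > 0):
            raise ValueError(f"site {self.id!r}: volume must be > 0, got {self.volume}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"site {self.id!r}: location must be finite")


# families that require each parameter
_NEEDS_THETA = {"power", "exponential", "cutter"}
_NEEDS_T = {"buffer", "cutter"}


@dataclass(frozen=True)
class DecaySpec:
    """A spatial-interaction family plus its parameters.

    The per-site impact of a release of (effective) volume ``t`` at distance
    ``d`` from a region centroid is

    ========================  =============================================
    family                    impact k(t, d)
    ========================  =============================================
    ``containment``           ``t**alpha`` if the site lies in the region, else 0
    ``buffer``                ``t**alpha`` if ``d <= T``, else 0
    ``power``                 ``t**alpha / max(d, d_floor)**theta``
    ``exponential``           ``t**alpha * exp(-theta * d)``
    ``cutter``                ``t**alpha * (1 - (d/T)**2)**theta`` if ``d <= T``, else 0
    ``external``              copies the regions' precomputed external risk
    ========================  =============================================

    ``alpha`` is the exponent on volume, ``theta`` the decay rate, and
    ``threshold`` (``T``) the cutoff distance in miles for the buffer and
    cutter families.  ``log10_volumes`` requests the base-10 log transform of
    release volumes before exponentiation.  ``population_exponent`` is the
    gravity-model exponent on a destination population term; it defaults to 0
    (population terms set to 1), which is appropriate when the outcome is an
    age-adjusted rate rather than a count.
    """

    family: str
    alpha: float = 1.0
    theta: Optional[float] = None
    threshold: Optional[float] = None
    log10_volumes: bool = False
    population_exponent: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"unknown decay family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.family == "external":
            return
        if not (self.alpha > 0):
            raise ConfigurationError(f"alpha must be > 0, got {self.alpha}")
        if self.family in _NEEDS_THETA:
            if self.theta is None:
                raise ConfigurationError(f"family {self.family!r} requires theta")
            if not (self.theta > 0):
                raise ConfigurationError(f"theta must be > 0, got {self.theta}")
        if self.family in _NEEDS_T:
            if self.threshold is None:
                raise ConfigurationError(f"family {self.family!r} requires threshold T")
            if not (self.threshold > 0):
                raise ConfigurationError(f"threshold must be > 0, got {self.threshold}")

    def label(self) -> str:
        """Short human-readable parameterization label."""
        if self.family == "external":
            return "external"
        parts = [self.family, f"a={self.alpha:g}"]
        if self.family in _NEEDS_THETA:
            parts.append(f"th={self.theta:g}")
        if self.family in _NEEDS_T:
            parts.append(f"T={self.threshold:g}")
        if self.log10_volumes:
            parts.append("log10")
        return " ".join(parts)
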