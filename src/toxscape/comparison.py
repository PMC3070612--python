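"""Grid search over decay parameterizations and cross-model comparison.

The experiment proceeds the way national-scale exposure comparisons are
run: each decay family's parameter grid is searched exhaustively with OLS
(the parameterization minimizing the AIC wins; parameterizations that do
well under OLS also do well under the spatial regressions, so the costlier
spatial fits are reserved for the selected parameterizations), then OLS,
spatial lag, and spatial error models are fitted for every family at its
best parameterization, plus a no-exposure baseline and an external
risk-score passthrough when available.  Stratified OLS fits by rural-urban
continuum code and the urban-source share decomposition round out the
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import ConfigurationError, DecaySpec, Region, ReleaseSite
from .exposure import (
    DEFAULT_DISTANCE_FLOOR,
    RELEASE_SETS,
    cumulative_impact,
    select_releases,
    transform_volumes,
    urban_source_share,
)
from .geometry import distance_matrix, min_connecting_threshold
from .io import RunConfig, covariate_matrix, regions_frame
from .regression import (
    LOG2PI,
    RegressionResults,
    fit_ols,
    fit_spatial_error,
    fit_spatial_lag,
)
from .weights import SpatialWeights, distance_band_weights, queen_lattice_weights

log = logging.getLogger("toxscape")

__all__ = [
    "GridSpec",
    "GridSearchResult",
    "grid_search",
    "ComparisonResults",
    "build_comparison",
    "stratified_r2",
    "ExposureComparison",
    "run_experiment",
]

_KERNEL_FAMILIES = ("containment", "buffer", "power", "exponential", "cutter")


@dataclass(frozen=True)
class GridSpec:
    """Parameter grids searched per family.

    Defaults follow the production grids: alpha and theta from 1.0 to 5.0
    in steps of 0.5, distance thresholds 5, 10, 15, ... 500 miles, both the
    raw and log10-transformed volumes, and all three release sets.
    """

    alphas: Tuple[float, ...] = tuple(np.arange(1.0, 5.01, 0.5))
    thetas: Tuple[float, ...] = tuple(np.arange(1.0, 5.01, 0.5))
    thresholds: Tuple[float, ...] = tuple(np.arange(5.0, 500.01, 5.0))
    families: Tuple[str, ...] = _KERNEL_FAMILIES
    log10_options: Tuple[bool, ...] = (False, True)
    release_sets: Tuple[str, ...] = ("all_carcinogen", "lung_carcinogen", "lung_compound")

    def __post_init__(self) -> None:
        for name in ("alphas", "thetas", "thresholds", "families", "log10_options", "release_sets"):
            if not getattr(self, name):
                raise ConfigurationError(f"GridSpec.{name} must be nonempty")
        for fam in self.families:
            if fam not in _KERNEL_FAMILIES:
                raise ConfigurationError(f"cannot grid-search family {fam!r}")
        for rs in self.release_sets:
            if rs not in RELEASE_SETS:
                raise ConfigurationError(f"unknown release set {rs!r}")

    def combos(self, family: str):
        """Cartesian product of the parameters the family actually uses."""
        thetas = self.thetas if family in ("power", "exponential", "cutter") else (None,)
        thresholds = self.thresholds if family in ("buffer", "cutter") else (None,)
        for rs in self.release_sets:
            for lg in self.log10_options:
                for T in thresholds:
                    for th in thetas:
                        for a in self.alphas:
                            yield rs, lg, a, th, T


@dataclass
class GridSearchResult:
    family: str
    best_spec: DecaySpec
    best_release_set: str
    best_aic: float
    trace: pd.DataFrame


def _ols_aic_fast(Xb: np.ndarray, y: np.ndarray, extra: Optional[np.ndarray]) -> Tuple[float, float]:
    """(aic, rsquared) of OLS y ~ [Xb, extra], ML-variance likelihood."""
    X = Xb if extra is None else np.column_stack([Xb, extra])
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    llf = -0.5 * n * (LOG2PI + 1.0 + np.log(rss / n))
    return -2.0 * llf + 2.0 * (p + 1), 1.0 - rss / tss


def grid_search(
    sites: Sequence[ReleaseSite],
    regions: Sequence[Region],
    family: str,
    grid: GridSpec,
    covariates: Optional[Sequence[str]] = None,
    coords: str = "planar",
    d_floor: float = DEFAULT_DISTANCE_FLOOR,
) -> GridSearchResult:
    """Exhaustive AIC-minimizing search of one family's parameter grid.

    For every parameter combination the cumulative impact K is computed and
    an OLS regression of the outcome on the fixed covariates plus K is
    scored by AIC.  Ties are broken lexicographically by smallest
    (T, theta, alpha), then release set and transform flag.  Combinations
    whose K is (numerically) constant carry no information and are recorded
    with a degenerate flag and no AIC.
    """
    Xb = np.column_stack(
        [np.ones(len(regions)), covariate_matrix(regions, covariates).to_numpy()]
    )
    y = np.array([r.outcome for r in regions], dtype=float)
    region_index = {r.id: j for j, r in enumerate(regions)}

    D_all = distance_matrix(sites, regions, coords) if sites else np.zeros((0, len(regions)))
    vol_all = np.array([s.volume for s in sites], dtype=float)
    site_region = np.array([region_index[s.region_id] for s in sites], dtype=int)

    rows = []
    for rs, lg, a, th, T in grid.combos(family):
        keep = np.array([s.chemical_class in RELEASE_SETS[rs] for s in sites], dtype=bool)
        spec = DecaySpec(family, alpha=a, theta=th, threshold=T, log10_volumes=lg)
        if keep.any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t_eff = transform_volumes(vol_all[keep], lg)
            D = D_all[keep]
            t = t_eff[:, None]
            if family == "containment":
                k = np.zeros_like(D)
                k[np.arange(keep.sum()), site_region[keep]] = t_eff**a
            elif family == "buffer":
                k = np.where(D <= T, t**a, 0.0)
            elif family == "power":
                k = t**a / np.maximum(D, d_floor) ** th
            elif family == "exponential":
                k = t**a * np.exp(-th * D)
            else:  # cutter
                frac = np.clip(1.0 - (D / T) ** 2, 0.0, None)
                k = np.where(D <= T, t**a * frac**th, 0.0)
            K = k.sum(axis=0)
        else:
            K = np.zeros(len(regions))
        degenerate = float(np.ptp(K)) <= 1e-12 * max(1.0, float(np.abs(K).max()))
        if degenerate:
            aic_val, r2 = np.nan, np.nan
        else:
            aic_val, r2 = _ols_aic_fast(Xb, y, K)
        rows.append(
            {
                "family": family,
                "release_set": rs,
                "log10": lg,
                "alpha": a,
                "theta": th,
                "threshold": T,
                "aic": aic_val,
                "r_squared": r2,
                "degenerate": degenerate,
            }
        )
    trace = pd.DataFrame(rows)
    if trace["aic"].isna().all():
        raise RuntimeError(
            f"grid search for {family!r} produced no usable fit "
            f"({int(trace['degenerate'].sum())} degenerate cells)"
        )
    order = trace.sort_values(
        by=["threshold", "theta", "alpha", "release_set", "log10"],
        na_position="first",
        kind="stable",
    )
    best = order.loc[order["aic"].idxmin()]
    best_spec = DecaySpec(
        family,
        alpha=float(best["alpha"]),
        theta=None if pd.isna(best["theta"]) else float(best["theta"]),
        threshold=None if pd.isna(best["threshold"]) else float(best["threshold"]),
        log10_volumes=bool(best["log10"]),
    )
    return GridSearchResult(
        family=family,
        best_spec=best_spec,
        best_release_set=str(best["release_set"]),
        best_aic=float(best["aic"]),
        trace=trace,
    )


@dataclass
class ComparisonResults:
    """Cross-model comparison table plus the underlying fits.

    ``table`` is long-format with one row per (family, regression model)
    carrying AIC, OLS R-squared, the exposure-term p-value, and a note for
    degenerate or failed cells.  ``best_params`` summarizes the selected
    parameterization per family.  ``fits`` maps (family, model) to the full
    :class:`RegressionResults`.
    """

    table: pd.DataFrame
    best_params: pd.DataFrame
    fits: Dict[Tuple[str, str], RegressionResults] = field(default_factory=dict)
    impacts: Dict[str, object] = field(default_factory=dict)

    def min_aic_family(self, model: str) -> str:
        sub = self.table[(self.table["model"] == model) & self.table["aic"].notna()]
        return str(sub.loc[sub["aic"].idxmin(), "family"])

    def summary(self) -> str:
        lines = ["Best parameterizations:", self.best_params.to_string(index=False), ""]
        piv = self.table.pivot(index="family", columns="model", values="aic")
        lines += ["AIC by family and regression model:", piv.to_string()]
        for model in piv.columns:
            lines.append(f"minimum-AIC family ({model}): {self.min_aic_family(model)}")
        return "\n".join(lines)


def build_comparison(
    sites: Sequence[ReleaseSite],
    regions: Sequence[Region],
    weights: SpatialWeights,
    specs: Mapping[str, Tuple[DecaySpec, Optional[str]]],
    covariates: Optional[Sequence[str]] = None,
    coords: str = "planar",
    d_floor: float = DEFAULT_DISTANCE_FLOOR,
    models: Tuple[str, ...] = ("ols", "lag", "error"),
) -> ComparisonResults:
    """Fit OLS / spatial lag / spatial error for each family's best spec.

    The covariate set is fixed across all rows so the AICs are comparable.
    A ``no_term`` baseline (covariates only) is always included; a family
    whose K is constant has its exposure column dropped and the row flagged.
    Per-cell fit errors are recorded in the table, which is still emitted.
    """
    X0 = covariate_matrix(regions, covariates)
    y = np.array([r.outcome for r in regions], dtype=float)
    if not weights.row_standardized:
        # standardize once so the spectrum cache is shared across all fits
        weights = weights.row_standardize()

    design: Dict[str, Tuple[pd.DataFrame, str]] = {"no_term": (X0, "")}
    impacts: Dict[str, object] = {}
    rows: List[dict] = []
    fits: Dict[Tuple[str, str], RegressionResults] = {}
    best_rows = []

    for family, (spec, release_set) in specs.items():
        imp = cumulative_impact(
            sites, regions, spec, release_set=release_set, coords=coords, d_floor=d_floor
        )
        impacts[family] = imp
        note = ""
        K = imp.K
        if float(np.ptp(K)) <= 1e-12 * max(1.0, float(np.abs(K).max())):
            note = "degenerate exposure (constant K); term dropped"
            design[family] = (X0, note)
        else:
            Xf = X0.copy()
            Xf["exposure"] = K
            design[family] = (Xf, note)
        best_rows.append(
            {
                "family": family,
                "release_set": release_set,
                "alpha": spec.alpha if spec.family != "external" else np.nan,
                "theta": spec.theta,
                "threshold": spec.threshold,
                "log10": spec.log10_volumes if spec.family != "external" else np.nan,
            }
        )

    for family, (X, note) in design.items():
        for model in models:
            row = {"family": family, "model": model, "aic": np.nan,
                   "r_squared": np.nan, "exposure_pvalue": np.nan,
                   "spatial_coef": np.nan, "note": note}
            try:
                if model == "ols":
                    res = fit_ols(X, y)
                    row["r_squared"] = res.rsquared
                elif model == "lag":
                    res = fit_spatial_lag(X, y, weights)
                    row["spatial_coef"] = res.spatial_coef
                else:
                    res = fit_spatial_error(X, y, weights)
                    row["spatial_coef"] = res.spatial_coef
                row["aic"] = res.aic
                if "exposure" in res.params.index:
                    row["exposure_pvalue"] = float(res.pvalues["exposure"])
                fits[(family, model)] = res
            except Exception as exc:  # record, keep the table
                row["note"] = (note + "; " if note else "") + f"fit failed: {exc}"
                log.warning("comparison cell (%s, %s) failed: %s", family, model, exc)
            rows.append(row)

    table = pd.DataFrame(rows)
    best_params = pd.DataFrame(best_rows)
    return ComparisonResults(table=table, best_params=best_params, fits=fits, impacts=impacts)


def stratified_r2(
    sites: Sequence[ReleaseSite],
    regions: Sequence[Region],
    specs: Mapping[str, Tuple[DecaySpec, Optional[str]]],
    covariates: Optional[Sequence[str]] = None,
    coords: str = "planar",
) -> pd.DataFrame:
    """OLS R-squared per rural-urban continuum code, per family.

    The same specification is refitted on each code's region subset; codes
    with too few observations (n_obs <= n_params) are skipped with a
    warning.  The ``no_term`` column is the covariates-only baseline.
    """
    X0_all = covariate_matrix(regions, covariates)
    y_all = np.array([r.outcome for r in regions], dtype=float)
    K_by_family = {
        fam: cumulative_impact(sites, regions, spec, release_set=rs, coords=coords).K
        for fam, (spec, rs) in specs.items()
    }
    codes = np.array([r.rural_urban_code for r in regions])
    out = {}
    for code in sorted(set(codes.tolist())):
        mask = codes == code
        n_code = int(mask.sum())
        if n_code <= X0_all.shape[1] + 3:
            warnings.warn(
                f"rural-urban code {code}: only {n_code} regions, skipped", stacklevel=2
            )
            continue
        y = y_all[mask]
        X0 = X0_all.loc[mask].reset_index(drop=True)
        X0 = X0.loc[:, X0.nunique() > 1]  # drop constant-in-stratum columns
        row = {"no_term": fit_ols(X0, y).rsquared}
        for fam, K in K_by_family.items():
            Kc = K[mask]
            if np.ptp(Kc) <= 1e-12 * max(1.0, np.abs(Kc).max()):
                row[fam] = np.nan
                continue
            Xf = X0.copy()
            Xf["exposure"] = Kc
            row[fam] = fit_ols(Xf, y).rsquared
        out[code] = row
    df = pd.DataFrame(out).T
    df.index.name = "rural_urban_code"
    return df


class ExposureComparison:
    """End-to-end comparison model: grid search, then cross-model table.

    Statsmodels-style: construct from data, call :meth:`fit`, get a
    :class:`ComparisonResults`.

    Parameters
    ----------
    sites, regions
        The release sites and regions under study.
    weights : SpatialWeights, optional
        Weights for the spatial regressions; defaults to a distance band at
        the minimum connecting threshold.
    grid : GridSpec, optional
        Parameter grids; defaults to the production grids.
    covariates : sequence of str, optional
        Covariate names (defaults to every covariate on the regions).
    """

    def __init__(
        self,
        sites: Sequence[ReleaseSite],
        regions: Sequence[Region],
        weights: Optional[SpatialWeights] = None,
        grid: Optional[GridSpec] = None,
        covariates: Optional[Sequence[str]] = None,
        coords: str = "planar",
        include_external: Optional[bool] = None,
    ):
        self.sites = list(sites)
        self.regions = list(regions)
        self.coords = coords
        self.grid = grid or GridSpec()
        self.covariates = covariates
        if weights is None:
            thr = min_connecting_threshold(self.regions, coords)
            log.info("distance-band weights at minimum connecting threshold %.3f mi", thr)
            weights = distance_band_weights(self.regions, thr, coords)
        self.weights = weights
        if include_external is None:
            include_external = all(r.external_risk is not None for r in self.regions)
        self.include_external = include_external
        self.grid_results_: Dict[str, GridSearchResult] = {}

    def fit(self) -> ComparisonResults:
        specs: Dict[str, Tuple[DecaySpec, Optional[str]]] = {}
        for family in self.grid.families:
            gs = grid_search(
                self.sites, self.regions, family, self.grid,
                covariates=self.covariates, coords=self.coords,
            )
            self.grid_results_[family] = gs
            specs[family] = (gs.best_spec, gs.best_release_set)
            log.info("grid search %s: best %s (AIC %.2f)", family, gs.best_spec.label(), gs.best_aic)
        if self.include_external:
            specs["external"] = (DecaySpec("external"), None)
        return build_comparison(
            self.sites, self.regions, self.weights, specs,
            covariates=self.covariates, coords=self.coords,
        )


def run_experiment(config: RunConfig) -> Path:
    """Run the full pipeline and write its artifact bundle.

    Outputs (in ``config.outdir``): best_params.csv, comparison.csv,
    stratified_r2.csv, urban_share.csv, and manifest.json.  The run is
    deterministic given the seed; outputs are staged in a temporary
    directory and moved into place only on success, so a failing stage
    leaves no partial bundle.
    """
    from . import __version__
    from .io import read_regions_ex, read_sites
    from .synthetic import simulate

    if config.scenario is not None:
        scenario = simulate(dataclasses.replace(config.scenario, seed=config.seed))
        regions, sites = scenario.regions, scenario.sites
        coords = "planar"
    else:
        regions, coords = read_regions_ex(config.regions_path)
        sites = read_sites(config.sites_path)

    if config.weights_mode == "queen":
        side = int(round(len(regions) ** 0.5))
        if side * side != len(regions):
            raise ConfigurationError("queen weights require a square lattice scenario")
        weights = queen_lattice_weights(side, ids=[r.id for r in regions])
    else:
        thr = config.weights_threshold or min_connecting_threshold(regions, coords)
        weights = distance_band_weights(regions, thr, coords)

    grid = GridSpec(**config.grid) if config.grid else GridSpec()
    model = ExposureComparison(sites, regions, weights=weights, grid=grid, coords=coords)
    results = model.fit()

    specs = {
        fam: (gs.best_spec, gs.best_release_set) for fam, gs in model.grid_results_.items()
    }
    strat = stratified_r2(sites, regions, specs, coords=coords)

    shares = pd.DataFrame({"id": [r.id for r in regions]})
    for fam, imp in results.impacts.items():
        if imp.per_site is not None:
            shares[fam] = urban_source_share(imp, sites, regions)

    if config.prune_alpha is not None:
        from .regression import prune_covariates

        best_fam = results.min_aic_family("ols")
        X0 = covariate_matrix(regions)
        if best_fam in results.impacts:
            X0 = X0.copy()
            X0["exposure"] = results.impacts[best_fam].K
        y = np.array([r.outcome for r in regions], dtype=float)
        pruned_fit, kept = prune_covariates(
            X0, y, alpha=config.prune_alpha, protected=("exposure",)
        )
    else:
        pruned_fit, kept = None, None

    outdir = Path(config.outdir)
    tmp = Path(tempfile.mkdtemp(prefix="toxscape_stage_"))
    try:
        results.best_params.to_csv(tmp / "best_params.csv", index=False)
        results.table.to_csv(tmp / "comparison.csv", index=False)
        strat.to_csv(tmp / "stratified_r2.csv")
        shares.to_csv(tmp / "urban_share.csv", index=False)
        manifest = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "coords": coords,
            "n_regions": len(regions),
            "n_sites": len(sites),
            "weights_mode": config.weights_mode,
            "toxscape_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
        }
        if pruned_fit is not None:
            manifest["pruned_model"] = {"kept": kept, **pruned_fit.to_dict()}
        with open(tmp / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1)
        outdir.mkdir(parents=True, exist_ok=True)
        for f in tmp.iterdir():
            shutil.move(str(f), outdir / f.name)
    finally:
        shutil.rmtree(tmp, ignore_errors=True)
    return outdir
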