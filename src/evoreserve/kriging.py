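"""Geostatistical interpolation of lineage occurrence from genetic distances.

An empirical variogram of genetic vs geographic distance is fitted with a
bounded model family; the fitted correlation structure then drives
ordinary kriging of per-lineage indicator variables over the grid.  The
kriging weights depend only on geometry, so per-cell lineage probabilities
sum to one across a species' lineages by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.spatial.distance import cdist

from evoreserve.raster import Grid
from evoreserve.sdm import BinaryRange

log = logging.getLogger(__name__)

FAMILIES = ("spherical", "exponential", "gaussian", "linear")


@dataclass
class EmpiricalVariogram:
    lag_centers: np.ndarray
    semivariance: np.ndarray  # NaN where a bin holds no pairs
    pair_counts: np.ndarray


@dataclass
class VariogramModel:
    family: str
    nugget: float
    sill: float
    range_: float
    rss: float = np.nan

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.nugget < 0 or self.sill < self.nugget or self.range_ <= 0:
            raise ValueError("require 0 <= nugget <= sill and range > 0")

    def gamma(self, h: np.ndarray) -> np.ndarray:
        """Semivariance at separation h (gamma(0) = nugget by convention here
        only for h > 0; exactly at h = 0 the value is 0 for kriging exactness)."""
        h = np.asarray(h, dtype=float)
        u = h / self.range_
        c = self.sill - self.nugget
        if self.family == "spherical":
            g = np.where(u < 1.0, 1.5 * u - 0.5 * u**3, 1.0)
        elif self.family == "exponential":
            g = 1.0 - np.exp(-3.0 * u)
        elif self.family == "gaussian":
            g = 1.0 - np.exp(-3.0 * u**2)
        else:  # linear
            g = np.minimum(u, 1.0)
        out = self.nugget + c * g
        return np.where(h == 0, 0.0, out)

    def covariance(self, h: np.ndarray) -> np.ndarray:
        """Unit-sill correlation-like covariance (sill - gamma)/sill."""
        return (self.sill - self.gamma(h)) / self.sill


def empirical_variogram(
    dist: pd.DataFrame,
    coords: pd.DataFrame,
    n_lags: int = 10,
    cutoff: float | None = None,
) -> EmpiricalVariogram:
    """Bin pairs by geographic distance; gamma_hat(h_k) = sum d_gen^2 / (2 N_k)."""
    if len(dist) < 3:
        raise ValueError("need at least 3 samples")
    xy = coords.loc[dist.index, ["lon", "lat"]].to_numpy(float)
    geo = cdist(xy, xy)
    iu = np.triu_indices(len(dist), k=1)
    g, d = geo[iu], dist.to_numpy(float)[iu]
    if cutoff is None:
        cutoff = 0.5 * g.max()
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    keep = g <= cutoff
    if not keep.any():
        raise ValueError("no sample pairs within the cutoff distance")
    g, d = g[keep], d[keep]
    edges = np.linspace(0.0, cutoff, n_lags + 1)
    which = np.clip(np.digitize(g, edges[1:-1], right=True), 0, n_lags - 1)
    counts = np.bincount(which, minlength=n_lags)
    sums = np.bincount(which, weights=d**2, minlength=n_lags)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / (2.0 * np.maximum(counts, 1)), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return EmpiricalVariogram(centers, gamma, counts)


def fit_variogram(
    emp: EmpiricalVariogram,
    family: str = "spherical",
    init: tuple[float, float, float] | None = None,
    mode: str = "wls",
) -> VariogramModel:
    """Weighted least squares over (nugget, sill, range); weights = pair counts.

    ``mode='manual'`` echoes ``init`` verbatim (heuristic fitting by eye).
    """
    if mode == "manual":
        if init is None:
            raise ValueError("manual mode requires init=(nugget, sill, range)")
        return VariogramModel(family, *init)
    ok = emp.pair_counts > 0
    if ok.sum() < 3:
        raise ValueError("need >= 3 occupied lag bins for WLS fitting")
    h, g, w = emp.lag_centers[ok], emp.semivariance[ok], emp.pair_counts[ok].astype(float)
    if init is None:
        init = (0.0, float(np.nanmax(g)), float(h.max()))
    nug0, sill0, rng0 = init

    def residuals(theta: np.ndarray) -> np.ndarray:
        nugget, dsill, range_ = theta
        model = VariogramModel(family, nugget, nugget + dsill, range_)
        # evaluate at strictly positive h so the h==0 exactness rule is unused
        return np.sqrt(w) * (model.gamma(np.maximum(h, 1e-300)) - g)

    theta0 = np.array([max(nug0, 0.0), max(sill0 - nug0, 1e-6), max(rng0, 1e-6)])
    res = optimize.least_squares(
        residuals, theta0, bounds=([0.0, 1e-12, 1e-12], [np.inf] * 3)
    )
    if not res.success:
        raise RuntimeError(f"variogram fit failed: {res.message}; best iterate {res.x}")
    nugget, dsill, range_ = res.x
    return VariogramModel(family, float(nugget), float(nugget + dsill), float(range_), rss=float(2 * res.cost))


def _dedupe(samples: pd.DataFrame) -> pd.DataFrame:
    """Average indicators at duplicated coordinates (singular systems otherwise)."""
    if samples.duplicated(subset=["lon", "lat"]).any():
        log.info("averaging duplicate sample coordinates before kriging")
        return samples.groupby(["lon", "lat"], as_index=False).agg(
            {c: "mean" for c in samples.columns if c not in ("lon", "lat")}
        )
    return samples


def krige_indicator(
    samples: pd.DataFrame,
    vgm: VariogramModel,
    grid: Grid,
    mask: np.ndarray | None = None,
) -> dict[int, np.ndarray]:
    """Ordinary kriging of lineage-membership indicators.

    ``samples`` needs lon, lat, lineage.  One shared kriging system serves
    every lineage (the weights depend only on locations); predictions are
    clipped to [0, 1].  Returns {lineage id: probability raster}.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    lineages = sorted(samples["lineage"].unique())
    work = samples.copy()
    for lin in lineages:
        work[f"_z_{lin}"] = (samples["lineage"] == lin).astype(float)
    work = _dedupe(work.drop(columns=["lineage"]))
    xy = work[["lon", "lat"]].to_numpy(float)
    n = len(xy)

    A = np.ones((n + 1, n + 1))
    A[:n, :n] = vgm.covariance(cdist(xy, xy))
    A[n, n] = 0.0

    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    rr, cc = np.nonzero(mask)
    gx, gy = grid.cell_center(rr, cc)
    c0 = vgm.covariance(cdist(xy, np.column_stack([gx, gy])))
    B = np.vstack([c0, np.ones(len(rr))])
    try:
        W = np.linalg.solve(A, B)[:n]
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(f"singular kriging system: {exc}") from exc

    out: dict[int, np.ndarray] = {}
    for lin in lineages:
        z = work[f"_z_{lin}"].to_numpy()
        pred = np.clip(z @ W, 0.0, 1.0)
        raster = np.zeros(grid.shape)
        raster[rr, cc] = pred
        out[int(lin)] = raster
    return out


def lineage_binary(
    prob_raster: np.ndarray,
    species_binary: BinaryRange,
    feature_id: str,
    threshold: float = 0.5,
) -> BinaryRange:
    """Threshold a lineage probability surface and intersect with the species range."""
    if prob_raster.shape != species_binary.raster.shape:
        raise ValueError("probability raster and species range grids differ")
    binary = (prob_raster >= threshold) & species_binary.raster
    return BinaryRange(feature_id, "lineage", binary, status=species_binary.status)
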