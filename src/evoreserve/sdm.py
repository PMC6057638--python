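"""Presence-background maximum-entropy distribution modelling.

A regularized log-linear density over background cells (linear + quadratic
features of the selected landscape variables) is fitted by convex
minimization; replicate train/test splits give AUC-based evaluation, and
the minimum-training-presence rule turns mean suitability into a binary
range.  Feature classes are deliberately limited to linear+quadratic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score

from evoreserve.raster import Grid, LandscapeStack

log = logging.getLogger(__name__)

MAX_FULL_BACKGROUND = 50_000
BACKGROUND_SAMPLE = 10_000


class TooFewRecordsError(ValueError):
    """Raised when a feature has too few records to model."""


@dataclass
class BinaryRange:
    """A 0/1 range raster for one biodiversity feature."""

    feature_id: str
    kind: str  # "species" | "lineage"
    raster: np.ndarray  # bool
    status: str = "NE"

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=bool)

    @property
    def range_size(self) -> int:
        return int(self.raster.sum())


@dataclass
class SDMModel:
    var_names: list[str]
    beta: np.ndarray  # coefficients of the standardized feature expansion
    feat_mean: np.ndarray
    feat_sd: np.ndarray
    reg: float
    background: np.ndarray  # flat indices (into valid cells) of background
    log_z: float  # normalizer over background
    stack: LandscapeStack = field(repr=False)

    def _features_raw(self, values: np.ndarray) -> np.ndarray:
        # values: (n, n_vars) raw layer values -> (n, 2*n_vars) linear+quadratic
        return np.column_stack([values, values**2])

    def scores(self, values: np.ndarray) -> np.ndarray:
        f = (self._features_raw(values) - self.feat_mean) / self.feat_sd
        return f @ self.beta

    def suitability_map(self) -> np.ndarray:
        """Suitability in [0,1]: exponential density rescaled by its maximum."""
        out = np.zeros(self.stack.grid.shape)
        vals = self.stack.valid_matrix(self.var_names)
        s = self.scores(vals) - self.log_z
        s = np.exp(s - s.max())
        out[self.stack.mask] = s
        return out


@dataclass
class SDMEvaluation:
    feature_id: str
    replicates: pd.DataFrame  # replicate, n_train, n_test, auc_train, auc_test
    mean_map: np.ndarray
    sd_map: np.ndarray
    models: list[SDMModel] = field(repr=False)
    train_sets: list[pd.DataFrame] = field(repr=False)


def select_variables(stack: LandscapeStack, max_abs_corr: float = 0.75, k: int = 8) -> list[str]:
    """Greedy decorrelation: drop the most-correlated variable until all
    pairwise |r| <= max_abs_corr and at most k remain; ties by name."""
    names = sorted(stack.var_names)
    if k > len(names):
        k = len(names)
    while len(names) > 1:
        X = stack.valid_matrix(names)
        r = np.abs(np.corrcoef(X, rowvar=False))
        np.fill_diagonal(r, 0.0)
        if r.max() <= max_abs_corr and len(names) <= k:
            break
        mean_abs = r.mean(axis=1)
        names.pop(int(np.argmax(mean_abs)))
    return names


def occurrence_cells(occ: pd.DataFrame, grid: Grid) -> tuple[np.ndarray, np.ndarray]:
    if {"row", "col"} <= set(occ.columns):
        return occ["row"].to_numpy(int), occ["col"].to_numpy(int)
    return grid.cell_of(occ["lon"].to_numpy(), occ["lat"].to_numpy())


def thin_occurrences_pca3(occ: pd.DataFrame, stack: LandscapeStack, radius: float) -> pd.DataFrame:
    """Thin records clustered in the 3-D PCA space of the landscape variables.

    Records are considered in input order; one is discarded when it lies
    within ``radius`` (Euclidean, PC space) of an already-kept record.
    """
    if len(occ) < 2 or radius <= 0:
        return occ.copy()
    pca = PCA(n_components=min(3, stack.n_vars))
    pca.fit(stack.valid_matrix())
    rows, cols = occurrence_cells(occ, stack.grid)
    pcs = pca.transform(stack.values_at(rows, cols))
    kept: list[int] = []
    for i in range(len(occ)):
        if all(np.linalg.norm(pcs[i] - pcs[j]) >= radius for j in kept):
            kept.append(i)
    return occ.iloc[kept].copy()


def _background_indices(stack: LandscapeStack, n: int | None, rng: np.random.Generator) -> np.ndarray:
    n_valid = int(stack.mask.sum())
    if n is None:
        n = n_valid if n_valid <= MAX_FULL_BACKGROUND else BACKGROUND_SAMPLE
    if n >= n_valid:
        return np.arange(n_valid)
    return rng.choice(n_valid, size=n, replace=False)


def fit_maxent(
    occ_train: pd.DataFrame,
    stack: LandscapeStack,
    var_names: list[str] | None = None,
    background_n: int | None = None,
    reg: float = 1.0,
    seed: int = 0,
) -> SDMModel:
    """Fit the regularized maximum-entropy density.

    Minimizes ``-mean_presence(f(x).beta) + log sum_background exp(f(x).beta)
    + sum_f r_f |beta_f|`` with r_f = reg * sd_f / sqrt(n_presences) over
    standardized linear+quadratic features, via an L-BFGS-B split-variable
    formulation (the objective is convex).
    """
    if len(occ_train) < 3:
        raise TooFewRecordsError(f"need >= 3 training presences, got {len(occ_train)}")
    var_names = list(var_names) if var_names is not None else stack.var_names
    rng = np.random.default_rng(seed)

    valid_vals = stack.valid_matrix(var_names)
    bg_idx = _background_indices(stack, background_n, rng)
    raw_bg = np.column_stack([valid_vals[bg_idx], valid_vals[bg_idx] ** 2])
    feat_mean = raw_bg.mean(axis=0)
    feat_sd = raw_bg.std(axis=0)
    degenerate = feat_sd < 1e-12
    if degenerate.any():
        log.info("dropping %d zero-variance features", int(degenerate.sum()))
        feat_sd = np.where(degenerate, 1.0, feat_sd)
    Fb = (raw_bg - feat_mean) / feat_sd
    Fb[:, degenerate] = 0.0

    rows, cols = occurrence_cells(occ_train, stack.grid)
    raw_p = stack.values_at(rows, cols, var_names)
    Fp = (np.column_stack([raw_p, raw_p**2]) - feat_mean) / feat_sd
    Fp[:, degenerate] = 0.0

    n_feat = Fb.shape[1]
    r = np.full(n_feat, reg / np.sqrt(len(occ_train)))  # sd_f = 1 after standardization
    fp_mean = Fp.mean(axis=0)

    def objective(z: np.ndarray) -> tuple[float, np.ndarray]:
        beta = z[:n_feat] - z[n_feat:]
        s = Fb @ beta
        lz = logsumexp(s)
        w = np.exp(s - lz)
        smooth = -fp_mean @ beta + lz
        g_beta = -fp_mean + w @ Fb
        grad = np.concatenate([g_beta + r, -g_beta + r])
        return smooth + r @ np.abs(beta), grad

    z0 = np.zeros(2 * n_feat)
    res = optimize.minimize(
        objective, z0, jac=True, method="L-BFGS-B", bounds=[(0, None)] * (2 * n_feat)
    )
    beta = res.x[:n_feat] - res.x[n_feat:]
    beta[np.abs(beta) < 1e-12] = 0.0
    log_z = float(logsumexp(Fb @ beta))
    return SDMModel(var_names, beta, feat_mean, feat_sd, reg, bg_idx, log_z, stack)


def replicate_rule(n_records: int) -> int:
    """Replicate count: 10 (N>=20), 8 (10<=N<20), 4 (N<10); N<=5 unmodellable."""
    if n_records <= 5:
        raise TooFewRecordsError(f"{n_records} records: too few to model (use records_to_range)")
    if n_records >= 20:
        return 10
    if n_records >= 10:
        return 8
    return 4


def _auc(model: SDMModel, occ: pd.DataFrame, stack: LandscapeStack, bg_scores: np.ndarray) -> float:
    rows, cols = occurrence_cells(occ, stack.grid)
    p_scores = model.scores(stack.values_at(rows, cols, model.var_names))
    y = np.concatenate([np.ones(len(p_scores)), np.zeros(len(bg_scores))])
    s = np.concatenate([p_scores, bg_scores])
    if np.ptp(s) == 0:
        return 0.5
    return float(roc_auc_score(y, s))


def replicate_evaluate(
    occ: pd.DataFrame,
    stack: LandscapeStack,
    var_names: list[str] | None = None,
    test_fraction: float = 0.3,
    background_n: int | None = None,
    reg: float = 1.0,
    seed: int = 0,
) -> SDMEvaluation:
    """Replicated random 70/30 splits with train/test AUC and mean/SD maps."""
    n = len(occ)
    n_rep = replicate_rule(n)
    rng = np.random.default_rng(seed)
    feature_id = str(occ["feature_id"].iloc[0]) if "feature_id" in occ else "feature"

    maps, rows_out, models, train_sets = [], [], [], []
    for rep in range(n_rep):
        perm = rng.permutation(n)
        n_test = max(1, int(round(test_fraction * n)))
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        occ_train, occ_test = occ.iloc[train_idx], occ.iloc[test_idx]
        model = fit_maxent(occ_train, stack, var_names, background_n, reg, seed=seed + rep)
        vals = stack.valid_matrix(model.var_names)
        bg_scores = model.scores(vals[model.background])
        auc_tr = _auc(model, occ_train, stack, bg_scores)
        auc_te = _auc(model, occ_test, stack, bg_scores)
        maps.append(model.suitability_map())
        models.append(model)
        train_sets.append(occ_train)
        rows_out.append((rep, len(occ_train), len(occ_test), auc_tr, auc_te))

    stackmaps = np.stack(maps)
    replicates = pd.DataFrame(
        rows_out, columns=["replicate", "n_train", "n_test", "auc_train", "auc_test"]
    )
    return SDMEvaluation(
        feature_id, replicates, stackmaps.mean(axis=0), stackmaps.std(axis=0), models, train_sets
    )


def binarize_mtp(evaluation: SDMEvaluation, occ_train: pd.DataFrame, stack: LandscapeStack) -> tuple[BinaryRange, float]:
    """Minimum-training-presence binarization of the mean suitability map."""
    rows, cols = occurrence_cells(occ_train, stack.grid)
    theta = float(evaluation.mean_map[rows, cols].min())
    binary = (evaluation.mean_map >= theta) & stack.mask
    return BinaryRange(evaluation.feature_id, "species", binary), theta


def tss(
    binary: BinaryRange | np.ndarray,
    occ: pd.DataFrame,
    stack: LandscapeStack,
    background_n: int = 10_000,
    seed: int = 0,
) -> float:
    """True skill statistic: sensitivity + specificity - 1 against a random
    background sample (capped at the number of valid cells)."""
    raster = binary.raster if isinstance(binary, BinaryRange) else np.asarray(binary, bool)
    rng = np.random.default_rng(seed)
    rows, cols = occurrence_cells(occ, stack.grid)
    sens = float(raster[rows, cols].mean())
    flat = raster[stack.mask]
    idx = _background_indices(stack, min(background_n, len(flat)), rng)
    spec = float(1.0 - flat[idx].mean())
    return sens + spec - 1.0


def variable_contribution(
    model: SDMModel, stack: LandscapeStack, occ_train: pd.DataFrame, seed: int = 0, n_perm: int = 5
) -> pd.Series:
    """Permutation importance, normalized to sum to 100.

    The drop in training gain (mean presence score minus log mean
    background score) when one variable's cell values are permuted,
    averaged over ``n_perm`` permutations.
    """
    rng = np.random.default_rng(seed)
    vals = stack.valid_matrix(model.var_names)
    rows, cols = occurrence_cells(occ_train, stack.grid)
    p_vals = stack.values_at(rows, cols, model.var_names)
    bg = vals[model.background]

    def gain(pv: np.ndarray, bv: np.ndarray) -> float:
        sp = model.scores(pv)
        sb = model.scores(bv)
        return float(sp.mean() - (logsumexp(sb) - np.log(len(sb))))

    base = gain(p_vals, bg)
    drops = np.zeros(len(model.var_names))
    for j in range(len(model.var_names)):
        for _ in range(n_perm):
            perm = rng.permutation(len(vals))
            pv = p_vals.copy()
            bv = bg.copy()
            # permuted values drawn from the variable's distribution over cells
            pv[:, j] = vals[perm[: len(pv)], j]
            bv[:, j] = vals[perm[: len(bv)], j]
            drops[j] += base - gain(pv, bv)
    drops = np.maximum(drops / n_perm, 0.0)
    if drops.sum() == 0:
        drops = (np.abs(model.beta[: len(drops)]) + np.abs(model.beta[len(drops) :])) > 0
        drops = drops.astype(float)
    if drops.sum() == 0:
        drops[:] = 1.0
    return pd.Series(100.0 * drops / drops.sum(), index=model.var_names, name="contribution")


def records_to_range(occ: pd.DataFrame, stack: LandscapeStack, feature_id: str | None = None) -> BinaryRange:
    """Range of an unmodellable feature (N <= 5): exactly the record cells."""
    if not 1 <= len(occ) <= 5:
        raise ValueError(f"records_to_range applies to 1..5 records, got {len(occ)}")
    rows, cols = occurrence_cells(occ, stack.grid)
    raster = np.zeros(stack.grid.shape, dtype=bool)
    raster[rows, cols] = True
    fid = feature_id or (str(occ["feature_id"].iloc[0]) if "feature_id" in occ else "feature")
    return BinaryRange(fid, "species", raster & stack.mask)
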