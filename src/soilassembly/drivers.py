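"""Statistical attribution of community variation to abiotic/biotic drivers.

Contains the permutation machinery (standard and partial Mantel tests), the
LMG variance decomposition of multiple regressions, dominant-taxon driver
models, forward-selected distance-based redundancy analysis on a
Bray-Curtis embedding, and random-forest permutation importance with
response-permutation p-values.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .community import CountTable, PairMatrix
from .exceptions import (
    CollinearityError,
    DegenerateInputError,
    InvalidArgumentError,
    LabelMismatchError,
)


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    method: str  # "standard" or "partial"


def _pair_correlation(a: np.ndarray, b: np.ndarray) -> float:
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if len(a) < 3 or a.std() == 0 or b.std() == 0:
        raise DegenerateInputError("zero variance in a distance-matrix triangle")
    return float(np.corrcoef(a, b)[0, 1])


def mantel(
    A: PairMatrix,
    B: PairMatrix,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
    method: str = "pearson",
) -> MantelResult:
    """Mantel permutation test between two labelled symmetric matrices.

    r is the Pearson (or Spearman) correlation of the upper off-diagonal
    triangles; the null permutes rows and columns of B simultaneously.
    p uses the add-one estimator (1 + #{r_perm >= r_obs}) / (1 + n_perm)
    for ``alternative="greater"``; ``"two-sided"`` compares |r|.
    """
    if A.n < 4:
        raise InvalidArgumentError("need >= 4 samples")
    if alternative not in ("greater", "two-sided", "less"):
        raise InvalidArgumentError(f"unknown alternative {alternative!r}")
    B = B.reorder(A.labels)
    n = A.n
    iu = np.triu_indices(n, k=1)
    a = A.values[iu]
    if method == "spearman":
        a = stats.rankdata(a)

    def triangle_of(mat):
        t = mat[iu]
        return stats.rankdata(t) if method == "spearman" else t

    r_obs = _pair_correlation(a, triangle_of(B.values))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = _pair_correlation(a, triangle_of(B.values[np.ix_(perm, perm)]))
        if alternative == "greater":
            exceed += r_perm >= r_obs
        elif alternative == "less":
            exceed += r_perm <= r_obs
        else:
            exceed += abs(r_perm) >= abs(r_obs)
    p = (1 + exceed) / (1 + n_perm)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm, method="standard")


def _residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_mantel(
    A: PairMatrix,
    B: PairMatrix,
    C: PairMatrix,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Partial Mantel test of A vs B controlling for C (residual method).

    Triangles of A and B are each regressed on the triangle of C; r is the
    correlation of the residuals.  The null permutes the rows/columns of
    the symmetric matrix formed from B's residuals.
    """
    if A.n < 4:
        raise InvalidArgumentError("need >= 4 samples")
    B = B.reorder(A.labels)
    C = C.reorder(A.labels)
    n = A.n
    iu = np.triu_indices(n, k=1)
    a, b, c = A.values[iu], B.values[iu], C.values[iu]
    mask = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    if mask.sum() < 3:
        raise DegenerateInputError("too few finite pairs")
    if c[mask].std() == 0:
        raise DegenerateInputError("control matrix has zero variance")
    ra = np.full(len(a), np.nan)
    rb = np.full(len(b), np.nan)
    ra[mask] = _residuals(a[mask], c[mask])
    rb[mask] = _residuals(b[mask], c[mask])
    # a matrix explained entirely by the control carries no information
    # beyond it: the partial correlation is zero by convention
    if ra[mask].std() < 1e-12 or rb[mask].std() < 1e-12:
        return MantelResult(r=0.0, p=1.0, n_perm=n_perm, method="partial")
    r_obs = _pair_correlation(ra, rb)

    rb_mat = np.zeros((n, n))
    rb_mat[iu] = np.where(mask, rb, np.nan)
    rb_mat = rb_mat + rb_mat.T
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = _pair_correlation(ra, rb_mat[np.ix_(perm, perm)][iu])
        if alternative == "greater":
            exceed += r_perm >= r_obs
        elif alternative == "less":
            exceed += r_perm <= r_obs
        else:
            exceed += abs(r_perm) >= abs(r_obs)
    p = (1 + exceed) / (1 + n_perm)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm, method="partial")


# ---------------------------------------------------------------------------
# LMG variance decomposition
# ---------------------------------------------------------------------------

@dataclass
class ImportanceTable:
    """Per-predictor share of the full-model R2 (LMG decomposition)."""

    shares: pd.Series
    total_r2: float

    @property
    def ranks(self) -> pd.Series:
        return self.shares.rank(ascending=False, method="min").astype(int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"share": self.shares, "rank": self.ranks})


def _check_rank(X: np.ndarray, names) -> None:
    from scipy.linalg import qr

    Xc = X - X.mean(axis=0)
    if np.linalg.matrix_rank(Xc) < X.shape[1]:
        _, r, piv = qr(Xc, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(Xc.shape) * np.finfo(float).eps if diag.size else 0
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        bad += [names[j] for j in piv[len(diag):]]
        raise CollinearityError(bad or list(names))


def _r2(Xc: np.ndarray, yc: np.ndarray, sst: float, cols: tuple) -> float:
    if not cols:
        return 0.0
    beta, *_ = np.linalg.lstsq(Xc[:, cols], yc, rcond=None)
    resid = yc - Xc[:, cols] @ beta
    return 1.0 - float(resid @ resid) / sst


def lmg_importance(
    X: pd.DataFrame,
    y,
    method: str = "exact",
    n_orderings: int = 2000,
    seed: int = 0,
) -> ImportanceTable:
    """LMG relative importance of each predictor.

    The LMG share of predictor j averages, over all orderings of the
    predictors, the increase in R2 when j enters after the predictors
    preceding it.  ``method="exact"`` enumerates all subsets (p <= 12);
    ``method="sampling"`` averages over ``n_orderings`` random orderings
    and is the declared Monte-Carlo fallback for wider designs.
    Shares are non-negative and sum exactly to the full-model R2.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise LabelMismatchError("X and y lengths differ")
    if n <= p + 1:
        raise InvalidArgumentError("need n > p + 1 observations")
    if y.std() == 0:
        raise DegenerateInputError("response has zero variance")
    names = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    _check_rank(Xm, names)
    Xc = Xm - Xm.mean(axis=0)
    yc = y - y.mean()
    sst = float(yc @ yc)

    if method == "exact":
        if p > 12:
            raise InvalidArgumentError(
                "exact LMG is limited to 12 predictors; pre-group predictors "
                "or use method='sampling'"
            )
        cache = {}
        for k in range(p + 1):
            for cols in itertools.combinations(range(p), k):
                cache[cols] = _r2(Xc, yc, sst, cols)
        shares = np.zeros(p)
        fact = math.factorial
        for j in range(p):
            others = [i for i in range(p) if i != j]
            for k in range(p):
                w = fact(k) * fact(p - k - 1) / fact(p)
                for subset in itertools.combinations(others, k):
                    with_j = tuple(sorted(subset + (j,)))
                    shares[j] += w * (cache[with_j] - cache[subset])
        total = cache[tuple(range(p))]
    elif method == "sampling":
        rng = np.random.default_rng(seed)
        cache = {}

        def r2_of(cols):
            key = tuple(sorted(cols))
            if key not in cache:
                cache[key] = _r2(Xc, yc, sst, key)
            return cache[key]

        shares = np.zeros(p)
        for _ in range(n_orderings):
            order = rng.permutation(p)
            prev: list[int] = []
            r_prev = 0.0
            for j in order:
                prev.append(int(j))
                r_new = r2_of(prev)
                shares[j] += r_new - r_prev
                r_prev = r_new
        shares /= n_orderings
        total = r2_of(range(p))
    else:
        raise InvalidArgumentError(f"unknown method {method!r}")
    return ImportanceTable(
        shares=pd.Series(shares, index=names, name="lmg_share"),
        total_r2=float(total),
    )


# ---------------------------------------------------------------------------
# dominant taxa and per-taxon driver models
# ---------------------------------------------------------------------------

def dominant_taxa_select(
    table: CountTable,
    prevalence_min: float = 0.5,
    abundance_top: float = 0.10,
) -> list[str]:
    """Ubiquitous and abundant taxa.

    Keeps taxa whose occupancy exceeds ``prevalence_min`` of samples
    (strictly) and whose mean relative abundance lies in the top
    ``abundance_top`` quantile across taxa.
    """
    if not (0 <= prevalence_min < 1) or not (0 < abundance_top <= 1):
        raise InvalidArgumentError("thresholds outside (0, 1)")
    occupancy = (table.data > 0).sum(axis=0)
    mean_ra = table.relative().mean(axis=0)
    cutoff = mean_ra.quantile(1 - abundance_top)
    keep = (occupancy > prevalence_min * table.n_samples) & (mean_ra >= cutoff)
    return [t for t in table.taxon_ids if keep[t]]


def taxon_driver_models(
    table: CountTable,
    drivers: pd.DataFrame,
    taxa: list[str],
    abiotic: list[str],
    biotic: list[str],
    lmg_method: str = "exact",
    fdr_bh: bool = False,
) -> dict:
    """Abiotic-only vs abiotic+biotic regressions per dominant taxon.

    Drivers are z-scored; per taxon, the relative abundance is regressed on
    the abiotic set alone (r2_nonbio) and on the full set (r2_bio), the
    full model is LMG-decomposed, and the best predictor is the one with
    the largest share.  A one-sided Wilcoxon signed-rank test compares
    r2_bio against r2_nonbio across taxa.
    """
    missing = [c for c in abiotic + biotic if c not in drivers.columns]
    if missing:
        raise InvalidArgumentError(f"driver columns missing: {missing}")
    Z = drivers[abiotic + biotic].reindex(table.data.index).astype(float)
    if Z.isna().any().any():
        raise LabelMismatchError("drivers missing for some samples")
    Z = (Z - Z.mean()) / Z.std(ddof=0)
    rel = table.relative()
    rows = []
    for taxon in taxa:
        if taxon not in rel.columns:
            raise LabelMismatchError(f"taxon {taxon!r} not in the table")
        y = rel[taxon].to_numpy()
        imp_full = lmg_importance(Z, y, method=lmg_method)
        imp_abiotic = lmg_importance(Z[abiotic], y, method=lmg_method)
        n = len(y)

        def adjust(r2, p):
            return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)

        p_full = Z.shape[1]
        r2 = imp_full.total_r2
        if r2 < 1.0 and n > p_full + 1:
            f_stat = (r2 / p_full) / ((1 - r2) / (n - p_full - 1))
            model_p = float(stats.f.sf(f_stat, p_full, n - p_full - 1))
        else:
            model_p = 0.0
        rows.append(
            {
                "taxon": taxon,
                "best_predictor": imp_full.shares.idxmax(),
                "r2_bio": imp_full.total_r2,
                "r2_nonbio": imp_abiotic.total_r2,
                "r2_bio_adj": adjust(imp_full.total_r2, Z.shape[1]),
                "r2_nonbio_adj": adjust(imp_abiotic.total_r2, len(abiotic)),
                "model_p": model_p,
                **{f"share_{k}": v for k, v in imp_full.shares.items()},
            }
        )
    if not rows:
        warnings.warn("no taxa supplied; returning empty driver-model table")
        empty = pd.DataFrame(
            columns=["best_predictor", "r2_bio", "r2_nonbio"]
        ).rename_axis("taxon")
        return {"per_taxon": empty, "wilcoxon_p": float("nan")}
    per_taxon = pd.DataFrame(rows).set_index("taxon")
    if fdr_bh:
        from statsmodels.stats.multitest import multipletests

        per_taxon["model_p_adj"] = multipletests(
            per_taxon["model_p"], method="fdr_bh"
        )[1]
    # raw in-sample R2 is monotone in the predictor set, so the paired test
    # uses adjusted R2, which is centred under a null response
    diffs = per_taxon["r2_bio_adj"] - per_taxon["r2_nonbio_adj"]
    if len(diffs) >= 2 and (diffs != 0).any():
        wilcoxon_p = float(
            stats.wilcoxon(diffs, alternative="greater", zero_method="zsplit").pvalue
        )
    else:
        wilcoxon_p = float("nan")
    return {"per_taxon": per_taxon, "wilcoxon_p": wilcoxon_p}


# ---------------------------------------------------------------------------
# distance-based RDA with forward selection
# ---------------------------------------------------------------------------

def dbrda_forward(
    bc: PairMatrix,
    drivers: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 199,
    seed: int = 0,
) -> pd.DataFrame:
    """Forward selection of drivers on a PCoA embedding of Bray-Curtis.

    The dissimilarity is square-root transformed before principal
    coordinate analysis (correcting its non-Euclidean geometry); axes with
    non-positive eigenvalues are discarded.  Greedy forward selection adds,
    at each step, the driver with the largest increase in explained
    variance, admitted while its permutation p <= alpha (Freedman-Lane
    residual permutation of the candidate on the selected set).
    """
    from skbio import DistanceMatrix
    from skbio.stats.ordination import pcoa

    if bc.kind != "bray_curtis":
        raise InvalidArgumentError("expected a bray_curtis PairMatrix")
    Z = drivers.reindex(bc.labels).astype(float)
    if Z.isna().any().any():
        raise LabelMismatchError("drivers missing for some samples")
    Z = (Z - Z.mean()) / Z.std(ddof=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ordination = pcoa(DistanceMatrix(np.sqrt(bc.values), ids=bc.labels))
    eigvals = ordination.eigvals.to_numpy()
    keep = eigvals > 1e-10
    Y = ordination.samples.to_numpy()[:, keep]
    Y = Y - Y.mean(axis=0)
    total = float((Y**2).sum())
    Xall = Z.to_numpy()
    names = list(Z.columns)

    def r2(cols: list[int]) -> float:
        if not cols:
            return 0.0
        X = Xall[:, cols]
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        fitted = X @ beta
        return float((fitted**2).sum()) / total

    rng = np.random.default_rng(seed)
    selected: list[int] = []
    rows = []
    r_current = 0.0
    remaining = list(range(len(names)))
    while remaining:
        gains = [(r2(selected + [j]) - r_current, j) for j in remaining]
        gain, best = max(gains)
        if gain <= 0:
            break
        # Freedman-Lane: permute the candidate's residuals on the selected set
        x = Xall[:, best]
        if selected:
            Xs = Xall[:, selected]
            beta, *_ = np.linalg.lstsq(Xs, x, rcond=None)
            fitted_x = Xs @ beta
        else:
            fitted_x = np.full_like(x, x.mean())
        resid_x = x - fitted_x
        exceed = 0
        for _ in range(n_perm):
            x_perm = fitted_x + rng.permutation(resid_x)
            Xtry = np.column_stack([Xall[:, selected], x_perm]) if selected else x_perm[:, None]
            beta, *_ = np.linalg.lstsq(Xtry, Y, rcond=None)
            gain_perm = float(((Xtry @ beta) ** 2).sum()) / total - r_current
            exceed += gain_perm >= gain
        p = (1 + exceed) / (1 + n_perm)
        if p > alpha:
            break
        selected.append(best)
        r_current += gain
        rows.append(
            {
                "variable": names[best],
                "delta_r2": float(gain),
                "cumulative_r2": float(r_current),
                "p": float(p),
            }
        )
        remaining.remove(best)
    return pd.DataFrame(rows, columns=["variable", "delta_r2", "cumulative_r2", "p"])


# ---------------------------------------------------------------------------
# random-forest importance with permutation p-values
# ---------------------------------------------------------------------------

def _forest_importance(X, y, n_trees, n_repeats, rng):
    from sklearn.ensemble import RandomForestRegressor

    seed_int = int(rng.integers(2**31 - 1))
    forest = RandomForestRegressor(
        n_estimators=n_trees, random_state=seed_int, n_jobs=1
    )
    forest.fit(X, y)
    base_pred = forest.predict(X)
    base_mse = float(np.mean((y - base_pred) ** 2))
    n, p = X.shape
    imp = np.zeros(p)
    for j in range(p):
        increase = 0.0
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(n), j]
            mse = float(np.mean((y - forest.predict(Xp)) ** 2))
            increase += mse - base_mse
        imp[j] = increase / n_repeats
    return imp


def rf_importance(
    X: pd.DataFrame,
    y,
    n_trees: int = 500,
    n_perm: int = 99,
    seed: int = 0,
    n_repeats: int = 5,
) -> pd.DataFrame:
    """Random-forest permutation importance with response-permutation p.

    Importance of predictor j is the mean increase in MSE when its column
    is shuffled, expressed as a percentage of Var(y) (``incMSE_pct``).  The
    null distribution of each importance comes from refitting the forest on
    ``n_perm`` response-permuted datasets; p uses the add-one estimator.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 20:
        raise InvalidArgumentError("need >= 20 observations")
    if y.std() == 0:
        raise DegenerateInputError("response has zero variance")
    rng = np.random.default_rng(seed)
    Xm = X.to_numpy(dtype=float)
    obs = _forest_importance(Xm, y, n_trees, n_repeats, rng)
    null_exceed = np.zeros(len(X.columns))
    for _ in range(n_perm):
        y_perm = y[rng.permutation(len(y))]
        null = _forest_importance(Xm, y_perm, n_trees, n_repeats, rng)
        null_exceed += null >= obs
    p = (1 + null_exceed) / (1 + n_perm)
    scale = 100.0 / y.var()
    return pd.DataFrame(
        {"incMSE_pct": obs * scale, "p": p}, index=X.columns
    ).sort_values("incMSE_pct", ascending=False)
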