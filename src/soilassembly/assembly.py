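"""Phylogenetic null-model analysis of community assembly.

Implements the beta mean-nearest-taxon-distance (betaMNTD) turnover metric,
its tip-shuffle null model and the resulting beta nearest taxon index
(betaNTI) z-score, plus the three-way classification of sample pairs into
homogeneous selection (betaNTI < -2), variable selection (betaNTI > 2) and
stochasticity (|betaNTI| <= 2), and the fungal-richness grouping analysis
that tracks how those fractions shift along a richness gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .community import CountTable, PairMatrix
from .exceptions import (
    DegenerateInputError,
    InvalidArgumentError,
    InvalidTreeError,
    LabelMismatchError,
)


def cophenetic(tree: dendropy.Tree) -> pd.DataFrame:
    """Patristic (cophenetic) distance matrix between all tips.

    d_ij is the sum of branch lengths on the path between tips i and j.
    """
    for edge in tree.preorder_edge_iter():
        head = edge.head_node
        if head is None or head.parent_node is None:
            continue  # root stem does not enter tip-tip paths
        if edge.length is None:
            raise InvalidTreeError("tree has edges without branch lengths")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return pd.DataFrame(d, index=labels, columns=labels)


def _bmntd_core(F: np.ndarray, P: np.ndarray, D: np.ndarray) -> np.ndarray:
    """betaMNTD for all sample pairs.

    F: (n_taxa, n_samples) per-sample weights (zero for absent taxa,
    columns sum to 1); P: boolean presence, same shape; D: (n_taxa, n_taxa)
    cophenetic distances.  For samples k, m:

        0.5 * [ sum_i F[i,k] * min_{j in m} D[i,j]
              + sum_j F[j,m] * min_{i in k} D[i,j] ]

    The min includes i == j, so shared taxa contribute zero.
    """
    n_taxa, n_samples = F.shape
    M = np.empty((n_taxa, n_samples))
    for s in range(n_samples):
        M[:, s] = D[:, P[:, s]].min(axis=1)
    G = F.T @ M
    return 0.5 * (G + G.T)


def _weights(table: CountTable, taxa: list[str], weighted: bool):
    counts = table.data[taxa].to_numpy(dtype=float).T  # taxa x samples
    if (counts.sum(axis=0) == 0).any():
        raise InvalidArgumentError("empty community (zero row sum)")
    P = counts > 0
    if weighted:
        F = counts / counts.sum(axis=0, keepdims=True)
    else:
        F = P / P.sum(axis=0, keepdims=True)
    return F, P


def beta_mntd(
    table: CountTable, d: pd.DataFrame, weighted: bool = True
) -> PairMatrix:
    """Observed betaMNTD matrix over all sample pairs.

    ``d`` is a cophenetic distance frame whose index must cover the table's
    taxa.  ``weighted`` uses relative abundances as weights, otherwise each
    present taxon weighs 1/richness.
    """
    taxa = table.taxon_ids
    missing = set(taxa) - set(d.index)
    if missing:
        raise LabelMismatchError(f"taxa absent from the tree: {sorted(missing)[:5]}")
    D = d.loc[taxa, taxa].to_numpy(dtype=float)
    F, P = _weights(table, taxa, weighted)
    return PairMatrix(table.sample_ids, _bmntd_core(F, P, D), "bmntd")


@dataclass
class BNTIResult:
    """betaNTI z-scores together with the pieces they were built from."""

    bnti: PairMatrix
    obs_bmntd: PairMatrix
    null_mean: PairMatrix
    null_sd: PairMatrix
    n_null: int
    seed: int


def beta_nti(
    table: CountTable,
    tree: dendropy.Tree,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
    d: pd.DataFrame | None = None,
) -> BNTIResult:
    """betaNTI via tip-label shuffling.

    The null distribution keeps the communities fixed and randomises the
    phylogenetic relationships by shuffling taxon labels across the tree
    tips (an unconstrained permutation of the cophenetic matrix);
    betaNTI = (observed - null mean) / null sd per sample pair.  Pairs with
    zero null sd are set to NaN with a warning.
    """
    if n_null < 99:
        raise InvalidArgumentError("n_null must be >= 99")
    if d is None:
        d = cophenetic(tree)
    taxa = table.taxon_ids
    missing = set(taxa) - set(d.index)
    if missing:
        raise LabelMismatchError(f"taxa absent from the tree: {sorted(missing)[:5]}")
    # the shuffle domain is the WHOLE phylogeny: taxa are relocated across all
    # tree tips, not only across the tips observed in this table
    D_full = d.to_numpy(dtype=float)
    tip_index = {t: i for i, t in enumerate(d.index)}
    idx = np.array([tip_index[t] for t in taxa])
    D = D_full[np.ix_(idx, idx)]
    F, P = _weights(table, taxa, weighted)
    obs = _bmntd_core(F, P, D)

    rng = np.random.default_rng(seed)
    n_tips = D_full.shape[0]
    total = np.zeros_like(obs)
    total_sq = np.zeros_like(obs)
    for _ in range(n_null):
        perm = rng.permutation(n_tips)
        pidx = perm[idx]
        null = _bmntd_core(F, P, D_full[np.ix_(pidx, pidx)])
        total += null
        total_sq += null**2
    mean = total / n_null
    var = np.maximum(total_sq / n_null - mean**2, 0.0) * n_null / (n_null - 1)
    sd = np.sqrt(var)

    labels = table.sample_ids
    n = len(labels)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    degenerate = off & (sd == 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum()) // 2} sample pair(s) have zero null sd; "
            "betaNTI set to NaN"
        )
    z[degenerate] = np.nan
    np.fill_diagonal(z, np.nan)
    return BNTIResult(
        bnti=PairMatrix(labels, z, "bnti"),
        obs_bmntd=PairMatrix(labels, obs, "bmntd"),
        null_mean=PairMatrix(labels, mean, "bmntd"),
        null_sd=PairMatrix(labels, 0.5 * (sd + sd.T), "similarity"),
        n_null=n_null,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_pairs(values: np.ndarray) -> dict:
    """HS/VS/Sto fractions of a vector of betaNTI values (NaNs excluded)."""
    finite = values[np.isfinite(values)]
    n = len(finite)
    if n == 0:
        return {"HS": np.nan, "VS": np.nan, "Sto": np.nan, "n_pairs": 0}
    return {
        "HS": float((finite < -2).sum()) / n,
        "VS": float((finite > 2).sum()) / n,
        "Sto": float((np.abs(finite) <= 2).sum()) / n,
        "n_pairs": n,
    }


def classify_fractions(bnti: PairMatrix, groups: pd.Series) -> dict:
    """Per-group assembly-process fractions over within-group sample pairs."""
    if bnti.kind != "bnti":
        raise InvalidArgumentError("expected a betaNTI PairMatrix")
    groups = pd.Series(groups).reindex(bnti.labels)
    if groups.isna().any():
        raise LabelMismatchError("group labels missing for some samples")
    out = {}
    frame = bnti.to_frame()
    for label, members in groups.groupby(groups):
        ids = list(members.index)
        if len(ids) < 2:
            warnings.warn(f"group {label!r} has <2 samples; excluded")
            continue
        sub = frame.loc[ids, ids].to_numpy()
        iu = np.triu_indices(len(ids), k=1)
        out[label] = classify_pairs(sub[iu])
    return out


def richness_group_analysis(
    bnti: PairMatrix, fungal_richness: pd.Series, n_groups: int
) -> dict:
    """Assembly fractions across contiguous fungal-richness rank groups.

    Samples are ranked by fungal richness (ties broken by label order) and
    split into ``n_groups`` contiguous, equal-size groups.  Each group's
    within-group betaNTI pairs give its HS/VS/Sto fractions; each process
    fraction is then fitted against group mean richness with a degree-2
    polynomial, and ``trend_sign`` is the sign of the fitted first
    derivative averaged over the observed richness range.
    """
    if n_groups < 3:
        raise InvalidArgumentError("n_groups must be >= 3")
    richness_aligned = pd.Series(fungal_richness).reindex(bnti.labels)
    if richness_aligned.isna().any():
        raise LabelMismatchError("fungal richness missing for some samples")
    if n_groups > bnti.n / 2:
        raise InvalidArgumentError("n_groups must be <= n_samples / 2")
    if richness_aligned.nunique() == 1:
        raise DegenerateInputError("fungal richness is constant; grouping degenerate")
    order = np.argsort(richness_aligned.to_numpy(), kind="stable")
    chunks = np.array_split(order, n_groups)
    frame = bnti.to_frame()
    rows = []
    for g, chunk in enumerate(chunks):
        ids = [bnti.labels[i] for i in chunk]
        sub = frame.loc[ids, ids].to_numpy()
        iu = np.triu_indices(len(ids), k=1)
        fractions = classify_pairs(sub[iu])
        rows.append(
            {
                "group": g,
                "mean_richness": float(richness_aligned.loc[ids].mean()),
                **fractions,
            }
        )
    table = pd.DataFrame(rows).set_index("group")
    polyfit, trend_sign = {}, {}
    x = table["mean_richness"].to_numpy()
    for process in ("HS", "VS", "Sto"):
        y = table[process].to_numpy()
        ok = np.isfinite(y)
        coeffs = np.polyfit(x[ok], y[ok], 2)
        polyfit[process] = coeffs.tolist()
        derivative = 2 * coeffs[0] * x[ok] + coeffs[1]
        trend_sign[process] = int(np.sign(derivative.mean()))
    return {"groups": table, "polyfit": polyfit, "trend_sign": trend_sign}


def bnti_driver_mantel(
    bnti: PairMatrix,
    env: pd.DataFrame,
    variable: str,
    n_perm: int = 999,
    seed: int = 0,
):
    """Mantel test of betaNTI against the Euclidean distance of one driver."""
    from .drivers import mantel  # local import to avoid a cycle

    if variable not in env.columns:
        raise InvalidArgumentError(f"variable {variable!r} not in env")
    x = env[variable].reindex(bnti.labels).astype(float)
    if x.isna().any():
        raise LabelMismatchError(f"{variable} missing for some samples")
    if x.nunique() == 1:
        raise DegenerateInputError(f"{variable} has zero variance")
    dist = np.abs(x.to_numpy()[:, None] - x.to_numpy()[None, :])
    driver = PairMatrix(bnti.labels, dist, "euclidean_driver")
    return mantel(bnti, driver, n_perm=n_perm, seed=seed)
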