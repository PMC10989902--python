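"""Geographic distances and distance-decay relationships (DDRs)."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .community import PairMatrix
from .exceptions import InvalidArgumentError, LabelMismatchError

EARTH_RADIUS_KM = 6371.0


def haversine_matrix(env: pd.DataFrame) -> PairMatrix:
    """Great-circle distances (km) between all samples.

    ``env`` must carry ``latitude`` and ``longitude`` columns in degrees.
    """
    for col in ("latitude", "longitude"):
        if col not in env.columns:
            raise InvalidArgumentError(f"env lacks a {col!r} column")
    lat = env["latitude"].to_numpy(dtype=float)
    lon = env["longitude"].to_numpy(dtype=float)
    if (np.abs(lat) > 90).any() or (np.abs(lon) > 180).any():
        raise InvalidArgumentError("coordinates out of range")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = (
        np.sin(dphi / 2) ** 2
        + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    )
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return PairMatrix(list(env.index), d, "geographic_km")


def ddr_fit(
    similarity: PairMatrix,
    distance: PairMatrix,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
    log10_distance: bool = False,
) -> pd.DataFrame:
    """Per-group distance-decay regression of similarity on distance.

    Similarity is 1 - Bray-Curtis.  Within each group, ordinary least
    squares gives slope (per km, or per log10 km when ``log10_distance``),
    intercept and r2; the p-value is a two-sided Mantel permutation test,
    since pairwise observations are not independent.  Groups with fewer
    than 3 samples are excluded with a warning.
    """
    from .drivers import mantel
    from scipy import stats

    distance = distance.reorder(similarity.labels)
    groups = pd.Series(groups).reindex(similarity.labels)
    if groups.isna().any():
        raise LabelMismatchError("group labels missing for some samples")
    sim_frame = similarity.to_frame()
    dist_frame = distance.to_frame()
    rows = []
    for label, members in groups.groupby(groups):
        ids = list(members.index)
        if len(ids) < 3:
            warnings.warn(f"group {label!r} has <3 samples; excluded")
            continue
        iu = np.triu_indices(len(ids), k=1)
        sim = sim_frame.loc[ids, ids].to_numpy()[iu]
        dist = dist_frame.loc[ids, ids].to_numpy()[iu]
        if log10_distance:
            positive = dist > 0
            if not positive.all():
                warnings.warn(
                    f"group {label!r}: dropping {int((~positive).sum())} "
                    "zero-distance pair(s) under log10"
                )
            sim, dist = sim[positive], np.log10(dist[positive])
        if len(dist) < 3 or np.ptp(dist) == 0:
            warnings.warn(f"group {label!r}: degenerate distances; excluded")
            continue
        fit = stats.linregress(dist, sim)
        if np.ptp(sim) == 0:
            slope, intercept, r2 = 0.0, float(sim[0]), 0.0
            p = 1.0
        else:
            slope, intercept, r2 = fit.slope, fit.intercept, fit.rvalue**2
            sub_sim = PairMatrix(
                ids, sim_frame.loc[ids, ids].to_numpy(), "similarity"
            )
            sub_dist = PairMatrix(
                ids, dist_frame.loc[ids, ids].to_numpy(), "geographic_km"
            )
            p = mantel(
                sub_sim,
                sub_dist,
                n_perm=n_perm,
                seed=seed,
                alternative="two-sided",
            ).p
        rows.append(
            {
                "group": label,
                "slope": float(slope),
                "intercept": float(intercept),
                "r2": float(r2),
                "p": float(p),
                "n_pairs": int(len(ids) * (len(ids) - 1) / 2),
            }
        )
    return pd.DataFrame(rows).set_index("group")
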