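"""Count-table containers, rarefaction, alpha-diversity and dissimilarity.

The two central containers are :class:`CountTable` (an integer sample x taxon
abundance matrix with a kingdom label per taxon) and :class:`PairMatrix` (a
labelled symmetric matrix over samples, used for Bray-Curtis dissimilarity,
geographic distance, betaNTI and Euclidean driver distances alike).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .exceptions import EmptyResultError, InvalidArgumentError, LabelMismatchError

KINGDOMS = ("bacteria", "fungi")

#: recognised PairMatrix kinds; "bmntd" and "similarity" are internal additions
#: used by the assembly and spatial stages.
PAIR_KINDS = (
    "bray_curtis",
    "geographic_km",
    "bnti",
    "euclidean_driver",
    "bmntd",
    "similarity",
)

#: kinds whose diagonal must be exactly zero (dissimilarities / distances)
_ZERO_DIAG_KINDS = ("bray_curtis", "geographic_km", "euclidean_driver", "bmntd")


@dataclass
class CountTable:
    """Sample x taxon matrix of non-negative integer counts.

    Parameters
    ----------
    data:
        DataFrame with sample IDs as index and taxon IDs as columns.
    kingdom:
        Series mapping each taxon ID to ``"bacteria"`` or ``"fungi"``.
        A single string is broadcast to every taxon.
    """

    data: pd.DataFrame
    kingdom: pd.Series | str = "bacteria"

    def __post_init__(self):
        if not self.data.index.is_unique or not self.data.columns.is_unique:
            raise InvalidArgumentError("sample and taxon IDs must be unique")
        values = self.data.to_numpy()
        if values.size and (values < 0).any():
            raise InvalidArgumentError("counts must be non-negative")
        if values.size and not np.allclose(values, np.round(values)):
            raise InvalidArgumentError("counts must be integral")
        self.data = self.data.astype(np.int64)
        # drop taxa never observed so that occupancy-based logic stays sound
        zero = self.data.columns[(self.data == 0).all(axis=0)]
        if len(zero):
            warnings.warn(f"dropping {len(zero)} all-zero taxon columns")
            self.data = self.data.drop(columns=zero)
        if isinstance(self.kingdom, str):
            if self.kingdom not in KINGDOMS:
                raise InvalidArgumentError(f"unknown kingdom {self.kingdom!r}")
            self.kingdom = pd.Series(self.kingdom, index=self.data.columns)
        else:
            self.kingdom = pd.Series(self.kingdom).reindex(self.data.columns)
            if self.kingdom.isna().any():
                raise LabelMismatchError("kingdom labels missing for some taxa")
            bad = set(self.kingdom.unique()) - set(KINGDOMS)
            if bad:
                raise InvalidArgumentError(f"unknown kingdoms {sorted(bad)}")

    # -- basic accessors ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def relative(self) -> pd.DataFrame:
        """Row-normalised relative abundances."""
        totals = self.data.sum(axis=1)
        if (totals == 0).any():
            raise InvalidArgumentError("sample(s) with zero total count")
        return self.data.div(totals, axis=0)

    def merge(self, other: "CountTable") -> "CountTable":
        """Column-wise merge of two tables over the same sample set."""
        if set(self.sample_ids) != set(other.sample_ids):
            raise LabelMismatchError("sample sets differ between tables")
        if set(self.taxon_ids) & set(other.taxon_ids):
            raise InvalidArgumentError("taxon IDs overlap between tables")
        right = other.data.reindex(self.data.index)
        data = pd.concat([self.data, right], axis=1)
        kingdom = pd.concat([self.kingdom, other.kingdom])
        return CountTable(data, kingdom)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path, kingdom: pd.Series | str = "bacteria") -> "CountTable":
        """Read a counts TSV (first column = sample ID, header = taxon IDs)."""
        data = pd.read_csv(path, sep="\t", index_col=0)
        return cls(data, kingdom)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample")


@dataclass
class PairMatrix:
    """Labelled symmetric matrix over samples."""

    labels: list[str]
    values: np.ndarray
    kind: str = "bray_curtis"

    def __post_init__(self):
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise InvalidArgumentError("labels must be unique")
        if self.values.shape != (n, n):
            raise InvalidArgumentError("matrix shape does not match labels")
        if self.kind not in PAIR_KINDS:
            raise InvalidArgumentError(f"unknown PairMatrix kind {self.kind!r}")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise InvalidArgumentError("matrix must be symmetric")
        if self.kind in _ZERO_DIAG_KINDS and not np.allclose(
            np.diag(self.values), 0.0
        ):
            raise InvalidArgumentError(f"{self.kind} matrix must have zero diagonal")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper off-diagonal triangle, row-major."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reorder(self, labels) -> "PairMatrix":
        """Return a copy with rows/columns in the given label order."""
        labels = list(labels)
        if set(labels) != set(self.labels):
            raise LabelMismatchError("label sets differ")
        idx = [self.labels.index(l) for l in labels]
        return PairMatrix(labels, self.values[np.ix_(idx, idx)], self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path, kind: str) -> "PairMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(), kind)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped with a warning.  The
    draw is a single multivariate hypergeometric sample per row, so the
    result is deterministic given ``seed``.
    """
    if depth < 1:
        raise InvalidArgumentError("depth must be >= 1")
    totals = table.data.sum(axis=1)
    keep = totals[totals >= depth].index
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below depth {depth}: {dropped}"
        )
    if not len(keep):
        raise EmptyResultError("all samples fall below the rarefaction depth")
    rng = np.random.default_rng(seed)
    rows = []
    for s in keep:
        counts = table.data.loc[s].to_numpy()
        if counts.sum() == depth:
            rows.append(counts)
        else:
            rows.append(rng.multivariate_hypergeometric(counts, depth))
    data = pd.DataFrame(np.array(rows), index=list(keep), columns=table.taxon_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-zero columns expected here
        return CountTable(data, table.kingdom)


def shannon(table: CountTable) -> pd.Series:
    """Shannon diversity H = -sum p ln p per sample, in nats."""
    p = table.relative().to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return pd.Series(-terms.sum(axis=1), index=table.sample_ids, name="shannon")


def richness(table: CountTable) -> pd.Series:
    """Number of taxa with count > 0 per sample."""
    return pd.Series(
        (table.data > 0).sum(axis=1).to_numpy(),
        index=table.sample_ids,
        name="richness",
    )


def bray_curtis(table: CountTable) -> PairMatrix:
    """Pairwise Bray-Curtis dissimilarity BC = sum|a-b| / sum(a+b)."""
    if table.n_samples < 2:
        raise InvalidArgumentError("need at least 2 samples")
    counts = table.data.to_numpy(dtype=float)
    if (counts.sum(axis=1) == 0).any():
        raise InvalidArgumentError("sample(s) with zero total count")
    mat = squareform(pdist(counts, metric="braycurtis"))
    return PairMatrix(table.sample_ids, mat, "bray_curtis")


def prevalence_filter(table: CountTable, min_fraction: float = 0.10) -> CountTable:
    """Keep taxa present in strictly more than ``min_fraction`` of samples."""
    if not 0 <= min_fraction < 1:
        raise InvalidArgumentError("min_fraction must be in [0, 1)")
    occupancy = (table.data > 0).sum(axis=0)
    keep = occupancy[occupancy > min_fraction * table.n_samples].index
    if not len(keep):
        warnings.warn("prevalence filter removed every taxon")
    data = table.data[list(keep)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return CountTable(data, table.kingdom.reindex(keep))
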