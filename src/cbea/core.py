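"""Scaled log-ratio balance statistics on closed compositions.

The enrichment statistic for a taxon set is a compositional balance: the
log-ratio of the geometric mean of relative abundances inside the set to the
geometric mean of the complement, scaled so that balances are comparable
across set sizes.  For a composition of ``p`` parts and a set of size ``K``
the statistic is

    sqrt(K * (p - K) / p) * ln( g(x_in) / g(x_out) )

which is the two-group isometric log-ratio balance with the second group
fixed to the complement of the set.  Scores are invariant to rescaling of a
sample's raw counts, so count tables and relative-abundance tables score
identically after closure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CompositionTable",
    "SetCollection",
    "ScoreMatrix",
    "replace_zeros",
    "closure",
    "geometric_mean",
    "balance",
    "cbea_statistic",
    "score_matrix",
]


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


class AlignmentError(ValueError):
    """Raised when identifiers of two containers do not line up."""


def _check_unique(ids, what: str) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))
        raise InvalidInputError(f"duplicate {what}: {dup!r} appears more than once")
    return ids


@dataclass(frozen=True)
class CompositionTable:
    """A samples x taxa abundance matrix with row/column identifiers.

    Values may be raw counts or proportions; downstream scoring closes each
    row to the unit simplex, so the scale of a row is irrelevant.
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    taxon_ids: tuple[str, ...]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise InvalidInputError("values must be a 2-D samples x taxa matrix")
        n, p = values.shape
        if n < 1 or p < 2:
            raise InvalidInputError(f"need n >= 1 samples and p >= 2 taxa, got {n} x {p}")
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("non-finite abundance values")
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise InvalidInputError(
                f"negative abundance at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", _check_unique(self.sample_ids, "sample ids"))
        object.__setattr__(self, "taxon_ids", _check_unique(self.taxon_ids, "taxon ids"))
        if len(self.sample_ids) != n or len(self.taxon_ids) != p:
            raise InvalidInputError("identifier lengths do not match matrix shape")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=list(self.sample_ids),
                            columns=list(self.taxon_ids))


@dataclass(frozen=True)
class SetCollection:
    """Binary taxa x sets membership aligned with a CompositionTable.

    Every set must be a nonempty proper subset of the taxon universe: the
    balance against the complement is undefined for empty or all-taxa sets.
    """

    membership: np.ndarray
    set_names: tuple[str, ...]
    taxon_ids: tuple[str, ...]

    def __post_init__(self):
        memb = np.asarray(self.membership)
        if memb.ndim != 2:
            raise InvalidInputError("membership must be a 2-D taxa x sets matrix")
        if not np.isin(memb, (0, 1)).all():
            raise InvalidInputError("membership entries must be 0 or 1")
        memb = memb.astype(np.int8)
        p, m = memb.shape
        sizes = memb.sum(axis=0)
        bad = np.flatnonzero((sizes < 1) | (sizes > p - 1))
        if bad.size:
            name = self.set_names[bad[0]]
            raise InvalidInputError(
                f"set {name!r} has size {sizes[bad[0]]}; sets must be nonempty "
                f"proper subsets (1 <= K <= p-1 = {p - 1})"
            )
        object.__setattr__(self, "membership", memb)
        object.__setattr__(self, "set_names", _check_unique(self.set_names, "set names"))
        object.__setattr__(self, "taxon_ids", tuple(str(t) for t in self.taxon_ids))
        if len(self.set_names) != m or len(self.taxon_ids) != p:
            raise InvalidInputError("identifier lengths do not match membership shape")

    @property
    def n_sets(self) -> int:
        return self.membership.shape[1]

    @property
    def set_sizes(self) -> np.ndarray:
        return self.membership.sum(axis=0)

    def indices(self, set_name: str) -> np.ndarray:
        k = self.set_names.index(set_name)
        return np.flatnonzero(self.membership[:, k])

    @classmethod
    def from_dict(cls, sets: dict[str, list[str]], taxon_ids) -> "SetCollection":
        """Build membership from a name -> taxon-id-list mapping."""
        taxon_ids = tuple(str(t) for t in taxon_ids)
        pos = {t: i for i, t in enumerate(taxon_ids)}
        memb = np.zeros((len(taxon_ids), len(sets)), dtype=np.int8)
        for k, (_, members) in enumerate(sets.items()):
            for t in members:
                memb[pos[t], k] = 1
        return cls(memb, tuple(sets.keys()), taxon_ids)


@dataclass(frozen=True)
class ScoreMatrix:
    """Samples x sets matrix of raw balance scores."""

    values: np.ndarray
    sample_ids: tuple[str, ...]
    set_names: tuple[str, ...]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("scores must be finite")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "set_names", tuple(self.set_names))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=list(self.sample_ids),
                            columns=list(self.set_names))


def replace_zeros(table: CompositionTable, pseudocount: float = 1e-5) -> CompositionTable:
    """Add ``pseudocount`` to every entry if the table contains any zero.

    The log-ratio statistic is undefined on zeros.  When at least one zero is
    present the pseudocount is added uniformly to all entries (so already
    positive entries shift too, keeping within-row perturbation uniform); a
    zero-free table is returned unchanged.  Model-based zero replacement is a
    legitimate alternative the caller may apply beforehand.
    """
    if pseudocount <= 0:
        raise InvalidInputError(f"pseudocount must be positive, got {pseudocount}")
    if np.any(table.values < 0):
        raise InvalidInputError("negative entries are not valid abundances")
    n_zero = int(np.count_nonzero(table.values == 0))
    if n_zero == 0:
        return table
    logger.warning(
        "zero replacement triggered: %d zero cells; adding pseudocount %g to all entries",
        n_zero, pseudocount,
    )
    return CompositionTable(table.values + pseudocount, table.sample_ids, table.taxon_ids)


def closure(table: CompositionTable) -> CompositionTable:
    """Divide each row by its sum, projecting samples onto the unit simplex."""
    sums = table.values.sum(axis=1, keepdims=True)
    zero_rows = np.flatnonzero(sums.ravel() == 0)
    if zero_rows.size:
        raise InvalidInputError(
            f"sample {table.sample_ids[zero_rows[0]]!r} sums to zero; cannot close"
        )
    return CompositionTable(table.values / sums, table.sample_ids, table.taxon_ids)


def geometric_mean(values) -> float:
    """exp(mean(log(values))), evaluated in log space to avoid underflow."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InvalidInputError("geometric mean of an empty vector is undefined")
    if np.any(values <= 0):
        raise InvalidInputError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(values))))


def balance(row, group_R, group_S) -> float:
    """Two-group ILR balance sqrt(r*s/(r+s)) * log(g(row[R]) / g(row[S])).

    ``group_R`` and ``group_S`` are disjoint, nonempty index sets; ``r`` and
    ``s`` are their cardinalities.  Antisymmetric under swapping the groups.
    """
    row = np.asarray(row, dtype=float)
    R = np.asarray(sorted(set(int(i) for i in group_R)), dtype=int)
    S = np.asarray(sorted(set(int(i) for i in group_S)), dtype=int)
    if R.size == 0 or S.size == 0:
        raise InvalidInputError("balance groups must be nonempty")
    if np.intersect1d(R, S).size:
        raise InvalidInputError("balance groups must be disjoint")
    if np.any(row <= 0):
        raise InvalidInputError("balance requires strictly positive parts")
    r, s = R.size, S.size
    coef = np.sqrt(r * s / (r + s))
    logs = np.log(row)
    return float(coef * (logs[R].mean() - logs[S].mean()))


def cbea_statistic(row, set_indices) -> float:
    """Balance of a taxon set against its complement within one sample.

    Equals ``balance(row, set, complement)`` with coefficient
    sqrt(K*(p-K)/p); positive scores mean the set's geometric mean exceeds
    the complement's.
    """
    row = np.asarray(row, dtype=float)
    p = row.size
    idx = np.asarray(sorted(set(int(i) for i in set_indices)), dtype=int)
    K = idx.size
    if K < 1 or K > p - 1:
        raise InvalidInputError(
            f"set size must satisfy 1 <= K <= p-1 (K={K}, p={p}); the balance "
            "against the complement is undefined otherwise"
        )
    comp = np.setdiff1d(np.arange(p), idx)
    return balance(row, idx, comp)


def score_matrix(table: CompositionTable, sets: SetCollection) -> ScoreMatrix:
    """Raw balance scores for every sample x set pair.

    Vectorized over the whole table: with ``L = log(X)`` the score of set k is
    ``sqrt(K(p-K)/p) * (mean of L over the set - mean over the complement)``,
    the difference-of-mean-logs form of the statistic.
    """
    if table.taxon_ids != sets.taxon_ids:
        raise AlignmentError(
            "taxon identifiers of the table and the set collection differ "
            "(order matters); align them before scoring"
        )
    if np.any(table.values <= 0):
        raise InvalidInputError(
            "table must be strictly positive; apply replace_zeros first"
        )
    L = np.log(table.values)
    A = sets.membership.astype(float)
    p = table.n_taxa
    K = A.sum(axis=0)
    in_sum = L @ A                      # n x m
    out_sum = L.sum(axis=1, keepdims=True) - in_sum
    coef = np.sqrt(K * (p - K) / p)
    scores = coef * (in_sum / K - out_sum / (p - K))
    return ScoreMatrix(scores, table.sample_ids, sets.set_names)
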