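"""Calibration experiments: type-I error, power, and score-ranking AUROC.

Two inference levels are exercised.  At the *sample* level each sample is a
hypothesis: a random taxon set should not be significantly enriched in any
sample, so the fraction of samples rejected at alpha estimates type I error.
At the *population* level each set is a hypothesis: with randomly assigned
case/control labels, a Welch's t-test on per-sample scores should reject a
fraction alpha of sets.

Scoring methods are callables ``method(table, sets, seed) -> p-value matrix``
so that enrichment variants and baselines run through one harness; the
harness never looks at ground-truth labels while scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .core import CompositionTable, InvalidInputError, SetCollection
from .null_model import cbea
from .simulate import SimulatedDataset

__all__ = [
    "CalibrationReport",
    "cbea_method",
    "wilcoxon_method",
    "wilcoxon_baseline",
    "type1_sample_level",
    "type1_population",
    "power_and_auroc",
]


@dataclass(frozen=True)
class CalibrationReport:
    """Per-condition rejection-rate estimates with Monte-Carlo uncertainty."""

    method: str
    estimates: pd.DataFrame   # columns: condition, estimate, se, reps
    alpha: float
    n_reps: int
    interval: str = "wald"    # "wald" | "agresti-coull"

    @property
    def overall(self) -> float:
        return float(self.estimates["estimate"].mean())

    def __repr__(self):  # pragma: no cover - cosmetic
        return (f"CalibrationReport(method={self.method!r}, alpha={self.alpha}, "
                f"n_reps={self.n_reps}, overall={self.overall:.4f})")


def _proportion_ci(p_hat: float, n: int, interval: str):
    if interval == "agresti-coull":
        z = stats.norm.ppf(0.975)
        nt = n + z ** 2
        pt = (p_hat * n + z ** 2 / 2) / nt
        half = z * np.sqrt(pt * (1 - pt) / nt)
        return pt - half, pt + half
    se = np.sqrt(p_hat * (1 - p_hat) / n)
    return p_hat - 1.96 * se, p_hat + 1.96 * se


def cbea_method(family: str = "mixture2", adjust: bool = False,
                n_perm: int = 100, pseudocount: float = 1e-5):
    """Factory: enrichment p-values from the balance statistic's empirical null."""
    def method(table: CompositionTable, sets: SetCollection, seed) -> np.ndarray:
        res = cbea(table, sets, family=family, adjust=adjust,
                   output_type="pval", n_perm=n_perm,
                   pseudocount=pseudocount, seed=seed)
        return res.values

    method.descriptor = f"cbea[{family}{',adjusted' if adjust else ''}]"
    return method


def wilcoxon_baseline(row, set_indices) -> float:
    """Two-sided rank-sum p-value, in-set vs out-of-set abundances of one sample.

    All-tied inputs carry no rank information; p = 1 by convention.
    """
    row = np.asarray(row, dtype=float)
    idx = np.asarray(sorted(set(int(i) for i in set_indices)), dtype=int)
    p = row.size
    if idx.size < 1 or idx.size >= p:
        raise InvalidInputError("set must be a nonempty proper subset")
    comp = np.setdiff1d(np.arange(p), idx)
    x, y = row[idx], row[comp]
    if np.all(row == row[0]):
        return 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.pvalue)


def wilcoxon_method():
    """Factory: per-sample rank-sum baseline over every set."""
    def method(table: CompositionTable, sets: SetCollection, seed) -> np.ndarray:
        out = np.empty((table.n_samples, sets.n_sets))
        for k, name in enumerate(sets.set_names):
            idx = sets.indices(name)
            for i in range(table.n_samples):
                out[i, k] = wilcoxon_baseline(table.values[i], idx)
        return out

    method.descriptor = "wilcoxon"
    return method


def _random_set(rng, taxon_ids, size, name="random_set") -> SetCollection:
    p = len(taxon_ids)
    idx = rng.choice(p, size=size, replace=False)
    memb = np.zeros((p, 1), dtype=np.int8)
    memb[idx, 0] = 1
    return SetCollection(memb, (name,), tuple(taxon_ids))


def type1_sample_level(table: CompositionTable, set_sizes, n_reps: int = 100,
                       alpha: float = 0.05, method=None, seed=None,
                       interval: str = "wald") -> CalibrationReport:
    """Sample-level type I error via random taxon sets.

    Per replicate one uniformly random set of each requested size is scored
    and the fraction of samples with p < alpha recorded; the per-size
    estimate is the mean over replicates with its Monte-Carlo SE.
    """
    if method is None:
        method = cbea_method()
    set_sizes = [int(s) for s in np.atleast_1d(set_sizes)]
    if any(s < 1 or s > table.n_taxa - 1 for s in set_sizes):
        raise InvalidInputError("set sizes must satisfy 1 <= S <= p - 1")
    rng = np.random.default_rng(seed)
    rows = []
    for size in set_sizes:
        fracs = np.empty(n_reps)
        for r in range(n_reps):
            sets = _random_set(rng, table.taxon_ids, size)
            pvals = method(table, sets, int(rng.integers(2 ** 31)))
            fracs[r] = float(np.mean(pvals[:, 0] < alpha))
        est = float(fracs.mean())
        se = float(fracs.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else np.nan
        lo, hi = _proportion_ci(est, n_reps * table.n_samples, interval)
        rows.append({"condition": f"S={size}", "estimate": est, "se": se,
                     "ci_low": lo, "ci_high": hi, "reps": n_reps})
    return CalibrationReport(getattr(method, "descriptor", "custom"),
                             pd.DataFrame(rows), alpha, n_reps, interval)


def _welch_reject(scores: np.ndarray, labels: np.ndarray, alpha: float):
    """Welch's t per set across two groups; returns (n_reject, n_tested)."""
    a, b = scores[labels == 1], scores[labels == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=0, equal_var=False)
    pv = np.asarray(res.pvalue)
    tested = np.isfinite(pv)   # constant columns yield nan: excluded
    return int(np.sum(pv[tested] < alpha)), int(tested.sum())


def type1_population(scores: np.ndarray, n_label_perms: int = 100,
                     alpha: float = 0.05, seed=None, method: str = "scores",
                     interval: str = "wald") -> CalibrationReport:
    """Population-level type I error via random case/control labels.

    ``scores`` is any samples x sets score matrix (raw balances by default in
    the CLI).  Per replicate, labels are drawn uniformly (redrawn if one
    class is empty), Welch's t-test is applied per set, and the fraction of
    (testable) sets with p < alpha recorded.
    """
    scores = np.asarray(scores, dtype=float)
    n, m = scores.shape
    if n < 4:
        raise InvalidInputError("need at least 4 samples for label permutation")
    rng = np.random.default_rng(seed)
    fracs = np.empty(n_label_perms)
    n_excluded = 0
    for r in range(n_label_perms):
        labels = rng.integers(0, 2, size=n)
        while labels.min() == labels.max():
            labels = rng.integers(0, 2, size=n)
        n_rej, n_tested = _welch_reject(scores, labels, alpha)
        n_excluded += m - n_tested
        fracs[r] = n_rej / n_tested if n_tested else 0.0
    est = float(fracs.mean())
    se = float(fracs.std(ddof=1) / np.sqrt(n_label_perms)) if n_label_perms > 1 else np.nan
    lo, hi = _proportion_ci(est, n_label_perms * m, interval)
    df = pd.DataFrame([{"condition": "random_labels", "estimate": est, "se": se,
                        "ci_low": lo, "ci_high": hi, "reps": n_label_perms,
                        "excluded_tests": n_excluded}])
    return CalibrationReport(method, df, alpha, n_label_perms, interval)


def power_and_auroc(dataset: SimulatedDataset, method=None, alpha: float = 0.05,
                    seed=None, n_boot: int = 200):
    """Power on truly enriched sets plus score-ranking AUROC.

    Power is the rejection fraction restricted to truly enriched (set,
    sample) pairs — case samples only in two-group designs.  AUROC measures
    whether raw scores of an enriched set rank case samples above controls;
    a bootstrap percentile interval quantifies its uncertainty.
    """
    if method is None:
        method = cbea_method()
    enriched = dataset.enriched_sets()
    if not enriched:
        raise InvalidInputError("dataset has no truly enriched sets; AUROC undefined")
    rng = np.random.default_rng(seed)
    pvals = method(dataset.counts, dataset.sets, int(rng.integers(2 ** 31)))

    case_mask = (np.ones(dataset.counts.n_samples, dtype=bool)
                 if dataset.group_labels is None else dataset.group_labels == 1)
    cols = [dataset.sets.set_names.index(s) for s in enriched]
    rej = pvals[np.ix_(case_mask, cols)] < alpha
    power = float(rej.mean())
    n_pairs = int(rej.size)
    se = float(np.sqrt(power * (1 - power) / n_pairs))

    # rank quality of the continuous scores: truth = case/control per sample
    from .null_model import cbea as _cbea
    raw = _cbea(dataset.counts, dataset.sets, output_type="raw").values
    labels = (case_mask.astype(int) if dataset.group_labels is not None
              else np.ones(dataset.counts.n_samples, dtype=int))
    if labels.min() == labels.max():
        raise InvalidInputError("AUROC needs both classes present")
    scores = raw[:, cols].mean(axis=1)
    auroc = float(roc_auc_score(labels, scores))
    boot = np.empty(n_boot)
    idx_all = np.arange(labels.size)
    for b in range(n_boot):
        bi = rng.choice(idx_all, size=labels.size, replace=True)
        if labels[bi].min() == labels[bi].max():
            boot[b] = np.nan
            continue
        boot[b] = roc_auc_score(labels[bi], scores[bi])
    ci = tuple(np.nanpercentile(boot, [2.5, 97.5]))

    df = pd.DataFrame([{"condition": "enriched", "estimate": power, "se": se,
                        "reps": n_pairs}])
    report = CalibrationReport(getattr(method, "descriptor", "custom"), df,
                               alpha, n_pairs)
    return report, {"auroc": auroc, "ci_low": float(ci[0]),
                    "ci_high": float(ci[1]), "n_boot": n_boot}
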