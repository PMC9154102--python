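"""Synthetic taxonomic count tables with controlled enrichment structure.

The generator emulates the statistical features that stress set-enrichment
methods on microbiome data:

* **Overdispersed counts** — each taxon is negative-binomial with mean ``mu``
  and dispersion ``k`` (variance ``mu + mu^2/k``).
* **Sparsity** — independent Bernoulli zero-masking adds structural zeros on
  top of the NB sampling zeros.
* **Inter-taxa correlation** — a Gaussian copula imposes exchangeable
  correlation ``rho`` among the taxa of designated sets (and independence
  everywhere else).  ``rho`` lives on the latent normal scale; the
  correlation of the resulting counts is attenuated, so analyses should treat
  it as an ordinal knob.
* **Enrichment** — designated taxa get their NB mean multiplied by
  ``fold_change`` (dispersion unchanged), either in all samples or only in
  case samples for two-group designs.

``fold_change = 1`` with ``rho = 0`` is the global null.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .core import CompositionTable, SetCollection

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate", "simulate_two_groups"]


class ConfigError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated dataset.

    ``set_size * n_sets`` taxa are organised into disjoint annotated sets;
    any remaining taxa belong to no set.  ``rho`` applies within the blocks
    named by ``enriched_set_ids`` only, and ``fold_change`` multiplies the NB
    mean of exactly those blocks' taxa.  Designating a set with
    ``fold_change = 1`` therefore yields a correlated-but-null set.
    """

    n_samples: int = 500
    n_taxa: int = 400
    set_size: int = 50
    n_sets: int = 1
    nb_mean: float = 100.0
    nb_dispersion: float = 1.0
    zero_prob: float = 0.0
    rho: float = 0.0
    fold_change: float = 1.0
    enriched_set_ids: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1 or self.n_taxa < 2:
            raise ConfigError("need n_samples >= 1 and n_taxa >= 2")
        if self.set_size < 1 or self.n_sets < 1:
            raise ConfigError("need set_size >= 1 and n_sets >= 1")
        if self.set_size * self.n_sets > self.n_taxa:
            raise ConfigError(
                f"{self.n_sets} disjoint sets of size {self.set_size} do not "
                f"fit into {self.n_taxa} taxa"
            )
        if self.set_size >= self.n_taxa:
            raise ConfigError("a set must be a proper subset of the taxa")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ConfigError("nb_mean and nb_dispersion must be positive")
        if not 0.0 <= self.zero_prob < 1.0:
            raise ConfigError("zero_prob must lie in [0, 1)")
        if not 0.0 <= self.rho < 1.0:
            raise ConfigError("rho must lie in [0, 1)")
        if self.fold_change < 1.0:
            raise ConfigError("fold_change must be >= 1")
        object.__setattr__(self, "enriched_set_ids",
                           tuple(self.enriched_set_ids))
        known = {f"set_{k + 1}" for k in range(self.n_sets)}
        unknown = set(self.enriched_set_ids) - known
        if unknown:
            raise ConfigError(f"unknown enriched set ids: {sorted(unknown)}")

    @property
    def set_names(self) -> tuple[str, ...]:
        return tuple(f"set_{k + 1}" for k in range(self.n_sets))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["enriched_set_ids"] = list(self.enriched_set_ids)
        return d


@dataclass(frozen=True)
class SimulatedDataset:
    """Counts plus the annotations and ground truth used to generate them."""

    counts: CompositionTable
    sets: SetCollection
    truth: dict[str, bool]          # set name -> truly enriched
    config: SimulationConfig
    group_labels: np.ndarray | None = None   # 1 = case, 0 = control

    def enriched_sets(self) -> tuple[str, ...]:
        return tuple(s for s, t in self.truth.items() if t)


def _set_blocks(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Disjoint consecutive index blocks, one per annotated set."""
    return {name: np.arange(k * config.set_size, (k + 1) * config.set_size)
            for k, name in enumerate(config.set_names)}


def _latent_normal(rng, n, p, blocks, designated, rho):
    """Standard-normal latents with exchangeable correlation in designated blocks.

    Exchangeable correlation rho is realised as sqrt(rho) * shared factor +
    sqrt(1-rho) * idiosyncratic noise, which keeps unit marginal variance.
    """
    z = rng.standard_normal((n, p))
    if rho > 0:
        for name in designated:
            idx = blocks[name]
            shared = rng.standard_normal((n, 1))
            z[:, idx] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * z[:, idx]
    return z


def _nb_quantile(u, mean, dispersion):
    """NB quantile function under the (mean, dispersion) parameterisation."""
    size = dispersion
    prob = size / (size + mean)
    # clip away u == 1, where the quantile is infinite
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    return stats.nbinom.ppf(u, size, prob)


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Draw one dataset; every designated set is enriched in all samples."""
    counts, sets, truth = _simulate_counts(
        config, case_mask=np.ones(config.n_samples, dtype=bool))
    return SimulatedDataset(counts, sets, truth, config)


def simulate_two_groups(config: SimulationConfig, n_cases: int,
                        n_controls: int) -> SimulatedDataset:
    """Case/control design: enrichment applies to case samples only."""
    if n_cases + n_controls != config.n_samples:
        raise ConfigError(
            f"n_cases + n_controls must equal n_samples "
            f"({n_cases} + {n_controls} != {config.n_samples})"
        )
    if n_cases < 1 or n_controls < 1:
        raise ConfigError("both groups must be nonempty")
    case_mask = np.zeros(config.n_samples, dtype=bool)
    case_mask[:n_cases] = True
    counts, sets, truth = _simulate_counts(config, case_mask=case_mask)
    return SimulatedDataset(counts, sets, truth, config,
                            group_labels=case_mask.astype(int))


def _simulate_counts(config: SimulationConfig, case_mask: np.ndarray):
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_taxa
    blocks = _set_blocks(config)
    designated = config.enriched_set_ids

    z = _latent_normal(rng, n, p, blocks, designated, config.rho)
    u = stats.norm.cdf(z)

    mean = np.full((n, p), config.nb_mean)
    if config.fold_change > 1.0:
        for name in designated:
            mean[np.ix_(case_mask, blocks[name])] *= config.fold_change
    counts = _nb_quantile(u, mean, config.nb_dispersion)

    if config.zero_prob > 0.0:
        counts[rng.random((n, p)) < config.zero_prob] = 0.0

    sample_ids = tuple(f"sample_{i + 1}" for i in range(n))
    taxon_ids = tuple(f"taxon_{j + 1}" for j in range(p))
    table = CompositionTable(counts, sample_ids, taxon_ids)

    memb = np.zeros((p, config.n_sets), dtype=np.int8)
    for k, name in enumerate(config.set_names):
        memb[blocks[name], k] = 1
    sets = SetCollection(memb, config.set_names, taxon_ids)

    truth = {name: (name in designated and config.fold_change > 1.0)
             for name in config.set_names}
    return table, sets, truth


# supplementary-style evaluation grid: sparsity x correlation x set size
DEFAULT_SPARSITY_GRID = (0.0, 0.2, 0.4, 0.6)
DEFAULT_RHO_GRID = (0.0, 0.2, 0.5)
DEFAULT_SET_SIZES = (20, 50, 100, 150, 200)
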