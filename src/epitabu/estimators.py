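"""Scikit-learn style estimators wrapping the detection pipeline.

:class:`EpistasisDetector` is fit-shaped: given a genotype matrix X
(values 0/1/2) and a case-control vector y, ``fit`` runs the full
pipeline — bit encoding, mutual-information ranking, seed network,
genetic-tabu structure search, pair extraction — and exposes the learned
network and ranked pairs as fitted attributes.  :class:`Chi2Prefilter`
is transform-shaped and drops SNP columns failing the per-locus
chi-square screen; both compose with sklearn pipelines.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted, column_or_1d

from .epistasis import EpistasisReport, chi2_pvalues, extract_pairs
from .io import GenotypeTable, encode_bits
from .search import GAConfig, run

__all__ = ["EpistasisDetector", "Chi2Prefilter"]


def _table_from_xy(X, y, feature_names=None) -> GenotypeTable:
    X = check_array(X, dtype=np.int64)
    y = column_or_1d(y)
    if feature_names is None:
        feature_names = [f"SNP{i}" for i in range(X.shape[1])]
    return GenotypeTable(
        snp_names=list(feature_names),
        genotypes=X,
        phenotype=np.asarray(y, dtype=np.int64),
    )


class EpistasisDetector(BaseEstimator):
    """Detect epistatic SNP pairs by Bayesian-network structure search.

    Parameters mirror the search configuration; defaults are the
    published settings (population 50, crossover 0.7, mutation 0.002,
    tabu length 30, 60 iterations, stagnation after 3 generations).

    Attributes (after ``fit``)
    --------------------------
    network_ : DagIndividual
        Best-scoring acyclic network over SNP nodes plus the Class node.
    best_score_ : float
        BIC of ``network_``.
    pairs_ : list of (str, str, float)
        Reported SNP pairs with their mutual information, descending.
    report_ : EpistasisReport
        Full report object (pairs + metadata).
    history_ : list of dict
        Per-generation best/mean fitness trace.
    """

    def __init__(
        self,
        population_size: int = 50,
        crossover_prob: float = 0.7,
        mutation_prob: float = 0.002,
        tabu_length: int = 30,
        max_iterations: int = 60,
        stagnation_k: int = 3,
        fitness_threshold: float | None = None,
        top_n: int = 5,
        extraction_rule: str = "markov-blanket",
        log_base: float | None = None,
        random_state: int | None = None,
    ):
        self.population_size = population_size
        self.crossover_prob = crossover_prob
        self.mutation_prob = mutation_prob
        self.tabu_length = tabu_length
        self.max_iterations = max_iterations
        self.stagnation_k = stagnation_k
        self.fitness_threshold = fitness_threshold
        self.top_n = top_n
        self.extraction_rule = extraction_rule
        self.log_base = log_base
        self.random_state = random_state

    def _config(self) -> GAConfig:
        return GAConfig(
            population_size=self.population_size,
            crossover_prob=self.crossover_prob,
            mutation_prob=self.mutation_prob,
            tabu_length=self.tabu_length,
            max_iterations=self.max_iterations,
            stagnation_k=self.stagnation_k,
            fitness_threshold=self.fitness_threshold,
            top_n=self.top_n,
            log_base=self.log_base,
            rng_seed=self.random_state,
        )

    def fit(self, X, y, feature_names: list[str] | None = None):
        """Learn the network from genotypes X (0/1/2) and phenotype y (0/1)."""
        table = _table_from_xy(X, y, feature_names)
        return self.fit_table(table)

    def fit_table(self, table: GenotypeTable):
        """Learn the network directly from a :class:`GenotypeTable`."""
        result = run(table, self._config())
        bits = encode_bits(table)
        report = extract_pairs(
            result.best,
            bits,
            rule=self.extraction_rule,
            base=self.log_base,
            metadata={
                "config": self._config().__dict__,
                "seed": self.random_state,
                "generations_run": result.generations_run,
                "stopped_by": result.stopped_by,
                "best_bic": result.best_score,
            },
        )
        self.network_ = result.best
        self.best_score_ = result.best_score
        self.history_ = result.history
        self.report_: EpistasisReport = report
        self.pairs_ = report.pairs
        self.n_features_in_ = table.n_snps
        self.feature_names_in_ = np.asarray(table.snp_names, dtype=object)
        return self

    def top_pair(self) -> tuple[str, str] | None:
        """Highest-MI reported pair, or None when the report is empty."""
        check_is_fitted(self, "pairs_")
        return tuple(self.pairs_[0][:2]) if self.pairs_ else None


class Chi2Prefilter(SelectorMixin, BaseEstimator):
    """Select SNP columns by the 3x2 genotype-by-class chi-square test.

    ``keep_significant=True`` keeps SNPs with p < ``p_threshold`` (the
    class-associated ones); constant columns are always dropped.
    """

    def __init__(self, p_threshold: float = 0.01, keep_significant: bool = True):
        self.p_threshold = p_threshold
        self.keep_significant = keep_significant

    def fit(self, X, y):
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")
        table = _table_from_xy(X, y)
        self.pvalues_ = chi2_pvalues(table)
        self.n_features_in_ = table.n_snps
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "pvalues_")
        testable = ~np.isnan(self.pvalues_)
        if self.keep_significant:
            return testable & (self.pvalues_ < self.p_threshold)
        return testable & (self.pvalues_ >= self.p_threshold)
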