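"""From a learned network to ranked epistatic pairs, accuracy and the chi2 prefilter."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import chi2_contingency

from .bayesnet import DagIndividual
from .infotheory import mutual_information
from .io import BitMatrix, GenotypeTable

__all__ = [
    "EpistasisReport",
    "EvaluationResult",
    "EXTRACTION_RULES",
    "extract_pairs",
    "detection_accuracy",
    "chi2_pvalues",
    "chi2_prefilter",
    "read_report",
]

EXTRACTION_RULES = ("markov-blanket", "adjacent", "parents", "snp-edge")


@dataclass
class EpistasisReport:
    """Ranked SNP pairs read off the best network.

    ``pairs`` holds ``(name1, name2, mi)`` tuples sorted by descending
    MI (ties by name); names within a pair are sorted.
    """

    pairs: list[tuple[str, str, float]]
    source: DagIndividual | None = None
    metadata: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("SNP1\tSNP2\tMI\n")
            for a, b, mi in self.pairs:
                fh.write(f"{a}\t{b}\t{mi:.9f}\n")


def read_report(path) -> EpistasisReport:
    """Read a TSV report written by :meth:`EpistasisReport.to_tsv`."""
    pairs: list[tuple[str, str, float]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("SNP1"):
            raise ValueError(f"{path}: not an epistasis report (bad header)")
        for line in fh:
            if not line.strip():
                continue
            a, b, mi = line.rstrip("\n").split("\t")
            pairs.append((a, b, float(mi)))
    return EpistasisReport(pairs=pairs)


@dataclass(frozen=True)
class EvaluationResult:
    """Detection accuracy over a batch: accuracy = num_edge / n_datasets."""

    n_datasets: int
    num_edge: int

    @property
    def accuracy(self) -> float:
        return self.num_edge / self.n_datasets


def _class_adjacent(ind: DagIndividual) -> list[int]:
    c = ind.class_index
    adj = ind.adjacency
    return [i for i in range(c) if adj[i, c] or adj[c, i]]


def _markov_blanket(ind: DagIndividual) -> list[int]:
    """Parents, children and co-parents of children of the Class node."""
    c = ind.class_index
    adj = ind.adjacency
    parents = set(np.flatnonzero(adj[:, c]))
    children = set(np.flatnonzero(adj[c, :]))
    coparents: set[int] = set()
    for child in children:
        coparents |= set(np.flatnonzero(adj[:, child]))
    return sorted((parents | children | coparents) - {c})


def extract_pairs(
    best: DagIndividual,
    bits: BitMatrix,
    rule: str = "markov-blanket",
    base: float | None = None,
    metadata: dict | None = None,
) -> EpistasisReport:
    """Report epistatic SNP pairs implied by the learned network.

    Rules:

    - ``markov-blanket`` (default): every unordered pair of SNPs inside
      the Markov blanket of the Class node (its parents, children and
      co-parents of its children).  This is the set of loci the network
      itself declares informative about the phenotype; it matters under
      case-control ascertainment, where the best-scoring representation
      of a purely epistatic pair places the collider at one of the SNPs
      (Class -> SNP1 <- SNP2), leaving the partner SNP informative but
      not directly adjacent to Class;
    - ``adjacent``: every unordered pair of SNPs that are both adjacent
      to the Class node, in either edge direction;
    - ``parents``: both SNPs must be parents of Class;
    - ``snp-edge``: pairs joined by a SNP-SNP edge with at least one
      Class-adjacent endpoint.

    Each pair is annotated with I(Class | SNP1, SNP2) recomputed from the
    bit matrix, and the list is sorted by descending MI, ties by name.
    """
    if rule not in EXTRACTION_RULES:
        raise ValueError(f"unknown extraction rule {rule!r}; use one of {EXTRACTION_RULES}")
    if best.n_nodes != bits.n_snps + 1:
        raise ValueError("network node count does not match the bit matrix")
    c = best.class_index
    adj = best.adjacency
    if rule == "markov-blanket":
        index_pairs = list(combinations(_markov_blanket(best), 2))
    elif rule == "adjacent":
        snps = _class_adjacent(best)
        index_pairs = list(combinations(snps, 2))
    elif rule == "parents":
        snps = [i for i in range(c) if adj[i, c]]
        index_pairs = list(combinations(snps, 2))
    else:  # snp-edge
        adjacent = set(_class_adjacent(best))
        index_pairs = [
            (i, j)
            for i in range(c)
            for j in range(i + 1, c)
            if (adj[i, j] or adj[j, i]) and (i in adjacent or j in adjacent)
        ]
    if not index_pairs:
        warnings.warn("no SNP pair qualifies under the extraction rule", stacklevel=2)
    pairs = []
    for i, j in index_pairs:
        mi = mutual_information(bits, (i, j), base=base).mi
        name_a, name_b = sorted((best.node_names[i], best.node_names[j]))
        pairs.append((name_a, name_b, mi))
    pairs.sort(key=lambda p: (-p[2], p[0], p[1]))
    return EpistasisReport(pairs=pairs, source=best, metadata=metadata or {})


def detection_accuracy(
    reports: list[EpistasisReport],
    truths: list,
    top_m: int | None = None,
) -> EvaluationResult:
    """Fraction of datasets whose full planted SNP set appears as one
    reported tuple within the top ``top_m`` entries (all entries when
    ``top_m`` is None)."""
    if len(reports) != len(truths):
        raise ValueError(
            f"{len(reports)} reports but {len(truths)} truth sets"
        )
    num_edge = 0
    for report, truth in zip(reports, truths):
        truth_set = frozenset(truth)
        entries = report.pairs if top_m is None else report.pairs[:top_m]
        if any(frozenset(p[:-1]) == truth_set for p in entries):
            num_edge += 1
    return EvaluationResult(n_datasets=len(reports), num_edge=num_edge)


def chi2_pvalues(table: GenotypeTable) -> np.ndarray:
    """Per-SNP p-value of the 3-genotype x 2-class chi-square test.

    No continuity correction; genotype values unobserved in a SNP are
    dropped from its contingency table (reducing the degrees of
    freedom).  A SNP constant across samples gets p = NaN.
    """
    pvals = np.full(table.n_snps, np.nan)
    y = table.phenotype
    for s in range(table.n_snps):
        g = table.genotypes[:, s]
        obs = np.zeros((3, 2), dtype=np.int64)
        for v in (0, 1, 2):
            for c in (0, 1):
                obs[v, c] = int(np.sum((g == v) & (y == c)))
        obs = obs[obs.sum(axis=1) > 0]
        if obs.shape[0] < 2 or np.any(obs.sum(axis=0) == 0):
            continue  # constant genotype or single-class data: untestable
        pvals[s] = chi2_contingency(obs, correction=False).pvalue
    return pvals


def chi2_prefilter(
    table: GenotypeTable,
    p_threshold: float = 0.01,
    keep_below: bool = True,
) -> GenotypeTable:
    """Reduce a table to SNPs passing the per-locus chi-square screen.

    ``keep_below=True`` (default) keeps SNPs whose p-value is below the
    threshold, i.e. the class-associated ones; ``keep_below=False``
    inverts the direction.  Untestable (constant) SNPs are always
    dropped, with a warning.  Sample order is preserved.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must be in (0, 1)")
    pvals = chi2_pvalues(table)
    untestable = np.isnan(pvals)
    if untestable.any():
        names = [table.snp_names[i] for i in np.flatnonzero(untestable)]
        warnings.warn(
            f"dropping {len(names)} constant/untestable SNP(s): {names[:5]}...",
            stacklevel=2,
        )
    if keep_below:
        keep = ~untestable & (pvals < p_threshold)
    else:
        keep = ~untestable & (pvals >= p_threshold)
    return table.subset_snps(np.flatnonzero(keep))
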