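"""Entropy and mutual information between SNP loci and the phenotype.

All probabilities are maximum-likelihood plug-in frequencies obtained by
bitwise AND + popcount over the :class:`~epitabu.io.BitMatrix`:

    I(Class | SNP_1..SNP_k) = H(Class) + H(SNP_1..SNP_k)
                              - H(Class, SNP_1..SNP_k)

The logarithm base is configurable (natural log by default).  Rankings
are base-invariant; absolute thresholds on MI are not, so the base used
must be reported alongside any threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, product

from .io import BitMatrix

__all__ = [
    "MIResult",
    "entropy_class",
    "joint_prob",
    "joint_entropy",
    "mutual_information",
    "rank_all_pairs",
]

#: tolerance below which a negative MI is treated as floating-point noise
NEG_EPS = 1e-12
#: a negative MI below this magnitude indicates a real bug, not rounding
NEG_ERROR = 1e-9

DEFAULT_K_CAP = 3
GENOTYPE_VALUES = (0, 1, 2)


@dataclass(frozen=True, order=True)
class MIResult:
    """Mutual information of a strictly increasing SNP index combination."""

    snp_indices: tuple[int, ...]
    mi: float


def _log(x: float, base: float | None) -> float:
    return math.log(x) if base is None else math.log(x, base)


def _entropy_from_counts(counts, n: int, base: float | None) -> float:
    h = 0.0
    for c in counts:
        if c:
            p = c / n
            h -= p * _log(p, base)
    return h


def entropy_class(bits: BitMatrix, base: float | None = None) -> float:
    """H(Class) = -sum_c p(c) log p(c), with 0 log 0 = 0."""
    counts = [b.bit_count() for b in bits.class_bits]
    return _entropy_from_counts(counts, bits.n_samples, base)


def joint_prob(
    bits: BitMatrix,
    assignment: list[tuple[int, int]],
    class_value: int | None = None,
) -> float:
    """Frequency of samples matching a genotype assignment (and class).

    ``assignment`` is a list of ``(snp_index, genotype_value)`` pairs; the
    matching-sample count is popcount of the AND of the selected
    bitstrings, divided by ``n_samples``.
    """
    if not assignment and class_value is None:
        raise ValueError("assignment empty and no class value given")
    acc = bits.full_mask
    for snp, value in assignment:
        if not (0 <= snp < bits.n_snps):
            raise ValueError(f"SNP index {snp} out of range")
        if value not in GENOTYPE_VALUES:
            raise ValueError(f"genotype value {value} not in {{0,1,2}}")
        acc &= bits.snp_bits[snp][value]
    if class_value is not None:
        if class_value not in (0, 1):
            raise ValueError(f"class value {class_value} not in {{0,1}}")
        acc &= bits.class_bits[class_value]
    return acc.bit_count() / bits.n_samples


def _check_indices(bits: BitMatrix, snp_indices, k_cap: int) -> tuple[int, ...]:
    idx = tuple(int(i) for i in snp_indices)
    if not 1 <= len(idx) <= k_cap:
        raise ValueError(f"need between 1 and {k_cap} SNP indices, got {len(idx)}")
    if len(set(idx)) != len(idx):
        raise ValueError(f"SNP indices must be distinct: {idx}")
    for i in idx:
        if not 0 <= i < bits.n_snps:
            raise ValueError(f"SNP index {i} out of range")
    return idx


def joint_entropy(
    bits: BitMatrix,
    snp_indices,
    include_class: bool = False,
    base: float | None = None,
    k_cap: int = DEFAULT_K_CAP,
) -> float:
    """Joint entropy over 3^k genotype cells (times 2 with the class)."""
    idx = _check_indices(bits, snp_indices, k_cap)
    n = bits.n_samples
    class_values = (0, 1) if include_class else (None,)
    counts = []
    for values in product(GENOTYPE_VALUES, repeat=len(idx)):
        acc = bits.full_mask
        for snp, value in zip(idx, values):
            acc &= bits.snp_bits[snp][value]
        if include_class:
            for c in class_values:
                counts.append((acc & bits.class_bits[c]).bit_count())
        else:
            counts.append(acc.bit_count())
    return _entropy_from_counts(counts, n, base)


def mutual_information(
    bits: BitMatrix,
    snp_indices,
    base: float | None = None,
    k_cap: int = DEFAULT_K_CAP,
) -> MIResult:
    """I(Class | SNPs) = H(Class) + H(SNPs) - H(Class, SNPs)."""
    idx = tuple(sorted(_check_indices(bits, snp_indices, k_cap)))
    mi = (
        entropy_class(bits, base)
        + joint_entropy(bits, idx, include_class=False, base=base, k_cap=k_cap)
        - joint_entropy(bits, idx, include_class=True, base=base, k_cap=k_cap)
    )
    if mi < 0:
        if mi < -NEG_ERROR:
            raise ArithmeticError(
                f"mutual information {mi} is negative beyond rounding tolerance"
            )
        mi = 0.0
    return MIResult(snp_indices=idx, mi=mi)


def rank_all_pairs(
    bits: BitMatrix,
    k: int = 2,
    base: float | None = None,
    max_combinations: int = 2_000_000,
) -> list[MIResult]:
    """Score every k-combination of SNPs, sorted by descending MI.

    Ties are broken by lexicographic index order so the ranking is
    deterministic.  Raises when C(n_snps, k) exceeds ``max_combinations``
    (prefilter the table first, e.g. with the chi-square screen).
    """
    if k not in (2, 3):
        raise ValueError(f"k must be 2 or 3, got {k}")
    n_comb = math.comb(bits.n_snps, k)
    if n_comb > max_combinations:
        raise ValueError(
            f"{n_comb} combinations exceed the budget of {max_combinations}; "
            "reduce the SNP set first (e.g. chi-square prefilter)"
        )
    results = [
        mutual_information(bits, idx, base=base, k_cap=max(k, DEFAULT_K_CAP))
        for idx in combinations(range(bits.n_snps), k)
    ]
    results.sort(key=lambda r: (-r.mi, r.snp_indices))
    return results
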