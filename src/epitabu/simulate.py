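"""GAMETES-like simulator of purely epistatic case-control datasets.

A k-locus penetrance model assigns P(case | genotype combination) to all
3^k multilocus genotypes such that (i) the Hardy-Weinberg-weighted
marginal penetrance of every single locus equals the population
prevalence K — no main effects — and (ii) the heritability

    h2 = sum_g f_g (P_g - K)^2 / (K (1 - K))

hits its target, where f_g is the Hardy-Weinberg frequency of genotype
combination g.  Models are found by random search over deviation
*directions* inside the polytope {zero weighted marginals, penetrances
in [0, 1]}: a direction is either a Gaussian table projected onto the
marginal constraint or a vertex of the polytope obtained by maximizing
a random linear objective (vertices carry the largest attainable
variance, which matters for heritabilities near the feasible ceiling).
Each direction is scaled to the target variance when that fits inside
the box, or kept at its maximal in-box scale when the achieved
heritability still falls within the model tolerance; otherwise the next
random direction is tried.

Datasets embed the functional loci among independent noise SNPs and are
written in the GAMETES text dialect (genotypes 0/1/2, final ``Class``
column).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import GenotypeTable, write_genotypes

__all__ = [
    "PenetranceModel",
    "InfeasibleModelError",
    "hardy_weinberg_freqs",
    "achieved_heritability",
    "build_penetrance",
    "simulate_dataset",
    "simulate_batch",
]

#: tolerance on the per-locus marginal-penetrance (no-main-effect) constraint
MARGINAL_TOL = 1e-6
#: relative tolerance on achieved vs target heritability
H2_REL_TOL = 0.05


class InfeasibleModelError(RuntimeError):
    """No valid penetrance table found for the requested (h2, MAF, prevalence)."""


def hardy_weinberg_freqs(maf: float) -> np.ndarray:
    """Genotype frequencies [(1-p)^2, 2p(1-p), p^2] for minor-allele freq p.

    Coding: 0 = common homozygote, 1 = heterozygote, 2 = rare homozygote.
    """
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    q = 1.0 - maf
    return np.array([q * q, 2.0 * maf * q, maf * maf])


def _joint_freqs(maf: float, k: int) -> np.ndarray:
    f = hardy_weinberg_freqs(maf)
    out = f
    for _ in range(k - 1):
        out = np.multiply.outer(out, f)
    return out


@dataclass(frozen=True)
class PenetranceModel:
    """k-locus penetrance table with no single-locus marginal effects."""

    k: int
    maf: float
    prevalence: float
    h2: float
    table: np.ndarray  # shape (3,) * k, values in [0, 1]

    @property
    def genotype_freqs(self) -> np.ndarray:
        return _joint_freqs(self.maf, self.k)

    @property
    def achieved_h2(self) -> float:
        return achieved_heritability(self.table, self.genotype_freqs, self.prevalence)

    def marginal_penetrances(self) -> np.ndarray:
        """Per-locus, per-genotype marginal penetrance (should all equal prevalence)."""
        f = self.genotype_freqs
        out = np.empty((self.k, 3))
        for axis in range(self.k):
            other = tuple(a for a in range(self.k) if a != axis)
            weight = f.sum(axis=other)  # marginal HW freq of this locus
            joint = (f * self.table).sum(axis=other)
            out[axis] = joint / weight
        return out


def achieved_heritability(
    table: np.ndarray, freqs: np.ndarray, prevalence: float
) -> float:
    """Variance of penetrance around prevalence, scaled by K(1-K)."""
    dev = table - prevalence
    return float(np.sum(freqs * dev * dev) / (prevalence * (1.0 - prevalence)))


def _project_no_main_effect(
    dev: np.ndarray, locus_freqs: np.ndarray, max_iter: int = 500
) -> np.ndarray:
    """Zero out each locus's HW-weighted marginal of the deviation table."""
    k = dev.ndim
    dev = dev.copy()
    for _ in range(max_iter):
        worst = 0.0
        for axis in range(k):
            other = tuple(a for a in range(k) if a != axis)
            # weighted mean over the *other* axes, per value of this axis
            weights = np.ones_like(dev)
            for a in other:
                shape = [1] * k
                shape[a] = 3
                weights = weights * locus_freqs.reshape(shape)
            total = weights.sum(axis=other)
            marg = (weights * dev).sum(axis=other) / total
            worst = max(worst, float(np.abs(marg).max()))
            shape = [1] * k
            shape[axis] = 3
            dev = dev - marg.reshape(shape)
        if worst < 1e-13:
            break
    return dev


def _marginal_constraint_matrix(locus_freqs: np.ndarray, k: int) -> np.ndarray:
    """Rows of the linear map sending a deviation table to its weighted
    per-locus marginals (all must be zero for a purely epistatic model)."""
    rows = []
    for axis in range(k):
        for value in range(3):
            m = np.zeros((3,) * k)
            index = [slice(None)] * k
            index[axis] = value
            weights = np.ones((3,) * (k - 1))
            for a_other in range(k - 1):
                shape = [1] * (k - 1)
                shape[a_other] = 3
                weights = weights * locus_freqs.reshape(shape)
            m[tuple(index)] = weights
            rows.append(m.ravel())
    return np.array(rows)


def _max_in_box_scale(dev: np.ndarray, prevalence: float) -> float:
    """Largest s with prevalence + s*dev inside [0, 1] everywhere."""
    smax = np.inf
    for d in dev.ravel():
        if d < -1e-15:
            smax = min(smax, prevalence / (-d))
        elif d > 1e-15:
            smax = min(smax, (1.0 - prevalence) / d)
    return smax


def build_penetrance(
    k: int,
    maf: float,
    prevalence: float,
    h2: float,
    rng: np.random.Generator | int | None = None,
    max_tries: int = 200,
) -> PenetranceModel:
    """Random-search construction of a purely epistatic penetrance model.

    Tries alternate between Gaussian deviation tables projected onto the
    no-main-effect constraint and vertices of the constrained polytope
    (random-objective linear programs), which attain the largest
    heritabilities the constraints allow.  A direction is scaled to the
    exact target variance when that stays inside [0, 1]; when the target
    exceeds the direction's in-box ceiling but the ceiling is within
    ``H2_REL_TOL`` (relative) of target, the ceiling is accepted.  Every
    returned model satisfies the marginal (``MARGINAL_TOL``) and
    heritability invariants; otherwise :class:`InfeasibleModelError`.
    """
    from scipy.optimize import linprog

    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must be in (0, 1)")
    rng = np.random.default_rng(rng)
    locus_freqs = hardy_weinberg_freqs(maf)
    freqs = _joint_freqs(maf, k)
    target_var = h2 * prevalence * (1.0 - prevalence)
    n_cells = 3**k
    a_eq = _marginal_constraint_matrix(locus_freqs, k)
    b_eq = np.zeros(a_eq.shape[0])
    bounds = [(-prevalence, 1.0 - prevalence)] * n_cells
    best_ceiling = 0.0
    for attempt in range(max_tries):
        if attempt % 2 == 0:
            dev = _project_no_main_effect(rng.normal(size=(3,) * k), locus_freqs)
        else:
            lp = linprog(
                -rng.normal(size=n_cells), A_eq=a_eq, b_eq=b_eq,
                bounds=bounds, method="highs",
            )
            if lp.status != 0:
                continue
            dev = _project_no_main_effect(
                lp.x.reshape((3,) * k), locus_freqs
            )
        var = float(np.sum(freqs * dev * dev))
        if var < 1e-14:
            continue
        smax = _max_in_box_scale(dev, prevalence)
        ceiling_var = smax * smax * var
        best_ceiling = max(best_ceiling, ceiling_var / (prevalence * (1 - prevalence)))
        if ceiling_var >= target_var:
            scale = np.sqrt(target_var / var)
        elif ceiling_var >= (1.0 - H2_REL_TOL) * target_var:
            # target slightly above this direction's ceiling: accept the ceiling
            scale = smax
        else:
            continue
        table = np.clip(prevalence + scale * dev, 0.0, 1.0)
        model = PenetranceModel(
            k=k, maf=maf, prevalence=prevalence, h2=h2, table=table
        )
        marg_err = float(np.abs(model.marginal_penetrances() - prevalence).max())
        rel_err = abs(model.achieved_h2 - h2) / h2
        if marg_err <= MARGINAL_TOL and rel_err <= H2_REL_TOL:
            return model
    raise InfeasibleModelError(
        f"no valid penetrance table for k={k}, maf={maf}, prevalence={prevalence}, "
        f"h2={h2} after {max_tries} tries (best attainable h2 ~ {best_ceiling:.4f}; "
        "the combination is likely infeasible)"
    )


def _sample_functional(
    model: PenetranceModel,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
    max_attempts: int = 400,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample functional genotypes until both quotas are filled."""
    k = model.k
    flat_freqs = model.genotype_freqs.ravel()
    flat_pen = model.table.ravel()
    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    need = n_cases + n_controls
    got_cases = got_controls = 0
    batch = max(4 * need, 1000)
    for _ in range(max_attempts):
        combos = rng.choice(flat_freqs.size, size=batch, p=flat_freqs)
        status = rng.random(batch) < flat_pen[combos]
        genos = np.stack(np.unravel_index(combos, (3,) * k), axis=1)
        if got_cases < n_cases:
            take = genos[status][: n_cases - got_cases]
            cases.append(take)
            got_cases += take.shape[0]
        if got_controls < n_controls:
            take = genos[~status][: n_controls - got_controls]
            controls.append(take)
            got_controls += take.shape[0]
        if got_cases >= n_cases and got_controls >= n_controls:
            case_g = np.concatenate(cases)
            control_g = np.concatenate(controls)
            return case_g, control_g
    raise InfeasibleModelError(
        "case/control quota unreachable: prevalence too extreme for the sample size"
    )


def simulate_dataset(
    model: PenetranceModel,
    n_noise_snps: int = 18,
    n_cases: int = 400,
    n_controls: int = 400,
    noise_maf_range: tuple[float, float] = (0.05, 0.5),
    rng: np.random.Generator | int | None = None,
) -> tuple[GenotypeTable, list[str]]:
    """One dataset: planted loci among noise SNPs, with the truth names.

    Functional genotypes follow Hardy-Weinberg equilibrium at the model
    MAF; disease status is drawn from the penetrance table and sampled
    by rejection until the case/control quotas are met.  Noise SNPs are
    independent of status with MAFs uniform in ``noise_maf_range``.
    Planted column positions are randomized; sample rows are shuffled.
    """
    if min(n_noise_snps, n_cases, n_controls) < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(rng)
    case_g, control_g = _sample_functional(model, n_cases, n_controls, rng)
    n = n_cases + n_controls
    functional = np.concatenate([control_g, case_g])  # controls first, then cases
    phenotype = np.concatenate(
        [np.zeros(n_controls, dtype=np.int8), np.ones(n_cases, dtype=np.int8)]
    )
    row_order = rng.permutation(n)
    functional = functional[row_order]
    phenotype = phenotype[row_order]

    noise_mafs = rng.uniform(*noise_maf_range, size=n_noise_snps)
    noise = np.empty((n, n_noise_snps), dtype=np.int8)
    for j, maf in enumerate(noise_mafs):
        noise[:, j] = rng.choice(3, size=n, p=hardy_weinberg_freqs(maf))

    n_snps = model.k + n_noise_snps
    truth_names = [f"M0P{i}" for i in range(model.k)]
    noise_names = [f"N{j}" for j in range(n_noise_snps)]
    columns = np.concatenate([functional, noise], axis=1)
    names = truth_names + noise_names
    perm = rng.permutation(n_snps)
    table = GenotypeTable(
        snp_names=[names[i] for i in perm],
        genotypes=columns[:, perm],
        phenotype=phenotype,
    )
    return table, truth_names


def simulate_batch(
    out_dir,
    n_files: int,
    base_seed: int,
    k: int = 2,
    maf: float = 0.4,
    prevalence: float = 0.2,
    h2: float = 0.4,
    n_noise_snps: int = 18,
    n_cases: int = 400,
    n_controls: int = 400,
    noise_maf_range: tuple[float, float] = (0.05, 0.5),
) -> dict:
    """Write ``n_files`` datasets plus a JSON manifest mapping file -> truth.

    Per-file seeds are ``base_seed + i``, so the same base seed
    reproduces the batch byte for byte.  Returns the manifest dict.
    """
    if n_files < 1:
        raise ValueError("n_files must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = build_penetrance(
        k=k, maf=maf, prevalence=prevalence, h2=h2,
        rng=np.random.default_rng(base_seed),
    )
    manifest: dict = {
        "parameters": {
            "k": k, "maf": maf, "prevalence": prevalence, "h2": h2,
            "achieved_h2": model.achieved_h2,
            "n_noise_snps": n_noise_snps, "n_cases": n_cases,
            "n_controls": n_controls, "noise_maf_range": list(noise_maf_range),
            "base_seed": base_seed,
        },
        "files": {},
    }
    for i in range(n_files):
        seed = base_seed + i
        table, truth = simulate_dataset(
            model,
            n_noise_snps=n_noise_snps,
            n_cases=n_cases,
            n_controls=n_controls,
            noise_maf_range=noise_maf_range,
            rng=np.random.default_rng(seed),
        )
        filename = f"dataset_{i:03d}.txt"
        write_genotypes(table, out_dir / filename)
        manifest["files"][filename] = {"truth": truth, "seed": seed}
    with open(out_dir / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
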