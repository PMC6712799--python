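"""Reading, writing and bit-encoding of case-control genotype tables.

Tables follow the GAMETES text dialect: a delimited header row of SNP
names plus a final ``Class`` column, one row per sample.  Genotypes are
coded 0 (common homozygote), 1 (heterozygote), 2 (rare homozygote); the
class column is 0 (control) / 1 (case).

The bitwise representation (:class:`BitMatrix`) stores, for every SNP,
one indicator bitstring per genotype value, plus one bitstring per class
value.  Joint sample counts then reduce to AND + popcount, which is what
the mutual-information screening runs on.  Bit positions follow sample
order: the first data row occupies the *most significant* bit, so a
column read top-to-bottom prints exactly as the bitstring reads
left-to-right (a column ``1,1,0,1`` encodes genotype value 1 as the
bitstring ``1101``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeTable",
    "BitMatrix",
    "GenotypeFormatError",
    "GenotypeValidationError",
    "read_genotypes",
    "write_genotypes",
    "encode_bits",
    "decode_bits",
]

DEFAULT_CLASS_COLUMN = "Class"


class GenotypeFormatError(ValueError):
    """The file does not look like a GAMETES-dialect genotype table."""


class GenotypeValidationError(ValueError):
    """A cell violates the genotype (0/1/2) or class (0/1) coding."""


@dataclass
class GenotypeTable:
    """Samples x SNPs genotype matrix with a binary phenotype.

    Parameters
    ----------
    snp_names : list of str
        Unique locus identifiers, one per genotype column.
    genotypes : ndarray of shape (n_samples, n_snps)
        Genotype codes, each cell in {0, 1, 2}.
    phenotype : ndarray of shape (n_samples,)
        Case/control status, each cell in {0, 1}.
    """

    snp_names: list[str]
    genotypes: np.ndarray
    phenotype: np.ndarray
    class_name: str = DEFAULT_CLASS_COLUMN

    def __post_init__(self) -> None:
        self.genotypes = np.ascontiguousarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.ascontiguousarray(self.phenotype, dtype=np.int8)
        self.snp_names = list(self.snp_names)
        if self.genotypes.ndim != 2:
            raise GenotypeValidationError("genotypes must be a 2-D matrix")
        n_samples, n_snps = self.genotypes.shape
        if n_samples < 1:
            raise GenotypeValidationError("at least one sample is required")
        if n_snps < 1:
            # >= 2 SNPs are needed for pair analysis and enforced at parse
            # time; filtered tables may legitimately shrink to one column
            raise GenotypeValidationError("at least one SNP is required")
        if len(self.snp_names) != n_snps:
            raise GenotypeValidationError(
                f"{len(self.snp_names)} SNP names for {n_snps} genotype columns"
            )
        if len(set(self.snp_names)) != n_snps:
            raise GenotypeValidationError("SNP names must be unique")
        if self.class_name in self.snp_names:
            raise GenotypeValidationError(
                f"SNP name clashes with the phenotype column {self.class_name!r}"
            )
        if self.phenotype.shape != (n_samples,):
            raise GenotypeValidationError("phenotype length must equal n_samples")
        bad = np.argwhere((self.genotypes < 0) | (self.genotypes > 2))
        if bad.size:
            r, c = bad[0]
            raise GenotypeValidationError(
                f"genotype value {self.genotypes[r, c]} out of {{0,1,2}} at "
                f"sample row {r}, SNP {self.snp_names[c]!r}"
            )
        bad_ph = np.flatnonzero((self.phenotype < 0) | (self.phenotype > 1))
        if bad_ph.size:
            r = bad_ph[0]
            raise GenotypeValidationError(
                f"phenotype value {self.phenotype[r]} out of {{0,1}} at sample row {r}"
            )

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def subset_snps(self, indices: np.ndarray | list[int]) -> "GenotypeTable":
        """Return a new table restricted to the given SNP columns (sample order kept)."""
        indices = np.asarray(indices, dtype=int)
        return GenotypeTable(
            snp_names=[self.snp_names[i] for i in indices],
            genotypes=self.genotypes[:, indices],
            phenotype=self.phenotype.copy(),
            class_name=self.class_name,
        )


@dataclass(frozen=True)
class BitMatrix:
    """Per-SNP, per-genotype-value indicator bitstrings (Python integers).

    ``snp_bits[s][v]`` has bit ``n_samples - 1 - i`` set iff sample ``i``
    carries genotype value ``v`` at SNP ``s``; ``class_bits[c]`` likewise
    for class value ``c``.  Exactly one of the three genotype bitstrings
    is set per (SNP, sample), and one of the two class bitstrings per
    sample.
    """

    snp_bits: tuple[tuple[int, int, int], ...]
    class_bits: tuple[int, int]
    n_samples: int
    snp_names: tuple[str, ...] = field(default=())

    @property
    def n_snps(self) -> int:
        return len(self.snp_bits)

    @property
    def full_mask(self) -> int:
        return (1 << self.n_samples) - 1


def _bool_column_to_int(mask: np.ndarray) -> int:
    # sample 0 -> most significant bit
    return int("".join("1" if b else "0" for b in mask), 2) if mask.size else 0


def encode_bits(table: GenotypeTable) -> BitMatrix:
    """Convert a genotype table to the bitwise Boolean representation."""
    snp_bits = tuple(
        tuple(_bool_column_to_int(table.genotypes[:, s] == v) for v in (0, 1, 2))
        for s in range(table.n_snps)
    )
    class_bits = tuple(_bool_column_to_int(table.phenotype == c) for c in (0, 1))
    return BitMatrix(
        snp_bits=snp_bits,
        class_bits=class_bits,  # type: ignore[arg-type]
        n_samples=table.n_samples,
        snp_names=tuple(table.snp_names),
    )


def _int_to_bool_column(x: int, n: int) -> np.ndarray:
    return np.array([(x >> (n - 1 - i)) & 1 for i in range(n)], dtype=bool)


def decode_bits(bits: BitMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`encode_bits`; returns (genotypes, phenotype)."""
    n = bits.n_samples
    genotypes = np.zeros((n, bits.n_snps), dtype=np.int8)
    for s, triple in enumerate(bits.snp_bits):
        for v in (1, 2):
            genotypes[_int_to_bool_column(triple[v], n), s] = v
    phenotype = _int_to_bool_column(bits.class_bits[1], n).astype(np.int8)
    return genotypes, phenotype


def _sniff_delimiter(header_line: str) -> str:
    if "\t" in header_line:
        return "\t"
    if "," in header_line:
        return ","
    raise GenotypeFormatError(
        "could not detect a tab or comma delimiter in the header row"
    )


def read_genotypes(
    path,
    delimiter: str | None = None,
    class_column: str | None = None,
) -> GenotypeTable:
    """Read a GAMETES-dialect genotype table.

    Parameters
    ----------
    path : path-like
        Delimited text file with a header of SNP names plus a class column.
    delimiter : str, optional
        Field separator; auto-detected between tab and comma when omitted.
    class_column : str, optional
        Name of the phenotype column.  Default ``"Class"``; if that default
        is absent the last column is used with a warning, whereas an
        explicitly requested column that is absent raises.
    """
    explicit = class_column is not None
    class_column = class_column or DEFAULT_CLASS_COLUMN
    try:
        with open(path, "rt", encoding="utf-8") as fh:
            header_line = fh.readline()
    except OSError as exc:
        raise GenotypeFormatError(f"cannot read genotype file {path}: {exc}") from exc
    if not header_line.strip():
        raise GenotypeFormatError(f"{path}: empty file or blank header row")
    sep = delimiter or _sniff_delimiter(header_line)

    try:
        df = pd.read_csv(path, sep=sep, header=0, dtype=str, skipinitialspace=True)
    except pd.errors.ParserError as exc:
        raise GenotypeFormatError(f"{path}: malformed table ({exc})") from exc

    if class_column not in df.columns:
        if explicit:
            raise GenotypeFormatError(
                f"{path}: class column {class_column!r} not found in header"
            )
        warnings.warn(
            f"{path}: no {DEFAULT_CLASS_COLUMN!r} column; using last column "
            f"{df.columns[-1]!r} as the phenotype",
            stacklevel=2,
        )
        class_column = str(df.columns[-1])

    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise GenotypeFormatError(
            f"{path}: ragged or missing values around data row {row}"
        )

    snp_names = [c for c in df.columns if c != class_column]
    if len(snp_names) < 2:
        raise GenotypeFormatError(
            f"{path}: a genotype table needs at least two SNP columns"
        )

    def _to_int(col: pd.Series, allowed: set[int], what: str) -> np.ndarray:
        values = pd.to_numeric(col, errors="coerce")
        raw_bad = values.isna()
        as_int = values.fillna(-1).astype(int)
        bad = raw_bad | (values != as_int) | ~as_int.isin(list(allowed))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise GenotypeValidationError(
                f"{path}: invalid {what} value {col.iloc[row]!r} at data row "
                f"{row}, column {col.name!r}"
            )
        return as_int.to_numpy()

    genotypes = np.column_stack(
        [_to_int(df[name], {0, 1, 2}, "genotype") for name in snp_names]
    )
    phenotype = _to_int(df[class_column], {0, 1}, "class")
    return GenotypeTable(
        snp_names=snp_names,
        genotypes=genotypes,
        phenotype=phenotype,
        class_name=class_column,
    )


def write_genotypes(table: GenotypeTable, path, delimiter: str = "\t") -> None:
    """Write a table in GAMETES layout: SNP columns then the class column."""
    try:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write(delimiter.join([*table.snp_names, table.class_name]) + "\n")
            for i in range(table.n_samples):
                row = [str(int(v)) for v in table.genotypes[i]]
                row.append(str(int(table.phenotype[i])))
                fh.write(delimiter.join(row) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write genotype file {path}: {exc}") from exc
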