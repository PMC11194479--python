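"""Diploid genotype containers and STRUCTURE-format text I/O.

The STRUCTURE format (Pritchard lab) is whitespace-delimited text with one
individual id column, one population column, and diploid SNP calls either as
two consecutive rows per individual (one allele per row per locus, the
``two_row`` dialect) or as one row with two adjacent columns per locus
(``one_row``).  Missing data is conventionally coded ``-9``.

Allele codes are treated as opaque integer labels: the downstream classifier
only needs per-allele copy counts, so there is no reference/alternate or
strand semantics, and loci with more than two observed alleles are accepted.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeSet",
    "AlleleCountMatrix",
    "StructureParseError",
    "read_structure",
    "write_structure",
    "to_allele_counts",
    "subset_loci",
    "genotype_summary_frame",
]

DEFAULT_MISSING = -9


class StructureParseError(ValueError):
    """Raised when a STRUCTURE file is malformed (bad row length, odd row
    count in the two-row dialect, duplicate ids across non-paired rows)."""


@dataclass
class GenotypeSet:
    """Diploid genotype calls for individuals of known population origin.

    Parameters
    ----------
    individual_ids : list of str
        One id per individual.
    pop_labels : list of str
        Population of origin, one per individual, preserved verbatim.
    locus_names : list of str
        One name per locus.
    calls : ndarray of int, shape (n_individuals, n_loci, 2)
        Allele codes; ``missing_code`` marks missing calls.
    missing_code : int
        Reserved code for missing data (default -9).
    """

    individual_ids: list[str]
    pop_labels: list[str]
    locus_names: list[str]
    calls: np.ndarray
    missing_code: int = DEFAULT_MISSING
    allele_registry: list[np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, L = len(self.individual_ids), len(self.locus_names)
        if len(self.pop_labels) != n:
            raise ValueError(
                f"pop_labels has {len(self.pop_labels)} entries for {n} individuals"
            )
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"({n} individuals, {L} loci, 2)"
            )
        self.allele_registry = [
            np.unique(col[col != self.missing_code])
            for col in self.calls.transpose(1, 0, 2).reshape(L, 2 * n)
        ]

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def populations(self) -> list[str]:
        """Distinct population labels in sorted order."""
        return sorted(set(self.pop_labels))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeSet):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.pop_labels == other.pop_labels
            and self.locus_names == other.locus_names
            and self.missing_code == other.missing_code
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class AlleleCountMatrix:
    """Per-allele copy counts per individual — the classifier's input space.

    One column per (locus, allele) pair in the locus's observed-allele
    registry; entries count copies (0/1/2 for diploids).  ``missing_mask``
    is True for every column of a locus where the individual's call is
    missing.
    """

    values: np.ndarray
    column_names: list[str]
    missing_mask: np.ndarray
    column_to_locus: np.ndarray

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def rows(self, indices: np.ndarray) -> "AlleleCountMatrix":
        """Row-subset view (copy) keeping column metadata."""
        return AlleleCountMatrix(
            values=self.values[indices].copy(),
            column_names=self.column_names,
            missing_mask=self.missing_mask[indices].copy(),
            column_to_locus=self.column_to_locus,
        )


def _tokenize(text: str) -> list[list[str]]:
    rows = []
    for raw in text.splitlines():
        toks = raw.split()
        if toks:
            rows.append(toks)
    return rows


def read_structure(
    path,
    dialect: str = "auto",
    has_header: bool | None = None,
    missing_code: int = DEFAULT_MISSING,
    skip_cols: int = 0,
) -> GenotypeSet:
    """Read a STRUCTURE-format (.str/.stru) genotype file.

    Parameters
    ----------
    path : path-like or file-like
        Input file.
    dialect : {"auto", "two_row", "one_row"}
        ``two_row``: each individual occupies two consecutive rows, one
        allele per row per locus.  ``one_row``: one row per individual with
        two adjacent columns per locus.  ``auto`` tries ``two_row`` when the
        data-row count is exactly twice the distinct-id count and the rows
        pair up, else falls back to ``one_row``.
    has_header : bool or None
        Whether the first row is a locus-name header.  ``None`` auto-detects
        (a first row shorter than the data rows is taken as a header).
    missing_code : int
        Code for missing calls.
    skip_cols : int
        Extra metadata columns (e.g. pop-flag) after the id and population
        columns, skipped on read.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    rows = _tokenize(text)
    if not rows:
        raise StructureParseError("empty file")

    # Header auto-detection: a leading row strictly shorter than the next
    # row can only be a locus-name line.
    header: list[str] | None = None
    if has_header is None:
        if len(rows) > 1 and len(rows[0]) < len(rows[1]):
            header = rows.pop(0)
    elif has_header:
        header = rows.pop(0)
    if not rows:
        raise StructureParseError("no data rows after header")

    widths = {len(r) for r in rows}
    if len(widths) != 1:
        bad = next(i for i, r in enumerate(rows, 1) if len(r) != len(rows[0]))
        raise StructureParseError(
            f"inconsistent row length at data line {bad}: expected "
            f"{len(rows[0])} fields, found {len(rows[bad - 1])}"
        )
    width = widths.pop()
    meta = 2 + skip_cols
    if width < meta:
        raise StructureParseError(
            f"rows have {width} fields; need at least {meta} (id, pop"
            + (f", {skip_cols} skipped)" if skip_cols else ")")
        )

    if dialect == "auto":
        ids = [r[0] for r in rows]
        paired = (
            len(rows) % 2 == 0
            and len(set(ids)) * 2 == len(rows)
            and all(rows[i][0] == rows[i + 1][0] for i in range(0, len(rows), 2))
        )
        dialect = "two_row" if paired else "one_row"

    if dialect == "two_row":
        if len(rows) % 2 != 0:
            raise StructureParseError(
                f"two_row dialect requires an even number of data rows, got {len(rows)}"
            )
        n_loci = width - meta
        n_ind = len(rows) // 2
        ids, pops = [], []
        calls = np.empty((n_ind, n_loci, 2), dtype=np.int64)
        for i in range(n_ind):
            r1, r2 = rows[2 * i], rows[2 * i + 1]
            if r1[0] != r2[0]:
                raise StructureParseError(
                    f"rows {2 * i + 1} and {2 * i + 2} are not a pair: "
                    f"ids {r1[0]!r} vs {r2[0]!r}"
                )
            ids.append(r1[0])
            pops.append(r1[1])
            try:
                calls[i, :, 0] = [int(t) for t in r1[meta:]]
                calls[i, :, 1] = [int(t) for t in r2[meta:]]
            except ValueError as exc:
                raise StructureParseError(
                    f"non-integer allele code near data line {2 * i + 1}: {exc}"
                ) from None
        if len(set(ids)) != n_ind:
            raise StructureParseError("duplicate individual id across non-paired rows")
    elif dialect == "one_row":
        if (width - meta) % 2 != 0:
            raise StructureParseError(
                f"one_row dialect requires an even number of genotype columns, "
                f"got {width - meta}"
            )
        n_loci = (width - meta) // 2
        n_ind = len(rows)
        ids = [r[0] for r in rows]
        pops = [r[1] for r in rows]
        if len(set(ids)) != n_ind:
            raise StructureParseError("duplicate individual id in one_row dialect")
        calls = np.empty((n_ind, n_loci, 2), dtype=np.int64)
        for i, r in enumerate(rows):
            try:
                flat = np.array([int(t) for t in r[meta:]], dtype=np.int64)
            except ValueError as exc:
                raise StructureParseError(
                    f"non-integer allele code at data line {i + 1}: {exc}"
                ) from None
            calls[i] = flat.reshape(n_loci, 2)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if header is not None:
        if len(header) != n_loci:
            raise StructureParseError(
                f"header names {len(header)} loci but rows contain {n_loci}"
            )
        locus_names = list(header)
    else:
        locus_names = [f"locus_{j + 1}" for j in range(n_loci)]

    return GenotypeSet(ids, pops, locus_names, calls, missing_code=missing_code)


def write_structure(
    gset: GenotypeSet, path, dialect: str = "two_row", header: bool = True
) -> None:
    """Write a GenotypeSet as a STRUCTURE text file.

    The written file parses back to an equal GenotypeSet under the same
    dialect (and the same missing code).
    """
    buf = io.StringIO()
    if header and gset.n_loci:
        buf.write("\t".join(gset.locus_names) + "\n")
    if dialect == "two_row":
        for i, (ind, pop) in enumerate(zip(gset.individual_ids, gset.pop_labels)):
            for k in (0, 1):
                fields = [ind, pop] + [str(a) for a in gset.calls[i, :, k]]
                buf.write("\t".join(fields) + "\n")
    elif dialect == "one_row":
        for i, (ind, pop) in enumerate(zip(gset.individual_ids, gset.pop_labels)):
            fields = [ind, pop] + [str(a) for a in gset.calls[i].reshape(-1)]
            buf.write("\t".join(fields) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if hasattr(path, "write"):
        path.write(buf.getvalue())
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(buf.getvalue())


def to_allele_counts(gset: GenotypeSet) -> AlleleCountMatrix:
    """Expand genotypes to one copy-count column per (locus, allele) pair.

    Column ``locus.A`` holds the number of copies of allele ``A`` the
    individual carries at that locus (0, 1 or 2); a missing call masks all
    of the locus's columns for that individual.
    """
    n = gset.n_individuals
    cols: list[np.ndarray] = []
    names: list[str] = []
    col_locus: list[int] = []
    mask_cols: list[np.ndarray] = []
    for j, (name, registry) in enumerate(zip(gset.locus_names, gset.allele_registry)):
        if registry.size == 0:
            raise ValueError(f"locus {name!r} has no observed (non-missing) alleles")
        locus_calls = gset.calls[:, j, :]  # (n, 2)
        missing = np.any(locus_calls == gset.missing_code, axis=1)
        for allele in registry:
            counts = (locus_calls == allele).sum(axis=1).astype(float)
            counts[missing] = 0.0
            cols.append(counts)
            names.append(f"{name}.{allele}")
            col_locus.append(j)
            mask_cols.append(missing.copy())
    values = np.column_stack(cols) if cols else np.empty((n, 0))
    mask = np.column_stack(mask_cols) if mask_cols else np.empty((n, 0), dtype=bool)
    return AlleleCountMatrix(
        values=values,
        column_names=names,
        missing_mask=mask,
        column_to_locus=np.array(col_locus, dtype=np.int64),
    )


def subset_loci(gset: GenotypeSet, locus_names) -> GenotypeSet:
    """Restrict to the requested loci, in the requested order."""
    index = {name: j for j, name in enumerate(gset.locus_names)}
    try:
        keep = [index[name] for name in locus_names]
    except KeyError as exc:
        raise KeyError(f"unknown locus name {exc.args[0]!r}") from None
    return GenotypeSet(
        individual_ids=list(gset.individual_ids),
        pop_labels=list(gset.pop_labels),
        locus_names=list(locus_names),
        calls=gset.calls[:, keep, :].copy(),
        missing_code=gset.missing_code,
    )


def genotype_summary_frame(gset: GenotypeSet) -> pd.DataFrame:
    """Per-individual summary table: id, population, per-locus "a/b" strings."""
    data = {"individual": gset.individual_ids, "population": gset.pop_labels}
    for j, name in enumerate(gset.locus_names):
        col = []
        for i in range(gset.n_individuals):
            a, b = gset.calls[i, j]
            col.append(
                "./."
                if a == gset.missing_code or b == gset.missing_code
                else f"{a}/{b}"
            )
        data[name] = col
    return pd.DataFrame(data)
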