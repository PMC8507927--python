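"""shRNA library catalogue: the gene <-> shRNA <-> barcode design table.

Every downstream stage (simulation, quantification, ranking) indexes against a
:class:`LibraryDesign`.  A design mirrors the composition of commercial pooled
shRNA modules: a few thousand "reliable" genes targeted by 5 or 6 distinct
hairpins each, plus a small tail of auxiliary targets, with every hairpin
identified by a unique fixed-length DNA barcode.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ShRNARecord",
    "LibraryDesign",
    "generate_library",
    "read_library",
    "write_library",
    "ParameterError",
    "IntegrityError",
    "LibraryParseError",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


class ParameterError(ValueError):
    """An argument violates an operation's precondition."""


class IntegrityError(ValueError):
    """Data violates a structural invariant (e.g. duplicate barcodes)."""


class LibraryParseError(ValueError):
    """A library file could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class ShRNARecord:
    """One hairpin: its identifier, target gene, barcode and reliability flag."""

    shrna_id: str
    gene_symbol: str
    barcode: str
    reliable_flag: bool


@dataclass
class LibraryDesign:
    """Ordered shRNA catalogue with a single library-wide barcode length.

    Invariants (checked by :meth:`validate`): all barcodes are pairwise
    distinct, all have length ``barcode_length`` over {A,C,G,T}, and every
    reliable gene has 5 or 6 hairpins.
    """

    records: list[ShRNARecord]
    barcode_length: int
    name: str = "library"
    _gene_to_rows: dict[str, list[int]] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.validate()
        gene_to_rows: dict[str, list[int]] = {}
        for i, rec in enumerate(self.records):
            gene_to_rows.setdefault(rec.gene_symbol, []).append(i)
        object.__setattr__(self, "_gene_to_rows", gene_to_rows)

    def validate(self) -> None:
        seen: dict[str, str] = {}
        gene_counts: dict[str, int] = {}
        reliable: set[str] = set()
        for rec in self.records:
            if len(rec.barcode) != self.barcode_length:
                raise IntegrityError(
                    f"barcode {rec.barcode!r} has length {len(rec.barcode)}, "
                    f"design barcode_length is {self.barcode_length}"
                )
            if any(b not in _BASE_INDEX for b in rec.barcode):
                raise IntegrityError(f"barcode {rec.barcode!r} contains non-ACGT characters")
            if rec.barcode in seen:
                raise IntegrityError(
                    f"duplicate barcode {rec.barcode!r} shared by "
                    f"{seen[rec.barcode]!r} and {rec.shrna_id!r}"
                )
            seen[rec.barcode] = rec.shrna_id
            gene_counts[rec.gene_symbol] = gene_counts.get(rec.gene_symbol, 0) + 1
            if rec.reliable_flag:
                reliable.add(rec.gene_symbol)
        for gene in reliable:
            if not 5 <= gene_counts[gene] <= 6:
                raise IntegrityError(
                    f"reliable gene {gene!r} has {gene_counts[gene]} shRNAs; must have 5 or 6"
                )

    # -- convenience accessors ------------------------------------------------

    @property
    def complexity(self) -> int:
        """Number of hairpins (= number of distinct barcodes)."""
        return len(self.records)

    @property
    def shrna_ids(self) -> list[str]:
        return [r.shrna_id for r in self.records]

    @property
    def barcodes(self) -> list[str]:
        return [r.barcode for r in self.records]

    @property
    def reliable_genes(self) -> list[str]:
        out, seen = [], set()
        for r in self.records:
            if r.reliable_flag and r.gene_symbol not in seen:
                seen.add(r.gene_symbol)
                out.append(r.gene_symbol)
        return out

    def rows_for_gene(self, gene_symbol: str) -> list[int]:
        return list(self._gene_to_rows.get(gene_symbol, []))

    def __eq__(self, other) -> bool:
        if not isinstance(other, LibraryDesign):
            return NotImplemented
        return (
            self.records == other.records
            and self.barcode_length == other.barcode_length
            and self.name == other.name
        )


def _checksum_base(info: np.ndarray) -> np.ndarray:
    """Check base index: sum of info base indices mod 4.

    Appending it gives a code with minimum pairwise Hamming distance 2, so a
    single sequencing substitution can never convert one barcode into another.
    """
    return info.sum(axis=1) % 4


def _generate_barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    if length < 2:
        raise ParameterError("barcode_length must be >= 2")
    if 4 ** length < 2 * n:
        raise ParameterError(
            f"barcode space 4^{length} is smaller than 2 x {n}; increase barcode_length"
        )
    if 4 ** (length - 1) < n:
        raise ParameterError(
            f"cannot place {n} distance-2 barcodes of length {length}; increase barcode_length"
        )
    chosen: dict[bytes, None] = {}
    arr = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    while len(chosen) < n:
        batch = max(n - len(chosen), 64)
        info = rng.integers(0, 4, size=(2 * batch, length - 1))
        check = _checksum_base(info)
        full = np.concatenate([info, check[:, None]], axis=1)
        for row in arr[full]:
            key = row.tobytes()
            if key not in chosen:
                chosen[key] = None
                if len(chosen) == n:
                    break
    return [k.decode() for k in chosen]


def generate_library(
    n_reliable_genes: int,
    n_total_shrnas: int,
    barcode_length: int = 18,
    seed: int = 0,
    n_reliable_shrnas: int | None = None,
) -> LibraryDesign:
    """Synthesize a library design with the stated composition constraints.

    Each reliable gene receives 5 or 6 hairpins; which genes get 6 is decided
    by a seeded random order.  Hairpins beyond the reliable allocation are
    grouped into auxiliary targets named ``AUX0001``... (8 hairpins per target,
    last target possibly fewer).  Barcodes are random with minimum pairwise
    Hamming distance 2.

    Parameters
    ----------
    n_reliable_shrnas
        Total hairpins assigned to reliable genes.  Default assigns as many as
        feasible (capped at 6 per gene) before spilling into auxiliary targets.
    """
    if n_reliable_genes < 1 or n_total_shrnas < 1:
        raise ParameterError("n_reliable_genes and n_total_shrnas must be positive")
    lo, hi = 5 * n_reliable_genes, 6 * n_reliable_genes
    if n_total_shrnas < lo:
        raise ParameterError(
            f"{n_total_shrnas} shRNAs cannot give {n_reliable_genes} reliable genes "
            f">=5 each (need >= {lo})"
        )
    if n_reliable_shrnas is None:
        n_reliable_shrnas = min(n_total_shrnas, hi)
    if not lo <= n_reliable_shrnas <= hi:
        raise ParameterError(
            f"n_reliable_shrnas={n_reliable_shrnas} outside feasible range [{lo}, {hi}]"
        )
    if n_reliable_shrnas > n_total_shrnas:
        raise ParameterError("n_reliable_shrnas exceeds n_total_shrnas")

    rng = np.random.default_rng(seed)
    barcodes = _generate_barcodes(n_total_shrnas, barcode_length, rng)

    width = max(4, len(str(n_reliable_genes)))
    genes = [f"GENE{i + 1:0{width}d}" for i in range(n_reliable_genes)]
    k = n_reliable_shrnas - lo  # genes receiving a 6th hairpin
    order = rng.permutation(n_reliable_genes)
    counts = np.full(n_reliable_genes, 5, dtype=int)
    counts[order[:k]] = 6

    records: list[ShRNARecord] = []
    bc_iter = iter(barcodes)
    serial = 0
    for gi, gene in enumerate(genes):
        for j in range(counts[gi]):
            serial += 1
            records.append(
                ShRNARecord(f"sh{serial:06d}", gene, next(bc_iter), True)
            )
    n_aux = n_total_shrnas - n_reliable_shrnas
    aux_target = 0
    placed = 0
    while placed < n_aux:
        aux_target += 1
        for _ in range(min(8, n_aux - placed)):
            serial += 1
            placed += 1
            records.append(
                ShRNARecord(f"sh{serial:06d}", f"AUX{aux_target:04d}", next(bc_iter), False)
            )
    return LibraryDesign(records=records, barcode_length=barcode_length)


_COLUMNS = ["shrna_id", "gene_symbol", "barcode", "reliable_flag"]


def write_library(design: LibraryDesign, path) -> None:
    """Write a design as tab-separated text (header + one row per hairpin)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_COLUMNS)
        for r in design.records:
            w.writerow([r.shrna_id, r.gene_symbol, r.barcode,
                        "true" if r.reliable_flag else "false"])


def read_library(path, name: str | None = None) -> LibraryDesign:
    """Read a tab-separated library design; row order is preserved.

    Raises :class:`LibraryParseError` with a line number for malformed rows and
    :class:`IntegrityError` (naming the barcode) for duplicates.
    """
    records: list[ShRNARecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise LibraryParseError("empty file (missing header)", 1) from None
        if header != _COLUMNS:
            raise LibraryParseError(
                f"expected header {_COLUMNS}, got {header}", 1
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise LibraryParseError(f"expected 4 fields, got {len(row)}", lineno)
            sid, gene, bc, flag = row
            if flag not in ("true", "false"):
                raise LibraryParseError(f"reliable_flag must be true/false, got {flag!r}", lineno)
            records.append(ShRNARecord(sid, gene, bc, flag == "true"))
    if not records:
        return LibraryDesign(records=[], barcode_length=0,
                             name=name or "library")
    bc_len = len(records[0].barcode)
    return LibraryDesign(records=records, barcode_length=bc_len,
                         name=name or "library")
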