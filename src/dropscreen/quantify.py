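"""FASTQ -> shRNA x sample count matrix with per-sample QC.

The barcode sits at a fixed offset in every amplicon read, so quantification
is a substring extraction plus a hash lookup per read.  With mismatch
tolerance 1, a miss triggers enumeration of the 3L single-substitution
neighbours; reads equidistant from two barcodes are counted as ambiguous and
discarded (conservative, order-independent).
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .library import IntegrityError, LibraryDesign, ParameterError
from .simulate import SampleRecord

__all__ = [
    "BarcodeIndex",
    "QuantQC",
    "CountMatrix",
    "build_barcode_index",
    "quantify_fastq",
    "assemble_count_matrix",
    "qc_filter_samples",
    "FastqParseError",
]

_BASES = "ACGT"


class FastqParseError(ValueError):
    def __init__(self, message: str, record_index: int):
        super().__init__(f"record {record_index}: {message}")
        self.record_index = record_index


@dataclass
class QuantQC:
    """Read-fate tally for one sample; total = assigned + ambiguous + unassigned."""

    total_reads: int = 0
    assigned_reads: int = 0
    ambiguous_reads: int = 0
    unassigned_reads: int = 0
    barcode_recovery: float = 0.0

    def validate(self) -> None:
        if self.total_reads != self.assigned_reads + self.ambiguous_reads + self.unassigned_reads:
            raise IntegrityError("QC read fates do not sum to total_reads")
        if not 0.0 <= self.barcode_recovery <= 1.0:
            raise IntegrityError("barcode_recovery outside [0, 1]")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


class BarcodeIndex:
    """Exact or 1-mismatch barcode lookup over a library design."""

    def __init__(self, design: LibraryDesign, max_mismatch: int = 0):
        if max_mismatch not in (0, 1):
            raise ParameterError("max_mismatch must be 0 or 1")
        exact: dict[str, int] = {}
        for i, bc in enumerate(design.barcodes):
            if bc in exact:
                raise IntegrityError(f"duplicate barcode {bc!r} in design")
            exact[bc] = i
        self.design = design
        self.max_mismatch = max_mismatch
        self.barcode_length = design.barcode_length
        self._exact = exact

    AMBIGUOUS = -2
    NO_MATCH = -1

    def lookup(self, query: str) -> int:
        """Row index of the matching barcode, NO_MATCH, or AMBIGUOUS."""
        hit = self._exact.get(query)
        if hit is not None:
            return hit
        if self.max_mismatch == 0 or len(query) != self.barcode_length:
            return self.NO_MATCH
        found = self.NO_MATCH
        for pos in range(self.barcode_length):
            orig = query[pos]
            prefix, suffix = query[:pos], query[pos + 1:]
            for b in _BASES:
                if b == orig:
                    continue
                h = self._exact.get(prefix + b + suffix)
                if h is not None:
                    if found != self.NO_MATCH:
                        return self.AMBIGUOUS
                    found = h
        return found


def build_barcode_index(design: LibraryDesign, max_mismatch: int = 0) -> BarcodeIndex:
    """Build the lookup structure used by :func:`quantify_fastq`."""
    return BarcodeIndex(design, max_mismatch)


def _open_maybe_gzip(path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def quantify_fastq(
    fastq_path,
    index: BarcodeIndex,
    barcode_offset: int,
    barcode_length: int | None = None,
) -> tuple[np.ndarray, QuantQC]:
    """Tally reads per hairpin from one FASTQ file (plain or gzip).

    The barcode is the substring ``read[offset : offset+length]``; reads too
    short for the extraction are unassigned.  Returns counts aligned with the
    design's record order, and a QC record whose fates always sum to the total.
    """
    if barcode_length is None:
        barcode_length = index.barcode_length
    if barcode_length != index.barcode_length:
        raise ParameterError(
            f"barcode_length {barcode_length} does not match index ({index.barcode_length})"
        )
    if barcode_offset < 0:
        raise ParameterError("barcode_offset must be nonnegative")

    counts = np.zeros(index.design.complexity, dtype=np.int64)
    qc = QuantQC()
    end = barcode_offset + barcode_length
    lookup = index.lookup
    exact = index._exact
    mm = index.max_mismatch

    with _open_maybe_gzip(fastq_path) as fh:
        rec = 0
        while True:
            header = fh.readline()
            if not header:
                break
            rec += 1
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline()
            if not header.startswith("@"):
                raise FastqParseError("header line does not start with '@'", rec)
            if not plus.startswith("+"):
                raise FastqParseError("separator line does not start with '+'", rec)
            if not qual:
                raise FastqParseError("truncated record (missing quality line)", rec)
            qc.total_reads += 1
            if len(seq) < end:
                qc.unassigned_reads += 1
                continue
            bc = seq[barcode_offset:end]
            hit = exact.get(bc)
            if hit is None:
                if mm == 0:
                    qc.unassigned_reads += 1
                    continue
                hit = lookup(bc)
                if hit == BarcodeIndex.AMBIGUOUS:
                    qc.ambiguous_reads += 1
                    continue
                if hit == BarcodeIndex.NO_MATCH:
                    qc.unassigned_reads += 1
                    continue
            qc.assigned_reads += 1
            counts[hit] += 1

    if index.design.complexity:
        qc.barcode_recovery = float((counts > 0).mean())
    qc.validate()
    return counts, qc


@dataclass
class CountMatrix:
    """shRNA x sample integer counts plus sample metadata and design reference."""

    counts: pd.DataFrame  # rows indexed by shrna_id, columns by sample_id
    samples: list[SampleRecord]
    design: LibraryDesign

    def __post_init__(self):
        if list(self.counts.index) != self.design.shrna_ids:
            raise IntegrityError("count matrix rows must match the design's shRNA order")
        if (self.counts.values < 0).any():
            raise IntegrityError("counts must be nonnegative")

    def sample(self, sample_id: str) -> SampleRecord:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="shrna_id")

    @classmethod
    def from_tsv(cls, path, samples: list[SampleRecord], design: LibraryDesign) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="shrna_id")
        return cls(counts=df, samples=samples, design=design)


def assemble_count_matrix(
    per_sample_counts: dict[str, np.ndarray],
    samples: list[SampleRecord],
    design: LibraryDesign,
) -> CountMatrix:
    """Stack per-sample count vectors into a matrix, in sample-sheet order."""
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise IntegrityError(f"sample_id collision: {dup}")
    cols = {}
    for s in samples:
        if s.sample_id not in per_sample_counts:
            raise IntegrityError(f"no counts provided for sample {s.sample_id!r}")
        vec = np.asarray(per_sample_counts[s.sample_id])
        if vec.shape != (design.complexity,):
            raise IntegrityError(
                f"count vector for {s.sample_id!r} has length {vec.shape}, "
                f"design complexity is {design.complexity}"
            )
        cols[s.sample_id] = vec
    df = pd.DataFrame(cols, index=pd.Index(design.shrna_ids, name="shrna_id"))
    return CountMatrix(counts=df, samples=list(samples), design=design)


def qc_filter_samples(
    samples: list[SampleRecord],
    low: float = 0.10,
    high: float = 0.40,
) -> tuple[list[SampleRecord], list[tuple[SampleRecord, str]]]:
    """Apply the transduction-efficiency window: retain iff low <= TE <= high.

    Baseline samples are always retained (they are snap-frozen before
    selection and carry no efficiency of their own).  Excluded samples are
    returned with a reason string.
    """
    retained, excluded = [], []
    for s in samples:
        if s.is_baseline:
            retained.append(s)
            continue
        te = s.transduction_efficiency
        if te is None:
            raise ParameterError(
                f"sample {s.sample_id!r} is not baseline and has no transduction efficiency"
            )
        if te < low:
            excluded.append((s, f"transduction efficiency {te:.3f} < {low:.2f}"))
        elif te > high:
            excluded.append((s, f"transduction efficiency {te:.3f} > {high:.2f}"))
        else:
            retained.append(s)
    return retained, excluded
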