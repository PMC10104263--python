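"""sgRNA library and count-table I/O, plus the guide off-target mismatch search.

The library is the screen's reference: every guide maps a 20-nt protospacer
sequence to the gene it targets. Per-gene guide totals taken from the library
are the denominator of the enrichment score, so validation here is strict —
duplicate ids, non-ACGT sequences and wrong-length guides are hard errors,
not warnings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

GUIDE_ALPHABET = frozenset("ACGT")
DEFAULT_GUIDE_LENGTH = 20

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class LibraryError(ValueError):
    """Raised when a guide library violates its invariants."""


@dataclass(frozen=True)
class GuideRecord:
    """A single library entry: unique id, 20-nt ACGT protospacer, target gene."""

    guide_id: str
    sequence: str
    gene: str

    def __post_init__(self) -> None:
        if len(self.sequence) != DEFAULT_GUIDE_LENGTH:
            raise LibraryError(
                f"guide {self.guide_id!r}: sequence length "
                f"{len(self.sequence)} != {DEFAULT_GUIDE_LENGTH}"
            )
        if not set(self.sequence) <= GUIDE_ALPHABET:
            bad = sorted(set(self.sequence) - GUIDE_ALPHABET)
            raise LibraryError(
                f"guide {self.guide_id!r}: non-ACGT characters {bad}"
            )
        if not self.guide_id:
            raise LibraryError("empty guide_id")


class GuideLibrary:
    """Ordered collection of guides with a gene -> guide_ids index.

    Every guide maps to exactly one gene; ids are unique. Iteration yields
    :class:`GuideRecord` in library order (the order counts tables follow).
    """

    def __init__(self, records: Iterable[GuideRecord]):
        self.records: list[GuideRecord] = list(records)
        if not self.records:
            raise LibraryError("library is empty")
        seen: set[str] = set()
        self.gene_index: dict[str, list[str]] = {}
        for rec in self.records:
            if rec.guide_id in seen:
                raise LibraryError(f"duplicate guide_id {rec.guide_id!r}")
            seen.add(rec.guide_id)
            self.gene_index.setdefault(rec.gene, []).append(rec.guide_id)
        self._by_id = {rec.guide_id: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GuideRecord]:
        return iter(self.records)

    def __contains__(self, guide_id: str) -> bool:
        return guide_id in self._by_id

    def __getitem__(self, guide_id: str) -> GuideRecord:
        return self._by_id[guide_id]

    @property
    def guide_ids(self) -> list[str]:
        return [rec.guide_id for rec in self.records]

    @property
    def genes(self) -> list[str]:
        return list(self.gene_index)

    def guides_for_gene(self, gene: str) -> list[str]:
        if gene not in self.gene_index:
            raise KeyError(f"gene {gene!r} not in library")
        return list(self.gene_index[gene])

    def gene_of(self, guide_id: str) -> str:
        return self._by_id[guide_id].gene

    def sequence_map(self) -> dict[str, str]:
        """guide sequence -> guide_id (sequences are unique in a valid library)."""
        out: dict[str, str] = {}
        for rec in self.records:
            if rec.sequence in out:
                raise LibraryError(
                    f"guides {out[rec.sequence]!r} and {rec.guide_id!r} share a sequence"
                )
            out[rec.sequence] = rec.guide_id
        return out


_DEFAULT_COLUMNS = {"guide_id": "sgRNA", "sequence": "sequence", "gene": "gene"}


def _normalize_sequence(seq: str) -> str:
    # RNA-style inputs tolerated: uppercase and U->T before validation.
    return seq.strip().upper().replace("U", "T")


def read_library(
    path: str | Path,
    format: str | None = None,
    columns: Mapping[str, str] | None = None,
) -> GuideLibrary:
    """Read a guide library from a CSV/TSV table.

    Parameters
    ----------
    path
        Table with a header row naming at least the id, sequence and gene
        columns.
    format
        ``"csv"`` or ``"tsv"``; inferred from the file extension when omitted.
    columns
        Mapping from the roles ``guide_id``/``sequence``/``gene`` to the header
        names used in the file. Defaults to ``sgRNA``/``sequence``/``gene``.
    """
    path = Path(path)
    colmap = dict(_DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    if format is None:
        format = "tsv" if path.suffix.lower() in {".tsv", ".txt"} else "csv"
    sep = "\t" if format == "tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise LibraryError(f"{path}: empty library file") from exc
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise LibraryError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    if len(df) == 0:
        raise LibraryError(f"{path}: library has a header but no rows")

    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        seq = _normalize_sequence(str(rowd[colmap["sequence"]]))
        try:
            records.append(
                GuideRecord(
                    guide_id=str(rowd[colmap["guide_id"]]).strip(),
                    sequence=seq,
                    gene=str(rowd[colmap["gene"]]).strip(),
                )
            )
        except LibraryError as exc:
            raise LibraryError(f"{path}: row {i + 2}: {exc}") from exc
    return GuideLibrary(records)


def write_library(
    library: GuideLibrary,
    path: str | Path,
    format: str | None = None,
    columns: Mapping[str, str] | None = None,
) -> None:
    """Write a library table (inverse of :func:`read_library`)."""
    path = Path(path)
    colmap = dict(_DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    if format is None:
        format = "tsv" if path.suffix.lower() in {".tsv", ".txt"} else "csv"
    sep = "\t" if format == "tsv" else ","
    df = pd.DataFrame(
        {
            colmap["guide_id"]: [r.guide_id for r in library],
            colmap["sequence"]: [r.sequence for r in library],
            colmap["gene"]: [r.gene for r in library],
        }
    )
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------


@dataclass
class SampleDiagnostics:
    """Read-assignment bookkeeping for one sequencing sample.

    Invariant: assigned + unassigned_no_anchor + unassigned_no_match +
    ambiguous == total_reads, and assigned equals the column sum of counts.
    """

    total_reads: int = 0
    assigned: int = 0
    unassigned_no_anchor: int = 0
    unassigned_no_match: int = 0
    ambiguous: int = 0

    def check(self) -> None:
        parts = (
            self.assigned
            + self.unassigned_no_anchor
            + self.unassigned_no_match
            + self.ambiguous
        )
        if parts != self.total_reads:
            raise ValueError(
                f"read conservation violated: categories sum to {parts}, "
                f"total_reads={self.total_reads}"
            )


@dataclass
class CountTable:
    """Per-guide, per-sample integer read counts with assignment diagnostics.

    ``counts`` is guides x samples, indexed by guide_id in library order.
    """

    counts: pd.DataFrame
    diagnostics: dict[str, SampleDiagnostics] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample names in count table")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate guide ids in count table")
        if len(self.counts):
            vals = self.counts.to_numpy()
            if not np.issubdtype(vals.dtype, np.integer):
                if not np.all(vals == np.floor(vals)):
                    raise ValueError("counts must be integers")
                self.counts = self.counts.astype(np.int64)
            if (self.counts.to_numpy() < 0).any():
                raise ValueError("negative counts are not allowed")
        for sample in self.counts.columns:
            if sample not in self.diagnostics:
                n = int(self.counts[sample].sum()) if len(self.counts) else 0
                self.diagnostics[sample] = SampleDiagnostics(
                    total_reads=n, assigned=n
                )
        for diag in self.diagnostics.values():
            diag.check()

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def guide_ids(self) -> list[str]:
        return list(self.counts.index)

    def column(self, sample: str) -> pd.Series:
        return self.counts[sample]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.counts.shape == other.counts.shape
            and list(self.counts.index) == list(other.counts.index)
            and list(self.counts.columns) == list(other.counts.columns)
            and bool((self.counts.to_numpy() == other.counts.to_numpy()).all())
        )


_DIAG_RE = re.compile(
    r"^#\s*sample=(\S+)\s+total_reads=(\d+)\s+assigned=(\d+)\s+"
    r"unassigned_no_anchor=(\d+)\s+unassigned_no_match=(\d+)\s+ambiguous=(\d+)\s*$"
)


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write counts as TSV: comment header with per-sample diagnostics, then
    a ``guide_id`` column followed by one integer column per sample."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for sample in table.samples:
            d = table.diagnostics[sample]
            fh.write(
                f"# sample={sample} total_reads={d.total_reads} "
                f"assigned={d.assigned} "
                f"unassigned_no_anchor={d.unassigned_no_anchor} "
                f"unassigned_no_match={d.unassigned_no_match} "
                f"ambiguous={d.ambiguous}\n"
            )
        fh.write("guide_id\t" + "\t".join(table.samples) + "\n")
        for gid, row in table.counts.iterrows():
            fh.write(str(gid) + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_count_table(path: str | Path) -> CountTable:
    """Read a count TSV written by :func:`write_count_table`.

    Round-trips bit-exactly for integer counts; fractional or negative counts
    are hard errors.
    """
    path = Path(path)
    diagnostics: dict[str, SampleDiagnostics] = {}
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                m = _DIAG_RE.match(line)
                if m:
                    diagnostics[m.group(1)] = SampleDiagnostics(
                        total_reads=int(m.group(2)),
                        assigned=int(m.group(3)),
                        unassigned_no_anchor=int(m.group(4)),
                        unassigned_no_match=int(m.group(5)),
                        ambiguous=int(m.group(6)),
                    )
                continue
            if header is None:
                header = line.split("\t")
                if header[0] != "guide_id":
                    raise ValueError(f"{path}: first column must be guide_id")
            else:
                rows.append(line.split("\t"))
    if header is None:
        raise ValueError(f"{path}: no header line")
    samples = header[1:]
    index = [r[0] for r in rows]
    data = np.empty((len(rows), len(samples)), dtype=np.int64)
    for i, r in enumerate(rows):
        for j, cell in enumerate(r[1:]):
            try:
                v = int(cell)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-integer count {cell!r} for guide {r[0]!r}"
                ) from exc
            if v < 0:
                raise ValueError(f"{path}: negative count for guide {r[0]!r}")
            data[i, j] = v
    counts = pd.DataFrame(data, index=pd.Index(index, name="guide_id"), columns=samples)
    return CountTable(counts=counts, diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# Off-target mismatch search
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class OfftargetHit:
    """A candidate off-target site: subject, 0-based leftmost position on the
    forward strand, strand of the match, and exact Hamming mismatch count."""

    subject_id: str
    position: int
    strand: str
    mismatches: int


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def find_offtargets(
    guide: str,
    subjects: Iterable[tuple[str, str]] | Mapping[str, str],
    max_mismatch: int = 3,
) -> list[OfftargetHit]:
    """Scan subject sequences for near-matches of a guide on both strands.

    Every window of guide length whose Hamming distance to the guide (forward
    strand) or to its reverse complement (reverse strand) is at most
    ``max_mismatch`` is reported. ``N`` in a subject never matches. Positions
    are 0-based leftmost coordinates on the subject's forward strand; hits are
    sorted by (subject_id, position, strand).

    The default of three tolerated mismatches reflects common practice for
    nominating CRISPR off-target sites in amplicon-scale contexts.
    """
    guide = _normalize_sequence(guide)
    if not guide or not set(guide) <= GUIDE_ALPHABET:
        raise ValueError(f"guide must be non-empty ACGT, got {guide!r}")
    if not 0 <= max_mismatch <= len(guide):
        raise ValueError(f"max_mismatch must be in [0, {len(guide)}]")
    items = subjects.items() if isinstance(subjects, Mapping) else list(subjects)
    if not items:
        raise ValueError("subjects collection is empty")

    k = len(guide)
    queries = {"+": _encode(guide), "-": _encode(reverse_complement(guide))}
    hits: list[OfftargetHit] = []
    for subject_id, seq in items:
        seq = seq.strip().upper()
        if not set(seq) <= GUIDE_ALPHABET | {"N"}:
            raise ValueError(f"subject {subject_id!r}: alphabet must be ACGTN")
        if len(seq) < k:
            continue
        enc = _encode(seq)
        windows = np.lib.stride_tricks.sliding_window_view(enc, k)
        for strand, q in queries.items():
            mm = (windows != q).sum(axis=1)
            for pos in np.nonzero(mm <= max_mismatch)[0]:
                hits.append(
                    OfftargetHit(
                        subject_id=subject_id,
                        position=int(pos),
                        strand=strand,
                        mismatches=int(mm[pos]),
                    )
                )
    hits.sort(key=lambda h: (h.subject_id, h.position, h.strand))
    return hits


def read_fasta_subjects(path: str | Path) -> list[tuple[str, str]]:
    """Load (id, sequence) subject pairs from a FASTA file."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
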