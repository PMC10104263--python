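"""Assign sequencing reads to library guides and normalize count tables.

Reads from a pooled screen carry the guide between constant vector flanks.
Extraction locates the guide window either by anchoring on an exact flank
substring or at a fixed offset (for pre-trimmed reads); assignment is exact
dictionary lookup by default, with an optional single-mismatch mode backed
by a precomputed Hamming-1 neighborhood. Every read lands in exactly one
diagnostic category, so assigned + unassigned + ambiguous always equals the
read total.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library_io import CountTable, GuideLibrary, SampleDiagnostics

AMBIGUOUS = object()  # sentinel in the Hamming-1 neighborhood map


def extract_guide(
    read_sequence: str,
    anchor_5p: str | None = None,
    anchor_3p: str | None = None,
    guide_length: int = 20,
    offset: int | None = None,
) -> str | None:
    """Locate the guide window in a read.

    Anchored mode (default): the window of ``guide_length`` bases following
    the first exact occurrence of ``anchor_5p``; if ``anchor_3p`` is given it
    must follow the window exactly. Fixed-offset mode (``offset`` set): the
    window at that position, anchors ignored. Returns ``None`` when the
    anchor is absent or the window is truncated.
    """
    if guide_length <= 0:
        raise ValueError("guide_length must be positive")
    read = read_sequence.upper()
    if offset is not None:
        if offset < 0:
            raise ValueError("offset must be >= 0")
        start = offset
    else:
        if not anchor_5p:
            raise ValueError("anchor_5p required unless a fixed offset is given")
        idx = read.find(anchor_5p.upper())
        if idx < 0:
            return None
        start = idx + len(anchor_5p)
    end = start + guide_length
    if end > len(read):
        return None
    if offset is None and anchor_3p:
        a3 = anchor_3p.upper()
        if read[end : end + len(a3)] != a3:
            return None
    return read[start:end]


def hamming1_neighborhood(library: GuideLibrary) -> dict[str, object]:
    """Map every sequence at Hamming distance 1 from a library guide to that
    guide's id, or to the AMBIGUOUS sentinel when two guides collide."""
    neighbors: dict[str, object] = {}
    for rec in library:
        seq = rec.sequence
        for i, orig in enumerate(seq):
            for b in "ACGT":
                if b == orig:
                    continue
                neigh = seq[:i] + b + seq[i + 1 :]
                prev = neighbors.get(neigh)
                if prev is None:
                    neighbors[neigh] = rec.guide_id
                elif prev != rec.guide_id:
                    neighbors[neigh] = AMBIGUOUS
    return neighbors


def _open_fastq(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, encoding="utf-8")


def _iter_fastq(path: str | Path):
    i = 0
    with _open_fastq(path) as fh:
        try:
            for i, (title, seq, _qual) in enumerate(FastqGeneralIterator(fh), start=1):
                yield title, seq
        except ValueError as exc:
            raise ValueError(f"{path}: malformed FASTQ near record {i + 1}: {exc}") from exc


def count_guides(
    fastq: str | Path | Sequence[str | Path] | Mapping[str, str | Path],
    library: GuideLibrary,
    sample_name: str = "sample",
    anchor_5p: str | None = None,
    anchor_3p: str | None = None,
    offset: int | None = None,
    guide_length: int = 20,
    max_mismatch: int = 0,
    collect_assignments: bool = False,
):
    """Count guide occurrences in FASTQ file(s) into a :class:`CountTable`.

    ``fastq`` may be one path, a list of paths (pooled into one sample), or a
    mapping sample_name -> path. Exact matches are resolved by dictionary
    lookup; with ``max_mismatch=1`` a non-exact candidate is assigned iff
    exactly one library guide is at Hamming distance 1 (ties are counted as
    ambiguous). Defaults to exact matching.

    With ``collect_assignments=True`` additionally returns, per sample, a
    list of (read_title, assigned_guide_id_or_None) for auditing.
    """
    if len(library) == 0:
        raise ValueError("empty library")
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    if isinstance(fastq, (str, Path)):
        sample_paths: dict[str, list[Path]] = {sample_name: [Path(fastq)]}
    elif isinstance(fastq, Mapping):
        sample_paths = {s: [Path(p)] for s, p in fastq.items()}
    else:
        sample_paths = {sample_name: [Path(p) for p in fastq]}

    exact = library.sequence_map()
    neighbors = hamming1_neighborhood(library) if max_mismatch == 1 else {}
    guide_pos = {gid: i for i, gid in enumerate(library.guide_ids)}

    columns: dict[str, np.ndarray] = {}
    diagnostics: dict[str, SampleDiagnostics] = {}
    assignments: dict[str, list[tuple[str, str | None]]] = {}
    for sample, paths in sample_paths.items():
        counts = np.zeros(len(library), dtype=np.int64)
        diag = SampleDiagnostics()
        audit: list[tuple[str, str | None]] = []
        for path in paths:
            for title, seq in _iter_fastq(path):
                diag.total_reads += 1
                candidate = extract_guide(
                    seq, anchor_5p, anchor_3p, guide_length, offset
                )
                assigned: str | None = None
                if candidate is None:
                    diag.unassigned_no_anchor += 1
                else:
                    gid = exact.get(candidate)
                    if gid is not None:
                        assigned = gid
                    elif max_mismatch == 1:
                        hit = neighbors.get(candidate)
                        if hit is AMBIGUOUS:
                            diag.ambiguous += 1
                        elif hit is None:
                            diag.unassigned_no_match += 1
                        else:
                            assigned = hit  # type: ignore[assignment]
                    else:
                        diag.unassigned_no_match += 1
                    if assigned is not None:
                        counts[guide_pos[assigned]] += 1
                        diag.assigned += 1
                if collect_assignments:
                    audit.append((title, assigned))
        diag.check()
        columns[sample] = counts
        diagnostics[sample] = diag
        assignments[sample] = audit

    table = CountTable(
        counts=pd.DataFrame(
            columns, index=pd.Index(library.guide_ids, name="guide_id")
        ),
        diagnostics=diagnostics,
    )
    if collect_assignments:
        return table, assignments
    return table


@dataclass
class NormalizedTable:
    """Reads-per-million view of a count table.

    ``values`` has the shape of the source counts; each sample column sums to
    1e6 when the sample has assigned reads (and pseudocount handling keeps
    that property). The raw table is retained because guide *detection* is
    defined on raw counts while abundance is defined on RPM.
    """

    values: pd.DataFrame
    raw: CountTable
    pseudocount: float = 0.0
    warnings: list[str] | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def normalize_rpm(table: CountTable, pseudocount: float = 0.0) -> NormalizedTable:
    """Depth-normalize counts to reads per million assigned reads.

    value = (count + pseudocount) / (assigned + pseudocount * n_guides) * 1e6.
    A sample with zero assigned reads (and zero pseudocount) normalizes to
    all-zero with a recorded warning rather than NaN.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    n_guides = len(table.counts)
    values = {}
    warnings: list[str] = []
    for sample in table.samples:
        assigned = table.diagnostics[sample].assigned
        denom = assigned + pseudocount * n_guides
        if denom == 0:
            warnings.append(f"sample {sample!r}: no assigned reads; RPM set to 0")
            values[sample] = np.zeros(n_guides)
        else:
            values[sample] = (
                (table.counts[sample].to_numpy() + pseudocount) / denom * 1e6
            )
    return NormalizedTable(
        values=pd.DataFrame(values, index=table.counts.index),
        raw=table,
        pseudocount=pseudocount,
        warnings=warnings or None,
    )
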