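"""Per-gene enrichment scoring, ranking, and two-dose hit calling.

The screen sequences only the cells surviving drug selection, so a gene's
evidence of conferring resistance has two ingredients: how many of its
library guides are still detectable in the survivors, and how abundant the
detected guides are. The per-gene score combines both:

    score = (n_detected / n_library) * log2(max(avg_abundance, floor))

where ``n_detected`` counts the gene's guides with at least
``detection_threshold`` raw reads in the selected sample, ``n_library`` is
the gene's guide count in the library, and ``avg_abundance`` is the mean
reads-per-million of the *detected* guides. A gene with no detected guides
scores 0 by definition. The abundance floor (default 1 RPM, i.e. log2 >= 0)
keeps the score's sign aligned with enrichment rather than letting
sub-1-RPM noise drive it negative.

A variant that divides by log2(average abundance) instead of multiplying is
provided (``variant="division"``); multiplication is the default because
dividing by the log-abundance of a highly enriched gene would penalize
exactly the guides the screen selects for.

Hits are genes ranked in the top-k of *every* dose arm — resistance genes
should surface regardless of selection stringency, while noise-driven
high ranks rarely replicate across arms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import math

import pandas as pd

from .library_io import CountTable, GuideLibrary
from .quantify import NormalizedTable, normalize_rpm


@dataclass(frozen=True)
class GeneEnrichment:
    """Per-gene score record for one dose arm."""

    gene: str
    n_detected: int
    n_library: int
    avg_abundance: float  # mean RPM of detected guides; 0 when none detected
    score: float
    rank: int | None = None


def _as_normalized(table: NormalizedTable | CountTable) -> NormalizedTable:
    if isinstance(table, CountTable):
        return normalize_rpm(table)
    return table


def detected_guides(
    table: NormalizedTable | CountTable,
    library: GuideLibrary,
    gene: str,
    sample: str,
    detection_threshold: int = 1,
) -> int:
    """Number of a gene's guides with raw count >= threshold in a sample."""
    if detection_threshold < 1:
        raise ValueError("detection_threshold must be >= 1")
    norm = _as_normalized(table)
    if sample not in norm.raw.samples:
        raise KeyError(f"unknown sample {sample!r}")
    gids = library.guides_for_gene(gene)  # KeyError for unknown gene
    counts = norm.raw.counts[sample]
    return int((counts.loc[gids] >= detection_threshold).sum())


def gene_enrichment_score(
    table: NormalizedTable | CountTable,
    library: GuideLibrary,
    gene: str,
    sample: str,
    detection_threshold: int = 1,
    abundance_floor: float = 1.0,
    variant: str = "product",
    detected_only: bool = True,
) -> GeneEnrichment:
    """Score one gene in one selected sample.

    ``detected_only`` controls whether the abundance average runs over the
    detected guides (default) or all of the gene's library guides.
    """
    if abundance_floor <= 0:
        raise ValueError("abundance_floor must be > 0")
    if variant not in ("product", "division"):
        raise ValueError(f"unknown score variant {variant!r}")
    norm = _as_normalized(table)
    if sample not in norm.raw.samples:
        raise KeyError(f"unknown sample {sample!r}")
    gids = library.guides_for_gene(gene)
    n_library = len(gids)
    counts = norm.raw.counts[sample].loc[gids]
    detected = counts.index[counts >= detection_threshold]
    n_detected = len(detected)
    if n_detected == 0:
        return GeneEnrichment(gene, 0, n_library, 0.0, 0.0)
    pool = detected if detected_only else pd.Index(gids)
    avg = float(norm.values[sample].loc[pool].mean())
    log_term = math.log2(max(avg, abundance_floor))
    frac = n_detected / n_library
    if variant == "product":
        score = frac * log_term
    else:
        score = frac / log_term if log_term > 0 else 0.0
    return GeneEnrichment(gene, n_detected, n_library, avg, score)


def score_sample(
    table: NormalizedTable | CountTable,
    library: GuideLibrary,
    sample: str,
    detection_threshold: int = 1,
    abundance_floor: float = 1.0,
    variant: str = "product",
    min_detected: int = 1,
    detected_only: bool = True,
) -> list[GeneEnrichment]:
    """Score every gene in a sample and rank the result.

    ``min_detected`` pre-filters the ranking: genes with fewer detected
    guides keep their score but are pushed below all passing genes (score and
    tie-breaks still order them among themselves). Default 1, i.e. only
    fully undetected genes sink.
    """
    scores = [
        gene_enrichment_score(
            table,
            library,
            gene,
            sample,
            detection_threshold=detection_threshold,
            abundance_floor=abundance_floor,
            variant=variant,
            detected_only=detected_only,
        )
        for gene in library.gene_index
    ]
    passing = [s for s in scores if s.n_detected >= min_detected]
    failing = [s for s in scores if s.n_detected < min_detected]
    return rank_genes(passing, _tail=failing)


def rank_genes(
    scores: Iterable[GeneEnrichment],
    _tail: Iterable[GeneEnrichment] = (),
) -> list[GeneEnrichment]:
    """Sort by score desc, then n_detected desc, then gene symbol asc, and
    assign ranks 1..n. Duplicate gene entries are an error."""
    key = lambda s: (-s.score, -s.n_detected, s.gene)
    head = sorted(scores, key=key)
    tail = sorted(_tail, key=key)
    ordered = head + tail
    seen: set[str] = set()
    out = []
    for i, s in enumerate(ordered):
        if s.gene in seen:
            raise ValueError(f"duplicate gene entry {s.gene!r}")
        seen.add(s.gene)
        out.append(replace(s, rank=i + 1))
    return out


@dataclass
class HitCallResult:
    """Genes in the top-k of every dose arm, in rank order of the first arm."""

    rankings: dict[str, list[GeneEnrichment]]
    top_k: int
    hits: list[str]


def call_hits(
    per_dose_rankings: Mapping[str, Sequence[GeneEnrichment]],
    top_k: int = 10,
) -> HitCallResult:
    """Intersect the top-k gene sets of all dose arms.

    Requires at least two arms over an identical gene universe; an empty
    intersection is a valid (negative) result.
    """
    if len(per_dose_rankings) < 2:
        raise ValueError("need rankings for at least two dose arms")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    universes = {
        dose: frozenset(s.gene for s in ranking)
        for dose, ranking in per_dose_rankings.items()
    }
    first, *rest = universes.values()
    if any(u != first for u in rest):
        raise ValueError("dose arms cover different gene universes")

    top_sets = [
        {s.gene for s in ranking if s.rank is not None and s.rank <= top_k}
        for ranking in per_dose_rankings.values()
    ]
    common = set.intersection(*top_sets)
    first_arm = next(iter(per_dose_rankings.values()))
    hits = [s.gene for s in first_arm if s.gene in common]
    return HitCallResult(
        rankings={d: list(r) for d, r in per_dose_rankings.items()},
        top_k=top_k,
        hits=hits,
    )


def enrichment_report(
    result: HitCallResult, path: str | Path
) -> dict[str, pd.DataFrame]:
    """Write a per-gene TSV and return rank-vs-score series per dose arm.

    The TSV has one row per gene with per-dose n_detected, avg_abundance,
    score and rank columns plus an ``is_hit`` flag; the returned ``series``
    frames (rank, score, gene, is_hit per arm) are the data behind the
    waterfall plot screens are usually summarized with.
    """
    doses = list(result.rankings)
    first = result.rankings[doses[0]]
    genes = [s.gene for s in first]
    rows: dict[str, dict] = {g: {"gene": g} for g in genes}
    for dose in doses:
        for s in result.rankings[dose]:
            r = rows[s.gene]
            r[f"{dose}_n_detected"] = s.n_detected
            r[f"{dose}_avg_abundance"] = s.avg_abundance
            r[f"{dose}_score"] = s.score
            r[f"{dose}_rank"] = s.rank
    hitset = set(result.hits)
    for g in genes:
        rows[g]["is_hit"] = g in hitset
    df = pd.DataFrame([rows[g] for g in genes])
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")

    series = {
        dose: pd.DataFrame(
            {
                "rank": [s.rank for s in ranking],
                "score": [s.score for s in ranking],
                "gene": [s.gene for s in ranking],
                "is_hit": [s.gene in hitset for s in ranking],
            }
        )
        for dose, ranking in result.rankings.items()
    }
    return series
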