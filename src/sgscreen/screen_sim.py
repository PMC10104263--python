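"""Synthetic pooled CRISPR resistance-screen generator with known ground truth.

Emulates a GeCKO-style knockout screen in a drug-sensitive cell line: a
~6-guides-per-gene library with lognormal initial representation is
transduced at low MOI, bottlenecked by antibiotic selection, then put under
drug at two doses for a selection window. Guides of "planted" resistance
genes carry a survival multiplier s >= 1, so the true hit set is known and
every downstream stage (counting, scoring, hit calling) can be tested
against it. Sequencing counts are negative-binomial overdispersed; reads
can be emitted as FASTQ with constant vector flanks and substitution noise.

Selection is a single multiplicative survival step per dose arm, not a
birth-death process over the treatment window: one multiplier per dose is
the minimal model producing the enrichment structure the analysis is built
to detect. Multiply-infected cells are not modeled; MOI enters only as a
finite-cell multinomial bottleneck on the infected pool.

All randomness flows from ``config.seed`` through per-stage child streams,
so identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .library_io import (
    CountTable,
    GuideLibrary,
    GuideRecord,
    SampleDiagnostics,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Constant vector context around the guide in a sequencing read; the 5' piece
# is the end of the human U6 promoter region, the 3' piece the start of the
# sgRNA scaffold, as found in lentiviral guide-expression constructs.
DEFAULT_FLANK_5P = "TTGTGGAAAGGACGAAACACCG"
DEFAULT_FLANK_3P = "GTTTTAGAGCTAGAAATAGCAAG"


@dataclass
class ScreenSimConfig:
    """Full generative description of a synthetic screen.

    Parameters
    ----------
    n_genes, guides_per_gene
        Library shape; six guides per gene mirrors genome-scale knockout
        libraries.
    planted_genes
        gene -> selection advantage ``s`` (>= 1), the extra survival
        multiplier under drug for cells carrying that gene's guides.
    doses
        dose label -> baseline survival fraction for non-resistant cells
        over the drug-selection window. Defaults model a low and a high
        dose arm (e.g. 0.3 and 1 uM PARP-inhibitor for 14 days); the
        per-guide survival is capped at 1.
    moi
        Target multiplicity of infection; kept in the 0.3-0.4 range so most
        infected cells carry a single guide.
    cells_per_guide
        Initial coverage of the infected pool.
    representation_sigma
        Lognormal sigma of initial per-guide abundance (plasmid-pool skew).
    sequencing_depth
        Total reads per sample.
    dispersion
        Negative-binomial overdispersion alpha; variance = m + alpha*m^2.
        0 degenerates to Poisson.
    exact_depth
        If True, draw counts multinomially so each column sums exactly to
        ``sequencing_depth``.
    read_error_rate
        Per-base substitution probability for FASTQ emission (no indels).
    flank_5p, flank_3p
        Constant vector sequence around the guide in an emitted read.
    seed
        Master seed; every random stage derives its stream from it.
    """

    n_genes: int = 120
    guides_per_gene: int = 6
    planted_genes: dict[str, float] = field(default_factory=dict)
    doses: dict[str, float] = field(
        default_factory=lambda: {"dose_0.3uM": 0.05, "dose_1uM": 0.01}
    )
    moi: float = 0.35
    apply_moi_bottleneck: bool = True
    cells_per_guide: int = 300
    representation_sigma: float = 0.5
    sequencing_depth: int = 10_000_000
    dispersion: float = 0.1
    exact_depth: bool = False
    read_error_rate: float = 0.001
    flank_5p: str = DEFAULT_FLANK_5P
    flank_3p: str = DEFAULT_FLANK_3P
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.guides_per_gene < 1:
            raise ValueError("n_genes and guides_per_gene must be >= 1")
        if self.n_genes * self.guides_per_gene > 4**20:
            raise ValueError("library exceeds the number of distinct 20-mers")
        for gene, s in self.planted_genes.items():
            if s < 1:
                raise ValueError(f"planted gene {gene!r}: advantage s={s} < 1")
        for dose, surv in self.doses.items():
            if not 0 < surv <= 1:
                raise ValueError(f"dose {dose!r}: baseline survival {surv} not in (0,1]")
        if not 0 <= self.moi:
            raise ValueError("moi must be >= 0")
        if self.representation_sigma < 0:
            raise ValueError("representation_sigma must be >= 0")
        if self.sequencing_depth < 1:
            raise ValueError("sequencing_depth must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.read_error_rate <= 1:
            raise ValueError("read_error_rate must be in [0,1]")
        if not self.flank_5p or not self.flank_3p:
            raise ValueError("flanks must be non-empty")

    @property
    def n_guides(self) -> int:
        return self.n_genes * self.guides_per_gene

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenSimConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _rng(config: ScreenSimConfig, *stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), *stage]))


def make_library(config: ScreenSimConfig) -> GuideLibrary:
    """Random library of ``n_genes * guides_per_gene`` distinct 20-mers.

    Gene symbols are ``GENE0001..``; guide ids ``<gene>_g<k>``. Deterministic
    under ``config.seed``.
    """
    config.validate()
    rng = _rng(config, 0)
    n = config.n_guides
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n:
        batch = rng.integers(0, 4, size=(n - len(seqs) + 16, 20))
        for row in batch:
            s = _BASES[row].tobytes().decode("ascii")
            if s not in seen:
                seen.add(s)
                seqs.append(s)
                if len(seqs) == n:
                    break
    width = max(4, len(str(config.n_genes)))
    records = []
    i = 0
    for g in range(config.n_genes):
        gene = f"GENE{g + 1:0{width}d}"
        for k in range(config.guides_per_gene):
            records.append(
                GuideRecord(guide_id=f"{gene}_g{k + 1}", sequence=seqs[i], gene=gene)
            )
            i += 1
    lib = GuideLibrary(records)
    unknown = set(config.planted_genes) - set(lib.gene_index)
    if unknown:
        raise ValueError(f"planted genes not in simulated gene set: {sorted(unknown)}")
    return lib


def simulate_initial_representation(
    config: ScreenSimConfig, library: GuideLibrary
) -> np.ndarray:
    """Lognormal(0, sigma) per-guide abundance, normalized to sum 1.

    sigma = 0 collapses to the exactly uniform vector.
    """
    config.validate()
    rng = _rng(config, 1)
    n = len(library)
    logs = rng.normal(0.0, config.representation_sigma, size=n)
    w = np.exp(logs)
    return w / w.sum()


def apply_moi_bottleneck(
    abundance: np.ndarray, config: ScreenSimConfig
) -> np.ndarray:
    """Finite-cell bottleneck of the infected, antibiotic-selected pool.

    At MOI m a Poisson fraction 1 - e^-m of cells is infected and survives
    antibiotic selection; guides are assigned to that many cells
    multinomially, and the empirical cell fractions become the working
    abundance. Guides drawn zero times drop out of the screen.
    """
    infected_frac = 1.0 - np.exp(-config.moi)
    n_cells = int(round(len(abundance) * config.cells_per_guide * infected_frac))
    if n_cells < 1:
        raise ValueError("MOI bottleneck leaves no infected cells")
    rng = _rng(config, 2)
    cells = rng.multinomial(n_cells, abundance)
    return cells / cells.sum()


def survival_multipliers(
    config: ScreenSimConfig, library: GuideLibrary, dose: str
) -> np.ndarray:
    """Per-guide survival fraction under a dose, capped at 1."""
    if dose not in config.doses:
        raise KeyError(f"unknown dose label {dose!r}; have {list(config.doses)}")
    base = config.doses[dose]
    mult = np.full(len(library), base)
    for i, rec in enumerate(library):
        s = config.planted_genes.get(rec.gene)
        if s is not None:
            mult[i] = min(1.0, base * s)
    return mult


def simulate_selection(
    abundance: np.ndarray,
    config: ScreenSimConfig,
    dose: str,
    library: GuideLibrary,
) -> np.ndarray:
    """Expected post-selection abundance: mass times survival, renormalized."""
    if not np.isclose(abundance.sum(), 1.0):
        raise ValueError("abundance must sum to 1")
    post = abundance * survival_multipliers(config, library, dose)
    total = post.sum()
    if total <= 0:
        raise ValueError("selection annihilated the pool")
    return post / total


def simulate_counts(
    abundance: np.ndarray,
    config: ScreenSimConfig,
    sample_index: int = 0,
) -> np.ndarray:
    """Sequencing counts for one sample from an abundance vector.

    Negative binomial with mean depth*abundance and variance m + alpha*m^2;
    alpha = 0 degenerates to Poisson; ``exact_depth`` switches to a
    multinomial draw whose column sum is exactly the depth.
    """
    config.validate()
    rng = _rng(config, 3, sample_index)
    m = config.sequencing_depth * np.asarray(abundance, dtype=float)
    if config.exact_depth:
        return rng.multinomial(config.sequencing_depth, abundance)
    alpha = config.dispersion
    if alpha == 0:
        return rng.poisson(m)
    n_param = 1.0 / alpha
    counts = np.zeros(len(m), dtype=np.int64)
    pos = m > 0
    p = n_param / (n_param + m[pos])
    counts[pos] = rng.negative_binomial(n_param, p)
    return counts


@dataclass
class SimTruth:
    """Ground truth of a simulated screen: config echo, per-guide initial and
    expected post-selection abundance per dose, realized counts, planted genes."""

    config: ScreenSimConfig
    initial_abundance: pd.Series
    post_selection: dict[str, pd.Series]
    counts: dict[str, pd.Series]
    planted_genes: list[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "initial_abundance": self.initial_abundance.to_dict(),
            "post_selection": {d: s.to_dict() for d, s in self.post_selection.items()},
            "counts": {d: s.astype(int).to_dict() for d, s in self.counts.items()},
            "planted_genes": self.planted_genes,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class ScreenSimResult:
    library: GuideLibrary
    counts: CountTable
    truth: SimTruth


def run_screen(config: ScreenSimConfig) -> ScreenSimResult:
    """Run the full generative pipeline: library, representation, optional MOI
    bottleneck, per-dose selection, and per-dose sequencing counts."""
    config.validate()
    library = make_library(config)
    init = simulate_initial_representation(config, library)
    pool = apply_moi_bottleneck(init, config) if config.apply_moi_bottleneck else init

    index = pd.Index(library.guide_ids, name="guide_id")
    post: dict[str, pd.Series] = {}
    count_cols: dict[str, pd.Series] = {}
    diagnostics: dict[str, SampleDiagnostics] = {}
    for j, dose in enumerate(config.doses):
        ab = simulate_selection(pool, config, dose, library)
        post[dose] = pd.Series(ab, index=index)
        c = simulate_counts(ab, config, sample_index=j)
        count_cols[dose] = pd.Series(c, index=index)
        total = int(c.sum())
        diagnostics[dose] = SampleDiagnostics(total_reads=total, assigned=total)
    counts = CountTable(counts=pd.DataFrame(count_cols), diagnostics=diagnostics)
    truth = SimTruth(
        config=config,
        initial_abundance=pd.Series(pool, index=index),
        post_selection=post,
        counts=count_cols,
        planted_genes=sorted(config.planted_genes),
    )
    return ScreenSimResult(library=library, counts=counts, truth=truth)


def emit_fastq(
    counts: Mapping[str, int] | pd.Series,
    library: GuideLibrary,
    config: ScreenSimConfig,
    path: str | Path,
    sample_index: int = 0,
) -> None:
    """Write one read per count unit as Phred+33 FASTQ.

    Each read is flank_5p + guide + flank_3p with per-base substitution noise
    at ``read_error_rate``; read order is shuffled deterministically under the
    config seed. Read titles carry the originating guide
    (``sim_<i> origin=<guide_id>``) so assignments can be audited against
    truth. ``.gz`` paths are gzip-compressed.
    """
    config.validate()
    counts = pd.Series(counts)
    if (counts < 0).any() or not np.all(counts == counts.astype(int)):
        raise ValueError("counts must be non-negative integers")
    rng = _rng(config, 4, sample_index)
    flank5, flank3 = config.flank_5p.upper(), config.flank_3p.upper()
    read_len = len(flank5) + 20 + len(flank3)

    guide_order = {gid: i for i, gid in enumerate(library.guide_ids)}
    templates = np.empty((len(library), read_len), dtype=np.uint8)
    for i, rec in enumerate(library):
        templates[i] = np.frombuffer(
            (flank5 + rec.sequence + flank3).encode("ascii"), dtype=np.uint8
        )
    code = np.full(256, 255, dtype=np.uint8)
    for v, b in enumerate(b"ACGT"):
        code[b] = v
    templates_code = code[templates]

    origin = np.repeat(
        [guide_order[g] for g in counts.index], counts.astype(int).to_numpy()
    )
    rng.shuffle(origin)
    reads = templates_code[origin]
    if config.read_error_rate > 0 and reads.size:
        mask = rng.random(reads.shape) < config.read_error_rate
        shift = rng.integers(1, 4, size=int(mask.sum()))
        reads[mask] = (reads[mask] + shift) % 4

    qual = "I" * read_len
    ids = library.guide_ids
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt", encoding="utf-8") as fh:
        for i, (gi, row) in enumerate(zip(origin, reads)):
            fh.write(
                f"@sim_{i:08d} origin={ids[gi]}\n"
                f"{_BASES[row].tobytes().decode('ascii')}\n+\n{qual}\n"
            )


def with_seed(config: ScreenSimConfig, seed: int) -> ScreenSimConfig:
    """Copy of a config with a different master seed."""
    return replace(config, seed=int(seed))
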