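"""Per-gene enrichment scoring, ranking and two-dose hit calling."""

import math

import numpy as np
import pandas as pd
import pytest

from sgscreen import (
    GeneEnrichment,
    GuideLibrary,
    GuideRecord,
    call_hits,
    detected_guides,
    enrichment_report,
    gene_enrichment_score,
    normalize_rpm,
    rank_genes,
    score_sample,
)

from conftest import make_count_table


def _library(genes: dict[str, int]) -> GuideLibrary:
    rng = np.random.default_rng(1)
    bases = np.array(list("ACGT"))
    records = []
    for gene, n in genes.items():
        for k in range(n):
            records.append(
                GuideRecord(f"{gene}_g{k + 1}", "".join(rng.choice(bases, 20)), gene)
            )
    return GuideLibrary(records)


@pytest.fixture
def six_guide_setup():
    """Gene A: six guides at 256 RPM each; one filler guide absorbs the rest
    of a 1e6-read sample, so A's detected-guide mean RPM is exactly 256."""
    lib = _library({"A": 6, "FILLER": 1})
    counts = [256] * 6 + [1_000_000 - 6 * 256]
    table = make_count_table({"sel": counts}, lib.guide_ids)
    return lib, normalize_rpm(table)


class TestDetectedGuides:
    @pytest.mark.parametrize(
        "threshold,expected", [(1, 2), (5, 1), (11, 0)]
    )
    def test_threshold_semantics(self, threshold, expected):
        lib = _library({"A": 6})
        table = make_count_table({"s": [10, 3, 0, 0, 0, 0]}, lib.guide_ids)
        assert detected_guides(table, lib, "A", "s", threshold) == expected

    def test_unknown_gene_and_sample(self):
        lib = _library({"A": 2})
        table = make_count_table({"s": [1, 1]}, lib.guide_ids)
        with pytest.raises(KeyError):
            detected_guides(table, lib, "NOPE", "s")
        with pytest.raises(KeyError):
            detected_guides(table, lib, "A", "nope")


class TestGeneEnrichmentScore:
    def test_full_detection_at_256_rpm(self, six_guide_setup):
        lib, norm = six_guide_setup
        s = gene_enrichment_score(norm, lib, "A", "sel")
        assert s.n_detected == 6 and s.n_library == 6
        assert s.avg_abundance == pytest.approx(256.0)
        assert s.score == pytest.approx(8.0)  # 1.0 * log2(256)

    def test_half_detection_at_16_rpm(self):
        lib = _library({"A": 6, "FILLER": 1})
        counts = [16, 16, 16, 0, 0, 0, 1_000_000 - 48]
        norm = normalize_rpm(make_count_table({"sel": counts}, lib.guide_ids))
        s = gene_enrichment_score(norm, lib, "A", "sel")
        assert s.n_detected == 3
        assert s.score == pytest.approx(0.5 * 4.0)

    def test_zero_detected_scores_zero(self):
        lib = _library({"A": 6, "FILLER": 1})
        counts = [0] * 6 + [1_000_000]
        norm = normalize_rpm(make_count_table({"sel": counts}, lib.guide_ids))
        s = gene_enrichment_score(norm, lib, "A", "sel")
        assert s.score == 0.0 and s.n_detected == 0

    def test_abundance_floor_keeps_score_nonnegative(self):
        lib = _library({"A": 2, "FILLER": 1})
        counts = [1, 0, 3_999_999]  # guide at 0.25 RPM
        norm = normalize_rpm(make_count_table({"sel": counts}, lib.guide_ids))
        s = gene_enrichment_score(norm, lib, "A", "sel", abundance_floor=1.0)
        assert s.score == 0.0  # log2(max(0.25, 1)) = 0

    def test_division_variant(self, six_guide_setup):
        lib, norm = six_guide_setup
        s = gene_enrichment_score(norm, lib, "A", "sel", variant="division")
        assert s.score == pytest.approx(1.0 / 8.0)

    def test_all_guides_mean_option(self):
        lib = _library({"A": 2, "FILLER": 1})
        counts = [100, 0, 999_900]
        norm = normalize_rpm(make_count_table({"sel": counts}, lib.guide_ids))
        detected = gene_enrichment_score(norm, lib, "A", "sel")
        overall = gene_enrichment_score(norm, lib, "A", "sel", detected_only=False)
        assert detected.avg_abundance == pytest.approx(100.0)
        assert overall.avg_abundance == pytest.approx(50.0)

    def test_score_monotone_in_detection_and_abundance(self):
        lib = _library({"A": 6, "FILLER": 1})
        prev = -1.0
        for k in range(1, 7):
            counts = [64] * k + [0] * (6 - k) + [1_000_000 - 64 * k]
            norm = normalize_rpm(make_count_table({"s": counts}, lib.guide_ids))
            sc = gene_enrichment_score(norm, lib, "A", "s").score
            assert sc > prev
            prev = sc
        prev = -1.0
        for rpm in (4, 16, 64, 256):
            counts = [rpm] * 6 + [1_000_000 - rpm * 6]
            norm = normalize_rpm(make_count_table({"s": counts}, lib.guide_ids))
            sc = gene_enrichment_score(norm, lib, "A", "s").score
            assert sc > prev
            prev = sc

    def test_scale_invariance(self):
        """Multiplying all counts in a sample leaves RPM and scores unchanged."""
        lib = _library({"A": 3, "B": 3})
        base = [5, 9, 0, 40, 2, 11]
        for factor in (1, 7):
            counts = [c * factor for c in base]
            norm = normalize_rpm(make_count_table({"s": counts}, lib.guide_ids))
            if factor == 1:
                ref = {
                    g: gene_enrichment_score(norm, lib, g, "s").score
                    for g in ("A", "B")
                }
            else:
                for g in ("A", "B"):
                    assert gene_enrichment_score(norm, lib, g, "s").score == (
                        pytest.approx(ref[g], rel=1e-12)
                    )

    def test_brute_force_oracle_small_table(self):
        """Independent straight-line reimplementation on a 20-gene table."""
        rng = np.random.default_rng(17)
        lib = _library({f"G{i:02d}": 6 for i in range(20)})
        counts = rng.integers(0, 2_000, size=120)
        counts[rng.choice(120, 30, replace=False)] = 0
        table = make_count_table({"s": counts.tolist()}, lib.guide_ids)
        norm = normalize_rpm(table)
        total = counts.sum()
        for gene in lib.gene_index:
            gids = lib.guides_for_gene(gene)
            raw = [counts[lib.guide_ids.index(g)] for g in gids]
            det = [c for c in raw if c >= 1]
            if not det:
                expected = 0.0
            else:
                avg_rpm = sum(c / total * 1e6 for c in det) / len(det)
                expected = len(det) / len(gids) * math.log2(max(avg_rpm, 1.0))
            got = gene_enrichment_score(norm, lib, gene, "s").score
            assert got == pytest.approx(expected, abs=1e-12)


class TestRankGenes:
    def _ge(self, gene, score, n_detected=6):
        return GeneEnrichment(gene, n_detected, 6, 100.0, score)

    def test_basic_ordering(self):
        ranked = rank_genes([self._ge("A", 8.0), self._ge("B", 2.0), self._ge("C", 0.0)])
        assert [(s.gene, s.rank) for s in ranked] == [("A", 1), ("B", 2), ("C", 3)]

    def test_tie_broken_by_n_detected_then_symbol(self):
        ranked = rank_genes([
            self._ge("B", 5.0, n_detected=3),
            self._ge("A", 5.0, n_detected=6),
            self._ge("C", 5.0, n_detected=3),
        ])
        assert [s.gene for s in ranked] == ["A", "B", "C"]

    def test_duplicate_gene_rejected(self):
        with pytest.raises(ValueError):
            rank_genes([self._ge("A", 1.0), self._ge("A", 2.0)])

    def test_200_gene_sort_oracle(self):
        rng = np.random.default_rng(23)
        scores = [
            GeneEnrichment(f"G{i:03d}", int(rng.integers(1, 7)), 6, 10.0,
                           float(rng.choice([0.0, 1.5, 3.25, 7.0])))
            for i in range(200)
        ]
        ranked = rank_genes(scores)
        oracle = sorted(scores, key=lambda s: (-s.score, -s.n_detected, s.gene))
        assert [s.gene for s in ranked] == [s.gene for s in oracle]
        assert [s.rank for s in ranked] == list(range(1, 201))


class TestCallHits:
    def _ranking(self, genes):
        return rank_genes(
            [GeneEnrichment(g, 6, 6, 100.0, float(len(genes) - i))
             for i, g in enumerate(genes)]
        )

    def test_intersection(self):
        r1 = self._ranking(["A", "B", "C", "D"])
        r2 = self._ranking(["B", "A", "D", "C"])
        res = call_hits({"d1": r1, "d2": r2}, top_k=3)
        assert res.hits == ["A", "B"]  # first-arm rank order

    def test_disjoint_top_sets_empty(self):
        r1 = self._ranking(["A", "B", "C", "D"])
        r2 = self._ranking(["D", "C", "B", "A"])
        res = call_hits({"d1": r1, "d2": r2}, top_k=2)
        assert res.hits == []

    def test_mismatched_universe_rejected(self):
        r1 = self._ranking(["A", "B"])
        r2 = self._ranking(["A", "C"])
        with pytest.raises(ValueError, match="universe"):
            call_hits({"d1": r1, "d2": r2}, top_k=2)

    def test_single_arm_rejected(self):
        with pytest.raises(ValueError):
            call_hits({"d1": self._ranking(["A", "B"])}, top_k=1)


class TestEnrichmentReport:
    def test_tsv_round_trip_and_hit_flags(self, tmp_path):
        genes = ["A", "B", "C"]
        r1 = rank_genes([GeneEnrichment(g, 6, 6, 2.0 ** (8 - i), 8.0 - i)
                         for i, g in enumerate(genes)])
        r2 = rank_genes([GeneEnrichment(g, 6, 6, 2.0 ** (8 - i), 7.5 - i)
                         for i, g in enumerate(genes)])
        res = call_hits({"d1": r1, "d2": r2}, top_k=2)
        path = tmp_path / "report.tsv"
        series = enrichment_report(res, path)
        df = pd.read_csv(path, sep="\t")
        assert len(df) == 3
        assert set(df.columns) >= {"gene", "d1_score", "d2_rank", "is_hit"}
        assert list(df[df.is_hit].gene) == res.hits
        for i, g in enumerate(genes):
            assert df.loc[df.gene == g, "d1_score"].iloc[0] == pytest.approx(
                8.0 - i, abs=1e-9
            )
        assert list(series["d1"]["rank"]) == [1, 2, 3]


class TestScoreSample:
    def test_planted_genes_lead(self, small_config):
        from sgscreen import normalize_rpm, run_screen

        res = run_screen(small_config)
        norm = normalize_rpm(res.counts)
        for dose in small_config.doses:
            ranking = score_sample(norm, res.library, dose)
            top2 = {s.gene for s in ranking[:2]}
            assert top2 == {"GENE0001", "GENE0002"}

    def test_min_detected_filter_pushes_genes_down(self):
        lib = _library({"A": 3, "B": 3})
        counts = [1, 0, 0, 5, 5, 5]  # A: 1 detected guide; B: 3
        table = make_count_table({"s": counts}, lib.guide_ids)
        ranking = score_sample(table, lib, "s", min_detected=2)
        assert [s.gene for s in ranking] == ["B", "A"]
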