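import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromdomain import itraq, simulate
from chromdomain.errors import AnalysisError
from chromdomain.io import AnnotationTable, QuantTable
from chromdomain.itraq import (EnrichmentSummary, ProteinRatio, Thresholds,
                               Tier)


def quant_from_ratios(spec):
    """Build a QuantTable from {(rep, protein): [peptide ratios]} with
    control intensity fixed at 100."""
    rows = []
    for (rep, pid), ratios in spec.items():
        for k, r in enumerate(ratios):
            rows.append({"replicate_id": rep, "protein_id": pid,
                         "peptide_seq": f"{pid}_{k}",
                         "114": 100.0, "115": 100.0 * r})
    return QuantTable(pd.DataFrame(rows), ("114", "115"))


class TestProteinRatio:
    def test_constant_peptide_ratios(self):
        q = quant_from_ratios({("r1", "P1"): [2.0, 2.0, 2.0]})
        [pr] = itraq.protein_ratio_from_peptides(q, "115", "114")
        assert pr.raw_ratio == pytest.approx(2.0)
        assert pr.n_peptides == 3

    def test_median_of_skewed_ratios(self):
        q = quant_from_ratios({("r1", "P1"): [1.0, 2.0, 9.0]})
        [pr] = itraq.protein_ratio_from_peptides(q, "115", "114")
        assert pr.raw_ratio == pytest.approx(2.0)

    def test_mean_aggregation_selectable(self):
        q = quant_from_ratios({("r1", "P1"): [1.0, 2.0, 9.0]})
        [pr] = itraq.protein_ratio_from_peptides(q, "115", "114",
                                                 aggregation="mean")
        assert pr.raw_ratio == pytest.approx(4.0)

    def test_all_zero_control_excluded(self, caplog):
        rows = [{"replicate_id": "r1", "protein_id": "P1",
                 "peptide_seq": "A", "114": 0.0, "115": 10.0}]
        q = QuantTable(pd.DataFrame(rows), ("114", "115"))
        assert itraq.protein_ratio_from_peptides(q, "115", "114") == []

    def test_matches_brute_force_on_random_table(self):
        rng = np.random.default_rng(7)
        spec = {}
        for rep in ("r1", "r2"):
            for p in range(8):
                spec[(rep, f"P{p}")] = list(
                    rng.lognormal(0, 0.5, rng.integers(1, 6)))
        q = quant_from_ratios(spec)
        got = {(pr.replicate_id, pr.protein_id): pr.raw_ratio
               for pr in itraq.protein_ratio_from_peptides(q, "115", "114")}
        for key, ratios in spec.items():
            assert got[key] == pytest.approx(float(np.median(ratios)),
                                             rel=1e-12)


class TestBackgroundCorrection:
    annot = AnnotationTable({"BG1": "housekeeping",
                             "BG2": "ribosomal protein",
                             "X1": "histones"})

    def test_unit_background(self):
        ratios = [ProteinRatio("BG1", "r1", 1.0, 1),
                  ProteinRatio("BG2", "r1", 1.0, 1)]
        assert itraq.background_factor(ratios, self.annot, "r1") == 1.0

    def test_mean_of_background(self):
        ratios = [ProteinRatio("BG1", "r1", 0.5, 1),
                  ProteinRatio("BG2", "r1", 1.5, 1)]
        assert itraq.background_factor(ratios, self.annot, "r1") == 1.0

    def test_missing_background_raises(self):
        ratios = [ProteinRatio("X1", "r1", 2.0, 1)]
        with pytest.raises(AnalysisError, match="annotation"):
            itraq.background_factor(ratios, self.annot, "r1")

    def test_recovers_global_bias(self):
        rng = np.random.default_rng(11)
        g = 2.0
        ratios = [ProteinRatio(f"BG{i}", "r1",
                               g * rng.lognormal(0, 0.1), 1)
                  for i in range(1, 3)] + [
            ProteinRatio(f"B{i}", "r1", g * rng.lognormal(0, 0.1), 1)
            for i in range(200)]
        annot = AnnotationTable({r.protein_id: "housekeeping"
                                 for r in ratios})
        factor = itraq.background_factor(ratios, annot, "r1")
        assert factor == pytest.approx(g, rel=0.05)

    def test_correction_makes_background_mean_one(self):
        # every background protein in every replicate, equal weight: the
        # corrected background mean is algebraically 1
        ratios = []
        vals = {"r1": [0.8, 1.2, 2.0], "r2": [1.5, 3.0, 1.5]}
        for rep, vs in vals.items():
            for i, v in enumerate(vs):
                ratios.append(ProteinRatio(f"BG{i}", rep, v, 1))
        annot = AnnotationTable({f"BG{i}": "housekeeping" for i in range(3)})
        summaries = itraq.correct_and_summarize(ratios, annot)
        mean_bg = np.mean([s.avg_ratio for s in summaries])
        assert mean_bg == pytest.approx(1.0, abs=1e-9)

    def test_idempotence_factor_becomes_one(self):
        ratios = [ProteinRatio(f"BG{i}", "r1", v, 1)
                  for i, v in enumerate([0.5, 1.0, 4.5])]
        annot = AnnotationTable({f"BG{i}": "housekeeping" for i in range(3)})
        factor = itraq.background_factor(ratios, annot, "r1")
        corrected = [ProteinRatio(r.protein_id, r.replicate_id,
                                  r.raw_ratio / factor, r.n_peptides)
                     for r in ratios]
        assert itraq.background_factor(corrected, annot, "r1") == \
            pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance_of_corrected_ratios(self):
        spec = {("r1", "BG1"): [1.0, 1.1], ("r1", "BG2"): [0.9],
                ("r1", "X1"): [3.0, 2.8],
                ("r2", "BG1"): [1.0], ("r2", "BG2"): [1.2],
                ("r2", "X1"): [2.5]}
        q1 = quant_from_ratios(spec)
        q2 = quant_from_ratios(spec)
        # multiply replicate r1's domain channel by a constant
        mask = q2.data["replicate_id"] == "r1"
        q2.data.loc[mask, "115"] *= 7.3
        annot = AnnotationTable({"BG1": "housekeeping",
                                 "BG2": "ribosomal protein",
                                 "X1": "histones"})
        s1 = itraq.correct_and_summarize(
            itraq.protein_ratio_from_peptides(q1, "115", "114"), annot)
        s2 = itraq.correct_and_summarize(
            itraq.protein_ratio_from_peptides(q2, "115", "114"), annot)
        for a, b in zip(s1, s2):
            assert a.avg_ratio == pytest.approx(b.avg_ratio, abs=1e-9)


class TestSummaries:
    def test_average_and_total_peptides(self):
        ratios = [ProteinRatio("P1", r, 1.5, n)
                  for r, n in (("r1", 1), ("r2", 2), ("r3", 1))]
        ratios += [ProteinRatio("BG", r, 1.0, 1)
                   for r in ("r1", "r2", "r3")]
        annot = AnnotationTable({"BG": "housekeeping", "P1": "histones"})
        s = {x.protein_id: x
             for x in itraq.correct_and_summarize(ratios, annot)}
        assert s["P1"].avg_ratio == pytest.approx(1.5)
        assert s["P1"].total_peptides == 4

    def test_singleton_replicate_mean(self):
        ratios = [ProteinRatio("P1", "r1", 3.0, 1),
                  ProteinRatio("BG", "r1", 1.0, 1),
                  ProteinRatio("BG", "r2", 1.0, 1),
                  ProteinRatio("BG", "r3", 1.0, 1)]
        annot = AnnotationTable({"BG": "housekeeping", "P1": "histones"})
        s = {x.protein_id: x
             for x in itraq.correct_and_summarize(ratios, annot)}
        assert s["P1"].avg_ratio == pytest.approx(3.0)


class TestTierCalling:
    @pytest.mark.parametrize("ratio,peptides,expected", [
        (1.5, 2, Tier.STRICT),
        (1.5, 1, Tier.RELAXED_A),
        (1.2, 3, Tier.RELAXED_B),
        (1.0, 5, Tier.NONE),       # "greater than one" is strict
        (1.49, 2, Tier.RELAXED_B),
        (0.9, 10, Tier.NONE),
        (5.0, 3, Tier.STRICT),
    ])
    def test_boundary_conventions(self, ratio, peptides, expected):
        s = EnrichmentSummary("P", ratio, peptides)
        assert itraq.call_enrichment_tier(s) == expected

    @given(r1=st.floats(0.1, 10), r2=st.floats(0, 5),
           n1=st.integers(1, 20), n2=st.integers(0, 10))
    @settings(max_examples=200, deadline=None)
    def test_tier_monotonicity(self, r1, r2, n1, n2):
        lo = itraq.call_enrichment_tier(EnrichmentSummary("P", r1, n1))
        hi = itraq.call_enrichment_tier(
            EnrichmentSummary("P", r1 + r2, n1 + n2))
        assert hi >= lo


class TestComplexRule:
    def make_summaries(self):
        return [
            EnrichmentSummary("A", 2.0, 4, Tier.STRICT),
            EnrichmentSummary("B", 3.0, 2, Tier.STRICT),
            EnrichmentSummary("C", 1.6, 1, Tier.RELAXED_A),
        ]

    def test_coverage_and_depicted(self):
        cs = itraq.summarize_complex(
            "CPLX", {"A", "B", "C", "D"}, self.make_summaries())
        assert cs.coverage == pytest.approx(0.75)
        assert cs.depicted
        assert cs.avg_ratio == pytest.approx((2.0 + 3.0 + 1.6) / 3)
        assert cs.avg_peptides == pytest.approx(7 / 3)

    def test_below_half_not_depicted(self):
        members = {f"M{i}" for i in range(10)}
        summaries = [EnrichmentSummary(f"M{i}", 2.0, 3, Tier.STRICT)
                     for i in range(4)]
        cs = itraq.summarize_complex("CPLX", members, summaries)
        assert cs.coverage == pytest.approx(0.4)
        assert not cs.depicted

    def test_no_identified_member_flagged(self):
        cs = itraq.summarize_complex("CPLX", {"X", "Y"}, [])
        assert not cs.depicted
        assert cs.avg_ratio is None


class TestComposition:
    def test_fractions(self):
        summaries = [EnrichmentSummary(p, 1.0, 1) for p in "ABCD"]
        annot = AnnotationTable({"A": "histones", "B": "histones",
                                 "C": "ribosomal protein",
                                 "D": "ribosomal protein"})
        comp = itraq.functional_composition(summaries, annot)
        assert comp == {"histones": 0.5, "ribosomal protein": 0.5}

    def test_unannotated_proteins_are_other(self):
        summaries = [EnrichmentSummary("Z1", 1.0, 1)]
        comp = itraq.functional_composition(summaries, AnnotationTable({}))
        assert comp == {"other": 1.0}

    def test_fractions_sum_to_one_on_random_input(self):
        rng = np.random.default_rng(3)
        classes = ["histones", "housekeeping", "other", "RNA polymerases"]
        summaries = [EnrichmentSummary(f"P{i}", 1.0, 1) for i in range(57)]
        annot = AnnotationTable({f"P{i}": classes[rng.integers(4)]
                                 for i in range(57)})
        comp = itraq.functional_composition(summaries, annot)
        assert sum(comp.values()) == pytest.approx(1.0, abs=1e-12)


class TestParameterRecovery:
    def test_strict_calls_recover_spiked_proteins(self):
        """On the default synthetic dataset (200 background, 20 spiked at
        corrected ratio 3, CV 0.25, 3 replicates), the strict criterion
        finds the spikes without flooding the background."""
        quant, annot, truth = simulate.gen_itraq(
            simulate.ItraqSimConfig(seed=42))
        summaries, _, _ = itraq.run_enrichment(quant, annot, "115", "114")
        scores = simulate.score_itraq(truth, summaries, "STRICT")
        assert scores["sensitivity"] >= 0.85
        assert scores["specificity"] >= 0.95
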