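"""TPS arithmetic, discrepancy flagging, cutoff concordance, summaries."""

import numpy as np
import pytest

from peerce.tps import (CellCounts, ConcordanceConfig, ConcordanceRecord,
                        SlideScore, aggregate_patient, compute_tps,
                        concordance_report, correlation, cutoff_concordance,
                        flag_discrepancies, rater_summary,
                        reassessment_summary)


class TestComputeTps:
    def test_zero_numerator(self):
        assert compute_tps(CellCounts(0, 4366, 17)) == 0.0

    def test_cohort_annotation_counts(self):
        # 708 TC+ and 4366 TC- give a 13.95% aggregate score
        assert compute_tps(CellCounts(708, 4366, 2413)) == pytest.approx(13.95, abs=0.01)

    def test_all_positive(self):
        assert compute_tps(CellCounts(5, 0, 0)) == 100.0

    def test_no_tumor_cells_is_undefined_not_zero(self):
        assert compute_tps(CellCounts(0, 0, 250)) is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CellCounts(-1, 2, 3)

    def test_range_and_monotonicity(self, rng):
        for _ in range(50):
            pos, neg = int(rng.integers(0, 100)), int(rng.integers(1, 100))
            t = compute_tps(CellCounts(pos, neg, 0))
            assert 0.0 <= t <= 100.0
            assert compute_tps(CellCounts(pos + 1, neg, 0)) >= t
            assert compute_tps(CellCounts(pos, neg + 1, 0)) <= t

    def test_partition_invariance(self, rng):
        # re-tiling the same cells into different patch partitions
        total = CellCounts(37, 111, 52)
        parts = []
        remaining = [total.n_tcpos, total.n_tcneg, total.n_oc]
        for _ in range(4):
            take = [int(rng.integers(0, r + 1)) for r in remaining]
            parts.append(CellCounts(*take))
            remaining = [r - t for r, t in zip(remaining, take)]
        parts.append(CellCounts(*remaining))
        summed = CellCounts()
        for p in parts:
            summed = summed + p
        assert compute_tps(summed) == compute_tps(total)


class TestAggregate:
    def test_mean_of_two_slides(self):
        slides = [SlideScore("s1", "p", CellCounts(), tps_percent=12.33),
                  SlideScore("s2", "p", CellCounts(), tps_percent=11.39)]
        assert aggregate_patient(slides) == pytest.approx(11.86)

    def test_single_slide_identity(self):
        s = [SlideScore("s", "p", CellCounts(), tps_percent=7.5)]
        assert aggregate_patient(s) == 7.5

    def test_near_zero_pair(self):
        slides = [SlideScore("a", "p", CellCounts(), tps_percent=0.08),
                  SlideScore("b", "p", CellCounts(), tps_percent=0.20)]
        assert aggregate_patient(slides) == pytest.approx(0.14)

    def test_all_undefined_gives_none(self):
        slides = [SlideScore("a", "p", CellCounts(0, 0, 5))]
        assert aggregate_patient(slides) is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_patient([])


class TestFlagging:
    def test_printed_multislide_case(self):
        # AI 12.33 vs raters 2 / 30 / 20: only the 20 stays within 10 pp
        assert flag_discrepancies(12.33, [2, 30, 20]) == [True, True, False]

    def test_exactly_ten_points_not_flagged(self):
        assert flag_discrepancies(50.0, [60.0]) == [False]

    def test_identical_not_flagged(self):
        assert flag_discrepancies(33.3, [33.3]) == [False]

    def test_symmetry(self, rng):
        for _ in range(30):
            a, b = rng.uniform(0, 100, 2)
            assert flag_discrepancies(a, [b]) == flag_discrepancies(b, [a])


class TestCutoff:
    def test_two_discordant_of_63(self):
        ai = [10.0] * 61 + [30.0, 30.0]
        rater = [10.0] * 61 + [10.0, 10.0]
        acc, disc = cutoff_concordance(ai, rater)
        assert acc == pytest.approx(96.83, abs=0.01)
        assert disc == 2

    def test_four_discordant_of_63(self):
        ai = [10.0] * 59 + [30.0] * 4
        rater = [10.0] * 63
        acc, disc = cutoff_concordance(ai, rater)
        assert acc == pytest.approx(93.65, abs=0.01)
        assert disc == 4

    def test_identical_lists(self, rng):
        x = rng.uniform(0, 100, 20).tolist()
        acc, disc = cutoff_concordance(x, x)
        assert acc == 100.0 and disc == 0

    def test_boundary_is_positive(self):
        # exactly 20% binarizes positive on both sides
        acc, disc = cutoff_concordance([20.0], [20.0])
        assert acc == 100.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cutoff_concordance([1.0], [1.0, 2.0])


class TestCorrelation:
    def test_identity_is_one(self, rng):
        x = rng.uniform(0, 100, 10).tolist()
        assert correlation(x, x) == pytest.approx(1.0)

    def test_anticorrelation(self, rng):
        x = rng.uniform(0, 100, 10)
        assert correlation(x.tolist(), (100 - x).tolist()) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x, y = rng.uniform(0, 100, 15), rng.uniform(0, 100, 15)
        expect = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert correlation(x.tolist(), y.tolist()) == pytest.approx(expect)

    def test_zero_variance_is_null(self):
        assert correlation([5.0] * 5, [1.0, 2, 3, 4, 5]) is None

    def test_spearman_option(self, rng):
        x = rng.uniform(0, 100, 12)
        y = x ** 3  # monotone nonlinear
        cfg = ConcordanceConfig(correlation="spearman")
        assert correlation(x.tolist(), y.tolist(), cfg) == pytest.approx(1.0)


def _record(pid, flags, reassessed=None, revised=None, scores=None):
    n = len(flags)
    scores = scores or [10.0] * n
    return ConcordanceRecord(
        patient_id=pid, ai_tps=10.0, pathologist_tps=scores, flagged=flags,
        reassessed=reassessed if reassessed is not None else list(flags),
        revised_tps=revised if revised is not None else [None] * n)


class TestReassessment:
    def test_cohort_scale_rate(self):
        # 63 patients x 3 raters; 17 patients flagged, 33 assessments total
        records = [_record(f"p{i}", [True, True, False]) for i in range(16)]
        records += [_record("p16", [True, False, False])]
        records += [_record(f"p{i}", [False] * 3) for i in range(17, 63)]
        out = reassessment_summary(records)
        assert out["n_patients_flagged"] == 17
        assert out["n_assessments_flagged"] == 33
        assert out["n_assessments"] == 189
        assert out["pct_assessments"] == pytest.approx(17.46, abs=0.01)

    def test_no_flags_all_zero(self):
        records = [_record(f"p{i}", [False, False]) for i in range(5)]
        out = reassessment_summary(records)
        assert out["n_assessments_flagged"] == 0
        assert out["pct_assessments"] == 0.0
        assert out["n_patients_flagged"] == 0

    def test_matches_enumeration_oracle(self, rng):
        records = []
        for i in range(20):
            flags = [bool(rng.random() < 0.3) for _ in range(3)]
            records.append(_record(f"p{i}", flags))
        out = reassessment_summary(records)
        assert out["n_assessments_flagged"] == sum(sum(r.flagged) for r in records)
        assert out["n_patients_flagged"] == sum(1 for r in records if any(r.flagged))

    def test_changed_vs_unchanged(self):
        records = [
            _record("a", [True], reassessed=[True], revised=[25.0]),   # changed
            _record("b", [True], reassessed=[True], revised=[10.0]),   # same value
            _record("c", [True], reassessed=[True], revised=[None]),   # kept
        ]
        out = reassessment_summary(records)
        assert out["n_changed"] == 1 and out["n_unchanged"] == 2


class TestFlagRateMonotonicity:
    def test_flag_rate_increases_with_rater_noise(self):
        """With AI = truth and raters = truth + N(0, sd), the >10pp flag
        rate must grow with sd (200 simulated cohorts per noise level)."""
        from peerce.synth import simulate_pathologists
        rates = []
        for sd in (2.0, 6.0, 12.0):
            flagged = total = 0
            for rep in range(200):
                truth = list(np.random.default_rng(900 + rep).uniform(20, 80, 5))
                table = simulate_pathologists(truth, n_raters=1, noise_sd=sd,
                                              seed=int(sd * 1000) + rep)
                for t, s in zip(truth, table["tps"]):
                    flagged += abs(t - s) > 10
                    total += 1
            rates.append(flagged / total)
        assert rates[0] < rates[1] < rates[2]


def test_concordance_report_roundtrip():
    import pandas as pd

    ai = {"p1": 12.33, "p2": 50.0, "p3": 5.0}
    table = pd.DataFrame([
        {"patient_id": p, "rater_id": r, "tps": v}
        for p, vals in {"p1": [2, 30, 20], "p2": [55, 45, 18], "p3": [5, 6, 7]}.items()
        for r, v in zip(["r1", "r2", "r3"], vals)])
    report, summary, records = concordance_report(ai, table)
    assert len(report) == 9
    p1 = report[report.patient_id == "p1"].sort_values("rater_id")
    assert p1["flagged"].tolist() == [True, True, False]
    assert summary["reassessment"]["n_assessments"] == 9
    per = summary["raters"]["per_rater"]
    assert set(per) == {"r1", "r2", "r3"}
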