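import numpy as np
import pytest

from choroidnet import (PredictionRecord, aggregate_to_bscan, evaluate_records,
                        interval_table, mae, me, pcc, scatter_export)


def records_from(f, y, level="patch"):
    return [
        PredictionRecord(level=level, subject_id=f"S{i // 4:03d}", volume_id=f"V{i // 4:03d}",
                         slice_index=0, segment_index=i % 4,
                         predicted=float(fi), truth=float(yi))
        for i, (fi, yi) in enumerate(zip(f, y))
    ]


def random_records(rng, n, k=4):
    """n B-scans of k patches each with random predictions/truths."""
    out = []
    for b in range(n):
        for s in range(k):
            out.append(PredictionRecord(
                level="patch", subject_id=f"S{b:04d}", volume_id=f"V{b:04d}",
                slice_index=0, segment_index=s,
                predicted=float(rng.uniform(10, 150)), truth=float(rng.uniform(10, 150))))
    return out


class TestMetricOracles:
    def test_perfect_predictions(self):
        recs = records_from([5.0, 7.0], [5.0, 7.0])
        assert mae(recs) == (0.0, 0.0)

    def test_mae_symmetric_errors(self):
        assert mae(records_from([3, 7], [5, 5]))[0] == 2.0

    def test_me_offsetting_biases_cancel(self):
        value, sd = me(records_from([3, 7], [5, 5]))
        assert value == 0.0
        assert sd == 2.0

    def test_me_constant_offset(self):
        value, sd = me(records_from([8, 9, 10], [5, 6, 7]))
        assert value == pytest.approx(3.0) and sd == pytest.approx(0.0)

    def test_pcc_identity_and_antiphase(self):
        y = [1.0, 2.0, 3.0, 4.0]
        assert pcc(records_from(y, y)) == pytest.approx(1.0)
        centered_neg = [-v + 5.0 for v in y]
        assert pcc(records_from(centered_neg, y)) == pytest.approx(-1.0)

    def test_against_brute_force_recomputation(self):
        """mae/me/pcc match an independent two-pass textbook oracle to 1e-12."""
        rng = np.random.default_rng(7)
        f = rng.uniform(0, 150, 500)
        y = rng.uniform(0, 150, 500)
        recs = records_from(f, y)

        abs_errs = [abs(a - b) for a, b in zip(f, y)]
        errs = [a - b for a, b in zip(f, y)]
        n = len(errs)
        mean_ae = sum(abs_errs) / n
        sd_ae = (sum((e - mean_ae) ** 2 for e in abs_errs) / n) ** 0.5
        mean_e = sum(errs) / n
        sd_e = (sum((e - mean_e) ** 2 for e in errs) / n) ** 0.5
        fbar, ybar = sum(f) / n, sum(y) / n
        num = sum((a - fbar) * (b - ybar) for a, b in zip(f, y))
        den = (sum((a - fbar) ** 2 for a in f) * sum((b - ybar) ** 2 for b in y)) ** 0.5

        assert mae(recs)[0] == pytest.approx(mean_ae, abs=1e-12)
        assert mae(recs)[1] == pytest.approx(sd_ae, abs=1e-12)
        assert me(recs)[0] == pytest.approx(mean_e, abs=1e-12)
        assert me(recs)[1] == pytest.approx(sd_e, abs=1e-12)
        assert pcc(recs) == pytest.approx(num / den, abs=1e-12)
        assert -1.0 <= pcc(recs) <= 1.0

    def test_pcc_affine_invariance(self):
        rng = np.random.default_rng(8)
        f = rng.uniform(0, 100, 200)
        y = 0.7 * f + rng.normal(0, 5, 200)
        base = pcc(records_from(f, y))
        assert pcc(records_from(3.0 * f + 11.0, y)) == pytest.approx(base, abs=1e-12)
        assert pcc(records_from(f, 0.5 * y - 2.0)) == pytest.approx(base, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            mae([])
        with pytest.raises(ValueError, match="variance"):
            pcc(records_from([1.0, 1.0], [2.0, 3.0]))


class TestIntervalTable:
    def test_one_record_per_bin(self):
        recs = records_from([1, 6, 11, 16], [0, 0, 0, 0])
        assert np.array_equal(interval_table(recs), [0.25, 0.25, 0.25, 0.25])

    def test_boundary_is_inclusive_on_the_left_bin(self):
        recs = records_from([5.0, 5.0], [0.0, 0.0])
        assert np.array_equal(interval_table(recs), [1.0, 0.0, 0.0, 0.0])

    def test_against_counting_oracle_and_sums_to_one(self):
        rng = np.random.default_rng(9)
        ae = rng.uniform(0, 30, 1000)
        recs = records_from(ae, np.zeros(1000))
        table = interval_table(recs)
        counts = [0, 0, 0, 0]
        for e in ae:
            if e <= 5:
                counts[0] += 1
            elif e <= 10:
                counts[1] += 1
            elif e <= 15:
                counts[2] += 1
            else:
                counts[3] += 1
        assert np.array_equal(table, np.array(counts) / 1000)
        assert table.sum() == pytest.approx(1.0, abs=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(10)
        ae = rng.uniform(0, 30, 100)
        recs = records_from(ae, np.zeros(100))
        shuffled = list(recs)
        rng.shuffle(shuffled)
        assert np.array_equal(interval_table(recs), interval_table(shuffled))


class TestAggregation:
    def test_me_identical_across_levels_with_equal_groups(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            recs = random_records(rng, n=int(rng.integers(2, 8)), k=int(rng.integers(1, 6)))
            bscan = aggregate_to_bscan(recs)
            assert me(bscan)[0] == pytest.approx(me(recs)[0], abs=1e-9)
            assert mae(bscan)[0] <= mae(recs)[0] + 1e-12  # Jensen

    def test_single_patch_groups_preserve_values(self):
        recs = random_records(np.random.default_rng(12), n=5, k=1)
        bscan = aggregate_to_bscan(recs)
        assert sorted(r.predicted for r in bscan) == sorted(r.predicted for r in recs)
        assert sorted(r.truth for r in bscan) == sorted(r.truth for r in recs)

    def test_incomplete_group_names_the_bscan(self):
        recs = random_records(np.random.default_rng(13), n=3, k=4)
        with pytest.raises(ValueError, match="S0002"):
            aggregate_to_bscan(recs[:-1])

    def test_group_means(self):
        recs = random_records(np.random.default_rng(14), n=2, k=4)
        bscan = {r.subject_id: r for r in aggregate_to_bscan(recs)}
        for sid in ("S0000", "S0001"):
            members = [r for r in recs if r.subject_id == sid]
            assert bscan[sid].predicted == pytest.approx(
                np.mean([m.predicted for m in members]), abs=1e-12)
            assert bscan[sid].truth == pytest.approx(
                np.mean([m.truth for m in members]), abs=1e-12)


class TestReportsAndScatter:
    def test_report_invariants(self):
        recs = random_records(np.random.default_rng(15), n=30, k=4)
        report = evaluate_records(recs, "patch")
        assert sum(report.interval_percentages) == pytest.approx(1.0, abs=1e-9)
        assert -1.0 <= report.pcc <= 1.0
        assert report.mae >= abs(report.me)
        assert report.n_samples == 120

    def test_scatter_round_trip(self, tmp_path):
        """Re-importing the scatter CSV reproduces the metrics exactly."""
        recs = random_records(np.random.default_rng(16), n=20, k=2)
        path = tmp_path / "scatter.csv"
        df = scatter_export(recs, csv_path=path)
        assert len(df) == len(recs)

        import pandas as pd
        back = pd.read_csv(path)
        rebuilt = [
            PredictionRecord(level="patch", subject_id=str(i), volume_id=str(i),
                             slice_index=0, segment_index=0,
                             predicted=row.prediction, truth=row.truth)
            for i, row in enumerate(back.itertuples())
        ]
        assert mae(rebuilt) == pytest.approx(mae(recs), abs=1e-12)
        assert me(rebuilt) == pytest.approx(me(recs), abs=1e-12)
        assert pcc(rebuilt) == pytest.approx(pcc(recs), abs=1e-12)

    def test_identity_predictions_on_identity_line(self, tmp_path):
        y = np.linspace(10, 100, 20)
        recs = records_from(y, y)
        df = scatter_export(recs, figure_path=tmp_path / "fig.png")
        assert np.array_equal(df["truth"], df["prediction"])
        assert (tmp_path / "fig.png").exists()

    def test_markdown_table_mentions_all_metrics(self):
        recs = random_records(np.random.default_rng(17), n=10, k=4)
        text = evaluate_records(recs, "bscan").to_markdown()
        for token in ("MAE", "ME", "PCC", "AE <= 5"):
            assert token in text
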