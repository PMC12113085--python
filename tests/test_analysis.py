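"""Reliability statistics: agreement, repeats, kappa, Wilson, order, sessions."""

from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd
import pytest

from blindval import (ConfusionMatrix, DEFAULT_SCHEME, ProvenanceRecord,
                      ResponseLog, ValidationResponse, agreement_by_source,
                      build_report, build_schedule, cohen_kappa,
                      confusion_from_repeats, detect_sessions, order_effect,
                      rater_metrics, stratified_dsc, wilson_ci)
from blindval.analysis import BINARY_LABELS
from blindval.errors import AnalysisError, IncompleteLogError

from test_design import grid_catalog

T0 = datetime(2024, 3, 4, 9, 0, tzinfo=timezone.utc)
SCHEME = DEFAULT_SCHEME


def make_log(entries, t0=T0, step=60.0, dwell=30.0):
    """Build (log, provenance) from (image, source, replicate, label) rows."""
    log = ResponseLog(scheme=SCHEME)
    prov_entries = {}
    for i, (img, src, rep, label) in enumerate(entries):
        pid = f"pid{i:04d}"
        prov_entries[pid] = (img, src, rep)
        shown = t0 + timedelta(seconds=i * step)
        log.append(ValidationResponse(pid, label, shown_at=shown,
                                      answered_at=shown + timedelta(seconds=dwell)))
    return log, ProvenanceRecord(prov_entries)


class TestWilson:
    def test_published_accuracy_interval(self):
        lo, hi = wilson_ci(277, 300, 0.95)
        assert (round(lo, 3), round(hi, 3)) == (0.888, 0.948)

    def test_zero_successes_lower_bound_is_zero(self):
        lo, _ = wilson_ci(0, 40, 0.95)
        assert lo == 0.0

    def test_rejects_empty_sample(self):
        with pytest.raises(AnalysisError):
            wilson_ci(0, 0)

    def test_monte_carlo_coverage(self):
        """Wilson interval covers the true p 93-97% of the time at 95%."""
        rng = np.random.default_rng(2024)
        hits = 0
        trials = 500
        for _ in range(trials):
            p = rng.uniform(0.05, 0.95)
            n = int(rng.integers(20, 400))
            x = rng.binomial(n, p)
            lo, hi = wilson_ci(x, n, 0.95)
            hits += lo <= p <= hi
        assert 0.93 <= hits / trials <= 0.97


class TestRaterMetrics:
    def test_first_validator_matrix_reproduces_published_metrics(self):
        m = rater_metrics(ConfusionMatrix(BINARY_LABELS, [[245, 12], [11, 32]]))
        assert round(m.accuracy, 3) == 0.923
        assert round(m.acc_ci_low, 3) == 0.888
        assert round(m.acc_ci_high, 3) == 0.948
        assert round(m.kappa, 3) == 0.691
        assert round(m.balanced_accuracy, 3) == 0.849
        assert round(m.f1, 3) == 0.955
        assert round(m.precision, 3) == 0.957
        assert round(m.recall, 3) == 0.953

    def test_second_validator_matrix_reproduces_published_metrics(self):
        m = rater_metrics(ConfusionMatrix(BINARY_LABELS, [[249, 4], [22, 25]]))
        assert round(m.accuracy, 3) == 0.913
        assert round(m.kappa, 3) == 0.611
        assert round(m.balanced_accuracy, 3) == 0.758
        assert round(m.f1, 3) == 0.950
        assert round(m.precision, 3) == 0.919
        assert round(m.recall, 3) == 0.984

    def test_perfect_diagonal(self):
        m = rater_metrics(ConfusionMatrix(BINARY_LABELS, [[50, 0], [0, 10]]))
        assert m.accuracy == 1.0 and m.kappa == 1.0

    def test_chance_level_agreement_gives_zero_kappa(self):
        # rows proportional to column marginals -> p_o == p_e
        m = rater_metrics(ConfusionMatrix(BINARY_LABELS, [[36, 24], [24, 16]]))
        assert m.kappa == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_marginals_flag_kappa_undefined(self):
        m = rater_metrics(ConfusionMatrix(BINARY_LABELS, [[30, 0], [0, 0]]))
        assert m.kappa is None

    def test_kappa_matches_sklearn_on_random_matrices(self):
        """Independent cross-check against scikit-learn on label vectors."""
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(5)
        for _ in range(20):
            counts = rng.integers(1, 30, size=(2, 2))
            cm = ConfusionMatrix(BINARY_LABELS, counts)
            first, second = [], []
            for i, a in enumerate(BINARY_LABELS):
                for j, b in enumerate(BINARY_LABELS):
                    first += [a] * counts[i, j]
                    second += [b] * counts[i, j]
            assert cohen_kappa(cm) == pytest.approx(
                cohen_kappa_score(first, second))


class TestAgreementBySource:
    def test_hand_counted_tallies(self):
        entries = [
            ("i1", "L1", 1, "correct"), ("i2", "L1", 1, "oversegmented"),
            ("i3", "L1", 1, "correct"), ("i4", "L1", 1, "correct"),
            ("i1", "L2", 1, "incorrect"), ("i2", "L2", 1, "correct"),
            ("i3", "L2", 1, "undersegmented"), ("i4", "L2", 1, "correct"),
            ("i1", "model", 1, "correct"), ("i2", "model", 1, "correct"),
            ("i3", "model", 1, "correct"), ("i4", "model", 1, "oversegmented"),
        ]
        log, prov = make_log(entries)
        out = agreement_by_source(log, prov, SCHEME)
        assert out.loc["L1", "percent_agree"] == 75.0
        assert out.loc["L2", "percent_agree"] == 50.0
        assert out.loc["model", "percent_agree"] == 75.0
        assert (out["total"] == 4).all()
        cat_cols = list(SCHEME.categories)
        assert (out[cat_cols].sum(axis=1) == out["total"]).all()

    def test_duplicates_excluded_from_denominator(self):
        entries = [("i1", "L1", 1, "correct"), ("i1", "L2", 1, "correct"),
                   ("i1", "L1", 2, "incorrect")]
        log, prov = make_log(entries)
        out = agreement_by_source(log, prov, SCHEME)
        assert out.loc["L1", "total"] == 1
        assert out.loc["L1", "percent_agree"] == 100.0

    def test_missing_first_pass_rejected_with_ids(self):
        entries = [("i1", "L1", 1, "correct"), ("i1", "L2", 1, "correct")]
        log, prov_full = make_log(entries + [("i2", "L1", 1, "correct")])
        partial = ResponseLog(scheme=SCHEME)
        for r in list(log)[:2]:
            partial.append(r)
        with pytest.raises(IncompleteLogError) as err:
            agreement_by_source(partial, prov_full, SCHEME)
        assert "i2/L1" in err.value.missing


class TestConfusionFromRepeats:
    def test_crafted_pairs_match_hand_count(self):
        entries = [
            # six duplicated items with known label pairs
            ("i1", "L1", 1, "correct"), ("i1", "L1", 2, "correct"),
            ("i2", "L1", 1, "correct"), ("i2", "L1", 2, "oversegmented"),
            ("i3", "L2", 1, "oversegmented"), ("i3", "L2", 2, "oversegmented"),
            ("i4", "L2", 1, "undersegmented"), ("i4", "L2", 2, "correct"),
            ("i5", "model", 1, "incorrect"), ("i5", "model", 2, "incorrect"),
            ("i6", "model", 1, "correct"), ("i6", "model", 2, "correct"),
        ]
        log, prov = make_log(entries)
        tables = confusion_from_repeats(log, prov, SCHEME)
        k = tables.overall.to_frame()
        assert k.loc["correct", "correct"] == 2
        assert k.loc["correct", "oversegmented"] == 1
        assert k.loc["oversegmented", "oversegmented"] == 1
        assert k.loc["undersegmented", "correct"] == 1
        assert k.loc["incorrect", "incorrect"] == 1
        assert tables.overall.total == 6
        b = tables.overall_binary.to_frame()
        assert b.loc["agree", "agree"] == 2
        assert b.loc["agree", "disagree"] == 1
        assert b.loc["disagree", "agree"] == 1
        assert b.loc["disagree", "disagree"] == 2
        assert set(tables.per_source) == {"L1", "L2", "model"}
        assert tables.per_source["L1"][0].total == 2

    def test_binary_discordance_definition(self):
        entries = [("i1", "L1", 1, "correct"), ("i1", "L1", 2, "incorrect"),
                   ("i2", "L1", 1, "correct"), ("i2", "L1", 2, "correct")]
        log, prov = make_log(entries)
        b = confusion_from_repeats(log, prov, SCHEME).overall_binary
        assert b.n_discordant / b.total == 0.5

    def test_unpaired_duplicate_rejected(self):
        entries = [("i1", "L1", 2, "correct")]  # replicate 2 without replicate 1
        log, prov = make_log(entries)
        with pytest.raises(IncompleteLogError):
            confusion_from_repeats(log, prov, SCHEME)


class TestStratifiedDsc:
    def test_crafted_strata_match_hand_split(self):
        labels = {
            "i1": ("correct", "correct"),          # same (agree/agree)
            "i2": ("correct", "oversegmented"),    # different
            "i3": ("incorrect", "undersegmented"), # same (disagree/disagree)
            "i4": ("oversegmented", "correct"),    # different
            "i5": ("correct", "correct"),          # same
        }
        entries = []
        for img, (la, lb) in labels.items():
            entries += [(img, "L1", 1, la), (img, "L2", 1, lb)]
        log, prov = make_log(entries)
        dsc = {"i1": 0.9, "i2": 0.5, "i3": 0.7, "i4": 0.4, "i5": 0.8}
        rows = stratified_dsc(log, prov, dsc, ("L1", "L2"), SCHEME)
        by_flag = {r.same_label: r for r in rows}
        assert by_flag[True].n == 3
        assert by_flag[True].summary.mean == pytest.approx((0.9 + 0.7 + 0.8) / 3)
        assert by_flag[False].n == 2
        assert by_flag[False].summary.mean == pytest.approx(0.45)
        assert by_flag[True].n + by_flag[False].n == len(dsc)

    def test_single_stratum_when_validator_always_agrees(self):
        entries = [(f"i{k}", s, 1, "correct") for k in range(4) for s in ("L1", "L2")]
        log, prov = make_log(entries)
        dsc = {f"i{k}": 0.8 for k in range(4)}
        rows = stratified_dsc(log, prov, dsc, ("L1", "L2"), SCHEME)
        assert len(rows) == 1 and rows[0].same_label and rows[0].n == 4

    def test_singleton_stratum_flagged_without_ci(self):
        entries = [("i1", "L1", 1, "correct"), ("i1", "L2", 1, "incorrect"),
                   ("i2", "L1", 1, "correct"), ("i2", "L2", 1, "correct")]
        log, prov = make_log(entries)
        rows = stratified_dsc(log, prov, {"i1": 0.5, "i2": 0.9}, ("L1", "L2"), SCHEME)
        flagged = [r for r in rows if r.ci_flagged]
        assert len(flagged) == 2  # both strata are singletons here
        assert all(r.summary.ci_low is None for r in flagged)


class TestOrderEffect:
    def test_always_agree_validator_scores_100_everywhere(self):
        catalog = grid_catalog(12, ("a", "b", "c"))
        plan, prov = build_schedule(catalog, seed=3)
        log = ResponseLog(scheme=SCHEME)
        for i, pid in enumerate(plan.presentation_ids):
            shown = T0 + timedelta(seconds=60 * i)
            log.append(ValidationResponse(pid, "correct", shown_at=shown,
                                          answered_at=shown + timedelta(seconds=30)))
        table = order_effect(log, prov, plan, SCHEME)
        assert (table["percent_agree"] == 100.0).all()
        sums = table.groupby("source_id")["n"].sum()
        assert (sums == 12).all()

    def test_rank_partition_is_exhaustive_and_disjoint(self, synthetic_run):
        _, plan, prov, log = synthetic_run
        table = order_effect(log, prov, plan, SCHEME)
        assert (table.groupby("source_id")["n"].sum() == 25).all()
        assert table["percent_agree"].between(0, 100).all()


class TestSessions:
    @staticmethod
    def log_with_gaps(answer_minutes, dwell=50):
        log = ResponseLog(scheme=SCHEME)
        for i, m in enumerate(answer_minutes):
            answered = T0 + timedelta(minutes=m)
            log.append(ValidationResponse(
                f"p{i}", "correct",
                shown_at=answered - timedelta(seconds=dwell),
                answered_at=answered))
        return log

    def test_two_hour_gap_splits_sessions(self):
        table = detect_sessions(self.log_with_gaps([0, 10, 130]), SCHEME)
        assert list(table["n_items"]) == [2, 1]

    def test_exact_threshold_gap_stays_in_session(self):
        # next shown exactly 3600 s after previous answered: strictly-greater rule
        log = ResponseLog(scheme=SCHEME)
        log.append(ValidationResponse("p0", "correct", shown_at=T0,
                                      answered_at=T0 + timedelta(seconds=30)))
        shown = T0 + timedelta(seconds=30 + 3600)
        log.append(ValidationResponse("p1", "correct", shown_at=shown,
                                      answered_at=shown + timedelta(seconds=30)))
        table = detect_sessions(log, SCHEME)
        assert len(table) == 1
        just_over = ResponseLog(scheme=SCHEME)
        just_over.append(ValidationResponse("p0", "correct", shown_at=T0,
                                            answered_at=T0 + timedelta(seconds=30)))
        shown = T0 + timedelta(seconds=31 + 3600)
        just_over.append(ValidationResponse("p1", "correct", shown_at=shown,
                                            answered_at=shown + timedelta(seconds=30)))
        assert len(detect_sessions(just_over, SCHEME)) == 2

    def test_single_item_session_uses_its_own_span(self):
        table = detect_sessions(self.log_with_gaps([0], dwell=60), SCHEME)
        assert table.loc[0, "duration_s"] == 60.0
        assert table.loc[0, "items_per_hour"] == pytest.approx(60.0)

    def test_every_response_in_exactly_one_session(self, synthetic_run):
        _, _, _, log = synthetic_run
        table = detect_sessions(log, SCHEME)
        assert table["n_items"].sum() == len(log)
        # sessions ordered and non-overlapping
        assert (table["start"].values[1:] > table["end"].values[:-1]).all()


class TestBuildReport:
    def test_end_to_end_tables_present_and_deterministic(self, synthetic_run, tmp_path):
        catalog, plan, prov, log = synthetic_run
        from blindval.masks import dice
        agreement = agreement_by_source(log, prov, SCHEME)
        repeats = confusion_from_repeats(log, prov, SCHEME)
        sessions = detect_sessions(log, SCHEME)
        order = order_effect(log, prov, plan, SCHEME)
        strata = []
        for a, b in [("L1", "L2"), ("L1", "model"), ("L2", "model")]:
            dsc = {img: dice(catalog.masks[(img, a)], catalog.masks[(img, b)])
                   for img in catalog.images}
            strata.extend(stratified_dsc(log, prov, dsc, (a, b), SCHEME))

        expected = ["agreement_by_source.csv", "stratified_dsc.csv",
                    "confusion_overall.csv", "confusion_binary.csv",
                    "confusion_by_source.csv", "rater_metrics.csv",
                    "order_effect.csv", "sessions.csv"]
        out1 = build_report(tmp_path / "r1", agreement=agreement, repeats=repeats,
                            strata=strata, order=order, sessions=sessions)
        out2 = build_report(tmp_path / "r2", agreement=agreement, repeats=repeats,
                            strata=strata, order=order, sessions=sessions)
        for name in expected:
            assert (out1 / name).exists()
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()
        metrics = pd.read_csv(out1 / "rater_metrics.csv")
        assert set(metrics["scope"]) == {"overall", "L1", "L2", "model"}
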