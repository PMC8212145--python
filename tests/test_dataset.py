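"""Data-table parsing and per-feature statistics (changes, correlations, BH)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st
from scipy import stats

from pathcause import (
    Effect,
    FeatureKind,
    Site,
    SiteEffectLibrary,
    Ternary,
    assess_change_foldchange,
    assess_change_ttest,
    bh_fdr,
    correlate,
    effect_of_feature,
    inject_activity_hypothesis,
    parse_data_table,
    parse_site_string,
)
from conftest import make_row


class TestParseSiteString:
    def test_pipe_joined(self):
        assert [str(s) for s in parse_site_string("S235|S236")] == ["S235", "S236"]

    def test_single(self):
        assert parse_site_string("Y204") == (Site("Y", 204),)

    def test_empty(self):
        assert parse_site_string("") == ()

    def test_dedup_preserves_order(self):
        assert [str(s) for s in parse_site_string("Y2;S1;Y2")] == ["Y2", "S1"]

    def test_malformed_token_named(self):
        with pytest.raises(ValueError, match="Yx9"):
            parse_site_string("Y204|Yx9")


class TestParseDataTable:
    def _write(self, tmp_path, body, header="ID\tSymbols\tSites\tEffect\tT1\tT2\tC1\tC2"):
        path = tmp_path / "data.tsv"
        path.write_text(header + "\n" + body)
        return path

    def test_phospho_row(self, tmp_path):
        path = self._write(tmp_path, "r1\tGAB1\tY406\t\t1.2\t0.8\t0.1\t0.2\n")
        data = parse_data_table(path)
        row = data.row("r1")
        assert row.kind is FeatureKind.PHOSPHO
        assert row.symbols == ("GAB1",)
        assert row.sites == (Site("Y", 406),)
        assert data.samples == ("T1", "T2", "C1", "C2")

    def test_empty_sites_means_total_protein(self, tmp_path):
        path = self._write(tmp_path, "r1\tEGFR\t\t\t1\t2\t3\t4\n")
        assert parse_data_table(path).row("r1").kind is FeatureKind.TOTAL_PROTEIN

    def test_na_cell_becomes_missing(self, tmp_path):
        path = self._write(tmp_path, "r1\tEGFR\t\t\tNA\t2\t3\t4\n")
        row = parse_data_table(path).row("r1")
        assert np.isnan(row.values[0]) and row.values[1] == 2.0

    def test_feature_override(self, tmp_path):
        path = self._write(
            tmp_path,
            "r1\tESR1\t\trna\t1\t2\t3\t4\n",
            header="ID\tSymbols\tSites\tFeature\tT1\tT2\tC1\tC2",
        )
        assert parse_data_table(path).row("r1").kind is FeatureKind.RNA

    def test_effect_override(self, tmp_path):
        path = self._write(tmp_path, "r1\tEGFR\tT669\ti\t1\t2\t3\t4\n")
        assert parse_data_table(path).row("r1").effect_override is Effect.INHIBITING

    def test_duplicate_ids_rejected(self, tmp_path):
        path = self._write(tmp_path, "r1\tA\t\t\t1\t2\t3\t4\nr1\tB\t\t\t1\t2\t3\t4\n")
        with pytest.raises(ValueError, match="duplicate"):
            parse_data_table(path)

    def test_no_sample_columns_rejected(self, tmp_path):
        path = tmp_path / "data.tsv"
        path.write_text("ID\tSymbols\tSites\nr1\tA\t\n")
        with pytest.raises(ValueError, match="sample"):
            parse_data_table(path)

    def test_multi_symbol_row_indexed_under_each(self, tmp_path):
        path = self._write(tmp_path, "r1\tCDK1 CDK2\t\t\t1\t2\t3\t4\n")
        data = parse_data_table(path)
        assert data.by_symbol("CDK1")[0].id == "r1"
        assert data.by_symbol("CDK2")[0].id == "r1"


SAMPLES = ("T1", "T2", "T3", "C1", "C2", "C3")


def _row(values):
    return make_row("r", "X", values)


class TestTTest:
    def test_clear_shift_matches_textbook_welch(self):
        """Frozen against the closed-form Welch statistic and t distribution."""
        row = _row([5, 6, 7, 1, 2, 3])
        a = assess_change_ttest(row, SAMPLES[:3], SAMPLES[3:], min_n=2, samples=SAMPLES)
        # Independent oracle: Welch formula, both variances 1, n = 3.
        se = math.sqrt(1 / 3 + 1 / 3)
        t_expected = (6 - 2) / se
        df = 4.0  # equal variances and sizes: Welch-Satterthwaite df = 2n - 2
        p_expected = 2 * stats.t.sf(t_expected, df)
        assert a.statistic == pytest.approx(t_expected)
        assert a.p == pytest.approx(p_expected)
        assert a.p < 0.05
        assert a.direction is Ternary.TRUE
        # In a single-row dataset BH leaves p unchanged -> significant at 0.1.
        assert bh_fdr([a.p])[0] == pytest.approx(a.p)

    def test_identical_groups_direction_unknown(self):
        row = _row([1, 2, 3, 1, 2, 3])
        a = assess_change_ttest(row, SAMPLES[:3], SAMPLES[3:], min_n=2, samples=SAMPLES)
        assert a.statistic == pytest.approx(0.0)
        assert a.direction is Ternary.UNKNOWN

    def test_undersized_group_untestable(self):
        row = _row([1, np.nan, np.nan, 1, 2, 3])
        a = assess_change_ttest(row, SAMPLES[:3], SAMPLES[3:], min_n=2, samples=SAMPLES)
        assert a.p is None and a.direction is Ternary.UNKNOWN

    def test_zero_variance_equal_means_untestable(self):
        row = _row([2, 2, 2, 2, 2, 2])
        a = assess_change_ttest(row, SAMPLES[:3], SAMPLES[3:], samples=SAMPLES)
        assert a.p is None

    @given(st.integers(0, 2**32 - 1))
    @hyp_settings(derandomize=True, max_examples=25)
    def test_group_swap_flips_direction_keeps_p(self, seed):
        rng = np.random.default_rng(seed)
        row = _row(rng.normal(size=6) + np.r_[np.full(3, 1.0), np.zeros(3)])
        fwd = assess_change_ttest(row, SAMPLES[:3], SAMPLES[3:], samples=SAMPLES)
        rev = assess_change_ttest(row, SAMPLES[3:], SAMPLES[:3], samples=SAMPLES)
        assert fwd.p == pytest.approx(rev.p)
        if fwd.direction.is_known:
            assert rev.direction is ~fwd.direction


class TestFoldChange:
    @pytest.mark.parametrize(
        "test_vals, ctrl_vals, expected",
        [
            ((2.0, 2.0, 2.0), (1.0, 1.0, 1.0), Ternary.TRUE),
            ((1.0, 1.0, 1.0), (1.4, 1.4, 1.4), Ternary.UNKNOWN),
            ((1.0, 1.0, 1.0), (2.0, 2.0, 2.0), Ternary.FALSE),
        ],
    )
    def test_band(self, test_vals, ctrl_vals, expected):
        row = _row(list(test_vals) + list(ctrl_vals))
        a = assess_change_foldchange(row, SAMPLES[:3], SAMPLES[3:], 0.5, samples=SAMPLES)
        assert a.direction is expected

    def test_all_missing_group_untestable(self):
        row = _row([np.nan] * 3 + [1, 2, 3])
        a = assess_change_foldchange(row, SAMPLES[:3], SAMPLES[3:], 0.5, samples=SAMPLES)
        assert a.direction is Ternary.UNKNOWN and a.statistic is None


class TestCorrelate:
    def test_perfect_positive(self):
        a = correlate(_row([1, 2, 3, 4, 5, 6]), _row([2, 4, 6, 8, 10, 12]), min_n=3)
        assert a.coefficient == pytest.approx(1.0)
        assert a.sign is Ternary.TRUE

    def test_perfect_negative(self):
        a = correlate(_row([1, 2, 3, 4, 5, 6]), _row([8, 6, 4, 2, 0, -2]), min_n=3)
        assert a.coefficient == pytest.approx(-1.0)
        assert a.sign is Ternary.FALSE

    def test_insufficient_overlap_untestable(self):
        a = correlate(
            _row([1, 2, np.nan, np.nan, np.nan, np.nan]),
            _row([2, 4, np.nan, np.nan, np.nan, np.nan]),
            min_n=3,
        )
        assert not a.testable and a.n_used == 2

    def test_zero_variance_untestable(self):
        assert not correlate(_row([1] * 6), _row([1, 2, 3, 4, 5, 6]), min_n=3).testable

    @given(st.integers(0, 2**32 - 1))
    @hyp_settings(derandomize=True, max_examples=25)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=8), rng.normal(size=8)
        x[rng.integers(0, 8)] = np.nan
        a = correlate(make_row("a", "A", x), make_row("b", "B", y), min_n=3)
        b = correlate(make_row("b", "B", y), make_row("a", "A", x), min_n=3)
        assert (a.coefficient, a.p, a.n_used) == (b.coefficient, b.p, b.n_used)


def bh_reference(ps):
    """Brute-force BH: sort, scale by m/rank, cumulative minimum from the right."""
    ps = np.asarray(ps, dtype=float)
    m = len(ps)
    order = np.argsort(ps, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, ps[idx] * m / rank)
        q[idx] = running
    return q


class TestBhFdr:
    def test_textbook_example(self):
        # All four q-values collapse to 0.04 under step-up adjustment.
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_value_identity(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_ties(self):
        assert bh_fdr([0.05, 0.05, 0.05]) == pytest.approx([0.05] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_missing_passthrough(self):
        out = bh_fdr([0.01, None, 0.04])
        assert np.isnan(out[1])
        assert out[[0, 2]] == pytest.approx(bh_reference([0.01, 0.04]))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @hyp_settings(derandomize=True, max_examples=60)
    def test_matches_brute_force(self, ps):
        assert bh_fdr(ps) == pytest.approx(bh_reference(ps))


class TestHypothesisRows:
    def test_activation(self):
        row = inject_activity_hypothesis("EGF", "up")
        assert row.kind is FeatureKind.ACTIVITY
        assert row.activity_direction is True
        assert row.values is None

    def test_inactivation(self):
        assert inject_activity_hypothesis("AKT1", "down").activity_direction is False

    def test_duplicate_collapsed(self, egf_dataset, caplog):
        n = len(egf_dataset)
        with caplog.at_level("WARNING"):
            egf_dataset.add_hypothesis("EGF", "up")
        assert len(egf_dataset) == n

    def test_empty_symbol_rejected(self):
        with pytest.raises(ValueError):
            inject_activity_hypothesis("  ", "up")


class TestEffectOfFeature:
    @pytest.fixture
    def lib(self):
        return SiteEffectLibrary(
            [
                ("GAB1", Site("Y", 406), Effect.ACTIVATING),
                ("EGFR", Site("T", 669), Effect.INHIBITING),
                ("EGFR", Site("Y", 1068), Effect.ACTIVATING),
            ]
        )

    def test_total_protein_is_true(self, lib):
        assert effect_of_feature(make_row("r", "ANY", [1, 2]), lib) is Ternary.TRUE

    def test_activity_row_is_true(self, lib):
        assert effect_of_feature(inject_activity_hypothesis("EGF", "up"), lib) is Ternary.TRUE

    def test_activating_site(self, lib):
        row = make_row("r", "GAB1", [1, 2], sites=("Y406",))
        assert effect_of_feature(row, lib) is Ternary.TRUE

    def test_inhibiting_site(self, lib):
        row = make_row("r", "EGFR", [1, 2], sites=("T669",))
        assert effect_of_feature(row, lib) is Ternary.FALSE

    def test_unannotated_site_unknown(self, lib):
        row = make_row("r", "GAB1", [1, 2], sites=("Y999",))
        assert effect_of_feature(row, lib) is Ternary.UNKNOWN

    def test_disagreeing_sites_unknown(self, lib):
        row = make_row("r", "EGFR", [1, 2], sites=("T669", "Y1068"))
        assert effect_of_feature(row, lib) is Ternary.UNKNOWN

    def test_agreeing_plus_unannotated_sites_use_annotated(self, lib):
        row = make_row("r", "EGFR", [1, 2], sites=("Y1068", "S999"))
        assert effect_of_feature(row, lib) is Ternary.TRUE

    def test_override_wins(self, lib):
        row = make_row("r", "GAB1", [1, 2], sites=("Y406",),
                       effect_override=Effect.INHIBITING)
        assert effect_of_feature(row, lib) is Ternary.FALSE

    def test_rna_source_rejected(self, lib):
        row = make_row("r", "ESR1", [1, 2], kind=FeatureKind.RNA)
        with pytest.raises(ValueError):
            effect_of_feature(row, lib)
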