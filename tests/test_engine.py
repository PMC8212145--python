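"""Causality equations, structural applicability, and network assembly."""

import itertools

import numpy as np
import pytest

from pathcause import (
    AnalysisSettings,
    EngineCache,
    FeatureKind,
    PriorNetwork,
    PriorRelation,
    ProteomicDataset,
    RelationType,
    Site,
    SiteEffectLibrary,
    Ternary,
    applicable,
    build_result_network,
    correlate,
    evaluate_comparison,
    evaluate_correlation,
    sign_of_relation,
    sites_match,
)
from pathcause.synthetic import (
    GeneratorSpec,
    generate_comparison_dataset,
    generate_prior_network,
)
from conftest import make_row

T, F, U = Ternary.TRUE, Ternary.FALSE, Ternary.UNKNOWN

PHOS = RelationType.PHOSPHORYLATES
DEPHOS = RelationType.DEPHOSPHORYLATES
EXPR_UP = RelationType.UPREGULATES_EXPRESSION
EXPR_DOWN = RelationType.DOWNREGULATES_EXPRESSION


def _rel(rtype=PHOS, sites=("Y204",)):
    sites = tuple(Site.parse(s) for s in sites) if rtype.is_phospho else ()
    return PriorRelation("SRC", rtype, "TGT", sites)


SRC_ROW = make_row("src", "SRC", [1.0, 2.0], sites=("S10",))
TGT_ROW = make_row("tgt", "TGT", [1.0, 2.0], sites=("Y204",))


class TestSignOfRelation:
    @pytest.mark.parametrize(
        "rtype, expected",
        [(PHOS, True), (DEPHOS, False), (EXPR_UP, True), (EXPR_DOWN, False)],
    )
    def test_mapping(self, rtype, expected):
        assert sign_of_relation(rtype) is expected


class TestSitesMatch:
    def site(self, token):
        return Site.parse(token)

    def test_exact(self):
        assert sites_match([self.site("Y204")], [self.site("Y204")], 0)

    def test_within_tolerance(self):
        assert sites_match([self.site("Y204")], [self.site("Y202")], 2)

    def test_outside_tolerance(self):
        assert not sites_match([self.site("Y204")], [self.site("Y207")], 2)

    def test_residue_must_agree_at_zero_tolerance(self):
        assert not sites_match([self.site("Y204")], [self.site("S204")], 0)

    def test_residue_free_at_positive_tolerance(self):
        assert sites_match([self.site("Y204")], [self.site("S203")], 2)

    def test_strict_residue_flag(self):
        assert not sites_match(
            [self.site("Y204")], [self.site("S203")], 2, strict_residue=True
        )

    def test_unsited_prior_matches_any_only_when_permissive(self):
        row_sites = [self.site("Y204")]
        assert not sites_match([], row_sites, 0)
        matched = sites_match([], row_sites, 0, unsited_matches_any=True)
        assert matched == ((None, self.site("Y204")),)


class TestApplicable:
    settings = AnalysisSettings(mode="correlation")

    def test_phospho_needs_matching_phospho_target(self):
        assert applicable(_rel(PHOS), SRC_ROW, TGT_ROW, self.settings)
        other = make_row("tgt2", "TGT", [1, 2], sites=("Y999",))
        assert not applicable(_rel(PHOS), SRC_ROW, other, self.settings)

    def test_expression_cannot_explain_phospho(self):
        assert not applicable(_rel(EXPR_UP, ()), SRC_ROW, TGT_ROW, self.settings)

    def test_expression_explains_total_protein(self):
        total = make_row("tgt3", "TGT", [1, 2])
        assert applicable(_rel(EXPR_UP, ()), SRC_ROW, total, self.settings)

    def test_rna_target_requires_option(self):
        rna = make_row("tgt4", "TGT", [1, 2], kind=FeatureKind.RNA)
        assert not applicable(_rel(EXPR_UP, ()), SRC_ROW, rna, self.settings)
        on = AnalysisSettings(mode="correlation", rna_targets=True)
        assert applicable(_rel(EXPR_UP, ()), SRC_ROW, rna, on)

    def test_rna_source_rejected(self):
        rna_src = make_row("src2", "SRC", [1, 2], kind=FeatureKind.RNA)
        total = make_row("tgt5", "TGT", [1, 2])
        assert not applicable(_rel(EXPR_UP, ()), rna_src, total, self.settings)

    def test_hypothesis_never_a_target(self):
        from pathcause import inject_activity_hypothesis
        hyp = inject_activity_hypothesis("TGT", "up")
        assert not applicable(_rel(EXPR_UP, ()), SRC_ROW, hyp, self.settings)

    def test_row_cannot_explain_itself(self):
        auto = PriorRelation("TGT", PHOS, "TGT", (Site("Y", 204),))
        assert not applicable(auto, TGT_ROW, TGT_ROW, self.settings)


def oracle_parity(values):
    """Independent parity oracle: plain boolean XOR with unknown veto."""
    if any(v is None for v in values):
        return None
    out = False
    for v in values:
        out ^= v
    return out


_TO_TERNARY = {True: T, False: F, None: U}


class TestEquationEnumeration:
    """The comparison equation over realizable assignments vs the oracle."""

    def test_comparison_accepts_exactly_odd_parity(self):
        accepted = []
        for c_src, e, c_tgt in itertools.product([True, False, None], repeat=3):
            for rtype in (PHOS, DEPHOS):
                s = rtype.sign
                conj = evaluate_comparison(
                    _rel(rtype), SRC_ROW, TGT_ROW,
                    _TO_TERNARY[c_src], _TO_TERNARY[c_tgt], _TO_TERNARY[e],
                )
                want = oracle_parity(
                    [c_src, e, s, None if c_tgt is None else not c_tgt]
                )
                assert (conj is not None) == (want is True)
                if conj is not None:
                    accepted.append((c_src, e, s, c_tgt))
        assert len(accepted) == 8

    def test_correlation_accepts_exactly_odd_parity(self):
        accepted = []
        for corr, e in itertools.product([True, False, None], repeat=2):
            for rtype in (PHOS, DEPHOS):
                conj = evaluate_correlation(
                    _rel(rtype), SRC_ROW, TGT_ROW, _TO_TERNARY[corr], _TO_TERNARY[e]
                )
                want = oracle_parity([corr, e, rtype.sign])
                assert (conj is not None) == (want is True)
                if conj is not None:
                    accepted.append((corr, e, rtype.sign))
        assert len(accepted) == 4

    def test_fig1_style_consistent_chain_accepted(self):
        # up source, activating site, phosphorylation, up target
        conj = evaluate_comparison(_rel(PHOS), SRC_ROW, TGT_ROW, T, T, T)
        assert conj is not None and conj.mode == "comparison"

    def test_inhibiting_source_with_down_target_accepted(self):
        assert evaluate_comparison(_rel(PHOS), SRC_ROW, TGT_ROW, T, F, F) is not None

    def test_any_unknown_rejects(self):
        assert evaluate_comparison(_rel(PHOS), SRC_ROW, TGT_ROW, T, U, T) is None
        assert evaluate_correlation(_rel(PHOS), SRC_ROW, TGT_ROW, U, T) is None


class TestBuildResultNetwork:
    def test_egf_cascade_recovered(self, egf_priors, egf_dataset,
                                   egf_site_effects, comparison_settings):
        net = build_result_network(
            egf_priors, egf_dataset, comparison_settings, egf_site_effects
        )
        assert net.relation_keys() == {
            ("EGF", "phosphorylates", "EGFR"),
            ("EGFR", "phosphorylates", "GAB1"),
        }
        assert net.downstream_counts() == {"EGF": 1, "EGFR": 1}

    def test_insignificant_rows_give_empty_network(
        self, egf_priors, egf_site_effects, comparison_settings
    ):
        rows = [
            make_row("egfr_py1068", "EGFR", [0.1, -0.1, 0.0, 0.0, 0.1, -0.1], sites=("Y1068",)),
            make_row("gab1_py406", "GAB1", [0.0, 0.1, -0.1, -0.1, 0.0, 0.1], sites=("Y406",)),
        ]
        data = ProteomicDataset(rows, ["T1", "T2", "T3", "C1", "C2", "C3"])
        data.add_hypothesis("EGF", "up")
        net = build_result_network(egf_priors, data, comparison_settings, egf_site_effects)
        assert len(net) == 0

    def test_single_side_negation_flips_acceptance(
        self, egf_priors, egf_dataset, egf_site_effects, comparison_settings
    ):
        flipped_rows = []
        for row in egf_dataset.rows:
            if row.id == "gab1_py406":
                flipped_rows.append(
                    make_row(row.id, row.symbols[0], -row.values, sites=row.sites)
                )
            else:
                flipped_rows.append(row)
        data = egf_dataset.with_rows(flipped_rows)
        net = build_result_network(egf_priors, data, comparison_settings, egf_site_effects)
        assert ("EGFR", "phosphorylates", "GAB1") not in net.relation_keys()
        assert ("EGF", "phosphorylates", "EGFR") in net.relation_keys()

    def test_double_negation_invariance(self, egf_priors, egf_dataset,
                                        egf_site_effects, comparison_settings):
        """Swapping test/control negates every measured change; acceptance of
        relations among measured features is stable (the parity equation is
        invariant under double negation).  Hypothesis rows keep their stated
        direction, so the measured-only sub-dataset is used."""
        measured = egf_dataset.with_rows(
            [r for r in egf_dataset.rows if not r.id.startswith("hyp:")]
        )
        swapped = AnalysisSettings(
            mode="comparison",
            test_columns=comparison_settings.control_columns,
            control_columns=comparison_settings.test_columns,
            change_test="foldchange",
            fold_change_threshold=0.5,
        )
        a = build_result_network(egf_priors, measured, comparison_settings, egf_site_effects)
        b = build_result_network(egf_priors, measured, swapped, egf_site_effects)
        assert a.relation_keys() == b.relation_keys() == {("EGFR", "phosphorylates", "GAB1")}

    def test_order_invariance(self):
        spec = GeneratorSpec(n_proteins=15, seed=3, missing_rate=0.0)
        sp = generate_prior_network(spec)
        data, _ = generate_comparison_dataset(sp, spec)
        settings = AnalysisSettings(
            mode="comparison",
            test_columns=tuple(f"T{i+1}" for i in range(10)),
            control_columns=tuple(f"C{i+1}" for i in range(10)),
        )
        base = build_result_network(sp.network, data, settings, sp.site_effects)
        rng = np.random.default_rng(0)
        shuffled_rows = list(data.rows)
        rng.shuffle(shuffled_rows)
        shuffled_rels = list(sp.network.relations)
        rng.shuffle(shuffled_rels)
        other = build_result_network(
            PriorNetwork(shuffled_rels),
            data.with_rows(shuffled_rows),
            settings,
            sp.site_effects,
        )
        assert base.relation_keys() == other.relation_keys()

    def test_fdr_threshold_monotonicity(self):
        spec = GeneratorSpec(n_proteins=20, seed=5, effect_size=1.5)
        sp = generate_prior_network(spec)
        data, _ = generate_comparison_dataset(sp, spec)
        cols = dict(
            test_columns=tuple(f"T{i+1}" for i in range(10)),
            control_columns=tuple(f"C{i+1}" for i in range(10)),
        )
        keys = {}
        for fdr in (0.02, 0.1, 0.3):
            settings = AnalysisSettings(mode="comparison", feature_fdr=fdr, **cols)
            keys[fdr] = build_result_network(
                sp.network, data, settings, sp.site_effects
            ).relation_keys()
        assert keys[0.02] <= keys[0.1] <= keys[0.3]

    def test_comparison_without_groups_rejected(self, egf_priors, egf_dataset):
        with pytest.raises(ValueError):
            build_result_network(
                egf_priors, egf_dataset, AnalysisSettings(mode="comparison")
            )

    def test_empty_priors_warns_empty_result(self, egf_dataset, comparison_settings, caplog):
        with caplog.at_level("WARNING"):
            net = build_result_network(PriorNetwork(), egf_dataset, comparison_settings)
        assert len(net) == 0

    def test_site_tolerance_recovers_shifted_site(
        self, egf_priors, egf_site_effects, comparison_settings
    ):
        """A data site off by two positions matches only with tolerance."""
        rows = [
            make_row("egfr_py1068", "EGFR", [2, 2, 2, 0, 0, 0], sites=("Y1068",)),
            make_row("gab1_py404", "GAB1", [2, 2, 2, 0, 0, 0], sites=("Y404",)),
        ]
        data = ProteomicDataset(rows, ["T1", "T2", "T3", "C1", "C2", "C3"])
        data.add_hypothesis("EGF", "up")
        strict = build_result_network(egf_priors, data, comparison_settings, egf_site_effects)
        assert ("EGFR", "phosphorylates", "GAB1") not in strict.relation_keys()
        relaxed_settings = AnalysisSettings(
            mode="comparison",
            test_columns=comparison_settings.test_columns,
            control_columns=comparison_settings.control_columns,
            change_test="foldchange",
            fold_change_threshold=0.5,
            site_tolerance=2,
        )
        relaxed = build_result_network(egf_priors, data, relaxed_settings, egf_site_effects)
        assert ("EGFR", "phosphorylates", "GAB1") in relaxed.relation_keys()


class TestEngineCacheCorrelations:
    def test_matrix_path_matches_pairwise_scipy(self):
        """The masked-matrix all-pairs Pearson equals per-pair computation."""
        rng = np.random.default_rng(42)
        values = rng.normal(size=(12, 30))
        values[rng.random(values.shape) < 0.15] = np.nan
        rows = [make_row(f"r{i}", f"P{i}", values[i]) for i in range(12)]
        data = ProteomicDataset(rows, [f"S{j}" for j in range(30)])
        cache = EngineCache(data, AnalysisSettings(mode="correlation"))
        for i in range(12):
            for j in range(i + 1, 12):
                got = cache.raw_correlation(f"r{i}", f"r{j}")
                want = correlate(rows[i], rows[j], min_n=5)
                if not want.testable:
                    assert got is None
                else:
                    assert got is not None
                    assert got[0] == pytest.approx(want.coefficient, abs=1e-10)
                    assert got[1] == pytest.approx(want.p, rel=1e-8, abs=1e-12)
                    assert got[2] == want.n_used
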