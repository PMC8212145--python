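"""Ternary causality evaluation over (prior relation, source, target) triples.

The central test is a parity equation over three-valued signs.  For a
comparison (test vs control) analysis a prior relation explains a pair of
observed changes when

    c_source (+) e_source (+) s_relation (+) NOT c_target  =  TRUE

where ``(+)`` is ternary XOR, ``c`` is the change direction of a feature,
``e`` the effect of the source feature on its protein's activity, and ``s``
the sign of the relation (true for phosphorylation and expression
upregulation).  In a correlation (cohort) analysis the two change terms are
replaced by the sign of the pairwise correlation:

    corr_{source,target} (+) e_source (+) s_relation  =  TRUE

Any UNKNOWN operand (insignificant change, uncurated site) vetoes the
explanation.  Structural constraints apply before the sign logic: phospho
relations may only explain phosphoprotein targets on matching sites, and
expression relations only total-protein (optionally RNA) targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _scipy_stats

from .dataset import (
    ChangeAssessment,
    CorrelationAssessment,
    FeatureKind,
    MeasurementRow,
    ProteomicDataset,
    assess_change_foldchange,
    assess_change_ttest,
    bh_fdr,
    correlate,
    effect_of_feature,
)
from .priors import PriorNetwork, PriorRelation, RelationType, Site, SiteEffectLibrary
from .ternary import Ternary, ternary_parity

logger = logging.getLogger(__name__)

#: Feature kinds allowed as causal sources (protein-level evidence only).
SOURCE_KINDS = (FeatureKind.TOTAL_PROTEIN, FeatureKind.PHOSPHO, FeatureKind.ACTIVITY)


def sign_of_relation(rtype: RelationType) -> bool:
    """True for phosphorylation and expression upregulation, false for
    dephosphorylation and expression downregulation."""
    return rtype.sign


@dataclass
class AnalysisSettings:
    """Knobs governing one analysis run.

    mode
        ``"comparison"`` (two-group changes, Eq.-style parity on four terms)
        or ``"correlation"`` (cohort, parity on three terms).
    feature_fdr / correlation_fdr
        BH thresholds for change and correlation significance.  With
        ``fdr_control`` off the same thresholds apply to raw p-values.
    site_tolerance
        Maximum position difference for matching a prior site to a data
        site; at tolerance 0 residue letters must also agree, at tolerance
        > 0 matching is position-only unless ``strict_residue`` is set
        (literature site coordinates are often shifted by initial-methionine
        cleavage, which moves positions but not necessarily residues).
    unsited_prior_matches_any
        Whether a phospho prior without site annotation may explain any
        phosphosite on its target.
    """

    mode: str = "comparison"
    test_columns: tuple[str, ...] = ()
    control_columns: tuple[str, ...] = ()
    value_columns: tuple[str, ...] = ()
    change_test: str = "ttest"
    fold_change_threshold: float = 0.5
    feature_fdr: float = 0.1
    correlation_fdr: float = 0.1
    fdr_control: bool = True
    site_tolerance: int = 0
    strict_residue: bool = False
    unsited_prior_matches_any: bool = True
    rna_targets: bool = False
    correlation_method: str = "pearson"
    welch: bool = True
    min_group_n: int = 3
    min_corr_n: int = 5

    def __post_init__(self) -> None:
        if self.mode not in ("comparison", "correlation"):
            raise ValueError(f"unknown mode: {self.mode!r}")
        if self.change_test not in ("ttest", "foldchange"):
            raise ValueError(f"unknown change test: {self.change_test!r}")
        for name in ("feature_fdr", "correlation_fdr"):
            value = getattr(self, name)
            if not (0 < value <= 1):
                raise ValueError(f"{name} must lie in (0, 1]: {value}")
        if self.site_tolerance < 0:
            raise ValueError("site_tolerance must be >= 0")
        self.test_columns = tuple(self.test_columns)
        self.control_columns = tuple(self.control_columns)
        self.value_columns = tuple(self.value_columns)


def sites_match(
    prior_sites: Sequence[Site],
    row_sites: Sequence[Site],
    tolerance: int = 0,
    *,
    strict_residue: bool = False,
    unsited_matches_any: bool = False,
) -> tuple[tuple[Site | None, Site], ...]:
    """Match prior-annotated sites against a row's measured sites.

    Returns (prior_site, row_site) pairs with position difference within
    ``tolerance``.  With an empty prior site list, the permissive option
    pairs every row site with ``None``.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if not prior_sites:
        if unsited_matches_any:
            return tuple((None, r) for r in row_sites)
        return ()
    need_residue = tolerance == 0 or strict_residue
    pairs = []
    for p in prior_sites:
        for r in row_sites:
            if abs(p.position - r.position) > tolerance:
                continue
            if need_residue and p.residue != r.residue:
                continue
            pairs.append((p, r))
    return tuple(pairs)


def _matched_target_sites(
    relation: PriorRelation, target: MeasurementRow, settings: AnalysisSettings
) -> tuple[Site, ...]:
    pairs = sites_match(
        relation.target_sites,
        target.sites,
        settings.site_tolerance,
        strict_residue=settings.strict_residue,
        unsited_matches_any=settings.unsited_prior_matches_any,
    )
    matched: dict[Site, None] = {}
    for _, row_site in pairs:
        matched.setdefault(row_site, None)
    return tuple(matched)


def applicable(
    relation: PriorRelation,
    source: MeasurementRow,
    target: MeasurementRow,
    settings: AnalysisSettings,
) -> bool:
    """Structural check that ``relation`` may explain this feature pair.

    Phospho regulations explain phosphoprotein targets on matching sites;
    expression regulations explain total-protein (optionally RNA) targets.
    Sources must carry protein-level evidence (total protein, phosphosite,
    or an activity hypothesis); hypothesis rows never act as targets, and a
    row cannot explain itself.
    """
    if relation.source not in source.symbols or relation.target not in target.symbols:
        return False
    if source.id == target.id:
        return False
    if source.kind not in SOURCE_KINDS:
        return False
    if target.kind is FeatureKind.ACTIVITY:
        return False
    if relation.rtype.is_phospho:
        if target.kind is not FeatureKind.PHOSPHO:
            return False
        return bool(_matched_target_sites(relation, target, settings))
    if target.kind is FeatureKind.TOTAL_PROTEIN:
        return True
    return target.kind is FeatureKind.RNA and settings.rna_targets


@dataclass(frozen=True)
class CausalConjecture:
    """A prior relation paired with the feature evidence that satisfies the
    governing parity equation."""

    relation: PriorRelation
    source_row: str
    target_row: str
    matched_sites: tuple[Site, ...]
    mode: str
    e_source: Ternary
    source_evidence: ChangeAssessment | None = None
    target_evidence: ChangeAssessment | None = None
    correlation: CorrelationAssessment | None = None


def evaluate_comparison(
    relation: PriorRelation,
    source: MeasurementRow,
    target: MeasurementRow,
    c_source: Ternary,
    c_target: Ternary,
    e_source: Ternary,
    *,
    matched_sites: tuple[Site, ...] = (),
    source_evidence: ChangeAssessment | None = None,
    target_evidence: ChangeAssessment | None = None,
) -> CausalConjecture | None:
    """Comparison-setting causality check; returns a conjecture iff

    ``c_source (+) e_source (+) s_relation (+) NOT c_target == TRUE``.
    """
    verdict = ternary_parity(
        (
            c_source,
            e_source,
            Ternary.from_bool(sign_of_relation(relation.rtype)),
            ~c_target,
        )
    )
    if verdict is not Ternary.TRUE:
        return None
    return CausalConjecture(
        relation=relation,
        source_row=source.id,
        target_row=target.id,
        matched_sites=matched_sites,
        mode="comparison",
        e_source=e_source,
        source_evidence=source_evidence,
        target_evidence=target_evidence,
    )


def evaluate_correlation(
    relation: PriorRelation,
    source: MeasurementRow,
    target: MeasurementRow,
    corr_sign: Ternary,
    e_source: Ternary,
    *,
    matched_sites: tuple[Site, ...] = (),
    correlation: CorrelationAssessment | None = None,
) -> CausalConjecture | None:
    """Correlation-setting causality check; returns a conjecture iff

    ``corr (+) e_source (+) s_relation == TRUE``.
    """
    verdict = ternary_parity(
        (corr_sign, e_source, Ternary.from_bool(sign_of_relation(relation.rtype)))
    )
    if verdict is not Ternary.TRUE:
        return None
    return CausalConjecture(
        relation=relation,
        source_row=source.id,
        target_row=target.id,
        matched_sites=matched_sites,
        mode="correlation",
        e_source=e_source,
        correlation=correlation,
    )


class EngineCache:
    """Per-dataset statistics that survive identity permutation.

    Change assessments and pairwise correlations depend only on the value
    vectors, which label permutation leaves in place, so one cache serves
    the observed analysis and every permuted replicate.  Change p-values
    are pooled for BH per feature kind; activity-hypothesis rows have their
    stated direction and are exempt.
    """

    _MATRIX_LIMIT = 600  # rows; above this correlations are computed lazily

    def __init__(self, data: ProteomicDataset, settings: AnalysisSettings) -> None:
        self.data = data
        self.settings = settings
        self._change: dict[str, ChangeAssessment] | None = None
        self._corr: dict[frozenset, tuple[float, float, int] | None] = {}
        self._matrix_ready = False
        self._row_pos: dict[str, int] = {}

    # -- comparison ----------------------------------------------------
    def change(self, row_id: str) -> ChangeAssessment:
        if self._change is None:
            self._change = self._assess_all()
        return self._change[row_id]

    def _assess_all(self) -> dict[str, ChangeAssessment]:
        s = self.settings
        raw: dict[str, ChangeAssessment] = {}
        for row in self.data:
            if row.kind is FeatureKind.ACTIVITY:
                raw[row.id] = ChangeAssessment(
                    direction=Ternary.from_bool(row.activity_direction)
                )
                continue
            if s.change_test == "ttest":
                raw[row.id] = assess_change_ttest(
                    row, s.test_columns, s.control_columns, s.min_group_n,
                    samples=self.data.samples, welch=s.welch,
                )
            else:
                raw[row.id] = assess_change_foldchange(
                    row, s.test_columns, s.control_columns,
                    s.fold_change_threshold, samples=self.data.samples,
                )
        if s.change_test == "ttest":
            # BH per feature kind; untestable rows stay NaN.
            by_kind: dict[FeatureKind, list[str]] = {}
            for row in self.data:
                if row.kind is not FeatureKind.ACTIVITY:
                    by_kind.setdefault(row.kind, []).append(row.id)
            for ids in by_kind.values():
                qs = bh_fdr([raw[i].p for i in ids])
                for row_id, q in zip(ids, qs):
                    if not np.isnan(q):
                        raw[row_id] = replace(raw[row_id], q=float(q))
        final: dict[str, ChangeAssessment] = {}
        for row in self.data:
            if row.kind is FeatureKind.ACTIVITY:
                final[row.id] = raw[row.id]
            else:
                final[row.id] = raw[row.id].finalized(
                    s.feature_fdr, use_q=s.fdr_control and s.change_test == "ttest"
                )
        return final

    # -- correlation ---------------------------------------------------
    def raw_correlation(self, id_a: str, id_b: str) -> tuple[float, float, int] | None:
        """(coefficient, p, n_used) on pairwise-complete samples, or None
        when untestable.  Symmetric and memoized."""
        key = frozenset((id_a, id_b))
        if key in self._corr:
            return self._corr[key]
        if (
            not self._matrix_ready
            and self.settings.correlation_method == "pearson"
            and len(self.data) <= self._MATRIX_LIMIT
        ):
            self._compute_matrix()
            if key in self._corr:
                return self._corr[key]
        result = self._pair_correlation(id_a, id_b)
        self._corr[key] = result
        return result

    def _value_matrix(self) -> np.ndarray:
        cols = self.settings.value_columns or self.data.samples
        idx = self.data.column_indices(cols)
        measurable = [r for r in self.data if r.values is not None]
        self._row_pos = {r.id: i for i, r in enumerate(measurable)}
        return np.vstack([r.values[idx] for r in measurable]) if measurable else np.empty((0, len(idx)))

    def _pair_correlation(self, id_a: str, id_b: str):
        row_a, row_b = self.data.row(id_a), self.data.row(id_b)
        if row_a.values is None or row_b.values is None:
            return None
        cols = self.settings.value_columns or self.data.samples
        idx = self.data.column_indices(cols)
        sub_a = MeasurementRow(
            id="a", symbols=("X",), kind=FeatureKind.TOTAL_PROTEIN, values=row_a.values[idx]
        )
        sub_b = MeasurementRow(
            id="b", symbols=("Y",), kind=FeatureKind.TOTAL_PROTEIN, values=row_b.values[idx]
        )
        assessment = correlate(
            sub_a, sub_b, self.settings.min_corr_n, self.settings.correlation_method
        )
        if not assessment.testable:
            return None
        return (assessment.coefficient, assessment.p, assessment.n_used)

    def _compute_matrix(self) -> None:
        """All-pairs pairwise-complete Pearson via masked matrix products."""
        X = self._value_matrix()
        if X.shape[0] == 0:
            self._matrix_ready = True
            return
        M = (~np.isnan(X)).astype(float)
        Xz = np.nan_to_num(X)
        n = M @ M.T
        sx = Xz @ M.T           # sum of x_i over the joint support with j
        sxx = (Xz ** 2) @ M.T
        sxy = Xz @ Xz.T
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = sxy - sx * sx.T / n
            var_x = sxx - sx ** 2 / n
            var_y = sxx.T - sx.T ** 2 / n
            r = cov / np.sqrt(var_x * var_y)
            r = np.clip(r, -1.0, 1.0)
            df = n - 2
            t = r * np.sqrt(df / np.maximum(1.0 - r ** 2, 1e-300))
            p = 2.0 * _scipy_stats.t.sf(np.abs(t), np.maximum(df, 1))
        min_n = max(self.settings.min_corr_n, 3)
        ids = list(self._row_pos)
        for i, id_a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                id_b = ids[j]
                key = frozenset((id_a, id_b))
                if n[i, j] < min_n or not np.isfinite(r[i, j]) or var_x[i, j] <= 0 or var_y[i, j] <= 0:
                    self._corr[key] = None
                else:
                    self._corr[key] = (float(r[i, j]), float(p[i, j]), int(n[i, j]))
        self._matrix_ready = True


@dataclass
class ResultNetwork:
    """Accepted conjectures aggregated by prior relation.

    Every relation present has at least one supporting conjecture; a
    relation is reported once even when several feature pairs support it.
    """

    relations: tuple[PriorRelation, ...]
    conjectures: dict[tuple, tuple[CausalConjecture, ...]]
    settings: AnalysisSettings
    significance: "object | None" = None

    def __len__(self) -> int:
        return len(self.relations)

    def relation_keys(self) -> set[tuple[str, str, str]]:
        return {rel.key for rel in self.relations}

    def conjectures_for(self, relation: PriorRelation) -> tuple[CausalConjecture, ...]:
        return self.conjectures.get(relation.dedup_key, ())

    def downstream_counts(self) -> dict[str, int]:
        """Distinct explained targets per source protein."""
        targets: dict[str, set[str]] = {}
        for rel in self.relations:
            targets.setdefault(rel.source, set()).add(rel.target)
        return {src: len(tgts) for src, tgts in targets.items()}


def _enumerate_triples(
    priors: PriorNetwork, data: ProteomicDataset, settings: AnalysisSettings
):
    """Yield (relation, source_row, target_row, matched_sites) for every
    structurally applicable triple, in deterministic order."""
    for relation in sorted(priors, key=lambda r: r.dedup_key):
        sources = sorted(data.by_symbol(relation.source), key=lambda r: r.id)
        targets = sorted(data.by_symbol(relation.target), key=lambda r: r.id)
        for src in sources:
            for tgt in targets:
                if not applicable(relation, src, tgt, settings):
                    continue
                matched = (
                    _matched_target_sites(relation, tgt, settings)
                    if relation.rtype.is_phospho
                    else ()
                )
                yield relation, src, tgt, matched


def build_result_network(
    priors: PriorNetwork,
    data: ProteomicDataset,
    settings: AnalysisSettings,
    site_effects: SiteEffectLibrary | None = None,
    cache: EngineCache | None = None,
) -> ResultNetwork:
    """Evaluate the governing parity equation over all applicable triples.

    Deterministic given settings; invariant to row and prior ordering.
    """
    if site_effects is None:
        site_effects = SiteEffectLibrary()
    if settings.mode == "comparison" and not (
        settings.test_columns and settings.control_columns
    ):
        raise ValueError("comparison mode requires test and control column groups")
    if len(priors) == 0:
        logger.warning("empty prior network: result is empty")
    if cache is None:
        cache = EngineCache(data, settings)

    accepted: dict[tuple, list[CausalConjecture]] = {}
    relations: dict[tuple, PriorRelation] = {}

    if settings.mode == "comparison":
        for relation, src, tgt, matched in _enumerate_triples(priors, data, settings):
            e_src = effect_of_feature(src, site_effects, symbol=relation.source)
            src_assessment = cache.change(src.id)
            tgt_assessment = cache.change(tgt.id)
            conj = evaluate_comparison(
                relation, src, tgt,
                src_assessment.direction, tgt_assessment.direction, e_src,
                matched_sites=matched,
                source_evidence=src_assessment,
                target_evidence=tgt_assessment,
            )
            if conj is not None:
                accepted.setdefault(relation.dedup_key, []).append(conj)
                relations[relation.dedup_key] = relation
    else:
        triples = list(_enumerate_triples(priors, data, settings))
        # BH over the distinct testable feature pairs linked by >= 1 prior.
        pair_raw: dict[frozenset, tuple[float, float, int] | None] = {}
        for _, src, tgt, _ in triples:
            key = frozenset((src.id, tgt.id))
            if key not in pair_raw:
                pair_raw[key] = cache.raw_correlation(src.id, tgt.id)
        testable = [k for k, v in pair_raw.items() if v is not None]
        qs = bh_fdr([pair_raw[k][1] for k in testable])
        pair_assessment: dict[frozenset, CorrelationAssessment] = {}
        for key, q in zip(testable, qs):
            coeff, p, n_used = pair_raw[key]
            pair_assessment[key] = CorrelationAssessment(
                sign=Ternary.from_sign(coeff), coefficient=coeff,
                p=p, q=float(q), n_used=n_used,
            ).finalized(settings.correlation_fdr, use_q=settings.fdr_control)
        for relation, src, tgt, matched in triples:
            key = frozenset((src.id, tgt.id))
            assessment = pair_assessment.get(key)
            if assessment is None:
                continue
            e_src = effect_of_feature(src, site_effects, symbol=relation.source)
            conj = evaluate_correlation(
                relation, src, tgt, assessment.sign, e_src,
                matched_sites=matched, correlation=assessment,
            )
            if conj is not None:
                accepted.setdefault(relation.dedup_key, []).append(conj)
                relations[relation.dedup_key] = relation

    ordered = tuple(relations[k] for k in sorted(relations))
    return ResultNetwork(
        relations=ordered,
        conjectures={k: tuple(v) for k, v in sorted(accepted.items())},
        settings=settings,
    )
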