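"""Label-permutation significance tests.

Two permutation tests attach confidence to an extracted network.  The
*network-size test* asks whether the number of accepted relations exceeds
what label randomization produces by chance; the *downstream-size test*
asks, per source protein, whether it explains more distinct targets than
chance.  Randomization shuffles the assignment of molecular identities
(symbols + sites + effect annotation) to value vectors uniformly among rows
of the same feature kind, which preserves the data's change/correlation
structure while breaking its link to the prior network.  Activity-hypothesis
rows are never shuffled.

Monte Carlo p-values use the add-one estimator (r + 1) / (n + 1), so they
are never zero; the exhaustive mode enumerates every label bijection and
reports the exact p = #{permutations with statistic >= observed} / n!
(the identity permutation is included, so exact p-values are positive too).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .dataset import FeatureKind, MeasurementRow, ProteomicDataset, bh_fdr, effect_of_feature
from .engine import (
    AnalysisSettings,
    EngineCache,
    ResultNetwork,
    _enumerate_triples,
    build_result_network,
)
from .priors import PriorNetwork, SiteEffectLibrary
from .ternary import Ternary

logger = logging.getLogger(__name__)

_EXHAUSTIVE_LIMIT = 500_000


@dataclass
class PermutationScheme:
    """How to randomize: permutation count, seed, and randomization unit."""

    n_permutations: int = 1000
    seed: int = 0
    mode: str = "identity_shuffle"
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if self.mode != "identity_shuffle":
            raise ValueError(f"unknown permutation mode: {self.mode!r}")
        if not self.exhaustive and self.n_permutations < 100:
            raise ValueError("at least 100 permutations are required")


@dataclass(frozen=True)
class DownstreamEntry:
    observed: int
    p: float
    q: float | None = None


@dataclass
class SignificanceReport:
    observed_size: int
    network_size_p: float
    downstream: dict[str, DownstreamEntry]
    n_network_permutations: int
    n_downstream_permutations: int
    seed: int


def permute_labels(
    data: ProteomicDataset, seed: int | np.random.Generator
) -> ProteomicDataset:
    """Shuffle molecular identities among rows of the same feature kind.

    Row ids and value vectors stay in place (the id names the measured
    vector); the (symbols, sites, effect) identity moves.  Deterministic
    for an integer seed; pass a Generator to draw from an ongoing stream.
    """
    if len(data) == 0:
        raise ValueError("cannot permute an empty dataset")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    groups: dict[FeatureKind, list[int]] = {}
    for i, row in enumerate(data.rows):
        if row.kind is not FeatureKind.ACTIVITY:
            groups.setdefault(row.kind, []).append(i)
    assignment = {i: i for i in range(len(data.rows))}
    for kind in sorted(groups, key=lambda k: k.value):
        indices = groups[kind]
        perm = rng.permutation(len(indices))
        for slot, j in enumerate(perm):
            assignment[indices[slot]] = indices[j]
    new_rows = []
    for i, row in enumerate(data.rows):
        donor = data.rows[assignment[i]]
        new_rows.append(
            MeasurementRow(
                id=row.id,
                symbols=donor.symbols,
                sites=donor.sites,
                kind=row.kind,
                values=row.values,
                effect_override=donor.effect_override,
                activity_direction=row.activity_direction,
            )
        )
    return data.with_rows(new_rows)


class _PermutationTester:
    """Fast evaluation of the accepted-relation set under label bijections.

    Candidate triples are enumerated once against *identities*; a
    permutation then only re-resolves which row currently holds each
    identity.  Change assessments and pairwise correlations are functions
    of the value vectors alone, so they are computed once through
    :class:`EngineCache` and looked up per permutation.  Equivalence with
    ``build_result_network`` on explicitly permuted datasets is covered by
    the test suite.
    """

    def __init__(
        self,
        priors: PriorNetwork,
        data: ProteomicDataset,
        settings: AnalysisSettings,
        site_effects: SiteEffectLibrary | None = None,
    ) -> None:
        self.data = data
        self.settings = settings
        self.site_effects = site_effects or SiteEffectLibrary()
        self.cache = EngineCache(data, settings)

        # Shuffling groups: per-kind row indices (activity rows fixed).
        self.groups: list[list[int]] = []
        group_of_row: dict[int, tuple[int, int]] = {}
        by_kind: dict[FeatureKind, list[int]] = {}
        for i, row in enumerate(data.rows):
            if row.kind is not FeatureKind.ACTIVITY:
                by_kind.setdefault(row.kind, []).append(i)
        for kind in sorted(by_kind, key=lambda k: k.value):
            gid = len(self.groups)
            indices = by_kind[kind]
            self.groups.append(indices)
            for slot, ridx in enumerate(indices):
                group_of_row[ridx] = (gid, slot)

        row_index = {row.id: i for i, row in enumerate(data.rows)}

        # Candidates: (relation_ordinal, source key, target key, want) where
        # keys are ('g', gid, slot) for shuffled identities or ('r', ridx)
        # for fixed activity rows, and want = XOR(e, s) (comparison) or the
        # required positive-correlation flag (correlation).  Triples with
        # e_source unknown can never be accepted (want = None) but still
        # contribute their feature pair to the BH pool in correlation mode.
        self.candidates: list[tuple[int, tuple, tuple, bool | None, str]] = []
        self.rel_keys: list[tuple] = []
        rel_ordinal: dict[tuple, int] = {}
        self.rel_source: list[str] = []
        self.rel_target: list[str] = []
        for relation, src, tgt, _matched in _enumerate_triples(priors, data, settings):
            e_src = effect_of_feature(src, self.site_effects, symbol=relation.source)
            if relation.dedup_key not in rel_ordinal:
                rel_ordinal[relation.dedup_key] = len(self.rel_keys)
                self.rel_keys.append(relation.dedup_key)
                self.rel_source.append(relation.source)
                self.rel_target.append(relation.target)
            ordinal = rel_ordinal[relation.dedup_key]
            si, ti = row_index[src.id], row_index[tgt.id]
            src_key = (
                ("r", si) if data.rows[si].kind is FeatureKind.ACTIVITY
                else ("g",) + group_of_row[si]
            )
            tgt_key = ("g",) + group_of_row[ti]
            # Eq. parity reduces to: accept iff XOR(c_src, c_tgt) == XOR(e, s)
            # (comparison) or corr-positive == (e == s) (correlation).
            want: bool | None
            if e_src is Ternary.UNKNOWN:
                want = None
            else:
                e_bool = e_src is Ternary.TRUE
                s_bool = relation.rtype.sign
                if settings.mode == "comparison":
                    want = e_bool != s_bool
                else:
                    want = e_bool == s_bool
            self.candidates.append((ordinal, src_key, tgt_key, want, src.id))

        if settings.mode == "comparison":
            self._directions = [self.cache.change(row.id).direction for row in data.rows]
        self._row_ids = [row.id for row in data.rows]

    # -- permutation plumbing -----------------------------------------
    def identity_assignment(self) -> list[np.ndarray]:
        return [np.arange(len(g)) for g in self.groups]

    def random_assignment(self, rng: np.random.Generator) -> list[np.ndarray]:
        # permute_labels lets row i adopt the identity of row perm[i]; the
        # tester resolves identities to rows, which is the inverse map.
        # argsort keeps the two views of one rng draw interchangeable.
        return [np.argsort(rng.permutation(len(g))) for g in self.groups]

    def _resolve(self, key: tuple, perms: list[np.ndarray]) -> int:
        if key[0] == "r":
            return key[1]
        _, gid, slot = key
        return self.groups[gid][perms[gid][slot]]

    # -- statistics ----------------------------------------------------
    def accepted_relations(self, perms: list[np.ndarray]) -> set[int]:
        """Ordinals of relations accepted under the given assignment."""
        s = self.settings
        if s.mode == "comparison":
            accepted: set[int] = set()
            directions = self._directions
            for ordinal, src_key, tgt_key, want, _ in self.candidates:
                if want is None:
                    continue
                si = self._resolve(src_key, perms)
                ti = self._resolve(tgt_key, perms)
                if si == ti:
                    continue
                c_src = directions[si]
                c_tgt = directions[ti]
                if c_src is Ternary.UNKNOWN or c_tgt is Ternary.UNKNOWN:
                    continue
                if ((c_src is Ternary.TRUE) != (c_tgt is Ternary.TRUE)) == want:
                    accepted.add(ordinal)
            return accepted

        # Correlation mode: gather the distinct testable pairs, apply the
        # significance rule (BH step-up or raw threshold), then the parity.
        resolved: list[tuple[int, frozenset, bool]] = []
        pair_stats: dict[frozenset, tuple[float, float, int] | None] = {}
        for ordinal, src_key, tgt_key, want, _ in self.candidates:
            si = self._resolve(src_key, perms)
            ti = self._resolve(tgt_key, perms)
            if si == ti:
                continue
            pair = frozenset((self._row_ids[si], self._row_ids[ti]))
            if pair not in pair_stats:
                pair_stats[pair] = self.cache.raw_correlation(
                    self._row_ids[si], self._row_ids[ti]
                )
            if want is not None:
                resolved.append((ordinal, pair, want))
        testable = {k: v for k, v in pair_stats.items() if v is not None}
        alpha = s.correlation_fdr
        if s.fdr_control and testable:
            ps = np.sort(np.array([v[1] for v in testable.values()]))
            m = ps.size
            thresholds = alpha * (np.arange(1, m + 1) / m)
            passing = np.nonzero(ps <= thresholds)[0]
            cut = ps[passing[-1]] if passing.size else -1.0
        else:
            cut = alpha
        accepted = set()
        for ordinal, pair, want in resolved:
            stats = testable.get(pair)
            if stats is None:
                continue
            coeff, p, _ = stats
            if p > cut or coeff == 0.0:
                continue
            if (coeff > 0) == want:
                accepted.add(ordinal)
        return accepted

    def network_size(self, perms: list[np.ndarray]) -> int:
        return len(self.accepted_relations(perms))

    def downstream_counts(self, perms: list[np.ndarray]) -> dict[str, int]:
        targets: dict[str, set[str]] = {}
        for ordinal in self.accepted_relations(perms):
            targets.setdefault(self.rel_source[ordinal], set()).add(
                self.rel_target[ordinal]
            )
        return {src: len(t) for src, t in targets.items()}

    def iter_assignments(self, scheme: PermutationScheme):
        """Yield permutation assignments per the scheme (random or all)."""
        if scheme.exhaustive:
            total = 1
            for g in self.groups:
                total *= math.factorial(len(g))
            if total > _EXHAUSTIVE_LIMIT:
                raise ValueError(
                    f"exhaustive enumeration of {total} bijections exceeds limit"
                )
            perm_sets = [
                [np.array(p, dtype=int) for p in itertools.permutations(range(len(g)))]
                for g in self.groups
            ]
            for combo in itertools.product(*perm_sets):
                yield list(combo)
        else:
            rng = np.random.default_rng(scheme.seed)
            for _ in range(scheme.n_permutations):
                yield self.random_assignment(rng)


def _monte_carlo_p(r: int, n: int) -> float:
    return (r + 1) / (n + 1)


def network_size_test(
    priors: PriorNetwork,
    data: ProteomicDataset,
    settings: AnalysisSettings,
    scheme: PermutationScheme,
    site_effects: SiteEffectLibrary | None = None,
) -> float:
    """Permutation p-value for the observed number of accepted relations.

    p = (#{permutations with size >= observed} + 1) / (n + 1) under random
    sampling, or the exact enumeration fraction in exhaustive mode.  An
    observed size of zero short-circuits to p = 1 with a warning.
    """
    tester = _PermutationTester(priors, data, settings, site_effects)
    observed = tester.network_size(tester.identity_assignment())
    if observed == 0:
        logger.warning("observed network is empty; network-size p = 1")
        return 1.0
    count = 0
    total = 0
    for perms in tester.iter_assignments(scheme):
        total += 1
        if tester.network_size(perms) >= observed:
            count += 1
    if scheme.exhaustive:
        return count / total
    return _monte_carlo_p(count, total)


def downstream_size_test(
    priors: PriorNetwork,
    data: ProteomicDataset,
    settings: AnalysisSettings,
    scheme: PermutationScheme,
    site_effects: SiteEffectLibrary | None = None,
    proteins: Sequence[str] | None = None,
) -> dict[str, DownstreamEntry]:
    """Per-protein permutation test of the downstream target count.

    By default only proteins that source at least one accepted relation in
    the observed network are tested; BH q-values are computed across them.
    Explicitly requested proteins with zero observed targets receive p = 1.
    """
    tester = _PermutationTester(priors, data, settings, site_effects)
    observed = tester.downstream_counts(tester.identity_assignment())
    if proteins is None:
        tested = sorted(observed)
    else:
        tested = sorted({p.strip().upper() for p in proteins})
    counts = {sym: 0 for sym in tested}
    total = 0
    active = [sym for sym in tested if observed.get(sym, 0) > 0]
    if active:
        for perms in tester.iter_assignments(scheme):
            total += 1
            perm_counts = tester.downstream_counts(perms)
            for sym in active:
                if perm_counts.get(sym, 0) >= observed[sym]:
                    counts[sym] += 1
    entries: dict[str, DownstreamEntry] = {}
    for sym in tested:
        obs = observed.get(sym, 0)
        if obs == 0:
            p = 1.0
        elif scheme.exhaustive:
            p = counts[sym] / total
        else:
            p = _monte_carlo_p(counts[sym], total)
        entries[sym] = DownstreamEntry(observed=obs, p=p)
    qs = bh_fdr([entries[sym].p for sym in tested])
    return {
        sym: DownstreamEntry(entries[sym].observed, entries[sym].p, float(q))
        for sym, q in zip(tested, qs)
    }


def run_significance(
    priors: PriorNetwork,
    data: ProteomicDataset,
    settings: AnalysisSettings,
    network_scheme: PermutationScheme,
    downstream_scheme: PermutationScheme | None = None,
    site_effects: SiteEffectLibrary | None = None,
) -> SignificanceReport:
    """Run both permutation tests and assemble a report.

    Defaults follow common practice for permutation-based network tests:
    many permutations for the single network-size p-value, fewer for the
    per-protein downstream family (which is then BH-adjusted).
    """
    downstream_scheme = downstream_scheme or network_scheme
    tester = _PermutationTester(priors, data, settings, site_effects)
    observed_size = tester.network_size(tester.identity_assignment())
    p_network = network_size_test(priors, data, settings, network_scheme, site_effects)
    downstream = downstream_size_test(
        priors, data, settings, downstream_scheme, site_effects
    )
    return SignificanceReport(
        observed_size=observed_size,
        network_size_p=p_network,
        downstream=downstream,
        n_network_permutations=network_scheme.n_permutations,
        n_downstream_permutations=downstream_scheme.n_permutations,
        seed=network_scheme.seed,
    )
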