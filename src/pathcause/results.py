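"""Result serialization, recurrence ranking, and precision estimators.

The result network is written in an extended SIF dialect (one accepted
relation per line) and as a versioned JSON document carrying
conjecture-level evidence and the significance report.  Cross-dataset
recurrence ranking counts, per relation, how many result networks contain
it — the device used to find signaling relations that recur across many
cancer cohorts.  The precision estimators summarize inhibitor-validation
experiments: relations whose source is drugged should reverse downstream
when the drug is applied.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .engine import AnalysisSettings, ResultNetwork
from .priors import PriorNetwork, PriorRelation, RelationType, Site
from .significance import SignificanceReport

logger = logging.getLogger(__name__)

RESULT_SCHEMA_VERSION = 1

_SIF_HEADER = "Source\tRelation\tTarget\tMatchedSites\tMediators"


def write_sif(net: ResultNetwork, path: str | Path) -> None:
    """Write one line per accepted relation, in stable sorted order.

    The MatchedSites column lists the distinct data sites (sorted) that
    supported the relation across its conjectures.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_SIF_HEADER + "\n")
        for rel in net.relations:  # already sorted by dedup key
            matched: set[Site] = set()
            for conj in net.conjectures_for(rel):
                matched.update(conj.matched_sites)
            sites = ";".join(str(s) for s in sorted(matched))
            mediators = ";".join(rel.mediators)
            fh.write(f"{rel.source}\t{rel.rtype.value}\t{rel.target}\t{sites}\t{mediators}\n")


def read_sif(path: str | Path) -> PriorNetwork:
    """Read a result SIF back into a relation set.

    Matched sites re-attach as target-site annotations on phospho
    relations, so write-then-read reproduces the relation set.
    """
    path = Path(path)
    relations = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or (lineno == 1 and line.startswith("Source\t")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed SIF line")
            rtype = RelationType.parse(fields[1])
            sites = tuple(
                Site.parse(t) for t in fields[3].split(";") if t.strip()
            ) if len(fields) > 3 and rtype.is_phospho else ()
            mediators = tuple(
                m for m in fields[4].split(";") if m.strip()
            ) if len(fields) > 4 else ()
            relations.append(PriorRelation(fields[0], rtype, fields[2], sites, mediators))
    return PriorNetwork(relations)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (Site,)):
        return str(obj)
    if hasattr(obj, "value") and not isinstance(obj, (int, float, str)):
        return obj.value  # enums
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def write_json(
    net: ResultNetwork,
    path: str | Path,
    report: SignificanceReport | None = None,
) -> None:
    """Serialize the result network (and optional significance report).

    The schema is artifact-specific and versioned via ``schema_version``.
    """
    report = report if report is not None else net.significance
    document = {
        "schema_version": RESULT_SCHEMA_VERSION,
        "settings": _jsonable(net.settings),
        "n_relations": len(net),
        "relations": [
            {
                "source": rel.source,
                "relation": rel.rtype.value,
                "target": rel.target,
                "prior_sites": [str(s) for s in rel.target_sites],
                "mediators": list(rel.mediators),
                "conjectures": [
                    {
                        "source_row": conj.source_row,
                        "target_row": conj.target_row,
                        "matched_sites": [str(s) for s in conj.matched_sites],
                        "mode": conj.mode,
                        "e_source": conj.e_source.value,
                        "source_evidence": _jsonable(conj.source_evidence),
                        "target_evidence": _jsonable(conj.target_evidence),
                        "correlation": _jsonable(conj.correlation),
                    }
                    for conj in net.conjectures_for(rel)
                ],
            }
            for rel in net.relations
        ],
        "significance": _jsonable(report) if report is not None else None,
    }
    Path(path).write_text(json.dumps(document, indent=1, sort_keys=False) + "\n")


def read_json(path: str | Path) -> dict:
    document = json.loads(Path(path).read_text())
    if document.get("schema_version") != RESULT_SCHEMA_VERSION:
        raise ValueError(f"unsupported result schema: {document.get('schema_version')}")
    return document


def recurrence_rank(
    networks: Mapping[str, ResultNetwork | PriorNetwork | set],
    min_count: int = 1,
) -> list[tuple[tuple[str, str, str], int]]:
    """Count, per (source, relation, target), how many named networks
    contain it; rank descending, ties broken lexicographically.

    Relations present in fewer than ``min_count`` networks are dropped
    (set ``min_count=15`` to reproduce a recur-in-15-plus-datasets rule).
    """
    if len(networks) < 2:
        raise ValueError("recurrence ranking needs at least two networks")
    counts: dict[tuple[str, str, str], int] = {}
    for name in sorted(networks):
        net = networks[name]
        keys = net if isinstance(net, (set, frozenset)) else net.relation_keys()
        for key in keys:
            counts[key] = counts.get(key, 0) + 1
    ranked = [(key, n) for key, n in counts.items() if n >= min_count]
    ranked.sort(key=lambda item: (-item[1], item[0]))
    return ranked


@dataclass(frozen=True)
class ValidationCase:
    """One inhibitor-validation readout for an accepted relation.

    ``expected_direction`` is the downstream change direction predicted
    under inhibition of the relation's source; ``observed_change`` is the
    measured change (normalized units); ``significant`` flags whether the
    change passed the stated FDR threshold.
    """

    relation: str
    expected_direction: str
    observed_change: float
    significant: bool

    def __post_init__(self) -> None:
        if self.expected_direction not in ("up", "down"):
            raise ValueError(f"expected_direction must be 'up'/'down': {self.expected_direction!r}")
        if not math.isfinite(self.observed_change):
            raise ValueError("observed change must be finite")

    @property
    def in_expected_direction(self) -> bool:
        if self.observed_change > 0:
            return self.expected_direction == "up"
        if self.observed_change < 0:
            return self.expected_direction == "down"
        return False

    @property
    def contrary(self) -> bool:
        if self.observed_change == 0:
            return False
        return not self.in_expected_direction


def _round2(x: float) -> float:
    """Round half-up to two decimals (0.90625 -> 0.91)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PrecisionEstimates:
    """Three precision readings of a validation-case collection.

    ``naive`` counts every expected-direction change as a success.
    ``significant_only`` treats insignificant changes as unchanged.
    ``noise_adjusted`` assumes measurement noise symmetric around zero:
    the contrary-direction count estimates how many expected-direction
    cases are spurious, and is subtracted before dividing.  Raw ratios are
    retained; reported values are rounded half-up to two decimals.
    """

    n_cases: int
    n_expected: int
    n_contrary: int
    n_significant_expected: int
    adjusted_changed_count: int
    naive_raw: float
    significant_only_raw: float
    noise_adjusted_raw: float

    @property
    def naive(self) -> float:
        return _round2(self.naive_raw)

    @property
    def significant_only(self) -> float:
        return _round2(self.significant_only_raw)

    @property
    def noise_adjusted(self) -> float:
        return _round2(self.noise_adjusted_raw)


def precision_estimates(
    cases: Sequence[ValidationCase], fdr: float = 0.1
) -> PrecisionEstimates:
    """Compute the naive, significant-only and noise-adjusted precision of
    a set of inhibitor-validation cases.

    ``fdr`` records the threshold at which the per-case ``significant``
    flags were called; it does not alter the arithmetic.
    """
    cases = list(cases)
    if not cases:
        raise ValueError("precision estimation needs at least one case")
    n = len(cases)
    n_expected = sum(1 for c in cases if c.in_expected_direction)
    n_contrary = sum(1 for c in cases if c.contrary)
    n_sig_expected = sum(1 for c in cases if c.significant and c.in_expected_direction)
    adjusted = max(n_expected - n_contrary, 0)
    return PrecisionEstimates(
        n_cases=n,
        n_expected=n_expected,
        n_contrary=n_contrary,
        n_significant_expected=n_sig_expected,
        adjusted_changed_count=adjusted,
        naive_raw=n_expected / n,
        significant_only_raw=n_sig_expected / n,
        noise_adjusted_raw=adjusted / n,
    )
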