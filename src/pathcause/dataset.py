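"""Proteomic data tables and per-feature statistical assessments.

A dataset is a collection of measured molecular features (rows) over named
sample columns.  Rows are typed: total protein, phosphosite peptide, RNA,
or an injected *activity hypothesis* (an unmeasured row asserting a
protein's activity direction, e.g. ligand stimulation or drug-target
inactivation).  Values are assumed normalized/comparable; missing entries
are allowed and handled complete-case per group (comparisons) or
pairwise-complete (correlations).

The expected table dialect is TSV with header columns ``ID``, ``Symbols``,
``Sites`` and optionally ``Effect`` and ``Feature``, followed by sample
columns.  Symbols are space-joined; sites are ``|``- or ``;``-joined
residue+position tokens (``S235|S236``).
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .priors import Effect, Site, SiteEffectLibrary
from .ternary import Ternary

logger = logging.getLogger(__name__)


class FeatureKind(enum.Enum):
    TOTAL_PROTEIN = "protein"
    PHOSPHO = "phospho"
    RNA = "rna"
    ACTIVITY = "activity"

    @classmethod
    def parse(cls, token: str) -> "FeatureKind":
        canon = token.strip().lower()
        aliases = {
            "protein": cls.TOTAL_PROTEIN,
            "total_protein": cls.TOTAL_PROTEIN,
            "total-protein": cls.TOTAL_PROTEIN,
            "global": cls.TOTAL_PROTEIN,
            "phospho": cls.PHOSPHO,
            "phosphoprotein": cls.PHOSPHO,
            "rna": cls.RNA,
            "activity": cls.ACTIVITY,
        }
        if canon not in aliases:
            raise ValueError(f"unknown feature kind: {token!r}")
        return aliases[canon]


@dataclass
class MeasurementRow:
    """One measured molecular feature with its sample values.

    ``values`` is aligned to the dataset's sample columns and is ``None``
    only for activity-hypothesis rows, whose direction is fixed via
    ``activity_direction`` instead of being estimated from data.
    """

    id: str
    symbols: tuple[str, ...]
    sites: tuple[Site, ...] = ()
    kind: FeatureKind = FeatureKind.TOTAL_PROTEIN
    values: np.ndarray | None = None
    effect_override: Effect | None = None
    activity_direction: bool | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("row id must be nonempty")
        self.symbols = tuple(s.strip().upper() for s in self.symbols if s.strip())
        if not self.symbols:
            raise ValueError(f"row {self.id}: at least one gene symbol required")
        self.sites = tuple(self.sites)
        if self.kind is FeatureKind.PHOSPHO and not self.sites:
            raise ValueError(f"row {self.id}: phospho rows require at least one site")
        if self.kind is FeatureKind.ACTIVITY:
            if self.values is not None:
                raise ValueError(f"row {self.id}: activity rows carry no values")
            if self.activity_direction is None:
                raise ValueError(f"row {self.id}: activity rows need a direction")
        elif self.values is not None:
            self.values = np.asarray(self.values, dtype=float)

    @property
    def identity(self) -> tuple:
        """The molecular identity that label permutation shuffles."""
        return (self.symbols, self.sites, self.effect_override)


@dataclass
class ChangeAssessment:
    """Ternary change direction with its statistic and (adjusted) p-value.

    ``direction`` as produced by the assess functions is the provisional
    sign of the change; :meth:`finalized` demotes it to ``UNKNOWN`` when the
    row is untestable or not significant at the chosen threshold.
    """

    direction: Ternary
    statistic: float | None = None
    p: float | None = None
    q: float | None = None

    @classmethod
    def untestable(cls) -> "ChangeAssessment":
        return cls(direction=Ternary.UNKNOWN)

    @property
    def testable(self) -> bool:
        return self.p is not None or self.direction.is_known

    def finalized(self, threshold: float, use_q: bool = True) -> "ChangeAssessment":
        """Apply the significance threshold, yielding the final ternary call."""
        if self.p is None and self.q is None:
            return self  # fold-change style or untestable: already final
        crit = self.q if use_q else self.p
        if crit is None or crit > threshold:
            return replace(self, direction=Ternary.UNKNOWN)
        return self


@dataclass
class CorrelationAssessment:
    """Ternary correlation sign with coefficient, p, q and sample count."""

    sign: Ternary
    coefficient: float | None = None
    p: float | None = None
    q: float | None = None
    n_used: int = 0

    @classmethod
    def untestable(cls, n_used: int = 0) -> "CorrelationAssessment":
        return cls(sign=Ternary.UNKNOWN, n_used=n_used)

    @property
    def testable(self) -> bool:
        return self.p is not None

    def finalized(self, threshold: float, use_q: bool = True) -> "CorrelationAssessment":
        if self.p is None:
            return self
        crit = self.q if use_q else self.p
        if crit is None or crit > threshold:
            return replace(self, sign=Ternary.UNKNOWN)
        return self


class ProteomicDataset:
    """Rows plus the ordered sample column names they are aligned to."""

    def __init__(self, rows: Iterable[MeasurementRow], samples: Sequence[str]) -> None:
        self.rows: list[MeasurementRow] = list(rows)
        self.samples: tuple[str, ...] = tuple(samples)
        ids = [row.id for row in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate row IDs: {dupes[:5]}")
        for row in self.rows:
            if row.values is not None and row.values.shape != (len(self.samples),):
                raise ValueError(
                    f"row {row.id}: {row.values.shape[0]} values for "
                    f"{len(self.samples)} sample columns"
                )
        self._reindex()

    def _reindex(self) -> None:
        self._by_id = {row.id: row for row in self.rows}
        self._by_symbol: dict[str, list[MeasurementRow]] = {}
        for row in self.rows:
            for symbol in row.symbols:
                self._by_symbol.setdefault(symbol, []).append(row)

    def row(self, row_id: str) -> MeasurementRow:
        return self._by_id[row_id]

    def by_symbol(self, symbol: str) -> Sequence[MeasurementRow]:
        return self._by_symbol.get(symbol.upper(), ())

    def column_indices(self, columns: Sequence[str]) -> np.ndarray:
        missing = [c for c in columns if c not in self.samples]
        if missing:
            raise ValueError(f"unknown sample columns: {missing}")
        lookup = {name: i for i, name in enumerate(self.samples)}
        return np.array([lookup[c] for c in columns], dtype=int)

    def add_hypothesis(self, symbol: str, direction: str | bool) -> MeasurementRow:
        """Inject (or return the existing) activity-hypothesis row."""
        row = inject_activity_hypothesis(symbol, direction)
        existing = self._by_id.get(row.id)
        if existing is not None:
            logger.warning("duplicate hypothesis for %s collapsed", symbol)
            return existing
        self.rows.append(row)
        self._reindex()
        return row

    def with_rows(self, rows: Iterable[MeasurementRow]) -> "ProteomicDataset":
        return ProteomicDataset(rows, self.samples)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)


def parse_site_string(text: str) -> tuple[Site, ...]:
    """Parse ``|``- or ``;``-joined residue+position tokens into sites.

    Returns an ordered, deduplicated tuple; the empty string parses to an
    empty collection.  Malformed tokens raise ``ValueError`` naming the
    token.
    """
    if text is None:
        return ()
    text = str(text).strip()
    if not text or text.lower() == "nan":
        return ()
    tokens = [t for part in text.split("|") for t in part.split(";") if t.strip()]
    seen: dict[Site, None] = {}
    for token in tokens:
        seen.setdefault(Site.parse(token), None)
    return tuple(seen)


_META_COLUMNS = ("id", "symbols", "sites", "effect", "feature")


def parse_data_table(path: str | Path) -> ProteomicDataset:
    """Parse a TSV proteomic table into a :class:`ProteomicDataset`.

    Header must contain ``ID``, ``Symbols``, ``Sites`` (case-insensitive);
    ``Effect`` and ``Feature`` are optional overrides.  All remaining
    columns are sample columns; non-numeric cells become missing values.
    Duplicate IDs and tables without sample columns are hard errors.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    colmap = {c.strip().lower(): c for c in frame.columns}
    for required in ("id", "symbols", "sites"):
        if required not in colmap:
            raise ValueError(f"{path}: missing required column {required!r}")
    sample_cols = [c for c in frame.columns if c.strip().lower() not in _META_COLUMNS]
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns found")
    values = frame[sample_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)

    rows: list[MeasurementRow] = []
    for i in range(len(frame)):
        row_id = frame[colmap["id"]].iat[i].strip()
        symbols = tuple(frame[colmap["symbols"]].iat[i].split())
        sites = parse_site_string(frame[colmap["sites"]].iat[i])
        effect = None
        if "effect" in colmap:
            token = frame[colmap["effect"]].iat[i].strip()
            effect = Effect.parse(token) if token else None
        if "feature" in colmap and frame[colmap["feature"]].iat[i].strip():
            kind = FeatureKind.parse(frame[colmap["feature"]].iat[i])
        else:
            kind = FeatureKind.PHOSPHO if sites else FeatureKind.TOTAL_PROTEIN
        rows.append(
            MeasurementRow(
                id=row_id,
                symbols=symbols,
                sites=sites,
                kind=kind,
                values=values[i],
                effect_override=effect,
            )
        )
    n_missing = int(np.isnan(values).sum())
    logger.info(
        "%s: %d rows, %d sample columns, %d missing cells",
        path, len(rows), len(sample_cols), n_missing,
    )
    return ProteomicDataset(rows, sample_cols)


def _group_values(row: MeasurementRow, idx: np.ndarray) -> np.ndarray:
    vals = row.values[idx]
    return vals[~np.isnan(vals)]


def assess_change_ttest(
    row: MeasurementRow,
    test_columns: Sequence[str],
    control_columns: Sequence[str],
    min_n: int = 3,
    *,
    samples: Sequence[str],
    welch: bool = True,
) -> ChangeAssessment:
    """Two-sample t test of test vs control columns on non-missing values.

    Welch (unequal-variance) by default; ``welch=False`` selects the
    pooled-variance form.  Rows with fewer than ``min_n`` usable values in
    either group are untestable.  The returned direction is the provisional
    sign of (mean_test - mean_control); BH adjustment and thresholding
    happen downstream.
    """
    if min_n < 2:
        raise ValueError("min_n must be >= 2")
    if row.values is None:
        return ChangeAssessment.untestable()
    lookup = {name: i for i, name in enumerate(samples)}
    test = _group_values(row, np.array([lookup[c] for c in test_columns], dtype=int))
    ctrl = _group_values(row, np.array([lookup[c] for c in control_columns], dtype=int))
    if len(test) < min_n or len(ctrl) < min_n:
        return ChangeAssessment.untestable()
    diff = float(test.mean() - ctrl.mean())
    if test.std(ddof=1) == 0.0 and ctrl.std(ddof=1) == 0.0:
        if diff == 0.0:
            return ChangeAssessment.untestable()
        # Degenerate but unambiguous: identical values within each group.
        return ChangeAssessment(
            direction=Ternary.from_sign(diff), statistic=math.copysign(math.inf, diff), p=0.0
        )
    result = stats.ttest_ind(test, ctrl, equal_var=not welch)
    statistic, p = float(result.statistic), float(result.pvalue)
    if math.isnan(p):
        return ChangeAssessment.untestable()
    return ChangeAssessment(direction=Ternary.from_sign(diff), statistic=statistic, p=p)


def assess_change_foldchange(
    row: MeasurementRow,
    test_columns: Sequence[str],
    control_columns: Sequence[str],
    threshold: float,
    *,
    samples: Sequence[str],
) -> ChangeAssessment:
    """Mean-difference change call with a symmetric dead band.

    Direction is up when mean_test - mean_control >= threshold, down when
    <= -threshold, otherwise unknown.  No p/q is attached; values are
    assumed to be on a comparable (normalized, typically log) scale.
    """
    if threshold <= 0:
        raise ValueError("fold-change threshold must be positive")
    if row.values is None:
        return ChangeAssessment.untestable()
    lookup = {name: i for i, name in enumerate(samples)}
    test = _group_values(row, np.array([lookup[c] for c in test_columns], dtype=int))
    ctrl = _group_values(row, np.array([lookup[c] for c in control_columns], dtype=int))
    if len(test) == 0 or len(ctrl) == 0:
        return ChangeAssessment.untestable()
    diff = float(test.mean() - ctrl.mean())
    if diff >= threshold:
        direction = Ternary.TRUE
    elif diff <= -threshold:
        direction = Ternary.FALSE
    else:
        direction = Ternary.UNKNOWN
    return ChangeAssessment(direction=direction, statistic=diff)


def correlate(
    row_a: MeasurementRow,
    row_b: MeasurementRow,
    min_n: int = 5,
    method: str = "pearson",
) -> CorrelationAssessment:
    """Pairwise-complete correlation between two rows' value vectors.

    Untestable when fewer than ``min_n`` samples are complete in both rows
    or either row has zero variance on the shared support.  Symmetric in
    its arguments.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method: {method!r}")
    if row_a.values is None or row_b.values is None:
        return CorrelationAssessment.untestable()
    mask = ~(np.isnan(row_a.values) | np.isnan(row_b.values))
    n_used = int(mask.sum())
    if n_used < max(min_n, 3):
        return CorrelationAssessment.untestable(n_used)
    a, b = row_a.values[mask], row_b.values[mask]
    if a.std() == 0.0 or b.std() == 0.0:
        return CorrelationAssessment.untestable(n_used)
    if method == "pearson":
        res = stats.pearsonr(a, b)
    else:
        res = stats.spearmanr(a, b)
    coeff, p = float(res.statistic), float(res.pvalue)
    if math.isnan(coeff):
        return CorrelationAssessment.untestable(n_used)
    return CorrelationAssessment(
        sign=Ternary.from_sign(coeff), coefficient=coeff, p=p, n_used=n_used
    )


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order preserving.

    Missing entries (NaN/None) pass through as NaN and do not count toward
    the number of tests.  Values outside [0, 1] are a hard error.
    """
    arr = np.array([np.nan if p is None else float(p) for p in pvalues], dtype=float)
    if arr.size == 0:
        return arr
    finite = ~np.isnan(arr)
    if np.any((arr[finite] < 0) | (arr[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(arr.shape, np.nan)
    if finite.any():
        out[finite] = multipletests(arr[finite], method="fdr_bh")[1]
    return out


def inject_activity_hypothesis(symbol: str, direction: str | bool) -> MeasurementRow:
    """Build an activity-hypothesis row for ``symbol``.

    The row carries no values; its change direction is fixed to the stated
    activation (``"up"``/``True``) or inactivation (``"down"``/``False``)
    and is exempt from FDR control.  Its effect on downstream reasoning is
    that of an active protein (e = true).
    """
    if not symbol or not symbol.strip():
        raise ValueError("hypothesis symbol must be nonempty")
    if isinstance(direction, str):
        canon = direction.strip().lower()
        if canon not in ("up", "down"):
            raise ValueError(f"hypothesis direction must be 'up' or 'down': {direction!r}")
        up = canon == "up"
    else:
        up = bool(direction)
    symbol = symbol.strip().upper()
    return MeasurementRow(
        id=f"hyp:{symbol}:{'up' if up else 'down'}",
        symbols=(symbol,),
        kind=FeatureKind.ACTIVITY,
        activity_direction=up,
    )


def effect_of_feature(
    row: MeasurementRow,
    library: SiteEffectLibrary,
    symbol: str | None = None,
) -> Ternary:
    """Ternary effect of a source feature on its protein's activity.

    Total protein and activity rows read as ``TRUE`` (more protein / more
    activity means more downstream action).  Phospho rows consult the
    site-effect library; rows spanning several annotated sites must agree
    unanimously (all activating or all inhibiting) or the effect is
    ``UNKNOWN``, as is a row with no annotated site.  A per-row ``Effect``
    override from the data table wins over the library.

    RNA rows have no activity reading and are rejected.
    """
    if row.kind in (FeatureKind.TOTAL_PROTEIN, FeatureKind.ACTIVITY):
        return Ternary.TRUE
    if row.kind is FeatureKind.RNA:
        raise ValueError(f"row {row.id}: RNA rows cannot act as causal sources")
    if row.effect_override is not None:
        return row.effect_override.as_ternary
    symbols = (symbol.upper(),) if symbol else row.symbols
    annotated = {
        library.effect_of(sym, site)
        for sym in symbols
        for site in row.sites
    } - {Effect.UNKNOWN}
    if len(annotated) == 1:
        return next(iter(annotated)).as_ternary
    return Ternary.UNKNOWN
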