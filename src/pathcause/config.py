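"""Flat ``key = value`` analysis-parameters file.

One parameter per line; repeatable keys (column groups, hypotheses) appear
once per value.  Unknown keys are errors, not warnings — silent typos in
an analysis configuration are worse than a hard stop.  A config round-trips
unchanged through :meth:`AnalysisConfig.to_file` / :meth:`from_file`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

from .engine import AnalysisSettings


@dataclass
class AnalysisConfig:
    """Everything needed to re-run an analysis: paths, mode, thresholds."""

    proteomics_file: str = ""
    prior_file: str = ""
    site_effects_file: str = ""
    output_prefix: str = "results"

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

    run_significance: bool = False
    network_permutations: int = 10000
    downstream_permutations: int = 1000
    downstream_fdr: float = 0.1
    seed: int = 0

    hypotheses_activated: tuple[str, ...] = ()
    hypotheses_inactivated: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("feature_fdr", "correlation_fdr", "downstream_fdr"):
            value = getattr(self, name)
            if not (0 < value <= 1):
                raise ValueError(f"{name} must lie in (0, 1]: {value}")
        for name in (
            "test_columns", "control_columns", "value_columns",
            "hypotheses_activated", "hypotheses_inactivated",
        ):
            setattr(self, name, tuple(getattr(self, name)))

    def to_settings(self) -> AnalysisSettings:
        return AnalysisSettings(
            mode=self.mode,
            test_columns=self.test_columns,
            control_columns=self.control_columns,
            value_columns=self.value_columns,
            change_test=self.change_test,
            fold_change_threshold=self.fold_change_threshold,
            feature_fdr=self.feature_fdr,
            correlation_fdr=self.correlation_fdr,
            fdr_control=self.fdr_control,
            site_tolerance=self.site_tolerance,
            strict_residue=self.strict_residue,
            unsited_prior_matches_any=self.unsited_prior_matches_any,
            rna_targets=self.rna_targets,
            correlation_method=self.correlation_method,
            welch=self.welch,
            min_group_n=self.min_group_n,
            min_corr_n=self.min_corr_n,
        )

    # -- file format ---------------------------------------------------
    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        scalar: dict[str, object] = {}
        listy: dict[str, list[str]] = {}
        with path.open() as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in _KEYMAP:
                    raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
                name = _KEYMAP[key]
                if name in _LIST_FIELDS:
                    listy.setdefault(name, []).append(value)
                else:
                    if name in scalar:
                        raise ValueError(f"{path}:{lineno}: duplicate parameter {key!r}")
                    scalar[name] = _parse_scalar(name, value, path, lineno)
        kwargs: dict[str, object] = dict(scalar)
        for name, values in listy.items():
            kwargs[name] = tuple(values)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            key = _REVERSE_KEYMAP[f.name]
            value = getattr(self, f.name)
            if f.name in _LIST_FIELDS:
                lines.extend(f"{key} = {v}" for v in value)
            elif isinstance(value, bool):
                lines.append(f"{key} = {'true' if value else 'false'}")
            else:
                lines.append(f"{key} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")


_KEYMAP = {
    "proteomics-file": "proteomics_file",
    "prior-file": "prior_file",
    "site-effects-file": "site_effects_file",
    "output-prefix": "output_prefix",
    "mode": "mode",
    "test-column": "test_columns",
    "control-column": "control_columns",
    "value-column": "value_columns",
    "change-test": "change_test",
    "fold-change-threshold": "fold_change_threshold",
    "feature-fdr": "feature_fdr",
    "correlation-fdr": "correlation_fdr",
    "fdr-control": "fdr_control",
    "site-match-tolerance": "site_tolerance",
    "strict-residue-match": "strict_residue",
    "unsited-priors-match-any": "unsited_prior_matches_any",
    "rna-targets": "rna_targets",
    "correlation-method": "correlation_method",
    "welch": "welch",
    "min-group-size": "min_group_n",
    "min-correlation-samples": "min_corr_n",
    "run-significance": "run_significance",
    "network-permutations": "network_permutations",
    "downstream-permutations": "downstream_permutations",
    "downstream-fdr": "downstream_fdr",
    "seed": "seed",
    "hypothesis-activated": "hypotheses_activated",
    "hypothesis-inactivated": "hypotheses_inactivated",
}
_REVERSE_KEYMAP = {v: k for k, v in _KEYMAP.items()}
_LIST_FIELDS = {
    "test_columns", "control_columns", "value_columns",
    "hypotheses_activated", "hypotheses_inactivated",
}
_BOOL_FIELDS = {
    "fdr_control", "strict_residue", "unsited_prior_matches_any",
    "rna_targets", "welch", "run_significance",
}
_INT_FIELDS = {
    "site_tolerance", "min_group_n", "min_corr_n",
    "network_permutations", "downstream_permutations", "seed",
}
_FLOAT_FIELDS = {
    "fold_change_threshold", "feature_fdr", "correlation_fdr", "downstream_fdr",
}


def _parse_scalar(name: str, value: str, path: Path, lineno: int):
    try:
        if name in _BOOL_FIELDS:
            canon = value.lower()
            if canon not in ("true", "false"):
                raise ValueError(f"expected true/false, got {value!r}")
            return canon == "true"
        if name in _INT_FIELDS:
            return int(value)
        if name in _FLOAT_FIELDS:
            return float(value)
        return value
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: bad value for {name}: {exc}") from None
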