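import numpy as np
import pytest

from pathcause import (
    AnalysisSettings,
    Effect,
    FeatureKind,
    MeasurementRow,
    PriorNetwork,
    PriorRelation,
    ProteomicDataset,
    RelationType,
    Site,
    SiteEffectLibrary,
)


@pytest.fixture
def egf_priors() -> PriorNetwork:
    """A miniature growth-factor cascade: ligand -> receptor -> adaptor."""
    return PriorNetwork(
        [
            PriorRelation("EGF", RelationType.PHOSPHORYLATES, "EGFR", (Site("Y", 1068),)),
            PriorRelation("EGFR", RelationType.PHOSPHORYLATES, "GAB1", (Site("Y", 406),)),
        ]
    )


@pytest.fixture
def egf_site_effects() -> SiteEffectLibrary:
    return SiteEffectLibrary(
        [
            ("EGFR", Site("Y", 1068), Effect.ACTIVATING),
            ("GAB1", Site("Y", 406), Effect.ACTIVATING),
        ]
    )


def make_row(
    row_id,
    symbol,
    values,
    sites=(),
    kind=None,
    effect_override=None,
):
    sites = tuple(Site.parse(s) for s in sites) if sites and isinstance(sites[0], str) else tuple(sites)
    if kind is None:
        kind = FeatureKind.PHOSPHO if sites else FeatureKind.TOTAL_PROTEIN
    return MeasurementRow(
        id=row_id,
        symbols=(symbol,) if isinstance(symbol, str) else tuple(symbol),
        sites=sites,
        kind=kind,
        values=np.asarray(values, dtype=float) if values is not None else None,
        effect_override=effect_override,
    )


@pytest.fixture
def egf_dataset() -> ProteomicDataset:
    """Three test + three control samples; receptor and adaptor sites up."""
    rows = [
        make_row("egfr_py1068", "EGFR", [2.1, 1.9, 2.0, 0.0, 0.1, -0.1], sites=("Y1068",)),
        make_row("gab1_py406", "GAB1", [1.8, 2.2, 2.0, -0.1, 0.0, 0.1], sites=("Y406",)),
    ]
    data = ProteomicDataset(rows, ["T1", "T2", "T3", "C1", "C2", "C3"])
    data.add_hypothesis("EGF", "up")
    return data


@pytest.fixture
def comparison_settings() -> AnalysisSettings:
    return AnalysisSettings(
        mode="comparison",
        test_columns=("T1", "T2", "T3"),
        control_columns=("C1", "C2", "C3"),
        change_test="foldchange",
        fold_change_threshold=0.5,
    )
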