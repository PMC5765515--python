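import datetime as dt

import pytest

from uifscan.report_store import ConcernRecord, ReportRecord, ScreenConfig, TermHierarchy


@pytest.fixture
def small_hierarchy() -> TermHierarchy:
    """10 PTs under 3 HLTs, one SMQ of 4 PTs, mixed IME flags."""
    pt_to_hlt = {
        "pt_a": "hlt_1",
        "pt_b": "hlt_1",
        "pt_c": "hlt_1",
        "pt_d": "hlt_2",
        "pt_e": "hlt_2",
        "pt_f": "hlt_2",
        "pt_g": "hlt_3",
        "pt_h": "hlt_3",
        "pt_i": "hlt_3",
        "pt_q": "hlt_3",
    }
    return TermHierarchy(
        pt_to_hlt=pt_to_hlt,
        hlt_to_hlgt={"hlt_1": "hlgt_1", "hlt_2": "hlgt_1", "hlt_3": "hlgt_2"},
        hlgt_to_soc={"hlgt_1": "soc_1", "hlgt_2": "soc_1"},
        smq_members={
            "smq_x": {"pt_b": "broad", "pt_c": "narrow", "pt_d": "broad", "pt_g": "broad"}
        },
        ime_terms=frozenset({"pt_a", "pt_b", "pt_d", "pt_e", "pt_g", "pt_q"}),
        dme_terms=frozenset({"pt_c"}),
        quality_issue_terms=frozenset({"pt_q"}),
    )


@pytest.fixture
def loose_config() -> ScreenConfig:
    """All PTs countable, literature included — for counting arithmetic tests."""
    return ScreenConfig(threshold_tau=3, restrict_ime_dme=False)


def make_report(
    case_id="C1",
    date="2010-07-15",
    substance="drug s",
    product=None,
    pt="pt_a",
    literature=False,
    module="post_marketing",
) -> ReportRecord:
    return ReportRecord(
        case_id=case_id,
        receive_date=dt.date.fromisoformat(date),
        substance=substance,
        product_name=product,
        event_pt=pt,
        literature=literature,
        module=module,
    )


def make_concern(
    concern_id="c1",
    substance="drug s",
    index_date="2010-08-23",
    concern_type="QD",
    grouping=(("SMQ", "smq_x"),),
    product_names=None,
) -> ConcernRecord:
    return ConcernRecord(
        concern_id=concern_id,
        substance=substance,
        index_date=dt.date.fromisoformat(index_date),
        concern_type=concern_type,
        grouping_terms=tuple(grouping),
        product_names=product_names,
    )
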