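import pytest

from burdenkit.core import Cause, CauseList, CodeRange, DeathRecord


def make_cause(cause_id, group, ranges, source=False, name=None):
    return Cause(
        cause_id=cause_id,
        name=name or cause_id,
        disease_group=group,
        icd10_ranges=tuple(CodeRange.parse(r) for r in ranges),
        is_redistribution_source=source,
    )


@pytest.fixture
def toy_cause_list():
    """Small cause list with one cause per method-relevant role: two specific
    cardiovascular/respiratory causes, cancer sites, and three ill-defined
    sources (septicaemia, unknown primary, R-chapter)."""
    return CauseList(
        [
            make_cause("chd", "cardiovascular", ["I20-I25"]),
            make_cause("stroke", "cardiovascular", ["I60-I64"]),
            make_cause("pneumonia", "respiratory", ["J12-J18"]),
            make_cause("lung_ca", "cancer", ["C33-C34"]),
            make_cause("colorectal_ca", "cancer", ["C18-C20"]),
            make_cause("sepsis", "infections", ["A40-A41"], source=True),
            make_cause("cup", "cancer", ["C80"], source=True),
            make_cause("unspec_ca", "cancer", ["C76"], source=True),
            make_cause("ill_defined", "ill-defined", ["R00-R99"], source=True),
        ]
    )


def death(rid, ucod, associated=(), age=70, sex="F", weight=1.0):
    return DeathRecord(
        record_id=str(rid), age=age, sex=sex, ucod=ucod,
        associated=tuple(associated), weight=weight,
    )
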