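import pytest

from metasynth import MetaSummary, datasets, meta_analyze


@pytest.fixture(scope="session")
def table1_all():
    return datasets.table1()


@pytest.fixture(scope="session")
def table1_split():
    return datasets.table1(split=True)


@pytest.fixture(scope="session")
def table2():
    return datasets.table2()


@pytest.fixture(scope="session")
def acl():
    return datasets.acl_odds_ratios()


@pytest.fixture(scope="session")
def table2_group_summaries(table2):
    """Fixed-effects summaries of the three mixed-type groups, tagged with
    the scale each group originally reports."""
    native = {"smd_group": "smd", "or_group": "log_or", "r_group": "r"}
    out = []
    for mid in table2.meta_ids():
        s = meta_analyze(table2, mid, model="fixed")
        out.append(
            MetaSummary(
                meta_id=mid,
                effect_type=native[mid],
                estimate=s.estimate,
                variance=s.variance,
                n_studies=s.n_studies,
            )
        )
    return out
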