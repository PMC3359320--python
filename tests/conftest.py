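import pytest
from hypothesis import HealthCheck, settings

from equiframe import UNIVERSAL, default_framework
from equiframe.scoring import ScoreMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def framework():
    return default_framework()


def matrix_from_counts(framework, n_groups, n_concepts, n_quality34, doc_id="doc"):
    """Build a ScoreMatrix directly from target counts (no text involved).

    The first ``n_concepts`` concepts are mentioned; the first ``n_groups``
    of them sit in distinct base-group columns (the rest in Universal); the
    first ``n_quality34`` are at quality 3, the others at 1.
    """
    assert n_groups <= n_concepts <= len(framework.concepts)
    cells = {}
    groups = framework.base_group_ids
    for i, cid in enumerate(framework.concept_ids[:n_concepts]):
        column = groups[i] if i < n_groups else UNIVERSAL
        cells[(cid, column)] = 3 if i < n_quality34 else 1
    return ScoreMatrix(doc_id=doc_id, framework=framework, cells=cells)
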