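import numpy as np
import pytest

from clonedeconv.clustering import ClusterSet, ClusterSizeMatrix
from clonedeconv.segment_io import AlterationRecord


def make_record(event_id, chrom="1", start=1_000_000, end=5_000_000,
                alt_type="gain", mcf=None, **kw):
    return AlterationRecord(
        event_id=event_id, chrom=chrom, start_bp=start, end_bp=end,
        alt_type=alt_type, mcf=mcf or {}, **kw,
    )


@pytest.fixture
def sibling_size_matrix():
    """Stem 100 everywhere, A and B subclonal: the canonical two-biopsy
    fixture where biopsy 2 forbids B nesting under A."""
    clusters = ClusterSet(
        clusters={"Stem": ["s1"], "A": ["a1"], "B": ["b1"]},
        stem_cluster="Stem",
    )
    Z = ClusterSizeMatrix(
        cluster_ids=["Stem", "A", "B"],
        biopsies=["P1", "P2"],
        values=np.array([[100.0, 100.0], [60.0, 0.0], [30.0, 80.0]]),
    )
    return clusters, Z


@pytest.fixture
def single_biopsy_matrix():
    clusters = ClusterSet(
        clusters={"Stem": ["s1"], "A": ["a1"], "B": ["b1"]},
        stem_cluster="Stem",
    )
    Z = ClusterSizeMatrix(
        cluster_ids=["Stem", "A", "B"],
        biopsies=["P1"],
        values=np.array([[100.0], [60.0], [30.0]]),
    )
    return clusters, Z
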