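import numpy as np
import pandas as pd
import pytest

import commstate as cs


@pytest.fixture
def toy_counts() -> cs.AbundanceTable:
    """3 samples x 5 ASVs covering 3 genera plus one unassigned ASV."""
    frame = pd.DataFrame(
        [[3, 4, 2, 1, 0],
         [0, 5, 5, 0, 2],
         [1, 1, 1, 1, 1]],
        index=["s1", "s2", "s3"],
        columns=["a1", "a2", "b1", "c1", "u1"],
    )
    return cs.AbundanceTable(frame)


@pytest.fixture
def toy_taxonomy() -> cs.TaxonomyTable:
    frame = pd.DataFrame(
        {
            "phylum": ["P1", "P1", "P1", "P2", "P2"],
            "order": ["O1", "O1", "O2", "O3", "O3"],
            "family": ["F1", "F1", "F2", "F3", "F3"],
            "genus": ["Streptococcus", "Streptococcus", "Moraxella", "Neisseria", ""],
        },
        index=["a1", "a2", "b1", "c1", "u1"],
    )
    return cs.TaxonomyTable(frame)


@pytest.fixture
def toy_metadata() -> cs.SampleMetadata:
    frame = pd.DataFrame(
        {
            "subject_id": ["p1", "p2", "p3"],
            "site": ["oral", "oral", "nasopharyngeal"],
            "season": ["autumn", "autumn", "winter"],
            "age": [6, 9, 10],
            "sex": ["female", "male", "female"],
            "grade": ["1st grade", "3rd grade", "5th grade"],
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    return cs.SampleMetadata(frame)


@pytest.fixture
def toy_tsv_trio(tmp_path, toy_counts, toy_taxonomy, toy_metadata):
    paths = cs.write_tables(toy_counts, toy_taxonomy, toy_metadata, tmp_path)
    return paths


@pytest.fixture(scope="session")
def small_cohort():
    """One seeded study-like cohort shared by read-only tests."""
    spec = cs.reseed(cs.study_like_spec(), 42)
    return cs.simulate_cohort(spec)


def rel_from_array(x, ids=None) -> cs.RelativeAbundanceTable:
    """Profile matrix -> RelativeAbundanceTable without renormalizing rows
    that already sum to 1 (helper for geometric toys, rows are closed)."""
    x = np.asarray(x, dtype=float)
    ids = ids or [f"s{i}" for i in range(x.shape[0])]
    return cs.RelativeAbundanceTable(pd.DataFrame(x, index=ids))


def geometry_table(points, ids=None) -> cs.RelativeAbundanceTable:
    """Wrap raw coordinates as a profile table WITHOUT composition checks.

    Clustering and ordination only consume the numeric row geometry, so
    hand-computed Euclidean examples (merge heights, silhouettes) stay
    exact.  Bypasses the row-sum validation on purpose; never use where
    compositional semantics matter."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    ids = ids or [f"s{i}" for i in range(pts.shape[0])]
    rel = cs.RelativeAbundanceTable.__new__(cs.RelativeAbundanceTable)
    rel.fractions = pd.DataFrame(pts, index=ids)
    return rel
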