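import numpy as np
import pandas as pd
import pytest

from methtree import SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort shared by unit tests: 4 groups / 6 types /
    12 subtypes, strong markers, no batch effects or missingness."""
    spec = SyntheticSpec(
        n_groups=4, types_per_group=(1, 2, 2, 1), subtypes_per_type=2,
        samples_per_subtype=10, n_background_probes=300,
        n_markers_per_group=12, n_markers_per_type=8, n_sex_probes=10,
        seed=3)
    matrix, manifest, annotation, truth = generate_cohort(spec)
    return spec, matrix, manifest, annotation, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_manifest(counts: dict[str, int], subtype_counts=None) -> pd.DataFrame:
    """Helper: manifest with given per-type sample counts."""
    rows = []
    i = 0
    for ctype, n in counts.items():
        for j in range(n):
            i += 1
            sub = ctype if subtype_counts is None else subtype_counts[ctype][j]
            rows.append({"sample_id": f"s{i:03d}", "cancer_type": ctype,
                         "subtype": sub, "cohort": "c1", "split": "unassigned"})
    return pd.DataFrame(rows)
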