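import numpy as np
import pytest

import folatenet as fn


def moment_matched(n: int, mean: float, sd: float) -> np.ndarray:
    """A deterministic vector with exactly the given mean and sample SD."""
    z = np.linspace(-1.0, 1.0, n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


def build_table_matched_cohort() -> fn.CohortDataset:
    """A cohort realizing the published per-group genotype counts exactly
    and BNMN vectors with exactly the printed group means and SDs."""
    gs = fn.study_reference_summary()
    records = []
    for group, prefix in ((fn.GROUP_CASE, "MDS"), (fn.GROUP_CONTROL, "CTRL")):
        n = gs.n[group]
        bnmn = moment_matched(n, gs.bnmn_mean[group], gs.bnmn_sd[group])
        calls_per_locus = {}
        for schema in fn.CANONICAL_LOCI:
            counts = gs.genotype_counts[(group, schema.locus_name)]
            labels = []
            for label, c in zip(schema.genotype_labels, counts):
                labels.extend([label] * c)
            calls_per_locus[schema.locus_name] = labels
        for i in range(n):
            records.append(
                fn.SubjectRecord(
                    subject_id=f"{prefix}-{i + 1:03d}",
                    group=group,
                    bnmn=float(bnmn[i]),
                    calls={l: labels[i] for l, labels in calls_per_locus.items()},
                )
            )
    return fn.CohortDataset(records)


@pytest.fixture(scope="session")
def table_cohort() -> fn.CohortDataset:
    return build_table_matched_cohort()


@pytest.fixture(scope="session")
def table_encoded(table_cohort) -> fn.EncodedMatrix:
    return fn.encode_cohort(table_cohort)


@pytest.fixture(scope="session")
def synthetic_cohort() -> fn.CohortDataset:
    """A seeded study-calibrated synthetic cohort (n = 29 + 32)."""
    return fn.generate_cohort(fn.study_calibrated_config(seed=12345))


@pytest.fixture(scope="session")
def synthetic_encoded(synthetic_cohort) -> fn.EncodedMatrix:
    return fn.encode_cohort(synthetic_cohort)


@pytest.fixture(scope="session")
def study_maps():
    """Connectivity graphs of ten seeded study-calibrated cohorts."""
    graphs = []
    for seed in range(10):
        ds = fn.generate_cohort(fn.study_calibrated_config(seed=seed))
        em = fn.encode_cohort(ds)
        X, names = fn.condition_labelled_matrix(em)
        graphs.append(fn.train_autocm(X, names).connectivity_graph())
    return graphs


def random_cohort(rng: np.random.Generator, n: int = 8) -> fn.CohortDataset:
    """A small random but valid cohort with both groups present."""
    records = []
    for i in range(n):
        group = fn.GROUP_CASE if (i < 2 or rng.random() < 0.5) else fn.GROUP_CONTROL
        if i >= 2 and i < 4:
            group = fn.GROUP_CONTROL
        calls = {
            s.locus_name: s.genotype_labels[rng.integers(0, 3)] for s in fn.CANONICAL_LOCI
        }
        records.append(
            fn.SubjectRecord(f"S{i:03d}", group, float(rng.uniform(0, 30)), calls)
        )
    return fn.CohortDataset(records)
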