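import numpy as np
import pandas as pd
import pytest

from inflamsig.io import ExpressionMatrix, FlagMatrix, bundled_clinical_table
from inflamsig.survival import SurvivalInput


@pytest.fixture(scope="session")
def clinical_records():
    """The bundled 44-patient sarcoma cohort table."""
    return bundled_clinical_table()


@pytest.fixture
def small_expr():
    """2 genes x 3 samples, one group each side of a patient/control split."""
    data = pd.DataFrame(
        [[5.0, 6.0, 7.0], [2.5, 2.5, 9.0]],
        index=["GENE_A", "GENE_B"],
        columns=["s1", "s2", "s3"],
    )
    groups = pd.Series({"s1": "patient", "s2": "patient", "s3": "control"})
    return ExpressionMatrix(data, groups)


def make_expr(rng, n_genes=50, groups=("patient", 6, "control", 5), prefix="G"):
    """Random log2 matrix with the given (label, size, label, size, ...) groups."""
    labels, sizes = groups[0::2], groups[1::2]
    samples, glabels = [], []
    for lab, n in zip(labels, sizes):
        samples += [f"{lab}{i}" for i in range(n)]
        glabels += [lab] * n
    data = pd.DataFrame(
        rng.normal(8.0, 1.0, size=(n_genes, len(samples))),
        index=[f"{prefix}{i:03d}" for i in range(n_genes)],
        columns=samples,
    )
    return ExpressionMatrix(data, pd.Series(glabels, index=samples))


def make_flags(rng, n_probes, groups, p_present=0.5):
    """Random flag matrix; groups is a dict label -> n_samples."""
    samples, glabels = [], []
    for lab, n in groups.items():
        samples += [f"{lab}{i}" for i in range(n)]
        glabels += [lab] * n
    levels = np.array(["present", "marginal", "absent"])
    probs = [p_present, 0.1, 0.9 - p_present]
    calls = rng.choice(levels, p=probs, size=(n_probes, len(samples)))
    return FlagMatrix(
        pd.DataFrame(calls, index=[f"p{i:04d}" for i in range(n_probes)], columns=samples),
        pd.Series(glabels, index=samples),
    )


def surv_inputs(times, events, group="high", prefix="s"):
    return [
        SurvivalInput(f"{prefix}{i}", float(t), bool(e), group)
        for i, (t, e) in enumerate(zip(times, events))
    ]
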