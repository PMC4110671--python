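import numpy as np
import pandas as pd
import pytest

import methylrisk as mr


@pytest.fixture(scope="session")
def small_cohort():
    """One small discovery cohort with planted effects, shared read-only."""
    cfg = mr.SimConfig(n_cpgs=400, n_planted=60, n_carriers=40, n_wildtype=40,
                       n_cases=60, n_controls=60, attenuation=1.0, seed=3)
    ann, sets = mr.make_annotation(cfg.n_cpgs, 150, 0.1, seed=3)
    beta, sheet, truth = mr.simulate_discovery(cfg, ann, sets)
    return {"config": cfg, "annotation": ann, "gene_sets": sets,
            "beta": beta, "sheet": sheet, "truth": truth}


@pytest.fixture(scope="session")
def small_scan(small_cohort):
    table = mr.cpg_logistic_scan(small_cohort["beta"], small_cohort["sheet"])
    candidates = mr.select_candidates(table, 0.3)
    return table, candidates


@pytest.fixture
def tiny_beta_matrix():
    values = pd.DataFrame(
        [[0.1, 0.9], [0.5, 0.25], [0.0, 0.999]],
        index=pd.Index(["cg1", "cg2", "cg3"], name="cpg_id"),
        columns=["s1", "s2"],
    )
    return mr.BetaMatrix(values)


def make_signature(cpgs, coefs, means=None, scales=None, **metadata):
    idx = pd.Index(cpgs, name="cpg_id")
    n = len(cpgs)
    return mr.Signature(
        coefficients=pd.Series(coefs, index=idx, dtype=float),
        means=pd.Series(means if means is not None else np.zeros(n), index=idx),
        scales=pd.Series(scales if scales is not None else np.ones(n), index=idx),
        metadata=metadata,
    )
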