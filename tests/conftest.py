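import warnings
from dataclasses import replace

import pytest

import immunocensus as ic


@pytest.fixture(scope="session")
def tissues():
    return ic.default_tissues()


@pytest.fixture(scope="session")
def preset_bundle():
    """One reference synthetic bundle shared across read-only tests."""
    return ic.generate_bundle(replace(ic.reference_preset(), seed=7))


@pytest.fixture(scope="session")
def preset_result(preset_bundle):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ic.synthetic.run_bundle(preset_bundle)


@pytest.fixture(scope="session")
def grand_total_coverage():
    """Number of replicates (out of 100) whose census 95% CI covers the true
    grand total; computed once and shared."""
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(100):
            b = ic.generate_bundle(
                replace(ic.reference_preset(), seed=seed)
            )
            res = ic.synthetic.run_bundle(b)
            g = res.counts.grand_total
            hits += g.ci_low <= b.truth.grand_total <= g.ci_high
    return hits
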