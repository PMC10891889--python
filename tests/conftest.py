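import warnings

import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from baculoscribe.synthetic import (GenomeSpec, OrfPlan, HrPlan, make_genome,
                                    paper_shaped_spec)


def _mixed_orf_plan(n=20):
    classes = ["early", "late", "both", "none"]
    return [OrfPlan(60 + 7 * i, "+" if i % 2 else "-", classes[i % 4])
            for i in range(n)]


@pytest.fixture(scope="session")
def small_genome():
    """30-kb genome, 20 ORFs (mixed strands/promoter classes), 3 hrs."""
    spec = GenomeSpec(length_bp=30_000, gc_percent=45.0,
                      orf_plan=_mixed_orf_plan(),
                      hr_plan=[HrPlan(copies=4), HrPlan(copies=3),
                               HrPlan(copies=2)],
                      seed=3)
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        genome, truth = make_genome(spec)
    return genome, truth, spec


@pytest.fixture(scope="session")
def paper_genome():
    """Full paper-shaped genome: 160 kb, 45% GC, 140 ORFs, hrs of 4/3/2
    112-bp units."""
    spec = paper_shaped_spec(seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        genome, truth = make_genome(spec)
    return genome, truth, spec
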