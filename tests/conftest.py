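import numpy as np
import pytest

from gabasupp.cohort import (CohortSpec, generate_cohort, records_to_frame,
                             null_suppression_weights)
from gabasupp.pipeline import run_behavior
from gabasupp.suppression import analyze_suppression


@pytest.fixture(scope="session")
def studylike_behavior():
    """Simulated psychophysics for a small cohort with the default planted
    suppression structure (PWA dichoptic asymmetry, iso > cross)."""
    spec = CohortSpec(n_pwa=6, n_nsp=6, seed=41)
    records, truth = generate_cohort(spec)
    behavior = run_behavior(records, truth, spec)
    clinical = records_to_frame(records)
    analysis = analyze_suppression(behavior["cells"], clinical)
    return {"spec": spec, "records": records, "truth": truth,
            "clinical": clinical, **behavior, "analysis": analysis}


@pytest.fixture(scope="session")
def null_behavior():
    """Same cohort size with eye- and orientation-symmetric surround weights:
    no planted asymmetry, so suppression ratios should straddle 1."""
    spec = CohortSpec(n_pwa=6, n_nsp=6, seed=42,
                      suppression_weights=null_suppression_weights(0.3))
    records, truth = generate_cohort(spec)
    behavior = run_behavior(records, truth, spec)
    clinical = records_to_frame(records)
    analysis = analyze_suppression(behavior["cells"], clinical)
    return {"spec": spec, "records": records, "truth": truth,
            "clinical": clinical, **behavior, "analysis": analysis}
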