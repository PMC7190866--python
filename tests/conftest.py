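import hypothesis
import numpy as np
import pytest

from isoscreen import synthetic

hypothesis.settings.register_profile(
    "det", derandomize=True, deadline=None, max_examples=60
)
hypothesis.settings.load_profile("det")


@pytest.fixture
def noiseless_config():
    return synthetic.SimConfig(seed=11, noise_cv=0.0)


@pytest.fixture
def noisy_config():
    return synthetic.SimConfig(seed=11, noise_cv=0.05)


@pytest.fixture
def simple_truth():
    """One compound, Hill midpoint at 1 uM, full efficacy, single line."""
    return synthetic.CompoundTruth(
        "CPD-A", {"LINE1": synthetic.LinePotency(ed50=1.0, hill=1.0, emax=1.0)}
    )


@pytest.fixture
def three_line_truths():
    """Small panel: one mutant-selective, one pan-active, one inactive."""
    lp = synthetic.LinePotency
    panel = list(synthetic.DEFAULT_PANEL)
    sel = synthetic.CompoundTruth(
        "SEL",
        {panel[0]: lp(0.05), panel[1]: lp(50.0), panel[2]: lp(50.0)},
    )
    pan = synthetic.CompoundTruth("PAN", {ln: lp(0.05) for ln in panel})
    nul = synthetic.CompoundTruth("NUL", {ln: lp(500.0) for ln in panel})
    return [sel, pan, nul]
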