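import numpy as np
import pandas as pd
import pytest

from coopnet.formats_io import ExpressionMatrix, Pwm


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def simple_pwm():
    """Near-consensus 8-mer PWM (non-palindromic)."""
    return Pwm.from_consensus("M1", "motif1", "ACGTACGG")


@pytest.fixture
def uniform_pwm():
    return Pwm("U", "uniform", np.full((5, 4), 0.25))


def make_expression(values: np.ndarray, genes, condition="WKY", times=(0, 2, 4, 8), reps=2):
    """Expression matrix helper: values is genes x (times*reps)."""
    samples = []
    for t in times:
        for r in range(1, reps + 1):
            samples.append({"sample": f"{condition}_t{t}_r{r}", "condition": condition,
                            "time_h": float(t), "replicate": r})
    sheet = pd.DataFrame(samples).set_index("sample")
    data = pd.DataFrame(np.asarray(values, float), index=list(genes), columns=sheet.index)
    return ExpressionMatrix(data, sheet)


@pytest.fixture
def expr_factory():
    return make_expression
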