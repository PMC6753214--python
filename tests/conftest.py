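import numpy as np
import pandas as pd
import pytest

from predsel import Cohort, VariableSpec


def build_cohort(columns: dict, outcome: str | None = None, binary: set | None = None,
                 forced: set | None = None) -> Cohort:
    """Assemble a Cohort from plain column arrays, auto-generating ids."""
    binary = binary or set()
    forced = forced or set()
    df = pd.DataFrame(columns)
    n = len(df)
    df.insert(0, "sid", [f"s{i}" for i in range(n)])
    specs = [VariableSpec("sid", "id")]
    for col in columns:
        scale = "binary" if col in binary else "continuous"
        if col == outcome:
            role = "outcome"
        elif col in forced:
            role = "forced"
        else:
            role = "candidate"
        specs.append(VariableSpec(col, role, scale=scale))
    return Cohort(df, specs)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
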