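import numpy as np
import pandas as pd
import pytest

from medivote import LabeledTable, worked_example_table


@pytest.fixture
def worked_example():
    return worked_example_table()


@pytest.fixture
def tiny_numeric_table():
    """3 rows, two numeric features, categorical target."""
    df = pd.DataFrame({
        "hr": [72.0, 110.0, 95.0],
        "temp": [36.6, 38.2, 37.1],
        "label": ["ok", "fever", "ok"],
    })
    return LabeledTable(df, "label")


def random_categorical_table(rng: np.random.Generator, n_attrs: int,
                             domain_size: int, n_rows: int) -> LabeledTable:
    attrs = [f"a{i}" for i in range(n_attrs)]
    data = {a: [f"v{rng.integers(domain_size)}" for _ in range(n_rows)]
            for a in attrs}
    data["y"] = [f"c{rng.integers(3)}" for _ in range(n_rows)]
    return LabeledTable(pd.DataFrame(data, columns=attrs + ["y"]), "y")
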