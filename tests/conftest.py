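import numpy as np
import pandas as pd
import pytest

from glycoreg.catalogue import load_packaged_catalogue


@pytest.fixture(scope="session")
def packaged_catalogue():
    return load_packaged_catalogue()


@pytest.fixture()
def tiny_catalogue_file(tmp_path):
    """Write a small catalogue TSV and return its path."""

    def _write(rows, header="symbol\tpathways\tfunction_class\tpli\tclinvar_pathogenic"):
        p = tmp_path / "cat.tsv"
        p.write_text("\n".join([header] + rows) + "\n")
        return p

    return _write


def random_confusion(rng: np.random.Generator, k: int, high: int = 20) -> np.ndarray:
    """Random non-degenerate K x K confusion matrix."""
    while True:
        c = rng.integers(0, high, size=(k, k))
        s = c.sum()
        t, p = c.sum(axis=1), c.sum(axis=0)
        if s > 0 and (s * s - (t * t).sum()) > 0 and (s * s - (p * p).sum()) > 0:
            return c
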