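import numpy as np
import pytest

from intercoev.msa import Msa, PairedAlignment


def make_msa(rows, ids=None, label=""):
    """Build an Msa from a list of equal-length strings."""
    ids = ids or [f"s{i + 1}" for i in range(len(rows))]
    return Msa(ids, np.array([list(r) for r in rows], dtype="U1"), label=label)


def make_paired(rows_a, rows_b, ids=None):
    ids = ids or [f"s{i + 1}" for i in range(len(rows_a))]
    return PairedAlignment(
        make_msa(rows_a, ids, label="A"), make_msa(rows_b, list(ids), label="B")
    )


@pytest.fixture
def tiny_paired():
    """4 rows, L_A=3, L_B=4; columns chosen to have known entropies."""
    return make_paired(
        ["AAR", "AAR", "RAK", "RAK"],
        ["LLKK", "LKLK", "KKLL", "KLKL"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_columns(rng, n_rows, n_cols, n_symbols=6):
    """Random gap-free integer code columns over a small alphabet."""
    return rng.integers(0, n_symbols, size=(n_rows, n_cols))
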