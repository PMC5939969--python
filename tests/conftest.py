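"""Shared fixtures: random peptide generators and the grid-scan pI oracle."""

from __future__ import annotations

import numpy as np
import pytest

from ampholyte import ModifiedSequence, get_set

RESIDUES = list("ACDEFGHIKLMNPQRSTVWY")


def random_peptide(rng: np.random.Generator, min_len: int = 5, max_len: int = 30,
                   tryptic: bool = False) -> str:
    length = int(rng.integers(min_len, max_len + 1))
    seq = [RESIDUES[i] for i in rng.integers(0, len(RESIDUES), size=length)]
    if tryptic:
        seq[-1] = "K" if rng.random() < 0.5 else "R"
    return "".join(seq)


def grid_scan_pi(groups, step: float = 1e-5, lo: float = 0.0, hi: float = 14.0) -> float:
    """Exhaustive oracle: argmin over a regular pH grid of |net charge|.

    Evaluates the Henderson-Hasselbalch sum directly from the groups' pKas
    with numpy, independent of the bisection code path.
    """
    grid = np.arange(lo, hi + step / 2, step)
    total = np.zeros_like(grid)
    for g in groups:
        if g.polarity == "base":
            total += 1.0 / (1.0 + 10.0 ** (grid - g.pka))
        else:
            total -= 1.0 / (1.0 + 10.0 ** (g.pka - grid))
    return float(grid[np.argmin(np.abs(total))])


@pytest.fixture(scope="session")
def emboss():
    return get_set("emboss")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def random_peptides():
    """100 fixed random peptides (no modifications)."""
    gen = np.random.default_rng(424242)
    return [ModifiedSequence(random_peptide(gen)) for _ in range(100)]
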