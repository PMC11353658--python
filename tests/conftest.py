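"""Shared fixtures: random sequences, motif databases and toy complexes."""

from __future__ import annotations

import numpy as np
import pytest

from pepsilico.io_formats import CANONICAL_AA, ProteinRecord


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(CANONICAL_AA), size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240819)


@pytest.fixture
def random_proteins(rng) -> list[ProteinRecord]:
    return [
        ProteinRecord(id=f"R{i:03d}", sequence=random_sequence(rng, int(rng.integers(20, 200))))
        for i in range(25)
    ]
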