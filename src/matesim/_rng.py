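"""Small helpers around numpy's Generator/SeedSequence machinery."""
from __future__ import annotations

import numpy as np

RngLike = "int | np.random.SeedSequence | np.random.Generator | None"


def as_generator(rng) -> np.random.Generator:
    """Coerce an int seed, SeedSequence, Generator or None into a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def spawn(seed_parts) -> np.random.Generator:
    """Deterministic generator from a tuple of integer seed parts."""
    return np.random.default_rng(np.random.SeedSequence(list(seed_parts)))
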