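"""Shared helpers for the test suite."""

import numpy as np


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
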