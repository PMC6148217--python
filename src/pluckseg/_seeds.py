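"""Deterministic seed derivation.

All randomness in the package flows from a single root seed. Sub-seeds for
folds, iterations and classifiers are derived by hashing the root seed with
small integer role tags through :class:`numpy.random.SeedSequence`, which
gives independent, reproducible streams on every platform.
"""

from __future__ import annotations

import numpy as np

# role tags; distinct per purpose so streams never collide
ROLE_SAMPLING = 11
ROLE_CLASSIFIER = 23
ROLE_FOLDS = 37
ROLE_DATASET = 53


def derive_seed(*parts: int) -> int:
    """A 31-bit seed deterministically derived from integer parts."""
    ss = np.random.SeedSequence([int(p) & 0xFFFFFFFF for p in parts])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def derive_rng(*parts: int) -> np.random.Generator:
    return np.random.default_rng(derive_seed(*parts))
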