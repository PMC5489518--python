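"""Deterministic seed fan-out.

One user-facing master seed is expanded into independent per-component
seeds (search RNG, ELM hidden weights, CV splits, evaluation folds) so each
component can be re-seeded independently while the whole run stays
reconstructible from the master seed alone.
"""

from __future__ import annotations

import numpy as np

__all__ = ["derive_seed", "SEARCH", "ELM", "SPLIT", "EVAL"]

# documented stream indices
SEARCH, ELM, SPLIT, EVAL = 0, 1, 2, 3


def derive_seed(master: int, stream: int) -> int:
    """Child seed for (master, stream), stable across runs, < 2**31."""
    state = np.random.SeedSequence([int(master), int(stream)]).generate_state(1)[0]
    return int(state % (2**31))
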