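"""Named random-number streams.

One root seed reproducibly spawns independent streams for the different
stochastic components (texture, trajectory, spikes, shuffles, ...), so a
single component can be regenerated without replaying the others.
"""

from __future__ import annotations

import numpy as np

# Fixed identifiers so stream independence does not depend on call order.
_STREAM_IDS = {
    "texture": 1,
    "trajectory": 2,
    "spikes": 3,
    "shuffle": 4,
    "population": 5,
    "probe": 6,
    "experiment": 7,
}


def stream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Return the generator for the named stream under ``seed``.

    ``index`` distinguishes repeated uses of the same stream kind (e.g. the
    spike noise of different cells or trials).
    """
    try:
        sid = _STREAM_IDS[name]
    except KeyError:
        raise ValueError(f"unknown stream name {name!r}; known: {sorted(_STREAM_IDS)}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(sid, int(index)))
    return np.random.default_rng(ss)
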