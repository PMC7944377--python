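"""Seeding conventions.

A single master seed controls an entire scenario run. Independent named
substreams are derived through :class:`numpy.random.SeedSequence` spawn
keys, so that e.g. changing the number of Monte-Carlo iterations never
perturbs the calibration draws, and each module can be exercised in
isolation with a reproducible stream.
"""

from __future__ import annotations

from numpy.random import Generator, PCG64, SeedSequence

# Fixed spawn-key slots; appending to this table is backward compatible,
# reordering it is not.
STREAMS = {
    "cohort": 0,
    "mortality": 1,
    "shocks": 2,
    "calibration_mortality": 3,
    "calibration_dementia": 4,
    "iterations": 5,
    "screening": 6,
}


def substream(master_seed: int, name: str, *indices: int) -> Generator:
    """Return the named, optionally indexed, substream of ``master_seed``.

    ``substream(s, "iterations", i)`` yields mutually independent
    generators across iterations ``i`` and across stream names.
    """
    try:
        key = STREAMS[name]
    except KeyError:
        raise KeyError(f"unknown stream {name!r}; known: {sorted(STREAMS)}") from None
    ss = SeedSequence(master_seed, spawn_key=(key, *indices))
    return Generator(PCG64(ss))


def as_generator(seed) -> Generator:
    """Coerce an int, SeedSequence or Generator into a Generator."""
    if isinstance(seed, Generator):
        return seed
    if isinstance(seed, SeedSequence):
        return Generator(PCG64(seed))
    return Generator(PCG64(SeedSequence(seed)))
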