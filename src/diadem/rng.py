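"""Per-(patient, process) random-number streams.

Each simulated patient owns one independent generator per stochastic
process (depression onset, episode transitions, GP contacts, ...).  The
streams are keyed by ``(base_seed, patient_id, process index)`` through
:class:`numpy.random.SeedSequence`, so running the same patient under two
policies replays identical random numbers for every process a policy does
not touch — the common-random-numbers contract that lets policy contrasts
be computed without sampling noise from unrelated processes.
"""

from __future__ import annotations

import numpy as np

#: stochastic processes with their own stream, in fixed order
PROCESS_NAMES = (
    "onset",        # depression onset / relapse waiting times + severity
    "transition",   # within-episode progression / spontaneous recovery
    "contact",      # GP appointment inter-arrival times
    "review",       # annual-review attendance and screen inclusion
    "screen",       # screen-offer, Whooley and interview draws
    "treatment",    # dropout / response / dropout-time draws
    "complication", # annual complication event draws + event times
    "mortality",    # annual death draws + death times
    "hypo",         # severe hypoglycaemia events
)

_PROCESS_INDEX = {name: i for i, name in enumerate(PROCESS_NAMES)}


class PatientStreams:
    """Lazy bundle of named generators for one patient."""

    __slots__ = ("_seed", "_patient_id", "_gens")

    def __init__(self, base_seed: int, patient_id: int):
        self._seed = int(base_seed)
        self._patient_id = int(patient_id)
        self._gens: dict[str, np.random.Generator] = {}

    def __getattr__(self, name: str) -> np.random.Generator:
        try:
            idx = _PROCESS_INDEX[name]
        except KeyError:
            raise AttributeError(name) from None
        gens = self._gens
        gen = gens.get(name)
        if gen is None:
            ss = np.random.SeedSequence((self._seed, self._patient_id, idx))
            gen = np.random.Generator(np.random.PCG64(ss))
            gens[name] = gen
        return gen


def substream(base_seed: int, *key: int) -> np.random.Generator:
    """A standalone generator keyed by ``(base_seed, *key)`` — used for
    cohort generation and any script-level sampling."""
    return np.random.Generator(np.random.PCG64(
        np.random.SeedSequence((int(base_seed),) + tuple(int(k) for k in key))))
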