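"""Deterministic random-number streams.

Two mechanisms coexist:

* **Named streams** (:func:`stream_rng` / :func:`stream_seed`) — ordinary
  ``numpy`` generators keyed by a master seed plus a tuple of names.  Used for
  cohort generation and probabilistic-sensitivity parameter draws, so that
  adding one more draw never perturbs any other stream.

* **Counter-based per-event uniforms** (:func:`event_uniform`) — a stateless
  splitmix64-style hash of ``(seed, person id, cycle, event)`` mapped to a
  uniform in ``[0, 1)``.  Because the draw depends only on that tuple and
  never on how many draws were made before it, every strategy sees the same
  underlying random numbers for the same person-cycle-event: common random
  numbers across strategies hold by construction.
"""

from __future__ import annotations

import hashlib

import numpy as np

_MASK64 = (1 << 64) - 1
_GOLDEN = 0x9E3779B97F4A7C15
_MIX1 = 0xBF58476D1CE4E5B9
_MIX2 = 0x94D049BB133111EB


def _name_key(name: object) -> int:
    """Stable 63-bit integer key for a stream name (never Python ``hash``)."""
    digest = hashlib.sha256(repr(name).encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little") >> 1


def stream_seed(master_seed: int, *names: object) -> int:
    """Derive a deterministic sub-seed (< 2**31) from a master seed and names."""
    z = (int(master_seed) * _GOLDEN) & _MASK64
    for name in names:
        z = _splitmix_int((z + _name_key(name)) & _MASK64)
    return z >> 33


def stream_rng(master_seed: int, *names: object) -> np.random.Generator:
    """A numpy Generator on the named stream derived from ``master_seed``."""
    return np.random.default_rng(stream_seed(master_seed, *names))


def _splitmix_int(z: int) -> int:
    """splitmix64 finalizer on Python integers (exact 64-bit arithmetic)."""
    z = (z ^ (z >> 30)) * _MIX1 & _MASK64
    z = (z ^ (z >> 27)) * _MIX2 & _MASK64
    return z ^ (z >> 31)


def _splitmix_array(z: np.ndarray) -> np.ndarray:
    z = (z ^ (z >> np.uint64(30))) * np.uint64(_MIX1)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(_MIX2)
    return z ^ (z >> np.uint64(31))


# Registry of microsimulation event names; codes enter the hash, so the list
# is append-only once results need to stay reproducible.
EVENT_CODES = {
    "gp_contact": 1,
    "supply_R": 2,
    "supply_P": 3,
    "supply_SR": 4,
    "demand_R": 5,
    "demand_P": 6,
    "demand_SR": 7,
    "fatal_fall": 8,
    "other_cause_death": 9,
    "fall": 10,
    "faller_type": 11,
    "ma_count": 12,
    "hospitalisation": 13,
    "cognitive": 14,
    "fear_of_falling": 15,
    "gait_balance": 16,
    "activity": 17,
    "ltc": 18,
}


def event_uniform(
    seed: int, person_id: np.ndarray | int, cycle: int, event: str
) -> np.ndarray | float:
    """Uniform(0, 1) draw keyed by ``(seed, person_id, cycle, event)``.

    ``person_id`` may be a scalar or an integer array; the result has the
    same shape.  Identical tuples always yield identical values.
    """
    code = EVENT_CODES[event]
    base = _splitmix_int((int(seed) * _GOLDEN + (cycle + 1)) & _MASK64)
    base = _splitmix_int((base + code * _GOLDEN) & _MASK64)
    pid = np.asarray(person_id, dtype=np.uint64)
    z = _splitmix_array(np.uint64(base) + np.uint64(_GOLDEN) * pid)
    u = (z >> np.uint64(11)).astype(np.float64) * 2.0 ** -53
    if np.isscalar(person_id) or np.ndim(person_id) == 0:
        return float(u)
    return u
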