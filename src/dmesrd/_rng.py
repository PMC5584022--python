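"""Counter-based uniform draws for per-agent daily hazards.

The engine draws each agent's daily Bernoulli events from a stateless
SplitMix64-style hash of (seed, channel, agent id, day) rather than a
sequential stream. Draws are then a pure function of who and when, so two
scenario runs under the same master seed give *identical* draws to every
agent they share — exact common random numbers — no matter how the
population or the order of processing differs between runs.
"""

from __future__ import annotations

import numpy as np

_GOLD = np.uint64(0x9E3779B97F4A7C15)
_M1 = np.uint64(0xBF58476D1CE4E5B9)
_M2 = np.uint64(0x94D049BB133111EB)
_INV53 = 2.0**-53


def _mix(x: np.ndarray) -> np.ndarray:
    """SplitMix64 finalizer: full avalanche of a 64-bit word."""
    x = (x + _GOLD)
    x = (x ^ (x >> np.uint64(30))) * _M1
    x = (x ^ (x >> np.uint64(27))) * _M2
    return x ^ (x >> np.uint64(31))


def stream_key(master_seed: int, realization: int) -> np.uint64:
    with np.errstate(over="ignore"):
        return _mix(np.uint64(master_seed & 0xFFFFFFFF) * _GOLD ^ np.uint64(realization))


def uniform(key: np.uint64, channel: int, ids: np.ndarray, day: int) -> np.ndarray:
    """U(0,1) per agent id, deterministic in (key, channel, id, day)."""
    with np.errstate(over="ignore"):
        h = _mix(np.asarray(ids, dtype=np.uint64) ^ (key + np.uint64(channel) * _GOLD))
        h = _mix(h ^ np.uint64(day))
    return (h >> np.uint64(11)) * _INV53


def uniform1(key: np.uint64, channel: int, agent_id: int, day: int) -> float:
    return float(uniform(key, channel, np.asarray([agent_id]), day)[0])


def poisson1(key: np.uint64, channel: int, day: int, lam: float) -> int:
    """One Poisson(lam) count per day by inverse transform (small lam)."""
    if lam <= 0:
        return 0
    u = uniform1(key, channel, 0, day)
    p = np.exp(-lam)
    cum = p
    k = 0
    while u > cum and k < 1000:
        k += 1
        p *= lam / k
        cum += p
    return k


def triangular1(u: float, left: float, mode: float, right: float) -> float:
    """Inverse-CDF triangular sample from one uniform."""
    fc = (mode - left) / (right - left)
    if u < fc:
        return left + np.sqrt(u * (right - left) * (mode - left))
    return right - np.sqrt((1.0 - u) * (right - left) * (right - mode))


def erlang1(key: np.uint64, channel: int, agent_id: int, day: int, shape: int, scale: float) -> float:
    """Erlang(shape, scale) as a sum of hashed exponentials."""
    total = 0.0
    for j in range(shape):
        u = uniform1(key, channel + j, agent_id, day)
        total += -scale * np.log(1.0 - u)
    return total
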