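"""Shared brute-force oracle helpers for the test suite."""

import numpy as np


def simulate_chain(T, n, seed, start=0):
    """Exact discrete Markov-chain sampling."""
    rng = np.random.default_rng(seed)
    cum = np.cumsum(T, axis=1)
    out = np.empty(n, dtype=np.int64)
    s = start
    u = rng.random(n)
    for i in range(n):
        out[i] = s
        s = int(np.searchsorted(cum[s], u[i]))
    return out


def brute_force_committor(T, start, source, sink, n_paths, seed):
    """P(hit sink before source) by direct path sampling."""
    rng = np.random.default_rng(seed)
    cum = np.cumsum(T, axis=1)
    stop = set(source) | set(sink)
    sink = set(sink)
    state = np.full(n_paths, start, dtype=np.int64)
    hit = np.zeros(n_paths, dtype=bool)
    active = np.ones(n_paths, dtype=bool)
    while active.any():
        idx = np.flatnonzero(active)
        u = rng.random(len(idx))
        nxt = np.array([
            np.searchsorted(cum[s], uu) for s, uu in zip(state[idx], u)
        ])
        state[idx] = nxt
        hit[idx] |= np.isin(nxt, list(sink))
        active[idx] = ~np.isin(nxt, list(stop))
    p = hit.mean()
    return p, np.sqrt(p * (1 - p) / n_paths)


def brute_force_mfpt(T, start, sink, n_paths, seed, max_steps=1_000_000):
    """Mean first-passage step count by direct path sampling."""
    rng = np.random.default_rng(seed)
    cum = np.cumsum(T, axis=1)
    sink = set(sink)
    state = np.full(n_paths, start, dtype=np.int64)
    steps = np.zeros(n_paths)
    active = np.ones(n_paths, dtype=bool)
    for _ in range(max_steps):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        u = rng.random(len(idx))
        nxt = np.array([
            np.searchsorted(cum[s], uu) for s, uu in zip(state[idx], u)
        ])
        state[idx] = nxt
        steps[idx] += 1
        active[idx] = ~np.isin(nxt, list(sink))
    return steps.mean(), steps.std() / np.sqrt(n_paths)
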