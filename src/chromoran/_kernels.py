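"""Numba inner loops for Monte Carlo trajectories.

Graphs enter as CSR arrays (``indptr``, ``indices``, ``data``) of the
dispersal matrix, rows indexed by the reproducing node.  Outcome codes:
1 = mutant fixed, 0 = mutant lost, -1 = censored at the step guard.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def embedded_trajectory(
    indptr, indices, data, a_node, b_node, x, seed, max_events
):
    """Embedded-chain trajectory for a fixed coloring.

    Each iteration samples one change of the occupancy vector from the
    conditioned (no-self-loop) transition law; self-loop steps of the
    full process are accounted for through the expected number of wall
    steps per event, which is accumulated into the returned step count.

    Returns (outcome, events, expected_wall_steps).
    """
    np.random.seed(seed)
    n = x.size
    nmut = 0
    for i in range(n):
        nmut += x[i]
    rowsum = np.zeros(n)
    for j in range(n):
        for e in range(indptr[j], indptr[j + 1]):
            rowsum[j] += data[e]
    gain = np.zeros(n)
    loss = np.zeros(n)
    events = 0
    wall = 0.0
    while 0 < nmut < n and events < max_events:
        for i in range(n):
            gain[i] = 0.0
            loss[i] = 0.0
        denom = 0.0
        for j in range(n):
            if x[j] == 1:
                fj = a_node[j]
            else:
                fj = b_node[j]
            denom += fj * rowsum[j]
            for e in range(indptr[j], indptr[j + 1]):
                i = indices[e]
                w = data[e]
                if x[j] == 1:
                    if x[i] == 0:
                        gain[i] += a_node[j] * w
                else:
                    if x[i] == 1:
                        loss[i] += b_node[j] * w
        total = 0.0
        for i in range(n):
            total += gain[i] + loss[i]
        wall += denom / total  # mean wall steps until the next change
        u = np.random.random() * total
        acc = 0.0
        chosen = -1
        up = False
        for i in range(n):
            acc += gain[i]
            if acc > u:
                chosen = i
                up = True
                break
            acc += loss[i]
            if acc > u:
                chosen = i
                up = False
                break
        if chosen < 0:  # numerical edge: take the last active node
            for i in range(n - 1, -1, -1):
                if gain[i] > 0.0 or loss[i] > 0.0:
                    chosen = i
                    up = gain[i] > 0.0
                    break
        if up:
            x[chosen] = 1
            nmut += 1
        else:
            x[chosen] = 0
            nmut -= 1
        events += 1
    if nmut == 0:
        return 0, events, wall
    if nmut == n:
        return 1, events, wall
    return -1, events, wall


@njit(cache=True)
def direct_trajectory(
    indptr,
    indices,
    data,
    is_red,
    a_G,
    a_R,
    b_G,
    b_R,
    x,
    p,
    shuffle_first,
    seed,
    max_steps,
):
    """Direct wall-step trajectory, optionally with dynamic coloring.

    Each step: with probability ``p`` the color labels are permuted
    uniformly at random (Fisher-Yates on ``is_red``), before the
    birth-death event if ``shuffle_first`` and after it otherwise; the
    reproducer is drawn with probability proportional to fitness times
    its outgoing dispersal weight and the offspring replaces a neighbor
    drawn from the reproducer's dispersal row.

    Returns (outcome, steps, steps_float) with steps_float == steps.
    """
    np.random.seed(seed)
    n = x.size
    nmut = 0
    for i in range(n):
        nmut += x[i]
    rowsum = np.zeros(n)
    for j in range(n):
        for e in range(indptr[j], indptr[j + 1]):
            rowsum[j] += data[e]
    steps = 0
    while 0 < nmut < n and steps < max_steps:
        do_shuffle = p > 0.0 and np.random.random() < p
        if do_shuffle and shuffle_first:
            for k in range(n - 1, 0, -1):
                j = np.random.randint(0, k + 1)
                tmp = is_red[k]
                is_red[k] = is_red[j]
                is_red[j] = tmp
        # fitness-proportional choice of the reproducer
        total = 0.0
        for j in range(n):
            if x[j] == 1:
                fj = a_R if is_red[j] == 1 else a_G
            else:
                fj = b_R if is_red[j] == 1 else b_G
            total += fj * rowsum[j]
        u = np.random.random() * total
        acc = 0.0
        parent = n - 1
        for j in range(n):
            if x[j] == 1:
                fj = a_R if is_red[j] == 1 else a_G
            else:
                fj = b_R if is_red[j] == 1 else b_G
            acc += fj * rowsum[j]
            if acc > u:
                parent = j
                break
        # dispersal along the parent's row
        v = np.random.random() * rowsum[parent]
        acc = 0.0
        child = indices[indptr[parent + 1] - 1]
        for e in range(indptr[parent], indptr[parent + 1]):
            acc += data[e]
            if acc > v:
                child = indices[e]
                break
        if x[child] != x[parent]:
            nmut += x[parent] - x[child]
            x[child] = x[parent]
        if do_shuffle and not shuffle_first:
            for k in range(n - 1, 0, -1):
                j = np.random.randint(0, k + 1)
                tmp = is_red[k]
                is_red[k] = is_red[j]
                is_red[j] = tmp
        steps += 1
    if nmut == 0:
        return 0, steps, float(steps)
    if nmut == n:
        return 1, steps, float(steps)
    return -1, steps, float(steps)
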