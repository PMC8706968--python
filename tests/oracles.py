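"""Independent brute-force oracles used to check the package's algorithms.

Deliberately separate implementations: the affine aligner here is a
top-down memoized recursion over sequence suffixes (the package uses an
iterative bottom-up DP), and the rank-sum oracle counts discordant pairs
directly without computing ranks.
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from typing import List

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 2, -4, -6, -1


def oracle_align_all(read: str, ref: str, max_paths: int = 100_000):
    """All optimal left-normalized event lists for a global affine alignment.

    Events: ('deletion', start, length) / ('insertion', start, length, seq),
    with substituted reference positions reported alongside.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        # best score aligning read[i:] vs ref[j:], given the previous move
        if i == len(read) and j == len(ref):
            return 0.0
        options = []
        if i < len(read) and j < len(ref):
            s = MATCH if read[i] == ref[j] else MISMATCH
            options.append(s + best(i + 1, j + 1, "M"))
        if j < len(ref):  # gap in read, consumes ref -> deletion
            cost = GAP_EXTEND if prev == "D" else GAP_OPEN + GAP_EXTEND
            options.append(cost + best(i, j + 1, "D"))
        if i < len(read):  # gap in ref, consumes read -> insertion
            cost = GAP_EXTEND if prev == "I" else GAP_OPEN + GAP_EXTEND
            options.append(cost + best(i + 1, j, "I"))
        return max(options)

    results = set()
    stack = [(0, 0, "M", ())]
    count = 0
    while stack and count < max_paths:
        i, j, prev, moves = stack.pop()
        if i == len(read) and j == len(ref):
            count += 1
            results.add(_moves_to_events(read, ref, moves))
            continue
        target = best(i, j, prev)
        if i < len(read) and j < len(ref):
            s = MATCH if read[i] == ref[j] else MISMATCH
            if s + best(i + 1, j + 1, "M") == target:
                stack.append((i + 1, j + 1, "M", moves + ("M",)))
        if j < len(ref):
            cost = GAP_EXTEND if prev == "D" else GAP_OPEN + GAP_EXTEND
            if cost + best(i, j + 1, "D") == target:
                stack.append((i, j + 1, "D", moves + ("D",)))
        if i < len(read):
            cost = GAP_EXTEND if prev == "I" else GAP_OPEN + GAP_EXTEND
            if cost + best(i + 1, j, "I") == target:
                stack.append((i + 1, j, "I", moves + ("I",)))
    return results, best(0, 0, "M")


def _moves_to_events(read: str, ref: str, moves) -> tuple:
    events: List[tuple] = []
    subs: List[int] = []
    i = j = k = 0
    while k < len(moves):
        mv = moves[k]
        if mv == "M":
            if read[i] != ref[j]:
                subs.append(j)
            i += 1
            j += 1
            k += 1
        elif mv == "D":
            start = j
            while k < len(moves) and moves[k] == "D":
                j += 1
                k += 1
            events.append(("deletion", start, j - start, ""))
        else:
            start, i0 = j, i
            while k < len(moves) and moves[k] == "I":
                i += 1
                k += 1
            events.append(("insertion", start, i - i0, read[i0:i]))
    return (_left_normalize(events, ref), tuple(subs))


def _left_normalize(events, ref) -> tuple:
    # events arrive in alignment-path order; normalize in that order
    out = []
    prev_end = 0
    for kind, start, length, seq in events:
        if kind == "deletion":
            s = start
            while s > prev_end and ref[s - 1] == ref[s + length - 1]:
                s -= 1
            out.append(("deletion", s, length, ""))
            prev_end = s + length
        else:
            s, ins = start, seq
            while s > prev_end and ins and ref[s - 1] == ins[-1]:
                ins = ref[s - 1] + ins[:-1]
                s -= 1
            out.append(("insertion", s, len(ins), ins))
            prev_end = s
    kind_order = {"deletion": 0, "insertion": 1}
    return tuple(sorted(out, key=lambda e: (e[1], kind_order[e[0]], e[2], e[3])))


def oracle_canonical(read: str, ref: str):
    """Least optimal (events, substitutions) pair under the coordinate order."""
    kind_order = {"deletion": 0, "insertion": 1}

    def key(item):
        events, subs = item
        return (tuple((e[1], kind_order[e[0]], e[2], e[3]) for e in events), subs)

    results, score = oracle_align_all(read, ref)
    return min(results, key=key), score


def oracle_u_statistic(a, b) -> float:
    """Mann-Whitney U for group a by direct pair counting (no ranks)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def oracle_mwu_exact_p(a, b) -> float:
    """Two-sided permutation p of U over all group assignments."""
    pooled = list(a) + list(b)
    n_a = len(a)
    centre = n_a * len(b) / 2
    u_obs = oracle_u_statistic(a, b)
    dev = abs(u_obs - centre)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        ia = set(idx)
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in ia]
        total += 1
        if abs(oracle_u_statistic(ga, gb) - centre) >= dev - 1e-12:
            hits += 1
    return hits / total


def oracle_microhomologies(target: str, min_len: int, k_max: int = 6):
    """Dumb triple-loop scan for collapsible flanking k-mer pairs."""
    n = len(target)
    found = {}
    for d in range(1, n):
        for i in range(0, n - d):
            for k in range(min_len, min(k_max, n - d - i) + 1):
                if target[i:i + k] == target[i + d:i + d + k]:
                    s = i
                    while s > 0 and target[s - 1] == target[s + d - 1]:
                        s -= 1
                    kk = 0
                    while s + kk < n - d and target[s + kk] == target[s + d + kk]:
                        kk += 1
                    found[(s, d)] = max(found.get((s, d), 0), kk)
    return sorted((s, d, k) for (s, d), k in found.items())
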