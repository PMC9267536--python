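"""Independent, deliberately naive reference implementations used as oracles.

Everything here is written in plain Python loops, straight from the textbook
description of each procedure, and shares no code with the package.
"""

from __future__ import annotations


def diana_oracle(d) -> list[tuple[list[int], float, list[int], list[int]]]:
    """Literal transcription of the DIANA splinter procedure.

    ``d`` is a square matrix (nested lists or array) of dissimilarities.
    Returns the divisions in order: (cluster, height, splinter, remainder).
    Ties (cluster choice, seed, mover) break toward the lowest item index.
    """
    n = len(d)
    clusters: list[list[int]] = [list(range(n))]
    splits = []
    while any(len(c) > 1 for c in clusters):
        # cluster with the largest diameter; ties -> lowest member index
        best_key, chosen = None, None
        for c in clusters:
            if len(c) < 2:
                continue
            diam = max(d[i][j] for i in c for j in c)
            key = (diam, -min(c))
            if best_key is None or key > best_key:
                best_key, chosen = key, c
        diam = best_key[0]
        c = chosen
        # splinter seed: largest average dissimilarity to the rest
        avg = {i: sum(d[i][j] for j in c if j != i) / (len(c) - 1) for i in c}
        top = max(avg.values())
        seed = min(i for i in c if avg[i] == top)
        splinter, rest = [seed], [i for i in c if i != seed]
        while len(rest) > 1:
            diffs = {}
            for i in rest:
                a = sum(d[i][j] for j in rest if j != i) / (len(rest) - 1)
                b = sum(d[i][j] for j in splinter) / len(splinter)
                diffs[i] = a - b
            mx = max(diffs.values())
            if mx <= 0:
                break
            mover = min(i for i in rest if diffs[i] == mx)
            rest.remove(mover)
            splinter.append(mover)
        clusters.remove(c)
        part_a, part_b = sorted(splinter), sorted(rest)
        clusters.extend([part_a, part_b])
        splits.append((sorted(c), diam, part_a, part_b))
    return splits


def divisive_coefficient_oracle(splits, n: int) -> float:
    """dc = mean over items of 1 - h(i)/H, h(i) = height isolating item i."""
    if not splits:
        return 0.0
    big_h = splits[0][1]
    if big_h == 0:
        return 0.0
    h = {}
    for _, height, a, b in splits:
        for part in (a, b):
            if len(part) == 1:
                h[part[0]] = height
    return sum(1.0 - h[i] / big_h for i in range(n)) / n


def gower_symmetric_oracle(x, y) -> float:
    """Simple-matching distance: mismatches over compared positions."""
    num = sum(1 for a, b in zip(x, y) if a != b)
    return num / len(x)


def hit_counts_oracle(calls) -> tuple[list[int], list[int]]:
    """Row and column sums of a 0/1 matrix, by explicit loops."""
    n = len(calls)
    m = len(calls[0])
    rows = [sum(calls[i][j] for j in range(m)) for i in range(n)]
    cols = [sum(calls[i][j] for i in range(n)) for j in range(m)]
    return rows, cols
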