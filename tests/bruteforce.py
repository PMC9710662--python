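"""Independent brute-force oracles used by the tests.

Everything here is deliberately written with explicit Python loops and
the standard library only (no numpy, no imports from the package's
numerical code paths), so agreement with the package is a genuine
cross-check and not a tautology.
"""

from __future__ import annotations

import math

COUNTED = "ACGT-"


def bf_column_entropy(column: str) -> float:
    counts: dict[str, int] = {}
    for c in column:
        if c in COUNTED:
            counts[c] = counts.get(c, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return 0.0
    ent = 0.0
    for n in counts.values():
        p = n / total
        ent -= p * math.log2(p)
    return ent


def bf_pairwise_cost(a: str, b: str, entropies: list[float]) -> float:
    cost = 0.0
    for k in range(len(a)):
        ca, cb = a[k], b[k]
        if ca in COUNTED and cb in COUNTED and ca != cb:
            cost += entropies[k]
    return cost


def _median(values: list[float]) -> float:
    vals = sorted(values)
    n = len(vals)
    mid = n // 2
    if n % 2:
        return vals[mid]
    return (vals[mid - 1] + vals[mid]) / 2.0


def _quartile(values: list[float], q: float) -> float:
    """Linear-interpolation ("type 7") quantile."""
    vals = sorted(values)
    pos = q * (len(vals) - 1)
    lo = math.floor(pos)
    hi = math.ceil(pos)
    frac = pos - lo
    return vals[lo] + frac * (vals[hi] - vals[lo])


def bf_detect_outliers(seqs: dict[str, str], k: float):
    """(per-sequence costs, threshold, flags) by explicit double loops."""
    names = list(seqs)
    length = len(next(iter(seqs.values())))
    entropies = [
        bf_column_entropy("".join(seqs[n][col] for n in names))
        for col in range(length)
    ]
    per_seq: dict[str, float] = {}
    for i, ni in enumerate(names):
        costs = []
        for j, nj in enumerate(names):
            if i == j:
                continue
            costs.append(bf_pairwise_cost(seqs[ni], seqs[nj], entropies))
        per_seq[ni] = _median(costs)
    values = list(per_seq.values())
    q1 = _quartile(values, 0.25)
    q3 = _quartile(values, 0.75)
    threshold = q3 + k * (q3 - q1)
    flags = {n: per_seq[n] > threshold for n in names}
    return per_seq, threshold, flags


def bf_codon_columns(start: int, end: int, frame: int) -> dict[int, set[int]]:
    """Columns of each codon position by per-column enumeration.

    Position 1 of a codon falls on column start + (frame - 1); positions
    cycle with period 3 and wrap around the marker start.
    """
    out: dict[int, set[int]] = {1: set(), 2: set(), 3: set()}
    for col in range(start, end + 1):
        pos = ((col - (start + frame - 1)) % 3) + 1
        out[pos].add(col)
    return out


def bf_components(membership: dict[str, dict[str, str]]) -> list[set[str]]:
    """Connected components by transitive closure on an explicit matrix.

    *membership* maps marker -> {sample -> residues}.  Two samples are
    adjacent when some marker holds both with a shared column where both
    characters are counted states.
    """
    samples = sorted({s for block in membership.values() for s in block})
    idx = {s: i for i, s in enumerate(samples)}
    n = len(samples)
    adj = [[i == j for j in range(n)] for i in range(n)]
    for block in membership.values():
        names = list(block)
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                sa, sb = block[names[a]], block[names[b]]
                linked = False
                for k in range(min(len(sa), len(sb))):
                    if sa[k] in COUNTED and sb[k] in COUNTED:
                        linked = True
                        break
                if linked:
                    adj[idx[names[a]]][idx[names[b]]] = True
                    adj[idx[names[b]]][idx[names[a]]] = True
    # Floyd-Warshall style transitive closure
    for k in range(n):
        for i in range(n):
            if adj[i][k]:
                for j in range(n):
                    if adj[k][j]:
                        adj[i][j] = True
    seen: set[int] = set()
    comps: list[set[str]] = []
    for i in range(n):
        if i in seen:
            continue
        comp = {samples[j] for j in range(n) if adj[i][j]}
        seen |= {idx[s] for s in comp}
        comps.append(comp)
    return comps
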