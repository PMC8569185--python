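"""Independent oracles used by the tests.

The local-alignment oracle enumerates every monotone set of aligned residue
pairs (the space of all gapped local alignments) and scores each directly:
substitution scores summed, minus ``gap_open + gap_extend * L`` for every
internal gap of length L in either sequence. It shares no code with the
dynamic-programming implementation it checks and is feasible only for short
sequences.
"""

from __future__ import annotations


def brute_force_local_score(
    a: str,
    b: str,
    table: dict[tuple[str, str], int],
    gap_open: int = 11,
    gap_extend: int = 1,
    noncanonical: int = -4,
) -> int:
    def sub(x: str, y: str) -> int:
        return table.get((x, y), noncanonical)

    def gap(length: int) -> int:
        return gap_open + gap_extend * length if length > 0 else 0

    m, n = len(a), len(b)
    best = 0

    def extend(last_i: int, last_j: int, acc: int) -> None:
        nonlocal best
        if acc > best:
            best = acc
        for i in range(last_i + 1, m):
            for j in range(last_j + 1, n):
                cost = gap(i - last_i - 1) + gap(j - last_j - 1)
                extend(i, j, acc + sub(a[i], b[j]) - cost)

    for i in range(m):
        for j in range(n):
            extend(i, j, sub(a[i], b[j]))
    return best
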