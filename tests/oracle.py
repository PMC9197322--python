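"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: every (position,
unit-length) pair is tested by direct slice stepping, and the overlap
policy is re-coded inline.
"""

from __future__ import annotations


def brute_force_ssrs(seq: str, min_repeats: dict[int, int]) -> list[tuple]:
    """All maximal perfect tandem tracts, by exhaustive candidate testing.

    Returns (start, end, unit_length, count, motif) tuples with 1-based
    inclusive coordinates, after longest-wins overlap resolution.
    """
    n = len(seq)
    candidates = []
    for k, min_count in min_repeats.items():
        for i in range(n - k + 1):
            unit = seq[i : i + k]
            if len(unit) < k or "N" in unit:
                continue
            # primitive units only: skip if unit repeats a shorter one
            if any(
                k % d == 0 and unit == unit[:d] * (k // d) for d in range(1, k)
            ):
                continue
            # left-maximality at character level: the periodic region must
            # actually begin here
            if i > 0 and seq[i - 1] != "N" and seq[i - 1] == seq[i + k - 1]:
                continue
            j = i + k
            while seq[j : j + k] == unit:
                j += k
            count = (j - i) // k
            if count >= min_count:
                candidates.append((i + 1, i + count * k, k, count, unit))

    # longest tract wins; ties: smaller unit length, then leftmost start
    chosen: list[tuple] = []
    for cand in sorted(
        candidates, key=lambda c: (-(c[1] - c[0] + 1), c[2], c[0])
    ):
        if all(cand[1] < c[0] or cand[0] > c[1] for c in chosen):
            chosen.append(cand)
    return sorted(chosen)


def brute_force_epcr(
    seq: str, fwd: str, rev: str, w_lo: int, w_hi: int
) -> list[tuple[int, int]]:
    """All convergent exact placements inside seq[w_lo:w_hi] (0-based
    half-open window), testing every substring pair directly. Returns
    (product_start, product_end) 1-based pairs, both orientations tried."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

    def rc(s: str) -> str:
        return "".join(comp[b] for b in reversed(s))

    window = seq[w_lo:w_hi]
    out = set()
    for a, b in ((fwd, rev), (rev, fwd)):
        rcb = rc(b)
        for i in range(len(window) - len(a) + 1):
            if window[i : i + len(a)] != a:
                continue
            for j in range(i + len(a), len(window) - len(rcb) + 1):
                if window[j : j + len(rcb)] == rcb:
                    out.add((w_lo + i + 1, w_lo + j + len(rcb)))
    return sorted(out)
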