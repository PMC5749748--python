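"""Independent brute-force oracles used by the test suite.

These are deliberately written from first principles (and, for the motif, from
the printed consensus string) so they share no code with the implementations
they check.
"""

from __future__ import annotations

import re

# ---------------------------------------------------------------------------
# Motif: parse the printed consensus rather than reusing the package's tables.

CONSENSUS = (
    "[IFVL]-[IFVL]-[AGST]-[AGST]-[AGST]-x-[DE]-x-x-[IFVL]-x-[IFVL]-[WY]-[DE]-"
    "[IFVL]-[RK]"
)
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def parse_consensus(text: str = CONSENSUS) -> list:
    classes = []
    for token in text.split("-"):
        if token == "x":
            classes.append(set(_AA20))
        else:
            m = re.fullmatch(r"\[([A-Z]+)\]", token)
            classes.append(set(m.group(1)))
    assert len(classes) == 16
    return classes


_CLASSES = parse_consensus()


def window_matches(window: str) -> bool:
    """Per-window brute-force motif check."""
    if len(window) != 16:
        return False
    return all(c in cls for c, cls in zip(window, _CLASSES))


def brute_scan(sequence: str) -> set:
    return {
        i
        for i in range(len(sequence) - 15)
        if window_matches(sequence[i : i + 16])
    }


# ---------------------------------------------------------------------------
# WD40 chains: exhaustive enumeration over all anchor subsets.


def brute_longest_chain(ends, min_len, max_len):
    """Maximum-length chain of anchor ends with successive spacing in range,
    by exhaustive subset enumeration (use only for <= ~12 anchors); ties to
    the lexicographically smallest chain."""
    from itertools import combinations

    best = ()
    for k in range(len(ends), 0, -1):
        chains = [
            c
            for c in combinations(sorted(ends), k)
            if all(min_len <= c[i + 1] - c[i] <= max_len for i in range(k - 1))
        ]
        if chains:
            best = min(chains)
            break
    return list(best)


# ---------------------------------------------------------------------------
# Global affine-gap alignment: exhaustive enumeration over all alignments.


def brute_align(a: str, b: str, sub, gap_open=11, gap_extend=1):
    """Enumerate every global alignment; a gap of length L costs
    gap_open + L * gap_extend.  Returns the lexicographic max of
    (score, identities, positives, aligned_columns)."""
    best = [None]

    def rec(i, j, state, score, idn, pos, pairs):
        if i == len(a) and j == len(b):
            t = (score, idn, pos, pairs)
            if best[0] is None or t > best[0]:
                best[0] = t
            return
        if i < len(a) and j < len(b):
            s = sub[a[i]][b[j]]
            rec(
                i + 1,
                j + 1,
                "M",
                score + s,
                idn + (a[i] == b[j]),
                pos + (s > 0),
                pairs + 1,
            )
        if i < len(a):  # a-residue against gap
            cost = gap_extend if state == "X" else gap_open + gap_extend
            rec(i + 1, j, "X", score - cost, idn, pos, pairs)
        if j < len(b):
            cost = gap_extend if state == "Y" else gap_open + gap_extend
            rec(i, j + 1, "Y", score - cost, idn, pos, pairs)

    rec(0, 0, "start", 0, 0, 0, 0)
    return best[0]
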