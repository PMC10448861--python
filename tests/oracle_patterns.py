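"""From-scratch PQS pattern oracle for cross-checking the regex scanner.

A tiny backtracking engine over explicit pattern trees, written without the
``re`` module, reproducing conventional leftmost / greedy-quantifier match
semantics: quantifiers try the longest take first, group repetitions try one
more repetition before closing, and scanning resumes at the end of each
match. Failure memoization (valid per top-level attempt, with repetition
counts capped at the quantifier minimum) keeps the search polynomial.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Set, Tuple


class CharRun:
    """Between lo and hi characters from a set, longest take first."""

    def __init__(self, chars: str, lo: int, hi: int):
        self.chars = set(chars)
        self.lo, self.hi = lo, hi

    def match(self, s: str, i: int, cont):
        n = 0
        limit = min(self.hi, len(s) - i)
        while n < limit and s[i + n] in self.chars:
            n += 1
        for take in range(n, self.lo - 1, -1):
            r = cont(i + take)
            if r is not None:
                return r
        return None


class Repeat:
    """At least ``lo`` repetitions of a sub-sequence, more-first (greedy)."""

    def __init__(self, sub: Tuple, lo: int):
        self.sub = sub
        self.lo = lo

    def match(self, s: str, i: int, cont):
        fail: Set[Tuple[int, int]] = set()

        def attempt(j: int, cnt: int):
            key = (j, min(cnt, self.lo))
            if key in fail:
                return None
            r = _match_seq(self.sub, 0, s, j,
                           lambda j2: attempt(j2, cnt + 1) if j2 > j else None)
            if r is not None:
                return r
            if cnt >= self.lo:
                r = cont(j)
                if r is not None:
                    return r
            fail.add(key)
            return None

        return attempt(i, 0)


def _match_seq(elems: Tuple, k: int, s: str, i: int, cont):
    if k == len(elems):
        return cont(i)
    return elems[k].match(s, i, lambda j: _match_seq(elems, k + 1, s, j, cont))


def _match_at(pattern: Tuple, s: str, i: int) -> Optional[int]:
    """End of the greedy match of ``pattern`` at position i, or None."""
    return _match_seq(pattern, 0, s, i, lambda j: j)


_G = "G"
_N = "ACT"       # non-G bases
_L = "ACGT"      # unrestricted loop alphabet
BIG = 10 ** 9

CANONICAL = (
    Repeat((CharRun(_G, 3, BIG), CharRun(_L, 1, 12)), 3),
    CharRun(_G, 3, BIG),
)
_BULGED_RUN = (
    CharRun(_G, 1, 1), CharRun(_N, 0, 1),
    CharRun(_G, 1, 1), CharRun(_N, 0, 1),
    CharRun(_G, 1, 1),
)
BULGED = (
    Repeat(_BULGED_RUN + (CharRun(_L, 1, 3),), 3),
) + _BULGED_RUN
IRREGULAR = (
    Repeat((CharRun(_G, 1, 2), CharRun(_N, 1, 2)), 7),
    CharRun(_G, 1, 2),
)

PATTERNS = {"canonical": CANONICAL, "bulged": BULGED, "irregular": IRREGULAR}


def oracle_find(pattern_name: str, seq: str) -> List[Tuple[int, int]]:
    """Leftmost, non-overlapping greedy matches of one class."""
    pattern = PATTERNS[pattern_name]
    out: List[Tuple[int, int]] = []
    i, n = 0, len(seq)
    while i < n:
        if seq[i] != "G":          # every grammar starts with G
            i += 1
            continue
        end = _match_at(pattern, seq, i)
        if end is None:
            i += 1
        else:
            out.append((i, end))
            i = end
    return out


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


_RANK = {"canonical": 0, "bulged": 1, "irregular": 2}


def oracle_scan(seq: str, chrom: str = "c", min_g: int = 12):
    """Full both-strand scan of one chromosome with the 5'-first resolution.

    Returns (chrom, start, end, strand, class, g_count) tuples sorted like
    the scanner's output; an independent replay of the whole scan contract.
    """
    n = len(seq)
    rev = _revcomp(seq)
    candidates = []
    for cls in PATTERNS:
        for s, e in oracle_find(cls, seq):
            sub = seq[s:e]
            if sub.count("G") >= min_g:
                candidates.append((s, e, "+", cls, sub.count("G")))
        for s, e in oracle_find(cls, rev):
            sub = rev[s:e]
            if sub.count("G") >= min_g:
                candidates.append((n - e, n - s, "-", cls, sub.count("G")))
    candidates.sort(
        key=lambda c: (c[0], _RANK[c[3]], 0 if c[2] == "+" else 1, -c[1])
    )
    kept = []
    kept_end = None
    for s, e, strand, cls, g in candidates:
        if kept_end is None or s >= kept_end + 1:
            kept.append((chrom, s, e, strand, cls, g))
            kept_end = e
    return kept
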