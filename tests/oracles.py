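"""Independent reference implementations used to check the package.

These deliberately share no code with peplib: the anchor oracle scans every
candidate substring with edlib's edit distance, and the alignment oracle is
a top-down recursion over the alignment graph (with an exhaustive,
memo-free path enumeration variant for tiny inputs).
"""

import functools
import math

import edlib


def brute_force_anchor(sequence, anchor, max_error_rate):
    """Best (start, end, distance) by scanning all candidate substrings.

    Minimizes (distance, start, span) lexicographically; returns None when
    the best distance exceeds floor(max_error_rate * len(anchor)).  Only
    substrings whose length is within `allowed` of the anchor length need
    scanning: any other substring has edit distance > allowed.
    """
    m = len(anchor)
    allowed = math.floor(max_error_rate * m)
    best = None
    for start in range(len(sequence) + 1):
        for span in range(max(0, m - allowed), m + allowed + 1):
            end = start + span
            if end > len(sequence):
                break
            d = edlib.align(anchor, sequence[start:end],
                            mode="NW", task="distance")["editDistance"]
            key = (d, start, span)
            if best is None or key < best:
                best = key
    if best is None or best[0] > allowed:
        return None
    d, start, span = best
    return start, start + span, d


def recursive_nw_score(query, reference, match=1.0, mismatch=-1.0, gap=-1.0):
    """Optimal global alignment score by cached top-down recursion."""

    @functools.lru_cache(maxsize=None)
    def best(i, j):
        if i == 0 and j == 0:
            return 0.0
        candidates = []
        if i > 0 and j > 0:
            s = match if query[i - 1] == reference[j - 1] else mismatch
            candidates.append(best(i - 1, j - 1) + s)
        if i > 0:
            candidates.append(best(i - 1, j) + gap)
        if j > 0:
            candidates.append(best(i, j - 1) + gap)
        return max(candidates)

    return best(len(query), len(reference))


def enumerate_nw_score(query, reference, match=1.0, mismatch=-1.0, gap=-1.0):
    """Optimal score by memo-free enumeration of every global alignment.

    Exponential; only usable for very short sequences.
    """
    def walk(i, j, score):
        if i == len(query) and j == len(reference):
            return score
        best = -math.inf
        if i < len(query) and j < len(reference):
            s = match if query[i] == reference[j] else mismatch
            best = max(best, walk(i + 1, j + 1, score + s))
        if i < len(query):
            best = max(best, walk(i + 1, j, score + gap))
        if j < len(reference):
            best = max(best, walk(i, j + 1, score + gap))
        return best

    return walk(0, 0, 0.0)
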