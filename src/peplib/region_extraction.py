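"""Locate the randomized region in each read and apply structural filters.

The region of interest is bracketed by two constant anchor sequences; a
read is searched in both orientations, the sequence strictly between the
two anchor hits is taken as ``left_flank + insert + right_flank``, and the
retention filters are applied in a fixed order so failure tallies are
deterministic:

    empty_region -> ambiguous_base -> flank_mismatch -> length_not_multiple_of_3

Anchor matching is a semi-global edit-distance search (substitutions and
indels both count one edit), accepted when the distance is at most
``floor(max_error_rate * len(anchor))``.  Ties are broken by lowest
distance, then leftmost start, then shortest span.  Partial anchor
occurrences hanging off the read ends are not considered: the whole anchor
must lie inside the read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

from .model_io import PipelineConfig, ReadRecord, TemplateSpec, reverse_complement

__all__ = ["AnchorMatch", "ExtractedRegion", "find_anchor", "extract_region",
           "extract_regions", "FAIL_REASONS"]

_ACGT = frozenset("ACGT")

FAIL_REASONS = (
    "no_upstream_anchor",
    "no_downstream_anchor",
    "flank_mismatch",
    "length_not_multiple_of_3",
    "ambiguous_base",
    "empty_region",
)


@dataclass(frozen=True)
class AnchorMatch:
    """Best occurrence of an anchor within a sequence."""

    start: int
    end: int
    distance: int


@dataclass(frozen=True)
class ExtractedRegion:
    """Extraction outcome for one read.

    ``region`` is the observed ``left_flank + insert + right_flank`` (empty
    when no region could be located); ``passed`` is True only when every
    structural filter succeeded, in which case ``fail_reason`` is None.
    """

    read_id: str
    region: str
    orientation: str  # "forward" | "reverse_complement"
    passed: bool
    fail_reason: Optional[str]


def _pigeonhole_pieces(anchor: str, n_pieces: int) -> List[str]:
    m = len(anchor)
    base, extra = divmod(m, n_pieces)
    pieces, pos = [], 0
    for i in range(n_pieces):
        size = base + (1 if i < extra else 0)
        pieces.append(anchor[pos:pos + size])
        pos += size
    return [p for p in pieces if p]


def _semiglobal_best(sequence: str, anchor: str) -> Tuple[int, int, int]:
    """Full DP: best (start, end, distance) of anchor within sequence.

    Minimizes edit distance over all substrings; among co-optimal matches
    the leftmost start wins, then the shortest span.
    """
    n, m = len(sequence), len(anchor)
    # D[j]: min edits aligning the anchor prefix to a substring ending at j;
    # S[j]: smallest achievable start among optimal alignments for D[j].
    dist = [0] * (n + 1)
    start = list(range(n + 1))
    for i in range(1, m + 1):
        a = anchor[i - 1]
        prev_dist, prev_start = dist, start
        dist = [i] + [0] * n
        start = [0] * (n + 1)
        for j in range(1, n + 1):
            sub = prev_dist[j - 1] + (0 if sequence[j - 1] == a else 1)
            up = prev_dist[j] + 1
            left = dist[j - 1] + 1
            best = sub if sub <= up else up
            if left < best:
                best = left
            cand_start = None
            if sub == best:
                cand_start = prev_start[j - 1]
            if up == best:
                s = prev_start[j]
                cand_start = s if cand_start is None else min(cand_start, s)
            if left == best:
                s = start[j - 1]
                cand_start = s if cand_start is None else min(cand_start, s)
            dist[j] = best
            start[j] = cand_start
    best_d = min(dist)
    best_start, best_end = None, None
    for j in range(n + 1):
        if dist[j] == best_d:
            cand = (start[j], j)
            if best_start is None or cand < (best_start, best_end):
                best_start, best_end = cand
    return best_start, best_end, best_d


def find_anchor(sequence: str, anchor: str,
                max_error_rate: float) -> Optional[AnchorMatch]:
    """Best occurrence of ``anchor`` within ``sequence``, or None.

    Accepts the lowest-edit-distance occurrence (substitutions and indels)
    iff its distance is <= ``floor(max_error_rate * len(anchor))``; ties are
    broken by leftmost start, then shortest span.

    An exact-substring fast path and a pigeonhole k-mer screen keep the
    common cases cheap; both are exact (the screen can only reject
    sequences that provably contain no acceptable occurrence).
    """
    if not anchor:
        raise ValueError("anchor must be non-empty")
    if not 0.0 <= max_error_rate < 0.5:
        raise ValueError("max_error_rate must be in [0, 0.5)")
    allowed = int(max_error_rate * len(anchor))
    idx = sequence.find(anchor)
    if idx >= 0:
        return AnchorMatch(idx, idx + len(anchor), 0)
    if allowed == 0:
        return None
    # A match with <= allowed edits must contain one of allowed+1 contiguous
    # anchor pieces exactly (each edit perturbs at most one piece).
    pieces = _pigeonhole_pieces(anchor, allowed + 1)
    if not any(sequence.find(p) >= 0 for p in pieces):
        return None
    s, e, d = _semiglobal_best(sequence, anchor)
    if d > allowed:
        return None
    return AnchorMatch(s, e, d)


def _search_orientation(sequence: str, spec: TemplateSpec,
                        max_error_rate: float):
    """Return ((region, total_distance), fail_reason) for one orientation."""
    up = find_anchor(sequence, spec.upstream_anchor, max_error_rate)
    if up is None:
        return None, "no_upstream_anchor"
    tail = sequence[up.end:]
    down = find_anchor(tail, spec.downstream_anchor, max_error_rate)
    if down is None:
        return None, "no_downstream_anchor"
    region = tail[:down.start]
    return (region, up.distance + down.distance), None


def _apply_filters(region: str, spec: TemplateSpec) -> Optional[str]:
    if not region:
        return "empty_region"
    if not set(region) <= _ACGT:
        return "ambiguous_base"
    if (len(region) < 6 or not region.startswith(spec.left_flank)
            or not region.endswith(spec.right_flank)):
        return "flank_mismatch"
    if len(region) % 3 != 0:
        return "length_not_multiple_of_3"
    return None


def extract_region(read: ReadRecord, spec: TemplateSpec,
                   config: PipelineConfig) -> ExtractedRegion:
    """Extract the randomized region (with flanks) from one read.

    Both orientations are searched when configured; if both yield anchor
    pairs, the orientation with the smaller total anchor edit distance wins
    (tie -> forward).  Every read yields an ExtractedRegion; absence of
    anchors is recorded as a failure, never an exception.
    """
    rate = config.anchor_max_error_rate
    fwd, fwd_reason = _search_orientation(read.sequence, spec, rate)
    rev, rev_reason = (None, None)
    if config.search_both_orientations:
        rev, rev_reason = _search_orientation(
            reverse_complement(read.sequence), spec, rate)

    if fwd is not None and (rev is None or fwd[1] <= rev[1]):
        region, orientation = fwd[0], "forward"
    elif rev is not None:
        region, orientation = rev[0], "reverse_complement"
    else:
        # Report the reason from the orientation that progressed furthest.
        reasons = {fwd_reason, rev_reason} - {None}
        reason = ("no_downstream_anchor" if "no_downstream_anchor" in reasons
                  else "no_upstream_anchor")
        return ExtractedRegion(read.read_id, "", "forward", False, reason)

    fail = _apply_filters(region, spec)
    return ExtractedRegion(read.read_id, region, orientation, fail is None, fail)


def extract_regions(reads, spec: TemplateSpec,
                    config: PipelineConfig) -> List[ExtractedRegion]:
    """Extract every read; convenience wrapper over :func:`extract_region`."""
    return [extract_region(read, spec, config) for read in reads]
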