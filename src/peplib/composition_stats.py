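"""Per-position amino-acid composition of the randomized insert.

For a truly random NNN insert every codon is equiprobable, so the expected
amino-acid frequency at each position is (number of encoding codons)/64 —
e.g. Leu 6/64, Met and Trp 1/64, stop 3/64.  Observed per-position
frequencies are compared against this expectation with total-variation
(TV) distance, a bounded [0, 1] summary (0 iff identical); a chi-square
goodness-of-fit p-value is carried as a secondary, descriptive column with
no multiplicity correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

__all__ = ["SYMBOLS", "CompositionTable", "theoretical_nnn_frequencies",
           "positional_frequencies"]

SYMBOLS = tuple("ACDEFGHIKLMNPQRSTVWY") + ("*",)


def theoretical_nnn_frequencies(exact: bool = False):
    """Amino-acid probabilities under uniform fully degenerate (NNN) codons.

    Enumerates all 64 codons under the standard genetic code.  Returns a
    float Series over the 20 amino acids plus ``*`` or, with ``exact=True``,
    a dict of :class:`fractions.Fraction`.
    """
    counts: Dict[str, int] = {s: 0 for s in SYMBOLS}
    for codon in itertools.product("ACGT", repeat=3):
        counts[str(Seq("".join(codon)).translate())] += 1
    if exact:
        return {s: Fraction(c, 64) for s, c in counts.items()}
    return pd.Series({s: c / 64 for s, c in counts.items()},
                     name="theoretical")[list(SYMBOLS)]


@dataclass(frozen=True)
class CompositionTable:
    """Observed vs theoretical per-position composition of the insert.

    ``observed`` rows are positions 1..P of the randomized insert (the
    flank residue and the terminal stop are excluded); each row sums to 1
    over the sequences long enough to contribute to that position, whose
    (weighted) number is in ``n_contributing``.
    """

    observed: pd.DataFrame
    theoretical: pd.Series
    tv_distance: pd.Series
    chi2_pvalue: pd.Series
    n_contributing: pd.Series

    @property
    def mean_tv_distance(self) -> float:
        return float(self.tv_distance.mean())

    def to_frame(self) -> pd.DataFrame:
        """One exportable table: observed matrix plus the summary columns."""
        out = self.observed.copy()
        out["tv_distance"] = self.tv_distance
        out["chi2_pvalue"] = self.chi2_pvalue
        out["n_contributing"] = self.n_contributing
        return out


def _insert_residues(peptide: str) -> str:
    """Insert part of a stored peptide: drop flank residue and terminal stop."""
    core = peptide[:-1] if peptide.endswith("*") else peptide
    return core[1:]


def positional_frequencies(variants: pd.DataFrame,
                           weighting: str = "by_read",
                           n_positions: Optional[int] = None
                           ) -> CompositionTable:
    """Tally residue frequencies at every insert position.

    ``weighting='by_read'`` weights each variant by its read count (the
    frequency of a residue among reads covering that position);
    ``'by_variant'`` counts each unique peptide once.  Sequences shorter
    than a position are excluded from that position's denominator.
    """
    if not len(variants):
        raise ValueError("positional_frequencies requires a non-empty variant table")
    if weighting == "by_read":
        weights = variants["read_count"].to_numpy(dtype=float)
    elif weighting == "by_variant":
        weights = np.ones(len(variants))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    inserts = [_insert_residues(p) for p in variants["peptide"]]
    max_len = max((len(s) for s in inserts), default=0)
    if n_positions is None:
        n_positions = max_len
    if n_positions == 0:
        raise ValueError("no insert residues to tally")
    sym_index = {s: i for i, s in enumerate(SYMBOLS)}
    counts = np.zeros((n_positions, len(SYMBOLS)))
    for seq, w in zip(inserts, weights):
        for p, residue in enumerate(seq[:n_positions]):
            counts[p, sym_index[residue]] += w

    totals = counts.sum(axis=1)
    theoretical = theoretical_nnn_frequencies()
    positions = pd.RangeIndex(1, n_positions + 1, name="position")
    with np.errstate(invalid="ignore"):
        freqs = counts / totals[:, None]
    observed = pd.DataFrame(freqs, index=positions, columns=list(SYMBOLS))
    tv = pd.Series(
        0.5 * np.abs(freqs - theoretical.to_numpy()[None, :]).sum(axis=1),
        index=positions, name="tv_distance")
    pvals = []
    for p in range(n_positions):
        if totals[p] > 0:
            expected = theoretical.to_numpy() * totals[p]
            pvals.append(stats.chisquare(counts[p], expected).pvalue)
        else:
            pvals.append(np.nan)
    chi2 = pd.Series(pvals, index=positions, name="chi2_pvalue")
    n_contributing = pd.Series(totals, index=positions, name="n_contributing")
    return CompositionTable(observed, theoretical, tv, chi2, n_contributing)
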