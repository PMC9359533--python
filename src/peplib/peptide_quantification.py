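"""Translate classified regions and collapse them to unique peptide variants.

Variant identity is at the peptide level: distinct nucleotide sequences
encoding the same peptide are summed (codon degeneracy), which is the level
at which the diversity estimator operates.  A nucleotide-level collapse is
available for diagnostics.
"""

from __future__ import annotations

from typing import Dict, Iterable, Tuple

import pandas as pd
from Bio.Seq import Seq

from .template_alignment import INSUFFICIENTLY_RANDOMIZED

__all__ = ["translate", "quantify_variants", "length_distribution"]


def translate(region: str, policy: str = "keep_symbol") -> str:
    """Translate a region (frame 0, standard genetic code).

    The full region is translated including the flank codons, so the output
    is: last secretion-signal residue + insert peptide + terminal ``*``.
    Under ``keep_symbol`` internal stops stay as ``*``; under
    ``truncate_at_stop`` the string is cut just after the first ``*``.
    """
    if len(region) % 3 != 0:
        raise ValueError(
            f"region length {len(region)} is not divisible by 3")
    peptide = str(Seq(region).translate())
    if policy == "truncate_at_stop":
        stop = peptide.find("*")
        if stop >= 0:
            peptide = peptide[:stop + 1]
    elif policy != "keep_symbol":
        raise ValueError(f"unknown internal stop policy {policy!r}")
    return peptide


def quantify_variants(classified: Iterable[Tuple[str, str]],
                      policy: str = "keep_symbol",
                      by_nucleotide: bool = False
                      ) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Collapse classified regions into a unique-variant table.

    Parameters
    ----------
    classified : iterable of (region, label)
        One entry per passed read: the extracted region string and its
        bias label.
    policy : str
        Internal-stop handling passed to :func:`translate`.
    by_nucleotide : bool
        Collapse on the nucleotide region instead of the peptide
        (diagnostic mode; the peptide column is still filled).

    Returns
    -------
    variants : DataFrame
        Columns ``peptide``, ``read_count``, ``fraction``, ``bias_class``
        (majority label of supporting reads, ties called
        insufficiently_randomized), sorted by descending read count then
        peptide.  ``fraction`` is read_count / R where R is the total
        number of passed reads.
    tallies : dict
        ``total`` (R) and per-label read counts.
    """
    counts: Dict[str, list] = {}
    translations: Dict[str, str] = {}
    tallies: Dict[str, int] = {"total": 0,
                               "insufficiently_randomized": 0,
                               "randomized": 0}
    for region, label in classified:
        peptide = translations.get(region)
        if peptide is None:
            peptide = translate(region, policy)
            translations[region] = peptide
        key = region if by_nucleotide else peptide
        entry = counts.setdefault(key, [peptide, 0, 0])
        entry[1] += 1
        if label == INSUFFICIENTLY_RANDOMIZED:
            entry[2] += 1
            tallies["insufficiently_randomized"] += 1
        else:
            tallies["randomized"] += 1
        tallies["total"] += 1

    total = tallies["total"]
    rows = []
    for key, (peptide, n_reads, n_biased) in counts.items():
        bias = (INSUFFICIENTLY_RANDOMIZED if n_biased * 2 >= n_reads
                else "randomized")
        row = {"peptide": peptide, "read_count": n_reads,
               "fraction": n_reads / total, "bias_class": bias}
        if by_nucleotide:
            row["region"] = key
        rows.append(row)
    columns = ["peptide", "read_count", "fraction", "bias_class"]
    if by_nucleotide:
        columns.append("region")
    variants = pd.DataFrame(rows, columns=columns)
    if len(variants):
        variants = variants.sort_values(
            ["read_count", "peptide"], ascending=[False, True],
            kind="mergesort").reset_index(drop=True)
    return variants, tallies


def length_distribution(variants: pd.DataFrame) -> pd.DataFrame:
    """Peptide length spectrum, by reads and by unique variants.

    Lengths are computed on the translated string excluding the terminal
    ``*`` (a full-length designed insert therefore scores flank residue +
    18 random residues = 19).
    """
    if not len(variants):
        return pd.DataFrame(columns=["length", "read_count", "variant_count"])
    lengths = variants["peptide"].map(
        lambda p: len(p) - 1 if p.endswith("*") else len(p))
    grouped = variants.assign(length=lengths).groupby("length").agg(
        read_count=("read_count", "sum"),
        variant_count=("peptide", "size"))
    return grouped.reset_index().sort_values("length").reset_index(drop=True)
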