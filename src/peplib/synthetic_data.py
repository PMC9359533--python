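"""Synthetic amplicon libraries with controllable template bias.

The generator emulates the statistical structure of template-guided
randomization experiments: a mixture of template-like inserts (the
template CDS with a few substitutions) and fully random inserts of the
designed length, heavy-tailed ("jackpot") per-variant abundances,
occasional insert-length aberrations, substitution plus homopolymer-indel
sequencing errors, and reads emitted in both orientations.  Three presets
mirror the regimes of interest: a heavily template-biased library
(``wpa``), a nearly unbiased one (``overflap``), and a fully unbiased one
(``overflap-asym``).

Reads are assembled as ``upstream_anchor + left_flank + insert +
right_flank + downstream_anchor``; everything, anchors included, is
subject to the error process.  All randomness derives from a single seed,
so identical calls reproduce identical libraries byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .model_io import ReadRecord, TemplateSpec, reverse_complement

__all__ = ["LibraryModel", "ErrorModel", "PRESETS", "preset_model",
           "generate_truth", "generate_reads"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class LibraryModel:
    """Ground-truth composition of a simulated plasmid library.

    ``template_bias_fraction`` is the total read-abundance mass of the
    template-like pool; ``abundance_skew`` is the sigma of a log-normal
    abundance draw (0 = uniform), chosen so that a handful of jackpot
    variants can dominate the read pool at sigma around 2.5.
    ``indel_aberration_rate`` is the per-variant probability that a random
    insert deviates from the designed length — in whole codons with
    probability 0.8 (yielding shorter/longer peptides) and frame-breaking
    otherwise (yielding filter failures).
    """

    n_true_variants: int
    template_bias_fraction: float = 0.0
    template_mutation_rate: float = 0.02
    abundance_skew: float = 0.0
    indel_aberration_rate: float = 0.0
    colony_count: int = 4000
    n_template_variants: int = 0

    def __post_init__(self) -> None:
        if self.n_true_variants < 1:
            raise ValueError("n_true_variants must be >= 1")
        for name in ("template_bias_fraction", "template_mutation_rate",
                     "indel_aberration_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.abundance_skew < 0:
            raise ValueError("abundance_skew must be >= 0")
        if self.colony_count < 1:
            raise ValueError("colony_count must be >= 1")
        if self.template_bias_fraction > 0 and self.n_template_variants < 1:
            raise ValueError(
                "template_bias_fraction > 0 requires n_template_variants >= 1")
        if self.n_template_variants > self.n_true_variants:
            raise ValueError("n_template_variants exceeds n_true_variants")


@dataclass(frozen=True)
class ErrorModel:
    """Per-read sequencing error process.

    ``substitution_rate`` applies i.i.d. per base; ``homopolymer_indel_rate``
    applies per homopolymer run of length >= 3 (a single-base insertion or
    deletion, emulating flow-based base-calling artefacts).
    """

    substitution_rate: float = 0.005
    homopolymer_indel_rate: float = 0.01

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "homopolymer_indel_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")


PRESETS: Dict[str, LibraryModel] = {
    "wpa": LibraryModel(
        n_true_variants=1000, n_template_variants=8,
        template_bias_fraction=0.5, template_mutation_rate=0.02,
        abundance_skew=2.5, indel_aberration_rate=0.05, colony_count=3802),
    "overflap": LibraryModel(
        n_true_variants=5000, n_template_variants=1,
        template_bias_fraction=3e-5, template_mutation_rate=0.02,
        abundance_skew=1.0, indel_aberration_rate=0.02, colony_count=4534),
    "overflap-asym": LibraryModel(
        n_true_variants=60000, n_template_variants=0,
        template_bias_fraction=0.0, template_mutation_rate=0.02,
        abundance_skew=1.0, indel_aberration_rate=0.02, colony_count=4865),
}


def preset_model(name: str) -> LibraryModel:
    """Look up a named preset; raises ``KeyError`` with the known names."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


def _random_insert(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, sequence: str, rate: float) -> str:
    if rate == 0.0:
        return sequence
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for pos in hits:
        choices = _BASES[_BASES != arr[pos]]
        arr[pos] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def _aberrant_length(rng: np.random.Generator, designed: int) -> int:
    if rng.random() < 0.8:  # whole-codon change, deletion-biased
        delta = 3 * int(rng.integers(1, 4))
        if rng.random() < 0.75:
            delta = -delta
    else:  # frame-breaking change
        delta = int(rng.choice([-2, -1, 1, 2]))
    return max(designed + delta, 1)


def generate_truth(model: LibraryModel, spec: TemplateSpec,
                   seed: int) -> pd.DataFrame:
    """Draw the ground-truth variant pool.

    Returns a DataFrame with columns ``variant_id``, ``origin``
    (template_like / random), ``insert`` (nucleotides, flanks excluded)
    and ``abundance`` (sums to 1; the template-like pool's total mass
    equals ``template_bias_fraction``).  Inserts are distinct; settings
    that cannot produce enough distinct template-like inserts raise.
    """
    rng = np.random.default_rng(seed)
    n_template = model.n_template_variants
    n_random = model.n_true_variants - n_template

    inserts: List[str] = []
    seen = set()
    for _ in range(n_template):
        for _attempt in range(1000):
            candidate = _mutate(rng, spec.template_insert,
                                model.template_mutation_rate)
            if candidate not in seen:
                break
        else:
            raise ValueError(
                "cannot draw distinct template-like inserts; increase "
                "template_mutation_rate or decrease n_template_variants")
        seen.add(candidate)
        inserts.append(candidate)
    for _ in range(n_random):
        length = spec.designed_random_length
        if model.indel_aberration_rate and rng.random() < model.indel_aberration_rate:
            length = _aberrant_length(rng, spec.designed_random_length)
        while True:
            candidate = _random_insert(rng, length)
            if candidate not in seen:
                break
        seen.add(candidate)
        inserts.append(candidate)

    def pool_abundance(n: int) -> np.ndarray:
        if n == 0:
            return np.empty(0)
        if model.abundance_skew == 0.0:
            return np.full(n, 1.0 / n)
        raw = rng.lognormal(mean=0.0, sigma=model.abundance_skew, size=n)
        return raw / raw.sum()

    bias = model.template_bias_fraction
    abundance = np.concatenate([
        pool_abundance(n_template) * bias,
        pool_abundance(n_random) * (1.0 - bias),
    ])
    abundance /= abundance.sum()
    origin = ["template_like"] * n_template + ["random"] * n_random
    return pd.DataFrame({
        "variant_id": np.arange(model.n_true_variants),
        "origin": origin,
        "insert": inserts,
        "abundance": abundance,
    })


def _find_runs(sequence: str, min_length: int = 3) -> List[Tuple[int, int]]:
    runs = []
    start = 0
    for i in range(1, len(sequence) + 1):
        if i == len(sequence) or sequence[i] != sequence[start]:
            if i - start >= min_length:
                runs.append((start, i))
            start = i
    return runs


def generate_reads(truth: pd.DataFrame, spec: TemplateSpec,
                   error_model: Optional[ErrorModel] = None,
                   n_reads: int = 10000, seed: int = 0) -> List[ReadRecord]:
    """Sample reads from a truth table.

    Variants are drawn by abundance; each read is the anchored amplicon
    with substitution and homopolymer-indel errors applied over its whole
    length, and roughly half the reads are emitted reverse-complemented.
    Read ids encode the source variant (``sim_<i>|v<variant_id>``) so
    recovery tests can join against the truth.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    error_model = error_model or ErrorModel()
    rng = np.random.default_rng(seed)

    base_seqs = [
        spec.upstream_anchor + spec.left_flank + insert
        + spec.right_flank + spec.downstream_anchor
        for insert in truth["insert"]
    ]
    base_runs = [_find_runs(s) for s in base_seqs]
    variant_ids = truth["variant_id"].to_numpy()
    picks = rng.choice(len(truth), size=n_reads,
                       p=truth["abundance"].to_numpy())
    flips = rng.random(n_reads) < 0.5

    sub_rate = error_model.substitution_rate
    hp_rate = error_model.homopolymer_indel_rate
    reads = []
    for i, (v, flip) in enumerate(zip(picks, flips)):
        seq = base_seqs[v]
        mutated = False
        if sub_rate > 0:
            new = _mutate(rng, seq, sub_rate)
            mutated = new != seq
            seq = new
        if hp_rate > 0:
            runs = _find_runs(seq) if mutated else base_runs[v]
            hits = np.nonzero(rng.random(len(runs)) < hp_rate)[0] if runs else []
            for r in reversed(hits):
                start, end = runs[r]
                if rng.random() < 0.5:
                    seq = seq[:start] + seq[start] + seq[start:]
                else:
                    seq = seq[:start] + seq[start + 1:]
        if flip:
            seq = reverse_complement(seq)
        reads.append(ReadRecord(f"sim_{i:06d}|v{variant_ids[v]}", seq,
                                "I" * len(seq)))
    return reads
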