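"""Model/Results surface tying the pipeline stages together.

``PeptideLibraryModel`` holds the inputs (reads, template, colony count,
options); ``fit()`` runs extraction -> classification -> translation ->
quantification -> CPO and returns a ``PeptideLibraryResults`` carrying the
variant table, the per-library summary and diagnostic tables, with
``summary()`` rendering the characteristics table as text.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Union

import pandas as pd

from . import cpo_diversity, peptide_quantification
from .composition_stats import CompositionTable, positional_frequencies
from .cpo_diversity import LibrarySummary
from .model_io import (PipelineConfig, ReadRecord, TemplateSpec,
                       alpha_msh_template, read_fastq)
from .region_extraction import FAIL_REASONS, extract_regions
from .template_alignment import classify_regions

__all__ = ["PeptideLibraryModel", "PeptideLibraryResults"]


class PeptideLibraryModel:
    """Diversity analysis of one randomized-peptide amplicon library.

    Parameters
    ----------
    reads : iterable of ReadRecord
        Single-end amplicon reads (see :func:`peplib.read_fastq`).
    colony_count : int
        Number of transformation-positive colonies observed for this
        library; the anchor of the CPO reconstruction.
    config : PipelineConfig, optional
        Template plus classifier/extraction options.  Defaults to the
        bundled alpha-MSH template with default thresholds.
    name : str
        Library label used in reports.

    Examples
    --------
    >>> model = PeptideLibraryModel.from_fastq("reads.fastq",
    ...                                        colony_count=3802)  # doctest: +SKIP
    >>> results = model.fit()  # doctest: +SKIP
    >>> print(results.summary())  # doctest: +SKIP
    """

    def __init__(self, reads: Iterable[ReadRecord], colony_count: int,
                 config: Optional[PipelineConfig] = None,
                 name: str = "library") -> None:
        if colony_count < 1:
            raise ValueError(f"colony_count must be >= 1, got {colony_count}")
        self.reads = list(reads)
        self.colony_count = int(colony_count)
        self.config = config or PipelineConfig(template=alpha_msh_template())
        self.name = name

    @classmethod
    def from_fastq(cls, path: Union[str, os.PathLike], colony_count: int,
                   config: Optional[PipelineConfig] = None,
                   name: Optional[str] = None) -> "PeptideLibraryModel":
        """Build a model from a FASTQ/FASTA file (gzip optional)."""
        reads = list(read_fastq(path))
        label = name if name is not None else os.path.basename(str(path))
        return cls(reads, colony_count, config=config, name=label)

    def fit(self) -> "PeptideLibraryResults":
        """Run the full pipeline and return the results object."""
        config = self.config
        template = config.template
        total_reads = len(self.reads)
        mean_read_length = (
            sum(len(r.sequence) for r in self.reads) / total_reads
            if total_reads else 0.0)

        regions = extract_regions(self.reads, template, config)
        passed = [r for r in regions if r.passed]
        fail_counts = {reason: 0 for reason in FAIL_REASONS}
        for r in regions:
            if not r.passed:
                fail_counts[r.fail_reason] += 1

        labels = classify_regions(passed, template, config.classifier)
        extraction = pd.DataFrame({
            "read_id": [r.read_id for r in regions],
            "orientation": [r.orientation for r in regions],
            "region": [r.region for r in regions],
            "passed": [r.passed for r in regions],
            "fail_reason": [r.fail_reason for r in regions],
        })
        classification = pd.DataFrame({
            "read_id": [r.read_id for r in passed],
            "region": [r.region for r in passed],
            "label": [lab for lab, _, _ in labels],
            "n_mismatches": [mm for _, mm, _ in labels],
            "n_gap_columns": [gc for _, _, gc in labels],
        })

        variants, tallies = peptide_quantification.quantify_variants(
            zip(classification["region"], classification["label"]),
            policy=config.internal_stop_policy)
        variants = cpo_diversity.compute_cpo(variants, self.colony_count)
        summary = cpo_diversity.summarize_library(
            variants, self.colony_count, total_reads, mean_read_length,
            library=self.name, fail_reason_counts=fail_counts)
        return PeptideLibraryResults(self, variants, summary, extraction,
                                     classification, tallies)


class PeptideLibraryResults:
    """Fitted pipeline outputs for one library.

    Attributes
    ----------
    variants : DataFrame
        One row per unique peptide: ``peptide``, ``read_count``,
        ``fraction``, ``bias_class``, ``cpo``.
    summary_ : LibrarySummary
        The per-library characteristics table (machine form).
    extraction : DataFrame
        Per-read extraction audit (orientation, region, pass/fail reason).
    classification : DataFrame
        Per passed read: bias label, mismatch and gap-column counts.
    read_label_tallies : dict
        Per-read label counts (before the majority collapse to variants).
    """

    def __init__(self, model: PeptideLibraryModel, variants: pd.DataFrame,
                 summary: LibrarySummary, extraction: pd.DataFrame,
                 classification: pd.DataFrame, tallies: dict) -> None:
        self.model = model
        self.variants = variants
        self.summary_ = summary
        self.extraction = extraction
        self.classification = classification
        self.read_label_tallies = tallies

    @property
    def estimated_unique_variants(self) -> int:
        """CPO-based estimate of unique peptide variants in the library."""
        return self.summary_.overall.estimated_variants

    def length_distribution(self) -> pd.DataFrame:
        """Peptide length spectrum (terminal stop excluded from lengths)."""
        return peptide_quantification.length_distribution(self.variants)

    def composition(self, weighting: str = "by_read") -> CompositionTable:
        """Per-position amino-acid composition of the randomized insert."""
        return positional_frequencies(self.variants, weighting=weighting)

    def summary(self) -> str:
        """Render the characteristics table as aligned text."""
        series = self.summary_.to_series()
        lines = [f"Library diversity summary — {self.summary_.library}",
                 "=" * 64]
        for key, value in series.items():
            if isinstance(value, float) and not float(value).is_integer():
                text = f"{value:,.2f}"
            else:
                text = f"{int(value):,}"
            lines.append(f"{key:<70s} {text:>14s}")
        lines.append("=" * 64)
        lines.append(
            f"Estimated unique peptide variants: {self.estimated_unique_variants:,}")
        return "\n".join(lines)

    def to_directory(self, outdir: Union[str, os.PathLike]) -> dict:
        """Write variants/lengths/composition/summary tables; returns paths."""
        import json

        os.makedirs(outdir, exist_ok=True)
        paths = {}

        def tsv(name: str, frame: pd.DataFrame, **kw) -> None:
            path = os.path.join(outdir, name)
            frame.to_csv(path, sep="\t", index=False, **kw)
            paths[name] = path

        tsv("variants.tsv", self.variants)
        tsv("lengths.tsv", self.length_distribution())
        if len(self.variants):
            comp = self.composition().to_frame().reset_index()
            tsv("composition.tsv", comp)
        summary_series = self.summary_.to_series()
        frame = summary_series.rename("value").rename_axis("characteristic")
        path = os.path.join(outdir, "summary.tsv")
        frame.to_csv(path, sep="\t")
        paths["summary.tsv"] = path
        path = os.path.join(outdir, "summary.json")
        with open(path, "w") as handle:
            json.dump({"schema_version": 1, **self.summary_.to_dict()},
                      handle, indent=2)
        paths["summary.json"] = path
        return paths

    def plot_length_distribution(self, ax=None):
        """Bar plot of reads per peptide length; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        dist = self.length_distribution()
        ax.bar(dist["length"], dist["read_count"], color="#4472a8")
        ax.set_xlabel("peptide length (aa, terminal stop excluded)")
        ax.set_ylabel("reads")
        ax.set_title(f"{self.summary_.library}: peptide length spectrum")
        return ax

    def plot_composition(self, weighting: str = "by_read", ax=None):
        """Heatmap of observed per-position residue frequencies."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 5))
        table = self.composition(weighting=weighting)
        im = ax.imshow(table.observed.T.to_numpy(), aspect="auto",
                       cmap="viridis", origin="lower")
        ax.set_yticks(range(len(table.observed.columns)),
                      table.observed.columns)
        ax.set_xticks(range(0, len(table.observed)),
                      table.observed.index)
        ax.set_xlabel("insert position")
        ax.set_ylabel("residue")
        plt.colorbar(im, ax=ax, label="frequency")
        return ax
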