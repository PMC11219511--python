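"""Site x sample count matrices: counting, filtering, normalization, and
methylation-level summaries.

The central objects are :class:`CountMatrix` (raw integer tag counts) and
:class:`RPMMatrix` (reads-per-million, ``count * 1e6 / library_total``).
Sites are kept only when at least one library covers them with more than
two reads; a site counts as *methylated* in a sample when its raw count is
at least one (the presence threshold is exposed because deeper thresholds
are defensible), and the methylation level of a context is the percentage
of its potential (in-silico predicted) sites observed methylated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from methylrad.digestion import TagFragment
from methylrad.io import FormatError, SampleMetadata

__all__ = [
    "CountMatrix",
    "RPMMatrix",
    "MethylationSummary",
    "count_tags",
    "filter_sites",
    "rpm_normalize",
    "methylated_site_counts",
    "methylation_level",
    "methylation_summary",
    "import_alignment_counts",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CountMatrix:
    """Raw tag counts, sites x samples, with optional sample metadata."""

    counts: pd.DataFrame
    metadata: SampleMetadata | None = None
    discards: pd.DataFrame | None = None  # per-sample unmatched/ambiguous tallies

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicated site ids")
        if self.metadata is not None:
            meta_samples = set(self.metadata.sample_ids)
            mat_samples = set(map(str, self.counts.columns))
            if meta_samples != mat_samples:
                raise FormatError(
                    "metadata sample set differs from count-table sample set: "
                    f"only-in-metadata={sorted(meta_samples - mat_samples)[:5]}, "
                    f"only-in-table={sorted(mat_samples - meta_samples)[:5]}"
                )

    @property
    def site_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        meta = self.metadata.subset(sample_ids) if self.metadata is not None else None
        return CountMatrix(self.counts[list(sample_ids)].copy(), metadata=meta)

    def __repr__(self) -> str:
        return (f"CountMatrix({len(self.counts)} sites x "
                f"{self.counts.shape[1]} samples)")


@dataclass
class RPMMatrix:
    """Reads-per-million normalized counts with the library totals used."""

    values: pd.DataFrame
    library_totals: pd.Series
    metadata: SampleMetadata | None = None

    @property
    def site_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class MethylationSummary:
    """Per-sample, per-context methylated-site counts and levels.

    ``table`` has one row per (sample, context) with columns
    ``n_methylated``, ``n_potential`` and ``level_percent``.
    """

    table: pd.DataFrame
    contexts: tuple[str, ...] = ("CG", "CHG")

    def group_mean_sd(self, decimals: int = 1) -> pd.DataFrame:
        """Mean +/- SD of methylated-site numbers and levels per context."""
        rows = []
        for ctx, sub in self.table.groupby("context", sort=False):
            rows.append(
                {
                    "context": ctx,
                    "n_potential": int(sub["n_potential"].iloc[0]),
                    "methylated_mean": round(sub["n_methylated"].mean(), decimals),
                    "methylated_sd": round(sub["n_methylated"].std(ddof=1), decimals),
                    "level_mean_percent": round(sub["level_percent"].mean(), decimals),
                    "level_sd_percent": round(sub["level_percent"].std(ddof=1), decimals),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Counting


def _hamming_within(a: str, b: str, limit: int) -> bool:
    if len(a) != len(b):
        return False
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return False
    return True


def count_tags(
    reads: Mapping[str, Iterable[str]],
    fragments: Sequence[TagFragment],
    max_mismatch: int = 0,
    metadata: SampleMetadata | None = None,
) -> CountMatrix:
    """Assign tag reads to fragments and accumulate per-site counts.

    A read is counted for the *unique* fragment it matches — on either
    strand — within ``max_mismatch`` substitutions.  Reads matching no
    fragment or more than one are discarded and tallied (``discards``).
    """
    site_ids = [f.site_id for f in fragments]
    if len(site_ids) != len(set(site_ids)):
        raise ValueError("duplicate site_ids in fragment set")

    # exact lookup: fragment sequence (either strand) -> set of site ids
    exact: dict[str, set[str]] = {}
    for f in fragments:
        for seq in (f.sequence, reverse_complement(f.sequence)):
            exact.setdefault(seq, set()).add(f.site_id)

    samples = list(reads)
    row = {sid: i for i, sid in enumerate(site_ids)}
    counts = np.zeros((len(site_ids), len(samples)), dtype=np.int64)
    discards = pd.DataFrame(0, index=samples, columns=["unmatched", "ambiguous"],
                            dtype=np.int64)
    for j, (sample, seqs) in enumerate(reads.items()):
        n_unmatched = n_ambiguous = 0
        for read in seqs:
            read = read.upper()
            hits = exact.get(read)
            if hits is None and max_mismatch > 0:
                rc = reverse_complement(read)
                hits = {
                    f.site_id
                    for f in fragments
                    if (_hamming_within(read, f.sequence, max_mismatch)
                        or _hamming_within(rc, f.sequence, max_mismatch))
                }
            if hits and len(hits) == 1:
                counts[row[next(iter(hits))], j] += 1
            elif not hits:
                n_unmatched += 1
            else:
                n_ambiguous += 1
        discards.loc[sample, "unmatched"] = n_unmatched
        discards.loc[sample, "ambiguous"] = n_ambiguous
    table = pd.DataFrame(counts, index=site_ids, columns=samples)
    return CountMatrix(table, metadata=metadata, discards=discards)


# ---------------------------------------------------------------------------
# Filtering and normalization


def filter_sites(matrix: CountMatrix, min_coverage: int = 3) -> CountMatrix:
    """Keep a site iff some library covers it with >= ``min_coverage`` reads.

    The default of 3 encodes the "coverage > 2 in at least one library"
    retention rule.  Site order is preserved; the operation is idempotent.
    """
    keep = matrix.counts.max(axis=1) >= min_coverage
    return CountMatrix(matrix.counts.loc[keep].copy(), metadata=matrix.metadata)


def rpm_normalize(
    matrix: CountMatrix,
    library_totals: pd.Series | Mapping[str, float] | None = None,
) -> RPMMatrix:
    """Reads per million: ``count * 1e6 / library_total`` per sample.

    ``library_totals`` defaults to the column sums of the count table (the
    total mapped reads available from the table itself); an externally
    recorded totals file may override it.
    """
    if library_totals is None:
        totals = matrix.counts.sum(axis=0).astype(float)
    else:
        totals = pd.Series(library_totals, dtype=float).reindex(matrix.sample_ids)
        if totals.isna().any():
            missing = list(totals.index[totals.isna()])
            raise ValueError(f"library totals missing for samples: {missing}")
    if (totals <= 0).any():
        zero = list(totals.index[totals <= 0])
        raise ValueError(f"non-positive library total for samples: {zero}")
    values = matrix.counts.astype(float).mul(1e6).div(totals, axis=1)
    return RPMMatrix(values=values, library_totals=totals, metadata=matrix.metadata)


# ---------------------------------------------------------------------------
# Methylation-level statistics


def methylated_site_counts(
    matrix: CountMatrix,
    context_map: Mapping[str, str],
    min_reads: int = 1,
) -> pd.DataFrame:
    """Number of methylated sites per sample, split by sequence context.

    A site is methylated in a sample iff its raw count >= ``min_reads``
    (default 1, the laxest presence rule, applied after the global
    coverage filter).  Returns a samples x contexts integer table.
    """
    missing = [s for s in matrix.site_ids if s not in context_map]
    if missing:
        raise KeyError(f"sites missing from context map: {missing[:5]}")
    contexts = pd.Series({s: context_map[s] for s in matrix.site_ids})
    present = (matrix.counts >= min_reads)
    out = {}
    for ctx in sorted(contexts.unique()):
        sites = contexts.index[contexts == ctx]
        out[ctx] = present.loc[sites].sum(axis=0)
    return pd.DataFrame(out).astype(np.int64)


def methylation_level(n_methylated: float, n_potential: float) -> float:
    """Percentage of potential methylation sites observed methylated."""
    if n_potential <= 0:
        raise ValueError("n_potential must be positive")
    if n_methylated < 0 or n_methylated > n_potential:
        raise ValueError("need 0 <= n_methylated <= n_potential")
    return 100.0 * n_methylated / n_potential


def methylation_summary(
    matrix: CountMatrix,
    context_map: Mapping[str, str],
    n_potential: Mapping[str, int],
    min_reads: int = 1,
) -> MethylationSummary:
    """Per-sample methylated-site counts and levels against the potential
    (in-silico) site totals per context."""
    per_sample = methylated_site_counts(matrix, context_map, min_reads=min_reads)
    rows = []
    for sample in per_sample.index:
        for ctx in per_sample.columns:
            n_meth = int(per_sample.loc[sample, ctx])
            n_pot = int(n_potential[ctx])
            rows.append(
                {
                    "sample_id": sample,
                    "context": ctx,
                    "n_methylated": n_meth,
                    "n_potential": n_pot,
                    "level_percent": methylation_level(n_meth, n_pot),
                }
            )
    return MethylationSummary(pd.DataFrame(rows),
                              contexts=tuple(per_sample.columns))


# ---------------------------------------------------------------------------
# Alignment import


def import_alignment_counts(
    alignments: Mapping[str, str],
    fragments: Sequence[TagFragment],
    mapq_min: int = 10,
    metadata: SampleMetadata | None = None,
) -> CountMatrix:
    """Count aligned reads per fragment from SAM/BAM files (one per sample),
    keeping records with mapping quality >= ``mapq_min`` (default 10, which
    drops BWA's duplicate/multi-mappings reported with MAPQ < 10).

    Alignment reference names must be fragment site ids.
    """
    import pysam

    site_ids = [f.site_id for f in fragments]
    known = set(site_ids)
    counts = pd.DataFrame(0, index=site_ids, columns=list(alignments),
                          dtype=np.int64)
    for sample, path in alignments.items():
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            unknown = set(fh.references) - known
            if unknown:
                raise FormatError(
                    f"{path}: reference(s) not in fragment set: "
                    f"{sorted(unknown)[:5]}"
                )
            for rec in fh:
                if rec.is_unmapped or rec.mapping_quality < mapq_min:
                    continue
                counts.loc[rec.reference_name, sample] += 1
    return CountMatrix(counts, metadata=metadata)
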