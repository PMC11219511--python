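"""Synthetic genomes, annotations, methylomes and reads with known truth.

Every pipeline stage can be exercised without any external data: a random
genome is built so that the four FspEI motifs occur *exactly* a requested
number of times (every accidental occurrence is destroyed, then the
requested occurrences are planted at non-overlapping positions and the
result is re-scanned before return); gene annotations are non-overlapping
intervals covering a target fraction of the genome; methylome counts are
negative-binomial draws (Var = mu + alpha mu^2, the same parameterization
the differential test assumes) with per-(site, group) methylation
occupancy and planted fold changes at chosen sites; and tag reads are
emitted as exact (optionally error-injected) copies of the fragment
sequences so that counting them recovers the count matrix.

The default experimental design mirrors a two-origin kelp common-garden
study: for each of two origins, ten field samples plus laboratory samples
reared at 5, 10 and 15 degrees C (three to four replicates each), 41
samples in total.  Default occupancies are context-specific (about 21% of
CG sites and 25% of CHG sites methylated), matching the methylation
levels typical of a chloroplast MethylRAD screen.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from methylrad.digestion import (
    FSPEI_MOTIFS,
    DigestedSite,
    TagFragment,
    scan_motifs,
)
from methylrad.io import Genome, GeneAnnotation, GeneRecord, SampleMetadata
from methylrad.quantification import CountMatrix, reverse_complement

__all__ = [
    "SimulationTruth",
    "DEFAULT_MOTIF_COUNTS",
    "DEFAULT_OCCUPANCY",
    "default_design",
    "simulate_genome",
    "simulate_annotation",
    "simulate_nb_counts",
    "simulate_methylome",
    "simulate_reads",
    "write_fastq",
]

#: Planted motif multiplicities for the default synthetic chloroplast,
#: chosen to mirror the site census of a real ~130-kb kelp chloroplast
#: (270 candidate sites: 69 CG-context and 201 CHG-context).
DEFAULT_MOTIF_COUNTS: dict[str, int] = {
    "CCGG": 69,
    "CCTGG": 61,
    "CCTGT": 77,
    "CCAGG": 63,
}

#: Default fraction of candidate sites that are methylation-capable,
#: per sequence context.
DEFAULT_OCCUPANCY: dict[str, float] = {"CG": 0.21, "CHG": 0.25}

_BASES = np.frombuffer(b"ACGT", dtype="S1")

_PRODUCTS = [
    "photosystem I P700 apoprotein",
    "photosystem II protein D1",
    "ATP synthase CF1 alpha chain",
    "acetolactate synthase large subunit",
    "ribulose bisphosphate carboxylase large chain",
    "cytochrome b6",
    "30S ribosomal protein S4",
    "protochlorophyllide reductase subunit B",
    "photosystem I assembly protein",
    "RNA polymerase beta subunit",
]


@dataclass
class SimulationTruth:
    """Everything needed to recompute the expected output of each stage."""

    seed: int
    planted_positions: dict[str, list[int]] = field(default_factory=dict)
    capable: pd.DataFrame | None = None          # site x group booleans
    diff_sites: list[str] = field(default_factory=list)
    true_log2fc: float = 0.0
    diff_factor: str | None = None
    diff_level: str | None = None
    library_size_factors: pd.Series | None = None
    dispersion: float | None = None
    mean_depth: float | None = None
    expected_counts: pd.DataFrame | None = None  # exact counts fed to reads

    def to_json(self, path) -> None:
        def _convert(value):
            if isinstance(value, pd.DataFrame):
                return {"index": list(value.index),
                        "columns": list(value.columns),
                        "data": value.to_numpy().tolist()}
            if isinstance(value, pd.Series):
                return {str(k): (v.item() if hasattr(v, "item") else v)
                        for k, v in value.items()}
            return value

        payload = {k: _convert(v) for k, v in dataclasses.asdict(self).items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)


def default_design() -> SampleMetadata:
    """The default synthetic sampling design: 2 origins x (10 field
    samples + 21 laboratory samples across 5/10/15 degrees C), 41 total."""
    rows = []
    lab_reps = {"Helgoland": {5: 4, 10: 3, 15: 4},
                "Spitsbergen": {5: 3, 10: 4, 15: 3}}
    for origin in ("Helgoland", "Spitsbergen"):
        tag = origin[0]
        for i in range(1, 11):
            rows.append({"sample_id": f"F{tag}{i}", "origin": origin,
                         "cultivation": "field", "temperature_C": None})
        for temp, n in lab_reps[origin].items():
            for i in range(1, n + 1):
                rows.append({"sample_id": f"L{tag}{temp}_{i}", "origin": origin,
                             "cultivation": "lab", "temperature_C": temp})
    return SampleMetadata(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Genome


def _find_occurrences(seq_bytes: np.ndarray, patterns: Sequence[str]) -> list[tuple[int, str]]:
    text = seq_bytes.tobytes().decode()
    hits = []
    for pat in patterns:
        start = 0
        while True:
            pos = text.find(pat, start)
            if pos < 0:
                break
            hits.append((pos, pat))
            start = pos + 1  # overlap-aware
    return hits


def simulate_genome(
    length: int = 130_000,
    motif_counts: Mapping[str, int] | None = None,
    seed: int = 0,
    genome_id: str = "synthetic_chloroplast",
    max_rounds: int = 200,
) -> tuple[Genome, SimulationTruth]:
    """Random genome containing each FspEI motif exactly ``motif_counts``
    times.

    A uniform-random background is scrubbed of every accidental motif
    occurrence by single-base substitution, the requested occurrences are
    planted at non-overlapping random positions (minimum gap of five bases
    so that no accidental match can bridge two planted sites), accidental
    occurrences created by planting are scrubbed again, and the final
    sequence is re-scanned to confirm the exact counts before returning.
    """
    if motif_counts is None:
        motif_counts = dict(DEFAULT_MOTIF_COUNTS)
    motif_counts = {k.upper(): int(v) for k, v in motif_counts.items()}
    unknown = set(motif_counts) - {m.pattern for m in FSPEI_MOTIFS}
    if unknown:
        raise ValueError(f"unknown motif(s): {sorted(unknown)}")
    patterns = [m.pattern for m in FSPEI_MOTIFS]
    footprint = sum((len(p) + 5) * motif_counts.get(p, 0) for p in patterns)
    if footprint >= length:
        raise ValueError("planted motif footprint exceeds genome length")

    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=length)

    # plant at non-overlapping positions with a 5-base safety gap
    slots: list[tuple[int, str]] = []
    taken = np.zeros(length, dtype=bool)
    for pat in patterns:
        for _ in range(motif_counts.get(pat, 0)):
            for _attempt in range(10_000):
                pos = int(rng.integers(0, length - len(pat)))
                lo, hi = max(0, pos - 5), min(length, pos + len(pat) + 5)
                if not taken[lo:hi].any():
                    taken[max(0, pos - 5):min(length, pos + len(pat) + 5)] = True
                    slots.append((pos, pat))
                    break
            else:
                raise RuntimeError("could not place motifs without overlap")
    planted_spans = np.zeros(length, dtype=bool)
    for pos, pat in slots:
        seq[pos:pos + len(pat)] = np.frombuffer(pat.encode(), dtype="S1")
        planted_spans[pos:pos + len(pat)] = True
    planted_set = {(pos, pat) for pos, pat in slots}

    # scrub accidental occurrences (pre-existing or created by planting)
    for _round in range(max_rounds):
        accidental = [h for h in _find_occurrences(seq, patterns)
                      if h not in planted_set]
        if not accidental:
            break
        for pos, pat in accidental:
            free = [i for i in range(pos, pos + len(pat))
                    if not planted_spans[i]]
            if not free:  # cannot happen with the 5-base gap; defensive
                raise RuntimeError("accidental occurrence inside planted spans")
            i = int(rng.choice(free))
            current = seq[i]
            choices = _BASES[_BASES != current]
            seq[i] = rng.choice(choices)
    else:
        raise RuntimeError("failed to scrub accidental motif occurrences")

    genome = Genome(id=genome_id, sequence=seq.tobytes().decode(),
                    circular=True)
    found = scan_motifs(genome)
    found_counts: dict[str, int] = {}
    for s in found:
        found_counts[s.motif.pattern] = found_counts.get(s.motif.pattern, 0) + 1
    expected = {p: motif_counts.get(p, 0) for p in patterns}
    observed = {p: found_counts.get(p, 0) for p in patterns}
    if observed != expected:
        raise RuntimeError(
            f"motif count verification failed: wanted {expected}, got {observed}"
        )
    truth = SimulationTruth(
        seed=seed,
        planted_positions={
            pat: sorted(pos for pos, p in slots if p == pat) for pat in patterns
        },
    )
    return genome, truth


# ---------------------------------------------------------------------------
# Annotation


def simulate_annotation(
    genome: Genome,
    n_genes: int = 139,
    seed: int = 0,
    genic_fraction: float = 0.6,
    min_gene_len: int = 60,
) -> GeneAnnotation:
    """Non-overlapping genes with random strands covering (approximately)
    ``genic_fraction`` of the genome."""
    if n_genes == 0:
        return GeneAnnotation(genome_id=genome.id, genes=[])
    length = len(genome)
    genic_total = int(round(genic_fraction * length))
    if n_genes * min_gene_len > genic_total:
        raise ValueError("cannot fit n_genes genes of min_gene_len in the "
                         "requested genic fraction")
    rng = np.random.default_rng(seed)
    extra = rng.multinomial(genic_total - n_genes * min_gene_len,
                            np.full(n_genes, 1.0 / n_genes))
    gene_lens = min_gene_len + extra
    intergenic_total = length - genic_total
    gaps = rng.multinomial(intergenic_total - (n_genes + 1),
                           np.full(n_genes + 1, 1.0 / (n_genes + 1))) + 1
    genes = []
    cursor = 0
    for i in range(n_genes):
        cursor += int(gaps[i])
        start = cursor
        end = start + int(gene_lens[i])
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneRecord(
                gene_id=f"gene{i + 1:03d}",
                start=start,
                end=end,
                strand=strand,
                product=_PRODUCTS[i % len(_PRODUCTS)],
            )
        )
        cursor = end
    return GeneAnnotation(genome_id=genome.id, genes=genes)


# ---------------------------------------------------------------------------
# Counts


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """NB(mu, alpha) with Var = mu + alpha mu^2 (gamma-Poisson mixture);
    alpha -> 0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, scale=mean * dispersion)
    return rng.poisson(lam)


def simulate_nb_counts(
    n_sites: int,
    group_sizes: tuple[int, int],
    mean: float = 50.0,
    dispersion: float = 0.1,
    n_diff: int = 0,
    log2fc: float = 0.0,
    seed: int = 0,
    size_factor_sd: float = 0.0,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Plain two-group NB count matrix for calibration studies.

    Returns (counts, group labels, diff site ids); the first ``n_diff``
    randomly chosen sites have their group-2 mean multiplied by
    ``2**log2fc``.  ``size_factor_sd`` adds lognormal per-sample depth
    variation.
    """
    rng = np.random.default_rng(seed)
    n1, n2 = group_sizes
    samples = [f"g1_{i}" for i in range(n1)] + [f"g2_{i}" for i in range(n2)]
    groups = pd.Series(["g1"] * n1 + ["g2"] * n2, index=samples)
    site_ids = [f"site{i:04d}" for i in range(n_sites)]
    diff_sites = list(rng.choice(site_ids, size=n_diff, replace=False)) if n_diff else []
    sf = (np.exp(rng.normal(0.0, size_factor_sd, size=n1 + n2))
          if size_factor_sd > 0 else np.ones(n1 + n2))
    mu = np.full((n_sites, n1 + n2), mean) * sf
    diff_idx = [site_ids.index(s) for s in diff_sites]
    mu[np.ix_(diff_idx, np.arange(n1, n1 + n2))] *= 2.0**log2fc
    counts = _nb_draw(rng, mu, dispersion)
    return (
        pd.DataFrame(counts, index=site_ids, columns=samples, dtype=np.int64),
        groups,
        diff_sites,
    )


def simulate_methylome(
    sites: Sequence[DigestedSite],
    design: SampleMetadata | None = None,
    baseline_occupancy: Mapping[str, float] | float | None = None,
    n_diff_sites: int = 20,
    log2fc: float = 2.0,
    dispersion: float = 0.1,
    mean_depth: float = 50.0,
    seed: int = 0,
    diff_factor: str = "origin",
    diff_level: str = "Spitsbergen",
    library_size_sd: float = 0.3,
    noise_rate: float = 0.02,
    occupancy_divergence: float = 0.1,
) -> tuple[CountMatrix, SimulationTruth]:
    """NB-distributed site x sample counts with known methylation truth.

    Each site is methylation-capable per sample group (the levels of
    ``diff_factor``) with the context-specific ``baseline_occupancy``:
    capability is shared across groups for most sites, and redrawn
    independently per group for a fraction ``occupancy_divergence`` of
    sites (group-specific presence/absence methylation; the marginal
    occupancy is unchanged).  Capable (site, sample) cells draw NB counts
    with mean ``mean_depth * library_size_factor``; the chosen
    differential sites (capable in every group) have their mean multiplied
    by ``2**log2fc`` in the ``diff_level`` group; incapable cells draw a
    tiny Poisson noise floor (rate ``noise_rate``).
    """
    if design is None:
        design = default_design()
    if baseline_occupancy is None:
        baseline_occupancy = dict(DEFAULT_OCCUPANCY)
    if isinstance(baseline_occupancy, (int, float)):
        baseline_occupancy = {"CG": float(baseline_occupancy),
                              "CHG": float(baseline_occupancy)}
    for ctx, prob in baseline_occupancy.items():
        if not 0.0 <= prob <= 1.0:
            raise ValueError(f"occupancy for {ctx} outside [0, 1]")
    if n_diff_sites > len(sites):
        raise ValueError("n_diff_sites exceeds the number of sites")

    rng = np.random.default_rng(seed)
    site_ids = [s.site_id for s in sites]
    contexts = {s.site_id: s.context for s in sites}
    groups = design.factor(diff_factor).astype(str)
    levels = list(pd.unique(groups))
    if diff_level not in levels:
        raise ValueError(f"diff_level {diff_level!r} not a level of {diff_factor!r}")

    shared = np.array(
        [rng.random() < baseline_occupancy[contexts[s]] for s in site_ids]
    )
    divergent = rng.random(len(site_ids)) < occupancy_divergence
    capable = pd.DataFrame(
        {
            lvl: np.where(
                divergent,
                [rng.random() < baseline_occupancy[contexts[s]] for s in site_ids],
                shared,
            )
            for lvl in levels
        },
        index=site_ids,
    ).astype(bool)
    capable_everywhere = [s for s in site_ids if capable.loc[s].all()]
    if n_diff_sites > len(capable_everywhere):
        n_diff_sites = len(capable_everywhere)
    diff_sites = (
        list(rng.choice(capable_everywhere, size=n_diff_sites, replace=False))
        if n_diff_sites
        else []
    )

    samples = design.sample_ids
    lib_factors = pd.Series(
        np.exp(rng.normal(0.0, library_size_sd, size=len(samples))),
        index=samples,
    )
    counts = np.zeros((len(site_ids), len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        lvl = groups[sample]
        mu = np.where(
            capable[lvl].to_numpy(),
            mean_depth * lib_factors[sample],
            0.0,
        )
        if diff_sites and lvl == diff_level:
            idx = [site_ids.index(s) for s in diff_sites]
            mu[idx] *= 2.0**log2fc
        col = _nb_draw(rng, mu, dispersion)
        noise = rng.poisson(noise_rate, size=len(site_ids))
        col = np.where(capable[lvl].to_numpy(), col, noise)
        counts[:, j] = col
    matrix = CountMatrix(
        pd.DataFrame(counts, index=site_ids, columns=samples),
        metadata=design,
    )
    truth = SimulationTruth(
        seed=seed,
        capable=capable,
        diff_sites=diff_sites,
        true_log2fc=log2fc,
        diff_factor=diff_factor,
        diff_level=diff_level,
        library_size_factors=lib_factors,
        dispersion=dispersion,
        mean_depth=mean_depth,
        expected_counts=matrix.counts.copy(),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Reads


def simulate_reads(
    fragments: Sequence[TagFragment],
    counts: CountMatrix,
    error_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Emit ``count(site, sample)`` copies of each fragment's sequence on a
    random strand, with optional per-base substitution errors.

    At ``error_rate = 0`` the output round-trips exactly through
    :func:`methylrad.quantification.count_tags`.
    """
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    frag_by_site = {f.site_id: f for f in fragments}
    missing = set(counts.site_ids) - set(frag_by_site)
    if missing:
        raise ValueError(f"counts reference unknown fragments: {sorted(missing)[:5]}")
    reads: dict[str, list[str]] = {}
    for sample in counts.sample_ids:
        sample_reads: list[str] = []
        col = counts.counts[sample]
        for site_id, n in col.items():
            if n == 0:
                continue
            frag = frag_by_site[site_id]
            for _ in range(int(n)):
                seq = frag.sequence
                if rng.random() < 0.5:
                    seq = reverse_complement(seq)
                if error_rate > 0:
                    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
                    hit = rng.random(len(arr)) < error_rate
                    for i in np.where(hit)[0]:
                        choices = _BASES[_BASES != arr[i]]
                        arr[i] = rng.choice(choices)
                    seq = arr.tobytes().decode()
                sample_reads.append(seq)
        order = rng.permutation(len(sample_reads))
        reads[sample] = [sample_reads[i] for i in order]
    return reads


def write_fastq(reads: Mapping[str, Sequence[str]], directory) -> dict[str, str]:
    """Write per-sample FASTQ files (constant quality); returns the paths."""
    import os

    os.makedirs(directory, exist_ok=True)
    paths = {}
    for sample, seqs in reads.items():
        path = os.path.join(str(directory), f"{sample}.fastq")
        with open(path, "w") as fh:
            for i, seq in enumerate(seqs):
                fh.write(f"@{sample}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")
        paths[sample] = path
    return paths


def read_fastq_sequences(path) -> list[str]:
    """Read the sequence lines of a FASTQ file."""
    from Bio import SeqIO

    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]
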