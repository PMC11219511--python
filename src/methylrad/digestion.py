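"""In-silico FspEI digestion of a genome into candidate methylation sites.

FspEI is a methylation-dependent Type IIb restriction enzyme.  For the
purposes of site discovery it is simulated by four recognition motifs:

=========  =======
motif      context
=========  =======
``CCGG``   CG
``CCTGG``  CHG
``CCTGT``  CHG
``CCAGG``  CHG
=========  =======

Scanning is forward-strand only over exactly this motif set: CCGG is
self-complementary and CCTGG/CCAGG are mutual reverse complements, so a
forward scan of the printed set already accounts for both strands of the
symmetric motifs; the asymmetric CCTGT is scanned as written.  Overlapping
matches are all reported.  ``N`` never matches any IUPAC code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from methylrad.io import Genome

__all__ = [
    "IUPAC_CODES",
    "FSPEI_MOTIFS",
    "RecognitionMotif",
    "DigestedSite",
    "TagFragment",
    "scan_motifs",
    "classify_context",
    "extract_fragments",
]

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes -> the set of concrete bases they match.
#: ``N`` in the *genome* is never matched (conservative: no phantom sites),
#: but ``N`` in a *pattern* matches any of A/C/G/T.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


@dataclass(frozen=True)
class RecognitionMotif:
    """An IUPAC DNA pattern with its methylation sequence context."""

    pattern: str
    context: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        bad = set(self.pattern) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"invalid IUPAC code(s) in pattern: {sorted(bad)}")
        if self.context not in ("CG", "CHG"):
            raise ValueError(f"context must be CG or CHG, got {self.context!r}")

    def __len__(self) -> int:
        return len(self.pattern)


#: The fixed FspEI simulation table.
FSPEI_MOTIFS: tuple[RecognitionMotif, ...] = (
    RecognitionMotif("CCGG", "CG"),
    RecognitionMotif("CCTGG", "CHG"),
    RecognitionMotif("CCTGT", "CHG"),
    RecognitionMotif("CCAGG", "CHG"),
)

_CONTEXT_BY_PATTERN = {m.pattern: m.context for m in FSPEI_MOTIFS}


@dataclass(frozen=True)
class DigestedSite:
    """One candidate methylation site: a motif match on the forward strand.

    ``start`` is the 0-based position of the motif's first base; site ids
    are deterministic (``<motif>_<start>``).
    """

    site_id: str
    start: int
    motif: RecognitionMotif
    strand: str = "+"

    @property
    def context(self) -> str:
        return self.motif.context

    @property
    def end(self) -> int:
        return self.start + len(self.motif)


@dataclass(frozen=True)
class TagFragment:
    """The MethylRAD tag excised around a site: motif plus symmetric flanks."""

    site_id: str
    start: int
    end: int
    sequence: str


def classify_context(pattern: str) -> str:
    """Map a recognition motif to its methylation context (CG or CHG)."""
    try:
        return _CONTEXT_BY_PATTERN[pattern.upper()]
    except KeyError:
        raise ValueError(
            f"unknown FspEI motif {pattern!r}; expected one of "
            f"{sorted(_CONTEXT_BY_PATTERN)}"
        ) from None


def _matches_at(seq: str, pos: int, pattern: str) -> bool:
    for offset, code in enumerate(pattern):
        if seq[pos + offset] not in IUPAC_CODES[code]:
            return False
    return True


def scan_motifs(
    genome: Genome,
    motifs: Sequence[RecognitionMotif] = FSPEI_MOTIFS,
) -> list[DigestedSite]:
    """Find every forward-strand occurrence of the recognition motifs.

    Overlapping matches (within and across motifs) are all reported.  The
    result is sorted by start position (ties by pattern) and is invariant
    under reordering of ``motifs``.  A genome shorter than every motif
    yields an empty list.
    """
    seq = genome.sequence
    sites: list[DigestedSite] = []
    for motif in motifs:
        plen = len(motif)
        for pos in range(len(seq) - plen + 1):
            if _matches_at(seq, pos, motif.pattern):
                sites.append(
                    DigestedSite(
                        site_id=f"{motif.pattern}_{pos}",
                        start=pos,
                        motif=motif,
                    )
                )
    sites.sort(key=lambda s: (s.start, s.motif.pattern))
    return sites


def extract_fragments(
    genome: Genome,
    sites: Iterable[DigestedSite],
    flank: int = 14,
    circular: bool | None = None,
) -> list[TagFragment]:
    """Excise the tag fragment around each site: motif plus ``flank`` bases
    on each side (default 14, giving 32-bp tags for 4-bp motifs).

    In linear mode (the default, matching a linear FASTA reference even for
    circular molecules) fragments overrunning either genome end are dropped
    with a warning; with ``circular=True`` they wrap around the origin.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    if circular is None:
        # linear even for circular molecules unless wrapping is requested,
        # matching the linear FASTA reference used for mapping
        circular = False
    seq = genome.sequence
    length = len(seq)
    fragments: list[TagFragment] = []
    n_dropped = 0
    for site in sites:
        start = site.start - flank
        end = site.start + len(site.motif) + flank
        if circular:
            frag_seq = "".join(seq[i % length] for i in range(start, end))
            fragments.append(
                TagFragment(site.site_id, start % length, end % length, frag_seq)
            )
        else:
            if start < 0 or end > length:
                n_dropped += 1
                logger.warning(
                    "fragment for site %s at [%d, %d) overruns the linear "
                    "genome; dropped", site.site_id, start, end,
                )
                continue
            fragments.append(TagFragment(site.site_id, start, end, seq[start:end]))
    if n_dropped:
        logger.warning("dropped %d boundary fragment(s) in linear mode", n_dropped)
    return fragments
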