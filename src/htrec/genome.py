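"""Core data model for rearranged haplotypes and their WGS-level observables.

A rearranged chromosome is represented as an ordered list of oriented
reference segments (a *derivative chromosome*).  From that single source of
truth two observables are derived elsewhere: breakpoint junctions (pairs of
oriented breakends, the arcs of a rearrangement plot) and a copy-number
profile (integer depth over reference bins).

Coordinates are 0-based, half-open throughout.  A breakend records the
retained terminal base adjacent to a junction and the side on which
reference sequence is retained: side ``R`` means retained sequence lies at
coordinates <= pos, side ``L`` means it lies at coordinates >= pos.  On
BEDPE export ``R`` maps to strand ``+`` and ``L`` to strand ``-``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence


@dataclass(frozen=True)
class GenomeModel:
    """Reference frame for one chromosome.

    ``baseline_cn`` is the total copy number across homologs (default 2,
    one rearranged haplotype plus one intact homolog).
    """

    chrom_name: str = "chr1"
    length: int = 1_000_000
    baseline_cn: int = 2

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"genome length must be positive, got {self.length}")
        if self.baseline_cn < 1:
            raise ValueError(f"baseline_cn must be >= 1, got {self.baseline_cn}")


@dataclass(frozen=True)
class Segment:
    """One oriented reference interval of a derivative chromosome."""

    start: int
    end: int
    forward: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid segment [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def reversed_(self) -> "Segment":
        return Segment(self.start, self.end, not self.forward)


@dataclass(frozen=True)
class DerivativeChromosome:
    """Ordered list of oriented reference segments: one rearranged haplotype."""

    genome: GenomeModel
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("derivative must contain at least one segment")
        for seg in self.segments:
            if seg.end > self.genome.length:
                raise ValueError(
                    f"segment [{seg.start}, {seg.end}) exceeds genome length "
                    f"{self.genome.length}"
                )

    @property
    def length(self) -> int:
        return sum(seg.length for seg in self.segments)

    def with_segments(self, segments: Iterable[Segment]) -> "DerivativeChromosome":
        return DerivativeChromosome(self.genome, tuple(segments))


def new_genome(
    length: int, baseline_cn: int = 2, chrom_name: str = "chr1"
) -> DerivativeChromosome:
    """Create an identity (unrearranged) derivative for a fresh genome model."""
    genome = GenomeModel(chrom_name=chrom_name, length=length, baseline_cn=baseline_cn)
    return DerivativeChromosome(genome, (Segment(0, length, True),))


@dataclass(frozen=True, order=True)
class Breakend:
    """One side of a rearrangement junction."""

    chrom: str
    pos: int
    side: str  # "R": retained sequence at <= pos; "L": retained at >= pos

    def __post_init__(self) -> None:
        if self.side not in ("R", "L"):
            raise ValueError(f"breakend side must be 'R' or 'L', got {self.side!r}")
        if self.pos < 0:
            raise ValueError(f"breakend position must be >= 0, got {self.pos}")


@dataclass(frozen=True)
class Junction:
    """A pair of oriented breakends joining two reference loci.

    Breakends are stored in canonical order (a <= b by chrom, pos, side) so
    that junction lists can be deduplicated and compared directly.
    """

    a: Breakend
    b: Breakend
    insert_len: int = 0

    def __post_init__(self) -> None:
        if self.insert_len < 0:
            raise ValueError("insert_len must be >= 0")
        if (self.b.chrom, self.b.pos, self.b.side) < (self.a.chrom, self.a.pos, self.a.side):
            a, b = self.a, self.b
            object.__setattr__(self, "a", b)
            object.__setattr__(self, "b", a)

    @property
    def intra_chromosomal(self) -> bool:
        return self.a.chrom == self.b.chrom

    @property
    def span(self) -> int:
        """Distance between breakend positions (intra-chromosomal only)."""
        if not self.intra_chromosomal:
            raise ValueError("span undefined for inter-chromosomal junction")
        return self.b.pos - self.a.pos

    def sort_key(self):
        return (self.a.chrom, self.a.pos, self.a.side, self.b.chrom, self.b.pos, self.b.side)


@dataclass(frozen=True)
class CopyNumberProfile:
    """Integer copy number over a contiguous tiling of [0, length)."""

    chrom: str
    segments: tuple[tuple[int, int, int], ...]  # (start, end, cn)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("copy-number profile must be non-empty")
        prev_end = self.segments[0][0]
        for start, end, cn in self.segments:
            if start != prev_end:
                raise ValueError(
                    f"profile not contiguous: segment starts at {start}, "
                    f"previous ends at {prev_end}"
                )
            if end <= start:
                raise ValueError(f"empty profile segment [{start}, {end})")
            if cn < 0:
                raise ValueError(f"negative copy number {cn} in [{start}, {end})")
            prev_end = end

    @property
    def start(self) -> int:
        return self.segments[0][0]

    @property
    def end(self) -> int:
        return self.segments[-1][1]

    def cn_at(self, pos: int) -> int:
        if not (self.start <= pos < self.end):
            raise ValueError(f"position {pos} outside profile [{self.start}, {self.end})")
        import bisect

        starts = [s for s, _, _ in self.segments]
        i = bisect.bisect_right(starts, pos) - 1
        return self.segments[i][2]

    def overlapping(self, start: int, end: int) -> list[tuple[int, int, int]]:
        """Profile segments clipped to [start, end)."""
        out = []
        for s, e, cn in self.segments:
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                out.append((lo, hi, cn))
        return out

    def modal_cn(self) -> int:
        """Length-weighted modal copy number (the de-facto baseline)."""
        weights: dict[int, int] = {}
        for s, e, cn in self.segments:
            weights[cn] = weights.get(cn, 0) + (e - s)
        return max(weights, key=lambda cn: (weights[cn], -cn))


@dataclass(frozen=True)
class TemplatedInsertionParams:
    """Parameters of a templated duplication with distant insertion.

    A copy of ``[template_start, template_start + template_len)`` is written
    into the chromosome at ``insertion_pos``, replacing ``site_deletion_len``
    bases there, in reverse orientation if ``inverted``.  Default sampling
    bounds (see :class:`htrec.simulate.SimulationProfile`): template length
    2 kb - 100 kb, insertion distance 10 kb - 5 Mb from the template
    midpoint, site deletion 6 bp - 1 kb, inverted with probability 0.8.
    """

    template_start: int
    template_len: int
    insertion_pos: int
    site_deletion_len: int
    inverted: bool = True

    def __post_init__(self) -> None:
        if self.template_len <= 0:
            raise ValueError("template_len must be positive")
        if self.site_deletion_len < 0:
            raise ValueError("site_deletion_len must be >= 0")
        t0, t1 = self.template_start, self.template_start + self.template_len
        s0, s1 = self.insertion_pos, self.insertion_pos + self.site_deletion_len
        if max(t0, s0) < min(t1, s1):
            raise ValueError("template and insertion site overlap")

    @property
    def template_end(self) -> int:
        return self.template_start + self.template_len

    @property
    def template_mid(self) -> int:
        return self.template_start + self.template_len // 2


#: Structural-variation event classes handled by the simulator/classifier.
EVENT_CLASSES = (
    "deletion",
    "tandem_duplication",
    "inversion",
    "fold_back_fusion",
    "bfb",
    "chromothripsis",
    "templated_insertion",
)


@dataclass(frozen=True)
class EventRecord:
    """Ground-truth record of one applied rearrangement event."""

    event_class: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.event_class!r}")
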