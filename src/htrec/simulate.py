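"""Rearrangement event simulator and observable derivation.

Events are applied to a :class:`~htrec.genome.DerivativeChromosome` one at a
time; each operation returns a new derivative.  ``derive_junctions`` and
``derive_copy_number`` turn a derivative into the observables a WGS calling
pipeline would report (breakpoint junctions and a binned integer copy-number
profile).  ``simulate_clone`` draws an event list from a genotype profile,
applies it with overlap rejection-resampling, and returns observables plus
the ground-truth event list for classifier validation.

The genotype profiles encode the two study conditions: wild-type subclones
carry 8-12 simple rearrangements (deletions, tandem duplications,
inversions) of typically <10 kb, while RTEL1-deficient subclones carry
15-35 events with a wide deletion-size distribution and additional complex
classes: templated duplications with distant intra-chromosomal insertion
(template 2-100 kb, inserted 10 kb - 5 Mb away, 6 bp - 1 kb deletion at the
insertion site, usually inverted), breakage-fusion-bridge cycles and
chromothripsis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from intervaltree import IntervalTree

from .genome import (
    CopyNumberProfile,
    DerivativeChromosome,
    EventRecord,
    Breakend,
    Junction,
    Segment,
    TemplatedInsertionParams,
    new_genome,
)

__all__ = [
    "new_genome",
    "apply_deletion",
    "apply_tandem_duplication",
    "apply_inversion",
    "apply_templated_insertion",
    "apply_bfb_cycles",
    "apply_chromothripsis",
    "derive_junctions",
    "derive_copy_number",
    "SimulationProfile",
    "PROFILES",
    "get_profile",
    "simulate_clone",
    "CloneResult",
]


# ---------------------------------------------------------------------------
# segment-list helpers


def _find_forward_segment(dc: DerivativeChromosome, start: int, end: int) -> int:
    """Index of the forward segment whose reference span contains [start, end).

    Raises ``ValueError`` when the interval is not fully inside a single
    forward-retained piece of the derivative (deleted, inverted, or split
    sequence cannot host a new event).
    """
    if not (0 <= start < end <= dc.genome.length):
        raise ValueError(
            f"interval [{start}, {end}) outside genome [0, {dc.genome.length})"
        )
    for i, seg in enumerate(dc.segments):
        if seg.forward and seg.start <= start and end <= seg.end:
            return i
    raise ValueError(
        f"interval [{start}, {end}) is not contained in a forward-retained "
        "segment of the derivative"
    )


def _mirror(segments: tuple[Segment, ...]) -> tuple[Segment, ...]:
    """Reverse-complement copy of a segment list."""
    return tuple(seg.reversed_() for seg in reversed(segments))


# ---------------------------------------------------------------------------
# simple events


def apply_deletion(
    dc: DerivativeChromosome, interval: tuple[int, int]
) -> DerivativeChromosome:
    """Delete reference interval [start, end) from the derivative."""
    start, end = interval
    i = _find_forward_segment(dc, start, end)
    seg = dc.segments[i]
    new = []
    if seg.start < start:
        new.append(Segment(seg.start, start, True))
    if end < seg.end:
        new.append(Segment(end, seg.end, True))
    return dc.with_segments(dc.segments[:i] + tuple(new) + dc.segments[i + 1 :])


def apply_tandem_duplication(
    dc: DerivativeChromosome, interval: tuple[int, int]
) -> DerivativeChromosome:
    """Duplicate [start, end) in place (head-to-tail)."""
    start, end = interval
    i = _find_forward_segment(dc, start, end)
    seg = dc.segments[i]
    new = (Segment(seg.start, end, True), Segment(start, seg.end, True))
    return dc.with_segments(dc.segments[:i] + new + dc.segments[i + 1 :])


def apply_inversion(
    dc: DerivativeChromosome, interval: tuple[int, int]
) -> DerivativeChromosome:
    """Invert [start, end) in place; copy number is unchanged."""
    start, end = interval
    i = _find_forward_segment(dc, start, end)
    seg = dc.segments[i]
    new = []
    if seg.start < start:
        new.append(Segment(seg.start, start, True))
    new.append(Segment(start, end, False))
    if end < seg.end:
        new.append(Segment(end, seg.end, True))
    return dc.with_segments(dc.segments[:i] + tuple(new) + dc.segments[i + 1 :])


def apply_templated_insertion(
    dc: DerivativeChromosome, params: TemplatedInsertionParams
) -> DerivativeChromosome:
    """Insert a copy of the template at a distant site on the same chromosome.

    The copy replaces ``site_deletion_len`` bases at ``insertion_pos`` and is
    inverted relative to the template when ``params.inverted``.  The template
    itself is untouched (its copy number rises by one); the replaced bases
    drop by one copy.
    """
    t0, t1 = params.template_start, params.template_end
    s0 = params.insertion_pos
    s1 = s0 + max(params.site_deletion_len, 0)
    # template must be present (it is read), site must be present (it is cut)
    _find_forward_segment(dc, t0, t1)
    i = _find_forward_segment(dc, s0, max(s1, s0 + 1))
    seg = dc.segments[i]
    if not (seg.start < s0 and s1 < seg.end):
        raise ValueError(
            "insertion site must lie strictly inside a forward segment "
            f"(site [{s0}, {s1}) vs segment [{seg.start}, {seg.end}))"
        )
    insert = Segment(t0, t1, not params.inverted)
    new = (Segment(seg.start, s0, True), insert, Segment(s1, seg.end, True))
    return dc.with_segments(dc.segments[:i] + new + dc.segments[i + 1 :])


# ---------------------------------------------------------------------------
# complex events


def apply_bfb_cycles(
    dc: DerivativeChromosome,
    n_cycles: int,
    rng: np.random.Generator | int | None = None,
    window_frac: float = 0.1,
) -> DerivativeChromosome:
    """Apply breakage-fusion-bridge cycles at the distal chromosome end.

    The distal telomere is lost by an initial break drawn uniformly within
    ``window_frac`` of the terminal segment; each cycle then fuses the
    retained arm to its reverse-complement sister copy (creating one
    fold-back junction at the current tip) and re-breaks the palindromic
    dicentric.  Successive break positions erode inward: break *k+1* is
    uniform in ``[p_k * (1 - window_frac), p_k)``, implemented by truncating
    the trailing mirrored arm at that reference coordinate.  The result is a
    monotone stepwise copy-number increase toward the fused end and copy
    loss distal to the first break.
    """
    if n_cycles < 1:
        raise ValueError(f"n_cycles must be >= 1, got {n_cycles}")
    rng = np.random.default_rng(rng)
    segs = list(dc.segments)
    last = segs[-1]
    if not last.forward:
        raise ValueError("terminal segment must be forward-oriented for BFB")

    def _draw(lo: int, hi: int) -> int:
        # uniform integer in [lo, hi); callers guarantee lo < hi
        return int(rng.integers(lo, hi))

    # initial telomere-loss break within the terminal window
    window = max(1, int(round(window_frac * last.length)))
    p = _draw(max(last.start + 1, last.end - window), last.end)
    segs[-1] = Segment(last.start, p, True)

    for _ in range(n_cycles):
        segs = segs + list(_mirror(tuple(segs)))  # sister fusion
        window = max(1, int(round(window_frac * p)))
        p_next = _draw(max(1, p - window), p)
        tail = segs[-1]
        if tail.forward or not (tail.start <= p_next < tail.end):
            raise ValueError(
                "BFB break position falls outside the trailing mirrored arm; "
                "apply BFB before rearranging the proximal chromosome body"
            )
        segs[-1] = Segment(p_next, tail.end, False)
        p = p_next
    return dc.with_segments(segs)


def apply_chromothripsis(
    dc: DerivativeChromosome,
    region: tuple[int, int],
    n_fragments: int,
    retain_prob: float,
    rng: np.random.Generator | int | None = None,
) -> DerivativeChromosome:
    """Shatter a region into fragments and re-ligate a random subset in place.

    The region is cut at ``n_fragments - 1`` uniform internal positions;
    each fragment is retained independently with ``retain_prob``, and the
    retained fragments are re-ligated in random order and orientation.
    Lost fragments drop by one copy, so the profile oscillates between two
    states inside the region; junction orientations are near-uniform over
    the four side categories.
    """
    start, end = region
    if n_fragments < 2:
        raise ValueError(f"n_fragments must be >= 2, got {n_fragments}")
    if not (0.0 <= retain_prob <= 1.0):
        raise ValueError(f"retain_prob must be in [0, 1], got {retain_prob}")
    if end - start < n_fragments:
        raise ValueError("region too small for the requested fragment count")
    rng = np.random.default_rng(rng)
    i = _find_forward_segment(dc, start, end)
    seg = dc.segments[i]

    cuts = rng.choice(np.arange(start + 1, end), size=n_fragments - 1, replace=False)
    bounds = [start] + sorted(int(c) for c in cuts) + [end]
    fragments = [Segment(a, b, True) for a, b in zip(bounds[:-1], bounds[1:])]
    kept = [f for f in fragments if rng.random() < retain_prob]
    order = rng.permutation(len(kept))
    shuffled = [
        kept[j] if rng.random() < 0.5 else kept[j].reversed_() for j in order
    ]

    new = []
    if seg.start < start:
        new.append(Segment(seg.start, start, True))
    new.extend(shuffled)
    if end < seg.end:
        new.append(Segment(end, seg.end, True))
    if not new and len(dc.segments) == 1:
        raise ValueError("chromothripsis would delete the entire derivative")
    return dc.with_segments(dc.segments[:i] + tuple(new) + dc.segments[i + 1 :])


# ---------------------------------------------------------------------------
# observables


def _junction_between(chrom: str, u: Segment, v: Segment) -> Junction | None:
    """Junction implied by derivative adjacency u->v, or None if contiguous."""
    if u.forward and v.forward and u.end == v.start:
        return None
    if (not u.forward) and (not v.forward) and u.start == v.end:
        return None
    a = Breakend(chrom, u.end - 1, "R") if u.forward else Breakend(chrom, u.start, "L")
    b = Breakend(chrom, v.start, "L") if v.forward else Breakend(chrom, v.end - 1, "R")
    return Junction(a, b)


def derive_junctions(dc: DerivativeChromosome) -> list[Junction]:
    """Unique breakpoint junctions implied by the derivative, sorted canonically.

    One junction is emitted per derivative adjacency whose reference
    coordinates are not contiguous in reference orientation; identical
    junctions (e.g. the mirrored repeats of a fold-back fusion) are
    deduplicated.
    """
    chrom = dc.genome.chrom_name
    out = set()
    for u, v in zip(dc.segments[:-1], dc.segments[1:]):
        j = _junction_between(chrom, u, v)
        if j is not None:
            out.add(j)
    return sorted(out, key=Junction.sort_key)


def derive_copy_number(
    dc: DerivativeChromosome, bin_size: int = 1
) -> CopyNumberProfile:
    """Binned integer copy-number profile over the whole reference.

    Per-base depth is the number of derivative segments covering a base plus
    ``baseline_cn - 1`` intact homolog copies; depth is averaged per bin,
    rounded to the nearest integer, and equal-CN neighbors are merged.
    """
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    length = dc.genome.length
    # piecewise-constant coverage via breakpoint sweep
    pts = {0, length}
    for seg in dc.segments:
        pts.add(seg.start)
        pts.add(seg.end)
    edges = np.array(sorted(pts), dtype=np.int64)
    depth = np.zeros(len(edges) - 1, dtype=np.int64)
    for seg in dc.segments:
        i0 = np.searchsorted(edges, seg.start)
        i1 = np.searchsorted(edges, seg.end)
        depth[i0:i1] += 1
    depth += dc.genome.baseline_cn - 1

    # cumulative integral of depth lets us average arbitrary bins exactly
    piece_len = np.diff(edges)
    cum = np.concatenate([[0], np.cumsum(depth * piece_len)])

    def integral(x: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(edges, x, side="right") - 1
        idx = np.clip(idx, 0, len(depth) - 1)
        return cum[idx] + depth[idx] * (x - edges[idx])

    bin_edges = np.arange(0, length + bin_size, bin_size, dtype=np.int64)
    bin_edges[-1] = length
    if bin_edges[-1] == bin_edges[-2]:
        bin_edges = bin_edges[:-1]
    ints = integral(bin_edges)
    means = (ints[1:] - ints[:-1]) / np.diff(bin_edges)
    cns = np.floor(means + 0.5).astype(int)  # round half up, deterministically

    segments = []
    run_start, run_cn = 0, int(cns[0])
    for k in range(1, len(cns)):
        if int(cns[k]) != run_cn:
            segments.append((int(bin_edges[run_start]), int(bin_edges[k]), run_cn))
            run_start, run_cn = k, int(cns[k])
    segments.append((int(bin_edges[run_start]), int(bin_edges[-1]), run_cn))
    return CopyNumberProfile(dc.genome.chrom_name, tuple(segments))


# ---------------------------------------------------------------------------
# clone simulation


@dataclass(frozen=True)
class SimulationProfile:
    """Event-count and size distributions for one genotype.

    Sizes are drawn log-uniformly within the given (min, max) ranges;
    event-class labels are drawn from ``class_weights``.  The defaults for
    the two named profiles encode the reported study conditions: wild-type
    subclones acquire 8-12 simple SVs of typically <10 kb; RTEL1-null
    subclones acquire 15-35 events including large deletions (>100 kb) and
    the complex classes.
    """

    name: str
    genome_length: int = 195_000_000  # mouse chromosome 1 scale
    baseline_cn: int = 2
    chrom_name: str = "chr1"
    n_events: tuple[int, int] = (8, 12)  # inclusive range
    class_weights: dict = field(
        default_factory=lambda: {
            "deletion": 0.5,
            "tandem_duplication": 0.35,
            "inversion": 0.15,
        }
    )
    deletion_size: tuple[int, int] = (500, 10_000)
    duplication_size: tuple[int, int] = (500, 10_000)
    inversion_size: tuple[int, int] = (500, 10_000)
    # templated-insertion sampling bounds (the printed ranges)
    template_len: tuple[int, int] = (2_000, 100_000)
    insertion_distance: tuple[int, int] = (10_000, 5_000_000)
    site_deletion_len: tuple[int, int] = (6, 1_000)
    inverted_prob: float = 0.8
    bfb_cycles: tuple[int, int] = (2, 4)
    bfb_window_frac: float = 0.1
    chromothripsis_fragments: tuple[int, int] = (10, 20)
    chromothripsis_retain_prob: float = 0.6
    chromothripsis_region_len: tuple[int, int] = (2_000_000, 4_000_000)
    # minimum spacing between independently placed events; emulates the
    # genome-wide sparsity of subclonal SVs (tens of events over ~2.5 Gb)
    # compressed onto a single modeled chromosome
    placement_margin: int = 1_050_000
    bin_size: int = 1_000
    max_retries: int = 1_000


PROFILES: dict[str, SimulationProfile] = {
    "wild_type": SimulationProfile(name="wild_type"),
    "rtel1_null": SimulationProfile(
        name="rtel1_null",
        n_events=(15, 35),
        class_weights={
            "deletion": 0.35,
            "tandem_duplication": 0.20,
            "inversion": 0.10,
            "templated_insertion": 0.25,
            "bfb": 0.05,
            "chromothripsis": 0.05,
        },
        deletion_size=(500, 300_000),
        duplication_size=(1_000, 100_000),
        inversion_size=(1_000, 50_000),
    ),
}


def get_profile(name_or_profile) -> SimulationProfile:
    if isinstance(name_or_profile, SimulationProfile):
        return name_or_profile
    try:
        return PROFILES[name_or_profile]
    except KeyError:
        raise ValueError(
            f"unknown profile {name_or_profile!r}; "
            f"available: {sorted(PROFILES)}"
        ) from None


@dataclass(frozen=True)
class CloneResult:
    junctions: list[Junction]
    copy_number: CopyNumberProfile
    events: list[EventRecord]
    derivative: DerivativeChromosome


def _log_uniform_int(rng: np.random.Generator, lo: int, hi: int) -> int:
    """Log-uniform integer in [lo, hi); floor keeps draws below the bound."""
    if lo >= hi - 1:
        return lo
    return max(lo, int(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


class PlacementError(RuntimeError):
    """Raised when rejection-resampling cannot place an event."""


def simulate_clone(
    profile_config: str | SimulationProfile,
    rng_seed: int | np.random.Generator | None = None,
) -> CloneResult:
    """Simulate one subclone: draw events, apply them, derive observables.

    Events are placed by uniform sampling with rejection against previously
    occupied reference intervals (with ``placement_margin`` padding); at
    most one BFB and one chromothripsis event are drawn per clone, and they
    are confined to disjoint zones of the chromosome (BFB at the distal
    end, chromothripsis in the proximal body) so their signatures remain
    separable, mirroring how such events present as distinct regional
    patterns in rearrangement profiles.
    """
    prof = get_profile(profile_config)
    rng = np.random.default_rng(rng_seed)
    L = prof.genome_length
    dc = new_genome(L, baseline_cn=prof.baseline_cn, chrom_name=prof.chrom_name)

    n = int(rng.integers(prof.n_events[0], prof.n_events[1] + 1))
    classes = list(prof.class_weights)
    weights = np.array([prof.class_weights[c] for c in classes], dtype=float)
    weights /= weights.sum()
    drawn: list[str] = []
    for _ in range(n):
        for _ in range(prof.max_retries):
            c = classes[int(rng.choice(len(classes), p=weights))]
            if c in ("bfb", "chromothripsis") and c in drawn:
                continue  # at most one complex regional event per class
            drawn.append(c)
            break

    has_bfb = "bfb" in drawn
    occupied = IntervalTree()
    events: list[EventRecord] = []

    # BFB first: it only touches the pristine distal end.  Everything else
    # then stays proximal of the realized erosion zone, with a gap wide
    # enough that fold-back and breakend clusters remain separable.
    if has_bfb:
        cycles = int(rng.integers(prof.bfb_cycles[0], prof.bfb_cycles[1] + 1))
        dc = apply_bfb_cycles(dc, cycles, rng, window_frac=prof.bfb_window_frac)
        tip = dc.segments[-1].start
        events.append(
            EventRecord("bfb", {"n_cycles": cycles, "window_frac": prof.bfb_window_frac})
        )
        body_end = tip - 6_000_000
        occupied.addi(body_end, L)
    else:
        body_end = int(0.95 * L)

    def place(length: int, lo: int, hi: int) -> int:
        for _ in range(prof.max_retries):
            if hi - length <= lo:
                break
            s = int(rng.integers(lo, hi - length))
            if not occupied.overlap(s - prof.placement_margin, s + length + prof.placement_margin):
                occupied.addi(s, s + length)
                return s
        raise PlacementError(
            f"could not place event of length {length} in [{lo}, {hi}) "
            f"after {prof.max_retries} retries"
        )

    # chromothripsis second: shatters one proximal region
    if "chromothripsis" in drawn:
        rlen = int(rng.integers(*prof.chromothripsis_region_len))
        # 1.5 Mb buffer keeps other breakpoints out of the cluster window
        buffer = 1_500_000
        start = place(rlen + 2 * buffer, int(0.02 * L), body_end) + buffer
        nfrag = int(rng.integers(prof.chromothripsis_fragments[0], prof.chromothripsis_fragments[1] + 1))
        dc = apply_chromothripsis(
            dc, (start, start + rlen), nfrag, prof.chromothripsis_retain_prob, rng
        )
        events.append(
            EventRecord(
                "chromothripsis",
                {
                    "region": (start, start + rlen),
                    "n_fragments": nfrag,
                    "retain_prob": prof.chromothripsis_retain_prob,
                },
            )
        )

    size_ranges = {
        "deletion": prof.deletion_size,
        "tandem_duplication": prof.duplication_size,
        "inversion": prof.inversion_size,
    }
    appliers = {
        "deletion": apply_deletion,
        "tandem_duplication": apply_tandem_duplication,
        "inversion": apply_inversion,
    }
    for c in drawn:
        if c in ("bfb", "chromothripsis"):
            continue
        if c == "templated_insertion":
            tlen = _log_uniform_int(rng, *prof.template_len)
            sdel = int(rng.integers(prof.site_deletion_len[0], prof.site_deletion_len[1] + 1))
            # distance is measured from the template midpoint, so it must
            # clear half the template (plus the site) to avoid overlap
            dist_lo = max(prof.insertion_distance[0], tlen // 2 + sdel + 1)
            dist = int(rng.integers(dist_lo, prof.insertion_distance[1]))
            inverted = bool(rng.random() < prof.inverted_prob)
            for _ in range(prof.max_retries):
                t0 = place(tlen, int(0.01 * L), body_end)
                mid = t0 + tlen // 2
                site = mid + dist if rng.random() < 0.5 else mid - dist
                # the site may sit close to its own template (distances start
                # at 10 kb) but must not overlap it, and must keep the full
                # margin to every other event
                hits = occupied.overlap(
                    site - prof.placement_margin, site + sdel + prof.placement_margin
                )
                foreign = [iv for iv in hits if (iv.begin, iv.end) != (t0, t0 + tlen)]
                overlaps_template = not (site + sdel <= t0 or t0 + tlen <= site)
                if (
                    not (0 < site and site + sdel < body_end)
                    or foreign
                    or overlaps_template
                ):
                    occupied.remove_overlap(t0, t0 + tlen)
                    continue
                occupied.addi(site, site + max(sdel, 1))
                params = TemplatedInsertionParams(t0, tlen, site, sdel, inverted)
                dc = apply_templated_insertion(dc, params)
                events.append(
                    EventRecord(
                        "templated_insertion",
                        {
                            "template_start": t0,
                            "template_len": tlen,
                            "insertion_pos": site,
                            "site_deletion_len": sdel,
                            "inverted": inverted,
                        },
                    )
                )
                break
            else:
                raise PlacementError("could not place templated insertion")
        else:
            size = _log_uniform_int(rng, *size_ranges[c])
            s = place(size, int(0.01 * L), body_end)
            dc = appliers[c](dc, (s, s + size))
            events.append(EventRecord(c, {"interval": (s, s + size)}))

    return CloneResult(
        junctions=derive_junctions(dc),
        copy_number=derive_copy_number(dc, bin_size=prof.bin_size),
        events=events,
        derivative=dc,
    )
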