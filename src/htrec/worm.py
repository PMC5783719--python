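"""The *mIn1* balancer marker-exchange scoring system for Ht-REC.

A heterozygous hermaphrodite carries one normal chromosome II and one copy
with the *mIn1* inversion, with visible markers flanking the balanced
interval (main-text cross: semi-dominant *dpy-25* on the normal chromosome;
recessive *rol-1* plus the semi-dominant *mIs14* GFP insertion on the
balancer).  Without recombination, self progeny segregate 50% heterozygous
: 25% normal homozygote : 25% balancer homozygote.  A heterologous
recombination (Ht-REC) crossover within the balanced interval exchanges the
flanking markers, producing reciprocal recombinant chromosomes and novel
phenotype combinations among the progeny.

The segregation model allows one crossover per parental meiosis with
probability ``r`` (reciprocal products, no double crossovers), gamete union
by self-fertilization, per-genotype viability weighting, and
renormalization over viable classes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "Marker",
    "CrossDesign",
    "ProgenyTally",
    "HtRecEstimate",
    "FoldChange",
    "IntervalDesign",
    "MapDistanceEstimate",
    "default_cross",
    "expected_progeny",
    "simulate_progeny",
    "estimate_frequency",
    "frequency_from_counts",
    "compare_frequencies",
    "FrequencyTestResult",
    "fold_change",
    "map_distance",
    "clopper_pearson",
]


# ---------------------------------------------------------------------------
# cross model


@dataclass(frozen=True)
class Marker:
    name: str
    dominance: str  # "recessive" | "semi_dominant"
    copy: str  # "normal" | "balancer" — which parental chromosome carries it

    def __post_init__(self) -> None:
        if self.dominance not in ("recessive", "semi_dominant"):
            raise ValueError(f"bad dominance {self.dominance!r}")
        if self.copy not in ("normal", "balancer"):
            raise ValueError(f"bad chromosome copy {self.copy!r}")


@dataclass(frozen=True)
class CrossDesign:
    """Marker-exchange cross: chromosome types, phenotype map, viabilities.

    ``chrom_types`` maps a chromosome-type name to the set of marker names
    it carries.  ``parental`` names the two chromosomes of the heterozygous
    parent; ``recombinant_products`` the two reciprocal crossover products.
    ``viability`` maps a genotype key (sorted chromosome-type pair joined
    with "/") to a survival probability in [0, 1]; missing keys default
    to 1.
    """

    markers: tuple[Marker, ...]
    chrom_types: dict = field(default_factory=dict)
    parental: tuple[str, str] = ("N", "B")
    recombinant_products: tuple[str, str] = ("R1", "R2")
    viability: dict = field(default_factory=dict)
    phenotype_names: dict = field(default_factory=dict)  # dosage label -> plate name

    def __post_init__(self) -> None:
        for v in self.viability.values():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"viability {v} outside [0, 1]")

    # -- genotype/phenotype machinery ------------------------------------

    def genotype_key(self, chrom_a: str, chrom_b: str) -> str:
        return "/".join(sorted((chrom_a, chrom_b)))

    def is_recombinant(self, genotype_key: str) -> bool:
        rec = set(self.recombinant_products)
        return any(c in rec for c in genotype_key.split("/"))

    def phenotype(self, genotype_key: str) -> str:
        """Phenotype label of a genotype, resolved by marker dosage.

        A semi-dominant marker is visible at dosage 1 and 2
        (distinguishably), a recessive one only when homozygous; genotypes
        with identical dosage signatures are therefore phenotypically
        identical and share one label.  ``phenotype_names`` maps dosage
        labels to the names used on the plate.
        """
        chroms = genotype_key.split("/")
        tokens = []
        for m in self.markers:
            dose = sum(m.name in self.chrom_types[c] for c in chroms)
            if m.dominance == "recessive":
                if dose == 2:
                    tokens.append(m.name)
            elif dose:
                tokens.append(f"{m.name}({dose})")
        label = " ".join(tokens) if tokens else "wild_type"
        return self.phenotype_names.get(label, label)

    def genotypes(self) -> list[str]:
        types = sorted(self.chrom_types)
        return sorted(
            {self.genotype_key(a, b) for a, b in itertools.combinations_with_replacement(types, 2)}
        )

    def recombinant_labels(self) -> set[str]:
        """Phenotype classes that unambiguously reveal a recombinant.

        A label also produced by a non-recombinant genotype (e.g. the
        reciprocal double recombinant, which mimics the balanced
        heterozygote) cannot be scored as an exchange — one reason the
        system under-detects the true exchange rate.
        """
        rec = {self.phenotype(g) for g in self.genotypes() if self.is_recombinant(g)}
        non = {self.phenotype(g) for g in self.genotypes() if not self.is_recombinant(g)}
        return rec - non


def default_cross() -> CrossDesign:
    """The main-text cross: dpy-25 / mIn1[rol-1 mIs14(GFP)] II.

    Chromosome types: N = normal (dpy-25), B = balancer (rol-1, GFP);
    crossover products R1 = dpy-25 + GFP, R2 = rol-1 only.
    """
    markers = (
        Marker("dpy-25", "semi_dominant", "normal"),
        Marker("rol-1", "recessive", "balancer"),
        Marker("GFP", "semi_dominant", "balancer"),
    )
    chrom_types = {
        "N": frozenset({"dpy-25"}),
        "B": frozenset({"rol-1", "GFP"}),
        "R1": frozenset({"dpy-25", "GFP"}),
        "R2": frozenset({"rol-1"}),
    }
    names = {
        "dpy-25(1) GFP(1)": "het_balanced",
        "dpy-25(2)": "normal_homozygote",
        "rol-1 GFP(2)": "balancer_homozygote",
    }
    return CrossDesign(markers=markers, chrom_types=chrom_types, phenotype_names=names)


# ---------------------------------------------------------------------------
# tallies and estimates


@dataclass(frozen=True)
class ProgenyTally:
    """Observed progeny counts per phenotype class."""

    counts: dict

    def __post_init__(self) -> None:
        for label, n in self.counts.items():
            if n < 0 or n != int(n):
                raise ValueError(f"count for {label!r} must be a non-negative integer")

    @property
    def n_total(self) -> int:
        return int(sum(self.counts.values()))

    def n_matching(self, labels: set[str]) -> int:
        return int(sum(n for label, n in self.counts.items() if label in labels))

    @classmethod
    def from_recombinant_counts(cls, n_recombinant: int, n_total: int) -> "ProgenyTally":
        if n_recombinant > n_total:
            raise ValueError("recombinant count exceeds total")
        return cls({"recombinant": n_recombinant, "parental": n_total - n_recombinant})


@dataclass(frozen=True)
class HtRecEstimate:
    n_recombinant: int
    n_total: int
    frequency_pct: float  # rounded to 2 decimals
    ci95: tuple[float, float]  # percent

    def __post_init__(self) -> None:
        if not (0.0 <= self.frequency_pct <= 100.0):
            raise ValueError("frequency_pct outside [0, 100]")


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval, as a fraction."""
    if n <= 0:
        raise ValueError("n must be positive")
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def estimate_frequency(
    tally: ProgenyTally,
    cross: CrossDesign | None = None,
    recombinant_labels: set[str] | None = None,
) -> HtRecEstimate:
    """Observed Ht-REC frequency (percent, 2 decimals) with exact 95% CI."""
    if tally.n_total == 0:
        raise ValueError("cannot estimate a frequency from an empty tally")
    if recombinant_labels is None:
        recombinant_labels = (
            cross.recombinant_labels() if cross is not None else {"recombinant"}
        )
    k = tally.n_matching(recombinant_labels)
    n = tally.n_total
    lo, hi = clopper_pearson(k, n)
    return HtRecEstimate(
        n_recombinant=k,
        n_total=n,
        frequency_pct=round(100.0 * k / n, 2),
        ci95=(round(100.0 * lo, 4), round(100.0 * hi, 4)),
    )


def frequency_from_counts(n_recombinant: int, n_total: int) -> HtRecEstimate:
    return estimate_frequency(ProgenyTally.from_recombinant_counts(n_recombinant, n_total))


# ---------------------------------------------------------------------------
# segregation model


def expected_progeny(
    cross: CrossDesign,
    r: float,
    viability: dict | None = None,
) -> dict:
    """Expected phenotype distribution of self progeny under the model.

    One crossover occurs within the balanced interval with probability ``r``
    in each parental meiosis, yielding the two reciprocal recombinant
    gametes with probability r/2 each; gametes unite by self-fertilization;
    genotype frequencies are weighted by viability and renormalized over
    viable classes.  With ``r = 0`` and unit viability the default cross
    returns the Mendelian 50/25/25 split.
    """
    if not (0.0 <= r <= 0.5):
        raise ValueError(f"Ht-REC rate r must be in [0, 0.5], got {r}")
    viab = dict(cross.viability)
    if viability:
        viab.update(viability)
    pa, pb = cross.parental
    r1, r2 = cross.recombinant_products
    gametes = {pa: (1 - r) / 2, pb: (1 - r) / 2, r1: r / 2, r2: r / 2}
    genotype_probs: dict[str, float] = {}
    for (ga, wa), (gb, wb) in itertools.product(gametes.items(), repeat=2):
        key = cross.genotype_key(ga, gb)
        genotype_probs[key] = genotype_probs.get(key, 0.0) + wa * wb
    weighted = {g: p * viab.get(g, 1.0) for g, p in genotype_probs.items()}
    total = sum(weighted.values())
    if total <= 0:
        raise ValueError("no viable progeny classes under the given viabilities")
    out: dict[str, float] = {}
    for g, p in weighted.items():
        if p == 0.0:
            continue
        label = cross.phenotype(g)
        out[label] = out.get(label, 0.0) + p / total
    return out


def simulate_progeny(
    cross: CrossDesign,
    r: float,
    viability: dict | None = None,
    n: int = 1_000,
    rng_seed: int | np.random.Generator | None = None,
) -> ProgenyTally:
    """Multinomial draw of ``n`` scored progeny from the expected distribution."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    dist = expected_progeny(cross, r, viability)
    labels = sorted(dist)
    draws = rng.multinomial(n, [dist[label] for label in labels])
    return ProgenyTally({label: int(k) for label, k in zip(labels, draws)})


# ---------------------------------------------------------------------------
# group tests and fold changes


@dataclass(frozen=True)
class FrequencyTestResult:
    method: str  # "fisher_exact" | "chi2"
    pvalue: float
    table: tuple[tuple[int, int], tuple[int, int]]


def compare_frequencies(
    a: tuple[int, int],
    b: tuple[int, int],
    fisher_threshold: int = 1_000,
) -> FrequencyTestResult:
    """Compare two recombinant frequencies via a 2x2 table.

    ``a`` and ``b`` are (n_recombinant, n_total) pairs.  Fisher's exact test
    (two-sided, point-probability method) is used when either group total is
    at most ``fisher_threshold``; otherwise the chi-square test without
    continuity correction.
    """
    (ka, na), (kb, nb) = a, b
    if na <= 0 or nb <= 0:
        raise ValueError("both group totals must be positive")
    if not (0 <= ka <= na and 0 <= kb <= nb):
        raise ValueError("recombinant counts must lie within group totals")
    table = ((ka, na - ka), (kb, nb - kb))
    if (ka + kb == 0) or (ka + kb == na + nb):
        # outcome margin is zero: chi-square is undefined, Fisher gives 1
        return FrequencyTestResult("degenerate", 1.0, table)
    if min(na, nb) <= fisher_threshold:
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return FrequencyTestResult("fisher_exact", float(p), table)
    res = stats.chi2_contingency(table, correction=False)
    return FrequencyTestResult("chi2", float(res.pvalue), table)


@dataclass(frozen=True)
class FoldChange:
    """Ratio of two rounded percentage frequencies.

    ``rounded`` and ``truncated`` can disagree (e.g. a ratio of 110.67
    truncates to 110 but rounds to 111); ``differs`` flags that case so the
    caller can report the convention used.
    """

    ratio: float
    rounded: int
    truncated: int

    @property
    def differs(self) -> bool:
        return self.rounded != self.truncated


def fold_change(est_a: HtRecEstimate, est_b: HtRecEstimate) -> FoldChange:
    """Fold increase of ``est_a`` over ``est_b`` (ratio of 2-dp percentages)."""
    if est_b.frequency_pct <= 0:
        raise ZeroDivisionError("fold change not defined (denominator frequency 0)")
    ratio = est_a.frequency_pct / est_b.frequency_pct
    return FoldChange(
        ratio=ratio,
        rounded=int(math.floor(ratio + 0.5)),
        truncated=int(ratio),
    )


# ---------------------------------------------------------------------------
# two-marker map distances


@dataclass(frozen=True)
class IntervalDesign:
    """Two-marker interval scored in a cis double-heterozygote self-cross.

    ``recombinant_labels`` are the phenotype classes that reveal a
    recombinant chromosome; ``detectability`` scales the observed
    recombinant-class fraction to the per-meiosis recombinant fraction for
    the direct estimator (1.0 when every recombinant gamete is visible).
    """

    label: str
    recombinant_labels: frozenset = frozenset({"recombinant"})
    detectability: float = 1.0


@dataclass(frozen=True)
class MapDistanceEstimate:
    interval: str
    estimator: str  # "direct" | "self_cross_corrected"
    n_recombinant: int
    n_total: int
    distance_cM: float
    ci95_cM: tuple[float, float]


def map_distance(
    tally: ProgenyTally,
    interval_design: IntervalDesign,
    estimator: str = "self_cross_corrected",
) -> MapDistanceEstimate:
    """Genetic map distance from recombinant phenotype classes.

    direct: distance = 100 * R / detectability with R the recombinant-class
    fraction.  self_cross_corrected: p = 1 - sqrt(1 - 2R) (the standard
    correction for a self-fertilizing cis double heterozygote, where only a
    subset of recombinant genotypes is phenotypically visible), distance =
    100 p.  The 95% CI is the exact binomial CI on the recombinant count
    propagated through the estimator.
    """
    if estimator not in ("direct", "self_cross_corrected"):
        raise ValueError(f"unknown estimator {estimator!r}")
    n = tally.n_total
    if n == 0:
        raise ValueError("empty tally")
    k = tally.n_matching(set(interval_design.recombinant_labels))
    big_r = k / n
    lo, hi = clopper_pearson(k, n)

    if estimator == "direct":
        f = interval_design.detectability
        if not (0 < f <= 1):
            raise ValueError("detectability must be in (0, 1]")
        transform = lambda x: 100.0 * x / f
    else:
        if big_r > 0.5 or hi > 0.5:
            raise ValueError(
                f"recombinant fraction {big_r:.4f} (CI upper {hi:.4f}) exceeds 0.5; "
                "the corrected estimator 1 - sqrt(1 - 2R) is undefined"
            )
        transform = lambda x: 100.0 * (1.0 - math.sqrt(1.0 - 2.0 * x))

    return MapDistanceEstimate(
        interval=interval_design.label,
        estimator=estimator,
        n_recombinant=k,
        n_total=n,
        distance_cM=transform(big_r),
        ci95_cM=(transform(lo), transform(hi)),
    )
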