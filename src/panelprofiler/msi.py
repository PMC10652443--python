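"""Microsatellite-instability scoring from per-locus read-length histograms.

For each microsatellite locus *i* a stable (MSS) baseline supplies a cut-point
repeat length C_i and the fraction p_i of MSS reads observed at lengths beyond
it.  In a tumor sample, the number of "unstable" reads n_i (reads beyond C_i)
out of N_i total is tested against Binomial(N_i, p_i); a locus is unstable
when the exact upper-tail probability P(X >= n_i) is at or below alpha
(default 0.001).  The MSI score is the fraction of unstable loci among the
top-k loci by coverage (default 30 of a 100-locus panel), and a sample is
MSI-H when the score reaches the classification threshold (default 0.4,
inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .errors import ValidationError

DEFAULT_ALPHA = 0.001
DEFAULT_TOP_K = 30
DEFAULT_SCORE_THRESHOLD = 0.4


@dataclass(frozen=True)
class LocusBaseline:
    """MSS baseline for one microsatellite locus.

    ``cut_point`` is the repeat length C_i beyond which reads count as
    unstable; ``p_i`` is the cumulative fraction of MSS reads beyond C_i.
    """

    locus_id: str
    cut_point: int
    p_i: float

    def __post_init__(self) -> None:
        if self.cut_point < 1:
            raise ValidationError(f"{self.locus_id}: cut_point must be >= 1")
        if not (0.0 <= self.p_i <= 1.0):
            raise ValidationError(f"{self.locus_id}: p_i {self.p_i} outside [0,1]")


@dataclass(frozen=True)
class LocusReadProfile:
    """Read-length histogram for one locus in one sample."""

    locus_id: str
    histogram: Mapping[int, int]

    def __post_init__(self) -> None:
        for length, count in self.histogram.items():
            if count < 0:
                raise ValidationError(
                    f"{self.locus_id}: negative read count at length {length}"
                )

    @property
    def total_reads(self) -> int:
        """N_i: total reads covering the locus."""
        return int(sum(self.histogram.values()))

    def unstable_reads(self, cut_point: int, both_sided: bool = False) -> int:
        """n_i: reads at lengths strictly beyond the cut-point.

        With ``both_sided=True`` reads strictly below the cut-point count as
        unstable too (length change in either direction).
        """
        n = sum(c for length, c in self.histogram.items() if length > cut_point)
        if both_sided:
            n += sum(c for length, c in self.histogram.items() if length < cut_point)
        return int(n)


@dataclass
class MSIResult:
    """Outcome of MSI scoring for one sample."""

    locus_flags: dict[str, str]  # locus_id -> stable | unstable
    loci_evaluated: int
    msi_score: float
    msi_class: str  # MSI-H | MSS
    alpha: float = DEFAULT_ALPHA
    score_threshold: float = DEFAULT_SCORE_THRESHOLD

    def to_dict(self) -> dict:
        return {
            "msi_class": self.msi_class,
            "msi_score": self.msi_score,
            "loci_evaluated": self.loci_evaluated,
            "alpha": self.alpha,
            "score_threshold": self.score_threshold,
            "locus_flags": dict(self.locus_flags),
        }


def select_loci(
    profiles: Sequence[LocusReadProfile], k: int = DEFAULT_TOP_K
) -> list[LocusReadProfile]:
    """Pick the k loci with the best coverage (largest N_i).

    Zero-coverage loci are excluded before ranking; ties at the selection
    boundary break by ascending locus id.  When fewer than k covered loci
    exist, all of them are returned with a warning.
    """
    if not profiles:
        raise ValidationError("no locus profiles supplied")
    covered = [p for p in profiles if p.total_reads > 0]
    covered.sort(key=lambda p: (-p.total_reads, p.locus_id))
    if len(covered) < k:
        warnings.warn(
            f"only {len(covered)} loci with coverage available; "
            f"requested top {k}",
            stacklevel=2,
        )
    return covered[:k]


def locus_tail_probability(n_i: int, N_i: int, p_i: float) -> float:
    """Exact binomial upper tail P(X >= n_i) with X ~ Binomial(N_i, p_i)."""
    if n_i < 0 or N_i < 0:
        raise ValidationError("read counts must be non-negative")
    if n_i > N_i:
        raise ValidationError(f"unstable reads {n_i} exceed total reads {N_i}")
    if not (0.0 <= p_i <= 1.0):
        raise ValidationError(f"p_i {p_i} outside [0,1]")
    if n_i == 0:
        return 1.0
    return float(stats.binom.sf(n_i - 1, N_i, p_i))


def classify_locus(
    profile: LocusReadProfile,
    baseline: LocusBaseline,
    alpha: float = DEFAULT_ALPHA,
    both_sided: bool = False,
) -> str:
    """Flag one locus as ``"stable"`` or ``"unstable"``.

    Unstable iff the tail probability of the observed unstable-read count
    under the MSS baseline is <= alpha (boundary inclusive).
    """
    if baseline.locus_id != profile.locus_id:
        raise ValidationError(
            f"baseline {baseline.locus_id} does not match profile {profile.locus_id}"
        )
    n_i = profile.unstable_reads(baseline.cut_point, both_sided=both_sided)
    p = locus_tail_probability(n_i, profile.total_reads, baseline.p_i)
    return "unstable" if p <= alpha else "stable"


def msi_score_and_class(
    flags: Sequence[str],
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> MSIResult:
    """Fold per-locus flags into an MSI score and MSI-H/MSS class.

    Score = unstable / evaluated, on the fraction scale; MSI-H iff
    score >= threshold (inclusive).
    """
    flags = list(flags)
    if not flags:
        raise ValidationError("no locus flags to score")
    bad = set(flags) - {"stable", "unstable"}
    if bad:
        raise ValidationError(f"unknown locus flags {sorted(bad)}")
    unstable = flags.count("unstable")
    score = unstable / len(flags)
    return MSIResult(
        locus_flags={},
        loci_evaluated=len(flags),
        msi_score=score,
        msi_class="MSI-H" if score >= score_threshold else "MSS",
        alpha=alpha,
        score_threshold=score_threshold,
    )


def call_msi(
    profiles: Sequence[LocusReadProfile],
    baselines: Mapping[str, LocusBaseline] | Iterable[LocusBaseline],
    alpha: float = DEFAULT_ALPHA,
    k: int = DEFAULT_TOP_K,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    both_sided: bool = False,
) -> MSIResult:
    """End-to-end MSI determination for one sample.

    Selects the top-k covered loci, tests each against its MSS baseline, and
    classifies the sample from the fraction of unstable loci.
    """
    if not isinstance(baselines, Mapping):
        baselines = {b.locus_id: b for b in baselines}
    selected = select_loci(profiles, k=k)
    flags: dict[str, str] = {}
    for prof in selected:
        base = baselines.get(prof.locus_id)
        if base is None:
            raise ValidationError(f"no MSS baseline for locus {prof.locus_id}")
        flags[prof.locus_id] = classify_locus(
            prof, base, alpha=alpha, both_sided=both_sided
        )
    result = msi_score_and_class(
        list(flags.values()), score_threshold=score_threshold, alpha=alpha
    )
    result.locus_flags = flags
    return result
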