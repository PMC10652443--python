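"""Somatic SNV detection by binomial test and the downstream filter cascade.

The caller models alt-read counts at a site as Binomial(depth, error_rate)
under the null hypothesis that all alt reads are sequencing error, and calls
a variant when the upper tail probability P(X >= alt_reads) falls below a
significance threshold and the site survives allele-fraction, supporting-read,
strand-bias and base-quality filters.  A separate "landscape" filter reduces
the call set to the reportable mutation classes (missense, stopgain,
frameshift and non-frameshift indels) and removes common polymorphisms by
population frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from scipy import stats

from .errors import ValidationError

#: Functional classes retained by the landscape (reporting) filter.
LANDSCAPE_CLASSES = frozenset(
    {"missense", "stopgain", "frameshift_indel", "nonframeshift_indel"}
)

#: Functional-class vocabulary for annotated variant tables.
FUNCTIONAL_CLASSES = frozenset(
    {
        "missense",
        "silent",
        "stopgain",
        "stoploss",
        "frameshift_indel",
        "nonframeshift_indel",
        "other",
    }
)


@dataclass(frozen=True)
class PileupRecord:
    """Per-site tumor read counts at a candidate SNV position.

    Coordinates are 1-based, VCF-style.  ``alt_fwd``/``alt_rev`` split the
    alt-supporting reads by sequencing strand.
    """

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    depth: int
    alt_reads: int
    alt_fwd: int
    alt_rev: int
    mean_base_quality: float

    def __post_init__(self) -> None:
        if self.depth < 0 or self.alt_reads < 0:
            raise ValidationError(f"negative counts at {self.chrom}:{self.pos}")
        if self.alt_reads > self.depth:
            raise ValidationError(
                f"alt_reads {self.alt_reads} > depth {self.depth} at "
                f"{self.chrom}:{self.pos}"
            )
        if self.alt_fwd < 0 or self.alt_rev < 0:
            raise ValidationError(f"negative strand counts at {self.chrom}:{self.pos}")
        if self.alt_fwd + self.alt_rev != self.alt_reads:
            raise ValidationError(
                f"strand split {self.alt_fwd}+{self.alt_rev} != alt_reads "
                f"{self.alt_reads} at {self.chrom}:{self.pos}"
            )

    @property
    def af(self) -> float:
        """Observed allele fraction; 0 when the site has no coverage."""
        return self.alt_reads / self.depth if self.depth > 0 else 0.0


@dataclass(frozen=True)
class VariantCall:
    """An annotated somatic variant.

    ``popfreq`` is the highest population allele frequency seen in germline
    databases (None for a novel variant); ``is_driver`` marks a curated driver
    annotation used only by TMB accounting.
    """

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_type: str  # SNV | INS | DEL
    functional_class: str
    af: float
    depth: int
    alt_reads: int
    popfreq: Optional[float] = None
    is_driver: bool = False
    p_value: float = float("nan")
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.variant_type not in {"SNV", "INS", "DEL"}:
            raise ValidationError(f"unknown variant_type {self.variant_type!r}")
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValidationError(
                f"unknown functional_class {self.functional_class!r}"
            )
        if not (0.0 <= self.af <= 1.0):
            raise ValidationError(f"af {self.af} outside [0,1]")
        if self.popfreq is not None and not (0.0 <= self.popfreq <= 1.0):
            raise ValidationError(f"popfreq {self.popfreq} outside [0,1]")
        if self.alt_reads > self.depth:
            raise ValidationError("alt_reads exceeds depth")


@dataclass(frozen=True)
class CallerParams:
    """Thresholds of the SNV caller and the landscape filter.

    The allele-fraction floor (5%), the population-frequency ceiling (0.015)
    and the tumor-content QC floor (20%) are the assay's stated operating
    points; the remaining knobs are named filters whose thresholds are
    conventional defaults and fully configurable.
    """

    error_rate: float = 0.01
    alpha_call: float = 1e-6
    min_af: float = 0.05
    min_alt_reads: int = 5
    max_strand_bias_p: float = 0.01
    min_base_quality: float = 25.0
    max_popfreq: float = 0.015
    tumor_content_min: float = 0.20

    def __post_init__(self) -> None:
        for name in ("error_rate", "alpha_call", "min_af", "max_strand_bias_p",
                     "max_popfreq", "tumor_content_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} = {v} outside [0,1]")
        if not (0.0 < self.error_rate < 1.0):
            raise ValidationError("error_rate must lie strictly in (0,1)")
        if self.min_alt_reads < 0:
            raise ValidationError("min_alt_reads must be >= 0")


def qc_sample(tumor_content: float, tumor_content_min: float = 0.20) -> bool:
    """Sample-level QC: eligible iff tumor cell content >= the floor (inclusive).

    Parameters
    ----------
    tumor_content
        Histologically estimated tumor cell fraction, in [0, 1].
    """
    if not (0.0 <= tumor_content <= 1.0):
        raise ValidationError(f"tumor_content {tumor_content} outside [0,1]")
    return tumor_content >= tumor_content_min


def binomial_alt_pvalue(alt_reads: int, depth: int, error_rate: float) -> float:
    """Upper-tail probability P(X >= alt_reads) for X ~ Binomial(depth, error_rate).

    This is the caller's per-site null model: every alt read is a sequencing
    error arriving independently at rate ``error_rate``.
    """
    if alt_reads < 0:
        raise ValidationError("alt_reads must be >= 0")
    if alt_reads > depth:
        raise ValidationError(f"alt_reads {alt_reads} > depth {depth}")
    if not (0.0 < error_rate < 1.0):
        raise ValidationError("error_rate must lie strictly in (0,1)")
    if alt_reads == 0:
        return 1.0
    # sf(k-1) = P(X >= k); exact via the regularized incomplete beta function
    return float(stats.binom.sf(alt_reads - 1, depth, error_rate))


def strand_bias_pvalue(alt_fwd: int, alt_rev: int, ref_fwd: int, ref_rev: int) -> float:
    """Two-sided Fisher exact test on the 2x2 strand table.

    Rows are (alt, ref), columns (forward, reverse).  An all-zero table is
    uninformative and returns 1 by convention.
    """
    counts = (alt_fwd, alt_rev, ref_fwd, ref_rev)
    if any(c < 0 for c in counts):
        raise ValidationError(f"negative count in strand table {counts}")
    if sum(counts) == 0:
        return 1.0
    _, p = stats.fisher_exact([[alt_fwd, alt_rev], [ref_fwd, ref_rev]])
    return float(p)


def _strand_fail(rec: PileupRecord, params: CallerParams) -> bool:
    # Pileups carry no reference strand split; split ref reads evenly. The
    # rule only triggers when one strand has zero alt reads, so the ref split
    # barely moves the Fisher p.
    ref_total = rec.depth - rec.alt_reads
    p = strand_bias_pvalue(rec.alt_fwd, rec.alt_rev, ref_total // 2,
                           ref_total - ref_total // 2)
    one_sided_alt = (rec.alt_fwd == 0 or rec.alt_rev == 0) and rec.alt_reads > 0
    return p < params.max_strand_bias_p and one_sided_alt


def call_snvs(
    pileups: Iterable[PileupRecord],
    params: CallerParams | None = None,
) -> list[VariantCall]:
    """Run the binomial caller over pileup records.

    A site is called when all of the following hold:

    * binomial tail p-value <= ``alpha_call``
    * allele fraction >= ``min_af`` (inclusive — 5% default)
    * alt-supporting reads >= ``min_alt_reads``
    * the strand-bias rule does not fire (Fisher p < ``max_strand_bias_p``
      with all alt reads on one strand)
    * mean base quality >= ``min_base_quality``

    Calls are returned sorted by (chrom, pos).  Gene and functional annotation
    are not known at pileup level; calls carry the placeholder gene ``"."``
    and class ``"other"`` until annotated.
    """
    params = params or CallerParams()
    calls: list[VariantCall] = []
    for rec in pileups:
        if rec.depth == 0:
            continue
        p = binomial_alt_pvalue(rec.alt_reads, rec.depth, params.error_rate)
        if p > params.alpha_call:
            continue
        if rec.af < params.min_af:
            continue
        if rec.alt_reads < params.min_alt_reads:
            continue
        if rec.mean_base_quality < params.min_base_quality:
            continue
        if _strand_fail(rec, params):
            continue
        calls.append(
            VariantCall(
                gene=".",
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref_base,
                alt=rec.alt_base,
                variant_type="SNV",
                functional_class="other",
                af=rec.af,
                depth=rec.depth,
                alt_reads=rec.alt_reads,
                p_value=p,
            )
        )
    calls.sort(key=lambda c: (c.chrom, c.pos))
    return calls


def apply_landscape_filter(
    calls: Sequence[VariantCall], max_popfreq: float = 0.015
) -> list[VariantCall]:
    """Reduce calls to the reportable mutation landscape.

    Keeps only missense, stopgain, frameshift-indel and non-frameshift-indel
    calls, and removes likely germline polymorphisms with population frequency
    strictly above ``max_popfreq``.  A missing popfreq annotation counts as 0
    (novel variant); input order is preserved and the operation is idempotent.
    """
    kept = []
    for c in calls:
        pf = c.popfreq if c.popfreq is not None else 0.0
        if pf > max_popfreq:
            continue
        if c.functional_class not in LANDSCAPE_CLASSES:
            continue
        kept.append(c)
    return kept


def annotate_calls(
    calls: Sequence[VariantCall],
    annotations: dict[tuple[str, int, str, str], dict],
) -> list[VariantCall]:
    """Attach gene/class/popfreq/driver annotation to raw caller output.

    ``annotations`` maps (chrom, pos, ref, alt) to a dict with any of the keys
    gene, functional_class, popfreq, is_driver.  Unannotated calls pass
    through unchanged.
    """
    out = []
    for c in calls:
        ann = annotations.get((c.chrom, c.pos, c.ref, c.alt))
        out.append(replace(c, **ann) if ann else c)
    return out
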