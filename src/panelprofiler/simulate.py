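"""Synthetic targeted-panel cohort generator.

Produces patients, per-site pileups and microsatellite read-length histograms
with the statistical structure the downstream analyses assume, together with
the ground truth needed for parameter-recovery tests:

* anatomic site, sex, age and PD-L1 TPS per patient;
* per-gene somatic alterations drawn with site-dependent probabilities;
* TMB background mutations at an MSI-status-dependent rate;
* pileups whose alt-read counts follow Binomial(depth, AF) at variant sites
  and Binomial(depth, error_rate) at reference sites;
* locus read-length histograms drawn as multinomials over repeat lengths,
  with MSI-H samples shifting a configurable fraction of loci so that reads
  beyond the MSS cut-point exceed the baseline expectation.

Randomness is counter-based: one global seed expands to per-patient
sub-streams, so growing the cohort never reshuffles earlier patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .msi import LocusBaseline, LocusReadProfile
from .stats import PatientRecord, SITES
from .variants import PileupRecord

# ---------------------------------------------------------------------------
# default study conditions

#: Site mix of the emulated cohort (duodenum-dominant, 268:15:15 of 298).
DEFAULT_SITE_PROBS = {
    "duodenum": 268 / 298,
    "jejunum": 15 / 298,
    "ileum": 15 / 298,
}

#: Per-gene alteration probability by site.  Overall frequencies track the
#: printed cohort landscape (TP53 0.53, KRAS 0.51, APC 0.31, ...); the
#: site-dependent genes follow the reported direction (APC/LRP1B/PIK3CA/POLE/
#: MSH6/MTOR enriched in jejunum+ileum, SMAD4/CDKN2A/VEGFA/CTNNB1/ERBB2 in
#: duodenum).
DEFAULT_GENE_SITE_PROBS: dict[str, dict[str, float]] = {
    "TP53":   {"duodenum": 0.53, "jejunum": 0.53, "ileum": 0.53},
    "KRAS":   {"duodenum": 0.51, "jejunum": 0.51, "ileum": 0.51},
    "APC":    {"duodenum": 0.29, "jejunum": 0.45, "ileum": 0.45},
    "SMAD4":  {"duodenum": 0.20, "jejunum": 0.08, "ileum": 0.08},
    "VEGFA":  {"duodenum": 0.16, "jejunum": 0.06, "ileum": 0.06},
    "CDKN2A": {"duodenum": 0.16, "jejunum": 0.06, "ileum": 0.06},
    "RAC1":   {"duodenum": 0.15, "jejunum": 0.15, "ileum": 0.15},
    "LRP1B":  {"duodenum": 0.13, "jejunum": 0.25, "ileum": 0.25},
    "MGMT":   {"duodenum": 0.14, "jejunum": 0.14, "ileum": 0.14},
    "CD74":   {"duodenum": 0.13, "jejunum": 0.13, "ileum": 0.13},
    "PIK3CA": {"duodenum": 0.09, "jejunum": 0.25, "ileum": 0.25},
    "ERBB2":  {"duodenum": 0.09, "jejunum": 0.03, "ileum": 0.03},
    "CTNNB1": {"duodenum": 0.06, "jejunum": 0.02, "ileum": 0.02},
    "FBXW7":  {"duodenum": 0.08, "jejunum": 0.08, "ileum": 0.08},
    "KMT2D":  {"duodenum": 0.07, "jejunum": 0.07, "ileum": 0.07},
    "MSH6":   {"duodenum": 0.04, "jejunum": 0.15, "ileum": 0.15},
    "POLE":   {"duodenum": 0.03, "jejunum": 0.12, "ileum": 0.12},
    "MTOR":   {"duodenum": 0.04, "jejunum": 0.12, "ileum": 0.12},
}

#: MSI-H prior by site: rare in duodenum, enriched in jejunum/ileum.
DEFAULT_MSI_H_PROB_BY_SITE = {"duodenum": 0.05, "jejunum": 0.30, "ileum": 0.30}

#: Mean TMB-eligible (non-driver) mutations per sample by MSI status.  With
#: the 2.2 Mb default coding footprint these give ~4 mut/Mb (MSS) and
#: ~23 mut/Mb (MSI-H), i.e. hypermutated MSI-H samples.
DEFAULT_TMB_RATE_BY_MSI = {"MSI-H": 50.0, "MSS": 9.0}

#: Coding footprint of the emulated 733-gene panel, megabases.
DEFAULT_REGION_SIZE_MB = 2.2

#: Tail mass beyond the cut-point for a shifted (unstable) locus.
MSI_SHIFT_TAIL = 0.35

_BASES = ("A", "C", "G", "T")

_CLASS_CHOICES_LANDSCAPE = (
    ("missense", 0.70), ("stopgain", 0.10),
    ("frameshift_indel", 0.10), ("nonframeshift_indel", 0.10),
)
_CLASS_CHOICES_BACKGROUND = (
    ("missense", 0.50), ("silent", 0.30), ("stopgain", 0.05),
    ("stoploss", 0.02), ("frameshift_indel", 0.07), ("nonframeshift_indel", 0.06),
)


def _gene_coords(gene: str, index: int) -> tuple[str, int]:
    chrom = str(index % 22 + 1)
    return chrom, (index + 1) * 3_000_000


@dataclass(frozen=True)
class TrueVariant:
    """A simulated somatic variant with its true allele fraction."""

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_type: str
    functional_class: str
    true_af: float
    is_driver: bool = False
    popfreq: Optional[float] = None


@dataclass
class GroundTruth:
    """Per-patient simulation truth for parameter-recovery experiments."""

    msi_status: dict[str, str] = field(default_factory=dict)
    mutated_genes: dict[str, frozenset[str]] = field(default_factory=dict)
    variants: dict[str, list[TrueVariant]] = field(default_factory=dict)
    unstable_locus_ids: dict[str, frozenset[str]] = field(default_factory=dict)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    ``gene_mut_probs`` maps (gene, site) to an alteration probability;
    entries keyed by gene alone apply to every site.  ``true_af_range`` and
    ``msi_unstable_locus_fraction`` are (low, high) intervals sampled
    uniformly per variant / per MSI-H sample.
    """

    n_patients: int = 298
    site_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SITE_PROBS))
    gene_mut_probs: dict = field(default_factory=dict)
    msi_h_prob_by_site: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MSI_H_PROB_BY_SITE))
    mean_depth: float = 500.0
    error_rate: float = 0.01
    true_af_range: tuple[float, float] = (0.10, 0.50)
    msi_unstable_locus_fraction: tuple[float, float] = (0.5, 0.9)
    tmb_rate_by_msi: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TMB_RATE_BY_MSI))
    region_size_mb: float = DEFAULT_REGION_SIZE_MB
    n_msi_loci: int = 100
    msi_locus_depth: float = 300.0
    n_ref_sites_per_patient: int = 100
    male_prob: float = 0.6
    age_range: tuple[float, float] = (40.0, 80.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.gene_mut_probs:
            self.gene_mut_probs = {
                (g, s): p
                for g, by_site in DEFAULT_GENE_SITE_PROBS.items()
                for s, p in by_site.items()
            }
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if abs(sum(self.site_probs.values()) - 1.0) > 1e-9:
            raise ValidationError("site_probs must sum to 1")
        for s, p in self.site_probs.items():
            if s not in SITES:
                raise ValidationError(f"site_probs: unknown site {s!r}")
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"site_probs[{s}] outside [0,1]")
            if p > 0 and s not in self.msi_h_prob_by_site:
                raise ValidationError(f"msi_h_prob_by_site missing site {s!r}")
        for key, p in self.gene_mut_probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"gene_mut_probs[{key}] outside [0,1]")
        for s, p in self.msi_h_prob_by_site.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"msi_h_prob_by_site[{s}] outside [0,1]")
        if self.mean_depth <= 0:
            raise ValidationError("mean_depth must be > 0")
        if not (0.0 < self.error_rate < 0.5):
            raise ValidationError("error_rate must lie in (0, 0.5)")
        lo, hi = self.true_af_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValidationError("true_af_range must lie within (0,1]")
        lo, hi = self.msi_unstable_locus_fraction
        if not (0.0 < lo <= hi <= 1.0):
            raise ValidationError(
                "msi_unstable_locus_fraction must lie within (0,1]")
        for k in ("MSI-H", "MSS"):
            if k not in self.tmb_rate_by_msi:
                raise ValidationError(f"tmb_rate_by_msi missing {k!r}")
            if self.tmb_rate_by_msi[k] < 0:
                raise ValidationError(f"tmb_rate_by_msi[{k}] must be >= 0")
        if self.region_size_mb <= 0:
            raise ValidationError("region_size_mb must be > 0")
        if self.n_msi_loci < 1:
            raise ValidationError("n_msi_loci must be >= 1")
        if self.msi_locus_depth < 1:
            raise ValidationError("msi_locus_depth must be >= 1")

    def gene_prob(self, gene: str, site: str) -> float:
        if (gene, site) in self.gene_mut_probs:
            return self.gene_mut_probs[(gene, site)]
        return self.gene_mut_probs.get(gene, 0.0)

    @property
    def genes(self) -> list[str]:
        names = {k[0] if isinstance(k, tuple) else k for k in self.gene_mut_probs}
        return sorted(names)


# ---------------------------------------------------------------------------
# microsatellite baseline panel and histograms

def default_baseline_panel(n_loci: int = 100) -> list[LocusBaseline]:
    """Deterministic MSS baseline panel: cut-points 12..25, p_i 0.01..0.05."""
    return [
        LocusBaseline(
            locus_id=f"MS{i + 1:03d}",
            cut_point=12 + i % 14,
            p_i=0.01 + 0.01 * (i % 5),
        )
        for i in range(n_loci)
    ]


def _mss_length_distribution(base: LocusBaseline) -> tuple[np.ndarray, np.ndarray]:
    """Repeat-length support and probabilities for a stable locus.

    Mass strictly beyond the cut-point equals the baseline p_i exactly, so
    the generated tail fraction is unbiased for the tail the locus test uses.
    """
    c, p = base.cut_point, base.p_i
    lengths = np.array([c - 3, c - 2, c - 1, c, c + 1, c + 2])
    probs = np.array([0.05, 0.15, 0.25, 0.55]) * (1.0 - p)
    return lengths, np.concatenate([probs, [0.7 * p, 0.3 * p]])


def _shifted_length_distribution(
    base: LocusBaseline, tail: float = MSI_SHIFT_TAIL
) -> tuple[np.ndarray, np.ndarray]:
    """Unstable-locus distribution: tail mass beyond C_i boosted to ``tail``."""
    c = base.cut_point
    lengths = np.array([c - 3, c - 2, c - 1, c, c + 1, c + 2, c + 3])
    body = np.array([0.05, 0.15, 0.25, 0.55]) * (1.0 - tail)
    return lengths, np.concatenate([body, tail * np.array([0.5, 0.3, 0.2])])


def simulate_locus_profiles(
    msi_status: str,
    n_loci: int,
    depth: float,
    baselines: Sequence[LocusBaseline] | Mapping[str, LocusBaseline],
    seed: int | None = None,
    unstable_fraction: float = 0.7,
    shift_tail: float = MSI_SHIFT_TAIL,
    rng: np.random.Generator | None = None,
) -> list[LocusReadProfile]:
    """Draw read-length histograms for ``n_loci`` microsatellite loci.

    MSS samples draw every locus from its baseline distribution; MSI-H
    samples shift ``unstable_fraction`` of loci (rounded, at least one) to a
    distribution with ``shift_tail`` mass beyond the cut-point.  Per-locus
    coverage is Poisson around ``depth``.
    """
    if msi_status not in ("MSI-H", "MSS"):
        raise ValidationError(f"unknown msi_status {msi_status!r}")
    if n_loci < 1:
        raise ValidationError("n_loci must be >= 1")
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    if not (0.0 < unstable_fraction <= 1.0):
        raise ValidationError("unstable_fraction must lie in (0,1]")
    if isinstance(baselines, Mapping):
        panel = [baselines[k] for k in sorted(baselines)]
    else:
        panel = list(baselines)
    if len(panel) < n_loci:
        missing = n_loci - len(panel)
        raise ValidationError(
            f"baseline panel covers {len(panel)} loci, {missing} more needed"
        )
    panel = panel[:n_loci]
    rng = rng if rng is not None else np.random.default_rng(seed)

    unstable_ids: set[str] = set()
    if msi_status == "MSI-H":
        n_unstable = max(1, int(round(unstable_fraction * n_loci)))
        idx = rng.choice(n_loci, size=n_unstable, replace=False)
        unstable_ids = {panel[i].locus_id for i in idx}

    profiles = []
    for base in panel:
        if base.locus_id in unstable_ids:
            lengths, probs = _shifted_length_distribution(base, shift_tail)
        else:
            lengths, probs = _mss_length_distribution(base)
        n_reads = max(1, int(rng.poisson(depth)))
        counts = rng.multinomial(n_reads, probs)
        profiles.append(
            LocusReadProfile(
                locus_id=base.locus_id,
                histogram={
                    int(l): int(c) for l, c in zip(lengths, counts) if c > 0
                },
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# pileups

def simulate_pileups(
    true_variants: Sequence[TrueVariant],
    mean_depth: float,
    error_rate: float,
    seed: int | None = None,
    n_ref_sites: int = 0,
    rng: np.random.Generator | None = None,
) -> list[PileupRecord]:
    """Draw pileup records for variant sites plus optional reference-only sites.

    Alt reads at a variant site follow Binomial(depth, true AF); at a
    reference site, Binomial(depth, error_rate).  Strand counts split the alt
    reads Binomial(alt, 0.5); mean base quality is Gaussian around Q32.
    """
    if not (0.0 < error_rate < 0.5):
        raise ValidationError("error_rate must lie in (0, 0.5)")
    if mean_depth <= 0:
        raise ValidationError("mean_depth must be > 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    records = []

    def _one(chrom: str, pos: int, ref: str, alt: str, rate: float) -> PileupRecord:
        depth = max(1, int(rng.poisson(mean_depth)))
        alt_reads = int(rng.binomial(depth, rate))
        alt_fwd = int(rng.binomial(alt_reads, 0.5)) if alt_reads else 0
        bq = float(np.clip(rng.normal(32.0, 2.0), 20.0, 40.0))
        return PileupRecord(
            chrom=chrom, pos=pos, ref_base=ref, alt_base=alt,
            depth=depth, alt_reads=alt_reads,
            alt_fwd=alt_fwd, alt_rev=alt_reads - alt_fwd,
            mean_base_quality=round(bq, 2),
        )

    for v in true_variants:
        if v.variant_type != "SNV":
            continue  # indels enter the pipeline as annotated table rows
        records.append(_one(v.chrom, v.pos, v.ref, v.alt, v.true_af))
    for j in range(n_ref_sites):
        ref, alt = _BASES[j % 4], _BASES[(j + 1) % 4]
        records.append(_one("R1", 1_000_000 + j, ref, alt, error_rate))
    return records


# ---------------------------------------------------------------------------
# whole-cohort simulation

def _patient_rng(seed: int, index: int) -> np.random.Generator:
    # counter-based sub-stream: patient i's draws never depend on cohort size
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(index,))
    )


def _draw_class(rng: np.random.Generator, choices) -> str:
    names = [c for c, _ in choices]
    probs = np.array([w for _, w in choices])
    return names[int(rng.choice(len(names), p=probs / probs.sum()))]


def _draw_variant(
    rng: np.random.Generator,
    gene: str,
    gene_index: int,
    functional_class: str,
    af_range: tuple[float, float],
    is_driver: bool,
    popfreq: Optional[float] = None,
) -> TrueVariant:
    chrom, base = _gene_coords(gene, gene_index)
    pos = int(base + rng.integers(0, 100_000))
    af = float(rng.uniform(*af_range))
    if functional_class in ("frameshift_indel", "nonframeshift_indel"):
        if rng.random() < 0.5:
            ref, alt, vtype = "AT", "A", "DEL"
        else:
            ref, alt, vtype = "A", "AT", "INS"
    else:
        ref = _BASES[int(rng.integers(4))]
        alt = _BASES[(int(_BASES.index(ref)) + 1 + int(rng.integers(3))) % 4]
        vtype = "SNV"
    return TrueVariant(
        gene=gene, chrom=chrom, pos=pos, ref=ref, alt=alt,
        variant_type=vtype, functional_class=functional_class,
        true_af=af, is_driver=is_driver, popfreq=popfreq,
    )


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[
    list[PatientRecord],
    dict[str, list[PileupRecord]],
    dict[str, list[LocusReadProfile]],
    GroundTruth,
]:
    """Generate the full synthetic cohort.

    Returns patient records (with truth-derived mutated gene sets, MSI class
    and TMB), per-patient pileups, per-patient microsatellite profiles, and
    the ground truth.
    """
    config.validate()
    baselines = default_baseline_panel(config.n_msi_loci)
    site_names = list(config.site_probs)
    site_p = np.array([config.site_probs[s] for s in site_names])
    genes = config.genes
    truth = GroundTruth()
    patients: list[PatientRecord] = []
    pileups: dict[str, list[PileupRecord]] = {}
    profiles: dict[str, list[LocusReadProfile]] = {}

    for i in range(config.n_patients):
        rng = _patient_rng(config.seed, i)
        pid = f"P{i + 1:04d}"
        site = site_names[int(rng.choice(len(site_names), p=site_p))]
        sex = "male" if rng.random() < config.male_prob else "female"
        age = float(rng.uniform(*config.age_range))
        msi_status = (
            "MSI-H" if rng.random() < config.msi_h_prob_by_site[site] else "MSS"
        )

        variants: list[TrueVariant] = []
        mutated = set()
        for gi, gene in enumerate(genes):
            if rng.random() < config.gene_prob(gene, site):
                mutated.add(gene)
                variants.append(
                    _draw_variant(
                        rng, gene, gi,
                        _draw_class(rng, _CLASS_CHOICES_LANDSCAPE),
                        config.true_af_range, is_driver=True, popfreq=0.0,
                    )
                )
        # TMB background: non-driver coding mutations on generic panel genes
        n_bg = int(rng.poisson(config.tmb_rate_by_msi[msi_status]))
        for _ in range(n_bg):
            bg_idx = int(rng.integers(0, 600))
            variants.append(
                _draw_variant(
                    rng, f"BG{bg_idx:03d}", 50 + bg_idx,
                    _draw_class(rng, _CLASS_CHOICES_BACKGROUND),
                    config.true_af_range, is_driver=False,
                )
            )
        # common germline polymorphisms that the popfreq filter must remove
        for _ in range(int(rng.poisson(3.0))):
            snp_idx = int(rng.integers(0, 600))
            variants.append(
                _draw_variant(
                    rng, f"BG{snp_idx:03d}", 700 + snp_idx, "missense",
                    (0.35, 0.65), is_driver=False,
                    popfreq=float(rng.uniform(0.02, 0.5)),
                )
            )

        eligible = sum(
            1 for v in variants
            if not v.is_driver and (v.popfreq or 0.0) <= 0.015
            and v.functional_class != "other"
        )
        tmb_per_mb = eligible / config.region_size_mb

        tps_draw = rng.random()
        if tps_draw < 0.45:
            pdl1 = 0.0
        elif tps_draw < 0.80:
            pdl1 = float(rng.uniform(1.0, 49.0))
        else:
            pdl1 = float(rng.uniform(50.0, 100.0))

        patients.append(
            PatientRecord(
                patient_id=pid, sex=sex, age=age, site=site,
                mutated_genes=frozenset(mutated), msi_class=msi_status,
                tmb_per_mb=tmb_per_mb, pdl1_tps=round(pdl1, 1),
            )
        )
        pileups[pid] = simulate_pileups(
            variants, config.mean_depth, config.error_rate,
            n_ref_sites=config.n_ref_sites_per_patient, rng=rng,
        )
        frac = float(rng.uniform(*config.msi_unstable_locus_fraction))
        profs = simulate_locus_profiles(
            msi_status, config.n_msi_loci, config.msi_locus_depth,
            baselines, unstable_fraction=frac, rng=rng,
        )
        profiles[pid] = profs

        truth.msi_status[pid] = msi_status
        truth.mutated_genes[pid] = frozenset(mutated)
        truth.variants[pid] = variants

    return patients, pileups, profiles, truth
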