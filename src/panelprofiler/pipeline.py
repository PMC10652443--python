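"""End-to-end wiring of the analysis stages.

The stage order matters: TMB consumes the somatic call set *before* the
landscape filter (silent and stoploss mutations count toward TMB but are not
reported in the mutation landscape), and the landscape-filtered gene sets
feed the cohort statistics.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .config import PipelineConfig
from .msi import LocusBaseline, LocusReadProfile, MSIResult, call_msi
from .stats import PatientRecord, biomarker_site_comparison
from .tmb import TMBResult, compute_tmb
from .variants import VariantCall, apply_landscape_filter


def profile_patient(
    calls: Sequence[VariantCall],
    locus_profiles: Sequence[LocusReadProfile],
    baselines: Mapping[str, LocusBaseline],
    config: PipelineConfig,
) -> tuple[TMBResult, list[VariantCall], MSIResult]:
    """Run TMB → landscape filter → MSI for one patient.

    ``calls`` are annotated somatic calls before any reporting filter.
    Returns the TMB result, the landscape-filtered calls, and the MSI result.
    """
    # population-frequency exclusion is the germline stand-in and applies
    # before TMB; the functional-class (landscape) reduction applies after,
    # so silent/stoploss calls still count toward the burden
    somatic = [
        c for c in calls
        if (c.popfreq or 0.0) <= config.caller.max_popfreq
    ]
    tmb = compute_tmb(somatic, config.tmb.region_size_mb)
    landscape = apply_landscape_filter(somatic, config.caller.max_popfreq)
    msi = call_msi(
        locus_profiles, baselines,
        alpha=config.msi.alpha, k=config.msi.top_k,
        score_threshold=config.msi.score_threshold,
        both_sided=config.msi.both_sided,
    )
    return tmb, landscape, msi


def profile_cohort(
    calls_by_patient: Mapping[str, Sequence[VariantCall]],
    profiles_by_patient: Mapping[str, Sequence[LocusReadProfile]],
    baselines: Mapping[str, LocusBaseline],
    metadata: Sequence[PatientRecord],
    config: PipelineConfig,
) -> tuple[list[PatientRecord], dict]:
    """Derive per-patient molecular summaries and the site biomarker report.

    ``metadata`` supplies sex/age/site/PD-L1; mutated gene sets, MSI class
    and TMB are recomputed from the molecular inputs.
    """
    meta = {p.patient_id: p for p in metadata}
    out: list[PatientRecord] = []
    for pid, calls in calls_by_patient.items():
        base = meta.get(pid)
        if base is None:
            continue
        tmb, landscape, msi = profile_patient(
            calls, profiles_by_patient.get(pid, []), baselines, config
        )
        out.append(
            PatientRecord(
                patient_id=pid, sex=base.sex, age=base.age, site=base.site,
                mutated_genes=frozenset(c.gene for c in landscape),
                msi_class=msi.msi_class, tmb_per_mb=tmb.tmb_per_mb,
                pdl1_tps=base.pdl1_tps,
            )
        )
    report = biomarker_site_comparison(
        out,
        merge_jejunum_ileum=config.stats.merge_jejunum_ileum,
        welch=config.stats.welch,
    )
    return out, report
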