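"""Readers and writers for the exchanged tabular formats.

All formats are UTF-8 TSV with a header row and '.' as decimal separator.
Readers validate structure and reject rather than coerce: a missing required
column or an unparseable numeric raises ``ValidationError`` naming the column
or line.  Every writer produces files its paired reader accepts.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .msi import LocusBaseline, LocusReadProfile
from .stats import PatientRecord
from .variants import FUNCTIONAL_CLASSES, PileupRecord, VariantCall

logger = logging.getLogger("panelprofiler")

PILEUP_COLUMNS = [
    "chrom", "pos", "ref", "alt", "depth", "alt_reads",
    "alt_fwd", "alt_rev", "mean_bq",
]
MAF_COLUMNS = [
    "patient_id", "gene", "chrom", "pos", "ref", "alt", "variant_type",
    "functional_class", "af", "depth", "alt_reads", "popfreq", "is_driver",
]
HISTOGRAM_COLUMNS = ["sample_id", "locus_id", "repeat_length", "read_count"]
BASELINE_COLUMNS = ["locus_id", "cut_point", "p_i"]
PATIENT_COLUMNS = ["patient_id", "sex", "age", "site"]


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    return df


def _num(df: pd.DataFrame, column: str, path, kind=float, optional=False):
    """Parse a column numerically; on failure cite the 1-based file line."""
    values = []
    for idx, raw in zip(df.index, df[column]):
        raw = raw.strip()
        if raw in ("", ".", "NA") and optional:
            values.append(None)
            continue
        try:
            values.append(kind(float(raw)) if kind is int else kind(raw))
        except (TypeError, ValueError):
            # header is line 1, first data row line 2
            raise ValidationError(
                f"{path}: line {idx + 2}: cannot parse {column}={raw!r} as "
                f"{kind.__name__}"
            ) from None
    return values


# ---------------------------------------------------------------------------
# pileups

def read_pileups(path: str | Path) -> list[PileupRecord]:
    df = _read_tsv(path, PILEUP_COLUMNS)
    cols = {
        c: _num(df, c, path, int)
        for c in ("pos", "depth", "alt_reads", "alt_fwd", "alt_rev")
    }
    bq = _num(df, "mean_bq", path, float)
    return [
        PileupRecord(
            chrom=row.chrom, pos=cols["pos"][i], ref_base=row.ref,
            alt_base=row.alt, depth=cols["depth"][i],
            alt_reads=cols["alt_reads"][i], alt_fwd=cols["alt_fwd"][i],
            alt_rev=cols["alt_rev"][i], mean_base_quality=bq[i],
        )
        for i, row in enumerate(df.itertuples(index=False))
    ]


def write_pileups(records: Sequence[PileupRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "chrom": r.chrom, "pos": r.pos, "ref": r.ref_base,
                "alt": r.alt_base, "depth": r.depth, "alt_reads": r.alt_reads,
                "alt_fwd": r.alt_fwd, "alt_rev": r.alt_rev,
                "mean_bq": r.mean_base_quality,
            }
            for r in records
        ],
        columns=PILEUP_COLUMNS
        if records
        else PILEUP_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MAF-like variant tables

def read_maf_like(path: str | Path) -> dict[str, list[VariantCall]]:
    """Read an annotated variant table grouped by patient.

    Functional classes outside the vocabulary map to ``"other"`` with a
    logged warning; row order within each patient is preserved.
    """
    df = _read_tsv(path, MAF_COLUMNS)
    pos = _num(df, "pos", path, int)
    depth = _num(df, "depth", path, int)
    alt_reads = _num(df, "alt_reads", path, int)
    af = _num(df, "af", path, float)
    popfreq = _num(df, "popfreq", path, float, optional=True)
    grouped: dict[str, list[VariantCall]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        fclass = row.functional_class
        if fclass not in FUNCTIONAL_CLASSES:
            logger.warning(
                "%s: line %d: functional_class %r outside vocabulary, "
                "mapped to 'other'", path, i + 2, fclass,
            )
            fclass = "other"
        driver_raw = str(row.is_driver).strip().lower()
        call = VariantCall(
            gene=row.gene, chrom=row.chrom, pos=pos[i], ref=row.ref,
            alt=row.alt, variant_type=row.variant_type,
            functional_class=fclass, af=af[i], depth=depth[i],
            alt_reads=alt_reads[i], popfreq=popfreq[i],
            is_driver=driver_raw in ("true", "1", "yes"),
            patient_id=row.patient_id,
        )
        grouped.setdefault(row.patient_id, []).append(call)
    return grouped


def write_maf_like(
    calls: Mapping[str, Sequence[VariantCall]] | Sequence[VariantCall],
    path: str | Path,
) -> None:
    if isinstance(calls, Mapping):
        flat = [(pid, c) for pid, cs in calls.items() for c in cs]
    else:
        flat = [(c.patient_id, c) for c in calls]
    rows = [
        {
            "patient_id": pid, "gene": c.gene, "chrom": c.chrom, "pos": c.pos,
            "ref": c.ref, "alt": c.alt, "variant_type": c.variant_type,
            "functional_class": c.functional_class, "af": c.af,
            "depth": c.depth, "alt_reads": c.alt_reads,
            "popfreq": "" if c.popfreq is None else c.popfreq,
            "is_driver": str(bool(c.is_driver)).lower(),
        }
        for pid, c in flat
    ]
    pd.DataFrame(rows, columns=MAF_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# microsatellite histograms and baselines

def read_locus_histograms(path: str | Path) -> dict[str, list[LocusReadProfile]]:
    """Read per-sample locus read-length histograms.

    Duplicate (sample, locus, length) rows are summed with a warning.
    """
    df = _read_tsv(path, HISTOGRAM_COLUMNS)
    lengths = _num(df, "repeat_length", path, int)
    counts = _num(df, "read_count", path, int)
    hist: dict[tuple[str, str], dict[int, int]] = {}
    order: dict[str, list[str]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        if counts[i] < 0:
            raise ValidationError(
                f"{path}: line {i + 2}: negative read_count {counts[i]}"
            )
        key = (row.sample_id, row.locus_id)
        if key not in hist:
            hist[key] = {}
            order.setdefault(row.sample_id, []).append(row.locus_id)
        if lengths[i] in hist[key]:
            warnings.warn(
                f"{path}: duplicate repeat_length {lengths[i]} for "
                f"{row.sample_id}/{row.locus_id}; counts summed",
                stacklevel=2,
            )
        hist[key][lengths[i]] = hist[key].get(lengths[i], 0) + counts[i]
    return {
        sample: [
            LocusReadProfile(locus_id=loc, histogram=hist[(sample, loc)])
            for loc in loci
        ]
        for sample, loci in order.items()
    }


def write_locus_histograms(
    profiles: Mapping[str, Sequence[LocusReadProfile]], path: str | Path
) -> None:
    rows = [
        {
            "sample_id": sample, "locus_id": p.locus_id,
            "repeat_length": length, "read_count": count,
        }
        for sample, ps in profiles.items()
        for p in ps
        for length, count in sorted(p.histogram.items())
    ]
    pd.DataFrame(rows, columns=HISTOGRAM_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_baseline_panel(path: str | Path) -> dict[str, LocusBaseline]:
    df = _read_tsv(path, BASELINE_COLUMNS)
    cuts = _num(df, "cut_point", path, int)
    pis = _num(df, "p_i", path, float)
    return {
        row.locus_id: LocusBaseline(
            locus_id=row.locus_id, cut_point=cuts[i], p_i=pis[i]
        )
        for i, row in enumerate(df.itertuples(index=False))
    }


def write_baseline_panel(
    baselines: Iterable[LocusBaseline], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {"locus_id": b.locus_id, "cut_point": b.cut_point, "p_i": b.p_i}
            for b in baselines
        ],
        columns=BASELINE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# patient metadata

def read_patients(path: str | Path) -> list[PatientRecord]:
    df = _read_tsv(path, PATIENT_COLUMNS)
    age = _num(df, "age", path, float)
    tmb = (
        _num(df, "tmb_per_mb", path, float, optional=True)
        if "tmb_per_mb" in df.columns else [None] * len(df)
    )
    tps = (
        _num(df, "pdl1_tps", path, float, optional=True)
        if "pdl1_tps" in df.columns else [None] * len(df)
    )
    patients = []
    for i, row in enumerate(df.itertuples(index=False)):
        genes = getattr(row, "mutated_genes", "")
        patients.append(
            PatientRecord(
                patient_id=row.patient_id, sex=row.sex, age=age[i],
                site=row.site,
                mutated_genes=frozenset(g for g in genes.split(";") if g),
                msi_class=getattr(row, "msi_class", "MSS") or "MSS",
                tmb_per_mb=tmb[i] if tmb[i] is not None else 0.0,
                pdl1_tps=tps[i],
            )
        )
    return patients


def write_patients(patients: Sequence[PatientRecord], path: str | Path) -> None:
    cols = PATIENT_COLUMNS + ["msi_class", "tmb_per_mb", "pdl1_tps",
                              "mutated_genes"]
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id, "sex": p.sex, "age": p.age,
                "site": p.site, "msi_class": p.msi_class,
                "tmb_per_mb": p.tmb_per_mb,
                "pdl1_tps": "" if p.pdl1_tps is None else p.pdl1_tps,
                "mutated_genes": ";".join(sorted(p.mutated_genes)),
            }
            for p in patients
        ],
        columns=cols,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# minimal VCF output

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n'
    '##INFO=<ID=AD,Number=1,Type=Integer,Description="Alt-supporting reads">\n'
    '##INFO=<ID=AF,Number=1,Type=Float,Description="Allele fraction">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def write_vcf_minimal(calls: Sequence[VariantCall], path: str | Path) -> None:
    """Write calls as a minimal, standards-compliant VCF v4.2 file.

    Records are sorted by (chrom, pos); an empty call set yields a
    header-only file.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(VCF_HEADER)
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            info = f"DP={c.depth};AD={c.alt_reads};AF={c.af:.6g}"
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}\n"
            )
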