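import pytest

from panelprofiler import PatientRecord, PileupRecord, VariantCall


def _patient(i: int, sex: str, site: str, age: float, genes=()) -> PatientRecord:
    return PatientRecord(
        patient_id=f"T{i:04d}", sex=sex, age=age, site=site,
        mutated_genes=frozenset(genes),
    )


@pytest.fixture(scope="session")
def table1_cohort():
    """A 298-patient cohort assembled from the printed demographic counts:
    184 male, 268 duodenum + 30 jejunum/ileum, 149 aged >= 60,
    152 KRAS-mutated, 158 TP53-mutated."""
    patients = []
    for i in range(298):
        sex = "male" if i < 184 else "female"
        site = "duodenum" if i < 268 else ("jejunum" if i < 283 else "ileum")
        age = 65.0 if i < 149 else 45.0
        genes = set()
        if i < 152:
            genes.add("KRAS")
        if i >= 140:  # 298 - 140 = 158 TP53-mutated
            genes.add("TP53")
        patients.append(_patient(i, sex, site, age, genes))
    return patients


@pytest.fixture(scope="session")
def toy_pileups():
    """Ten hand-constructed sites; exactly three survive every caller rule
    at default parameters (positions 100, 600, 800)."""

    def rec(pos, depth, alt, fwd, rev, bq):
        return PileupRecord(
            chrom="1", pos=pos, ref_base="A", alt_base="T", depth=depth,
            alt_reads=alt, alt_fwd=fwd, alt_rev=rev, mean_base_quality=bq,
        )

    return [
        rec(100, 200, 30, 15, 15, 30.0),     # pass
        rec(200, 10000, 300, 150, 150, 30.0),  # AF 0.03 < 0.05
        rec(300, 8, 4, 2, 2, 30.0),          # alt reads 4 < 5
        rec(400, 200, 30, 15, 15, 20.0),     # base quality below 25
        rec(500, 200, 20, 20, 0, 30.0),      # strand bias: all alt forward
        rec(600, 100, 15, 7, 8, 28.0),       # pass
        rec(700, 60, 5, 3, 2, 30.0),         # binomial p 3.5e-4 > 1e-6
        rec(800, 250, 50, 25, 25, 35.0),     # pass
        rec(900, 100, 0, 0, 0, 30.0),        # no alt evidence
        rec(1000, 200, 12, 11, 1, 24.0),     # base quality below 25
    ]


@pytest.fixture(scope="session")
def toy_annotated_calls():
    """Ten annotated variants; five survive the landscape filter
    (kept classes with popfreq <= 0.015, missing popfreq treated as 0)."""

    def call(i, fclass, popfreq, vtype="SNV"):
        ref, alt = ("A", "T") if vtype == "SNV" else ("AT", "A")
        return VariantCall(
            gene=f"G{i}", chrom="1", pos=1000 + i, ref=ref, alt=alt,
            variant_type=vtype, functional_class=fclass, af=0.2,
            depth=100, alt_reads=20, popfreq=popfreq,
        )

    return [
        call(1, "missense", 0.0),                      # keep
        call(2, "missense", 0.02),                     # popfreq > 0.015
        call(3, "silent", 0.0),                        # class dropped
        call(4, "stopgain", None),                     # keep
        call(5, "frameshift_indel", 0.001, "DEL"),     # keep
        call(6, "nonframeshift_indel", 0.015, "INS"),  # keep (boundary)
        call(7, "other", 0.0),                         # class dropped
        call(8, "stoploss", 0.0),                      # class dropped
        call(9, "missense", 0.5),                      # popfreq > 0.015
        call(10, "missense", None),                    # keep
    ]
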