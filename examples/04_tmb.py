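"""Compute tumor mutational burden from an annotated variant table.

TMB counts nonsynonymous AND synonymous coding mutations (missense, silent,
stop gain/loss, in-frame and frameshift indels), excludes annotated drivers,
and normalizes per megabase of examined coding region.
"""

from panelprofiler import VariantCall, compute_tmb, tmb_high_flag


def call(gene, fclass, driver=False):
    return VariantCall(gene=gene, chrom="1", pos=1000, ref="A", alt="T",
                       variant_type="SNV", functional_class=fclass,
                       af=0.2, depth=200, alt_reads=40, is_driver=driver)


calls = (
    [call("KRAS", "missense", driver=True)]          # driver: excluded
    + [call(f"G{i}", "missense") for i in range(14)]
    + [call(f"S{i}", "silent") for i in range(8)]    # synonymous still counts
    + [call("X1", "other")]                          # non-coding class: never counted
)

result = compute_tmb(calls, region_size_mb=2.2)
print(f"eligible mutations: {result.eligible_count} "
      f"(drivers excluded: {result.excluded_drivers})")
print(f"TMB = {result.tmb_per_mb:.2f} mut/Mb over {result.region_size_mb} Mb "
      f"-> TMB-high (>= 10): {tmb_high_flag(result.tmb_per_mb)}")
# 22 eligible mutations / 2.2 Mb = 10.00 mut/Mb, exactly at the inclusive
# TMB-high cutoff
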