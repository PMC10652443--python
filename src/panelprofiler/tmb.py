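"""Tumor mutational burden (TMB).

TMB counts both nonsynonymous and synonymous somatic SNVs and indels in the
examined coding region — missense, silent, stop gain, stop loss, in-frame and
frameshift mutations — with annotated driver mutations excluded, normalized
per megabase of examined coding sequence.  Note the class list is wider than
the reporting landscape filter (silent and stoploss count toward TMB), so TMB
must consume calls *before* that filter runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import ValidationError
from .variants import VariantCall

#: Functional classes eligible for the TMB count.
TMB_CLASSES = frozenset(
    {"missense", "silent", "stopgain", "stoploss",
     "nonframeshift_indel", "frameshift_indel"}
)

#: Pan-tumor TMB-high cutoff in mutations per megabase.
TMB_HIGH_CUTOFF = 10.0


@dataclass(frozen=True)
class TMBResult:
    eligible_count: int
    region_size_mb: float
    tmb_per_mb: float
    excluded_drivers: int

    def to_dict(self) -> dict:
        return {
            "eligible_count": self.eligible_count,
            "region_size_mb": self.region_size_mb,
            "tmb_per_mb": self.tmb_per_mb,
            "excluded_drivers": self.excluded_drivers,
            "tmb_high": tmb_high_flag(self.tmb_per_mb),
        }


def compute_tmb(calls: Sequence[VariantCall], region_size_mb: float) -> TMBResult:
    """Count TMB-eligible, non-driver mutations and normalize per megabase.

    ``region_size_mb`` is the coding footprint of the examined panel in Mb and
    has no default: TMB is meaningless without explicit normalization.
    """
    if region_size_mb <= 0:
        raise ValidationError(f"region_size_mb must be > 0, got {region_size_mb}")
    eligible = 0
    drivers = 0
    for c in calls:
        if c.functional_class not in TMB_CLASSES:
            continue
        if c.is_driver:
            drivers += 1
            continue
        eligible += 1
    return TMBResult(
        eligible_count=eligible,
        region_size_mb=region_size_mb,
        tmb_per_mb=eligible / region_size_mb,
        excluded_drivers=drivers,
    )


def tmb_high_flag(tmb_per_mb: float, cutoff: float = TMB_HIGH_CUTOFF) -> bool:
    """TMB-high iff the burden reaches the cutoff (inclusive, >= 10 mut/Mb)."""
    if tmb_per_mb < 0:
        raise ValidationError("tmb_per_mb must be >= 0")
    return tmb_per_mb >= cutoff
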