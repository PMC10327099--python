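"""Variant-selection chain producing the informative hom-alt record set.

Contamination is read off the reference-allele balance of high-confidence
homozygous-alternate calls, so the filter keeps autosomal biallelic SNVs
with GQ >= 20 and 20 <= DP <= 100 (all configurable), restricted to sites
whose reference allele frequency p lies strictly inside (0.10, 0.90):
terms are divided by p, and a near-zero p turns sequencing noise into a
huge contribution.

Every input record is assigned exactly one fate -- the first gate it fails
in a fixed precedence order, or ``retained`` -- so the
:class:`FilterReport` counts partition the input and audits are
reproducible.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Optional

from .io import HET, HOM_ALT, AlleleFrequencyMap, SiteGenotype, SiteKey

#: Rejection reasons in precedence order (first failing gate wins).
REJECTION_REASONS = (
    "non_autosomal",
    "multi_allelic",
    "wrong_variant_type",
    "gq_fail",
    "dp_fail",
    "not_hom_alt",
    "af_missing",
    "af_out_of_window",
)

AUTOSOMES = frozenset(str(i) for i in range(1, 23))

VARIANT_TYPES = ("snv", "indel", "all")


@dataclasses.dataclass
class FilterConfig:
    """Selection thresholds; defaults are the recommended configuration.

    DP and GQ bounds are inclusive; the reference-AF window is strict
    (``min_ref_af < p < max_ref_af``). ``min_sites`` is the sufficiency
    threshold below which an estimate is flagged, not rejected.
    """

    min_gq: int = 20
    min_dp: int = 20
    max_dp: int = 100
    min_ref_af: float = 0.10
    max_ref_af: float = 0.90
    variant_types: str = "snv"
    autosomes_only: bool = True
    min_sites: int = 500

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_ref_af < self.max_ref_af <= 1.0):
            raise ValueError(f"need 0 <= min_ref_af < max_ref_af <= 1, got ({self.min_ref_af}, {self.max_ref_af})")
        if self.min_dp >= self.max_dp:
            raise ValueError(f"need min_dp < max_dp, got ({self.min_dp}, {self.max_dp})")
        if self.min_gq < 0:
            raise ValueError(f"min_gq must be >= 0, got {self.min_gq}")
        if self.variant_types not in VARIANT_TYPES:
            raise ValueError(f"variant_types must be one of {VARIANT_TYPES}, got {self.variant_types!r}")


@dataclasses.dataclass
class FilterReport:
    """Per-reason rejection tallies; counts + retained == total input."""

    counts: dict[str, int] = dataclasses.field(
        default_factory=lambda: {r: 0 for r in REJECTION_REASONS}
    )
    retained: int = 0

    @property
    def total(self) -> int:
        return self.retained + sum(self.counts.values())

    def as_dict(self) -> dict[str, int]:
        d = dict(self.counts)
        d["retained"] = self.retained
        return d


def classify_variant_type(key: SiteKey) -> str:
    """``snv`` iff both alleles are single bases, else ``indel``."""
    return "snv" if len(key.ref) == 1 and len(key.alt) == 1 else "indel"


def _first_failure(rec: SiteGenotype, cfg: FilterConfig) -> Optional[str]:
    """Quality gates shared by selection and the het/hom ratio (no genotype,
    no AF gate). Returns the failed reason or None."""
    if cfg.autosomes_only and rec.key.contig not in AUTOSOMES:
        return "non_autosomal"
    if rec.multiallelic:
        return "multi_allelic"
    if cfg.variant_types != "all" and classify_variant_type(rec.key) != cfg.variant_types:
        return "wrong_variant_type"
    if rec.gq < cfg.min_gq:
        return "gq_fail"
    # missing DP/AD (sentinel -1) and zero informative reads fail here: every
    # estimator term needs both allele depths.
    if not (cfg.min_dp <= rec.dp <= cfg.max_dp) or rec.ad_ref < 0 or rec.ad_alt < 0 or rec.ad_ref + rec.ad_alt == 0:
        return "dp_fail"
    return None


def select_informative(
    records: Iterable[SiteGenotype],
    af: AlleleFrequencyMap,
    cfg: FilterConfig | None = None,
) -> tuple[list[tuple[SiteGenotype, float]], FilterReport]:
    """Apply the selection chain to one sample's records.

    Returns the retained ``(record, p)`` pairs -- p is the reference allele
    frequency ``1 - q`` from the AF map -- and a :class:`FilterReport`
    tallying every rejection. An empty retained set is legal; downstream
    flags it as insufficient.
    """
    cfg = cfg or FilterConfig()
    report = FilterReport()
    retained: list[tuple[SiteGenotype, float]] = []
    counts = report.counts
    for rec in records:
        reason = _first_failure(rec, cfg)
        if reason is not None:
            counts[reason] += 1
            continue
        if rec.gt != HOM_ALT:
            counts["not_hom_alt"] += 1
            continue
        q = af.alt_af(rec.key)
        if q is None:
            counts["af_missing"] += 1
            continue
        p = 1.0 - q
        if not (cfg.min_ref_af < p < cfg.max_ref_af):
            counts["af_out_of_window"] += 1
            continue
        retained.append((rec, p))
    report.retained = len(retained)
    return retained, report


def het_hom_ratio(records: Iterable[SiteGenotype], cfg: FilterConfig | None = None) -> float:
    """Het / hom-alt call ratio among records passing the quality gates.

    High contamination converts hom-alt calls to het, inflating this ratio
    while deflating the contamination estimate itself -- so it serves as
    the companion QC flag for heavily contaminated samples. Returns ``inf``
    when there are het calls but no hom-alt, ``nan`` when there are neither.
    """
    cfg = cfg or FilterConfig()
    n_het = 0
    n_hom = 0
    for rec in records:
        if _first_failure(rec, cfg) is not None:
            continue
        if rec.gt == HET:
            n_het += 1
        elif rec.gt == HOM_ALT:
            n_hom += 1
    if n_hom == 0:
        return math.nan if n_het == 0 else math.inf
    return n_het / n_hom
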