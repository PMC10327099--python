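"""Genotype input from VCF, allele-frequency joins, and result tables.

The estimator consumes only a minimal slice of a variant callset: per-sample
GT/AD/DP/GQ at biallelic sites, plus a population alternate-allele frequency
for each site. This module reads that slice from VCF (via cyvcf2), loads
allele frequencies either from the VCF's own ``INFO/AF`` or from an external
sites table, and writes the per-sample result TSV.

Coordinates are 1-based throughout (VCF convention); chromosome names are
normalized by stripping a leading ``chr`` so that ``chr1`` and ``1`` join.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import re
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator, Optional, Sequence

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .estimator import CharrResult

logger = logging.getLogger(__name__)

# Genotype class codes. The simulator's true-genotype dosage (count of alt
# alleles) coincides with these on purpose.
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

GT_LABELS = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}

#: Sentinel for an absent FORMAT integer (AD/DP/GQ not present in the record).
ABSENT = -1

_ALLELE_RE = re.compile(r"^[ACGT]+$")


class VcfSchemaError(ValueError):
    """The VCF lacks a structural requirement (e.g. no GT in FORMAT)."""


def normalize_contig(contig: str) -> str:
    """Strip a leading ``chr``/``Chr``/``CHR`` prefix from a contig name."""
    if contig[:3].lower() == "chr":
        return contig[3:]
    return contig


@dataclasses.dataclass(frozen=True)
class SiteKey:
    """Identity of a biallelic site: (contig, 1-based pos, ref, alt).

    Contig names are normalized and alleles uppercased on construction, so
    keys built from different VCF dialects compare equal.
    """

    contig: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "contig", normalize_contig(self.contig))
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not _ALLELE_RE.match(self.ref) or not _ALLELE_RE.match(self.alt):
            raise ValueError(f"alleles must be non-empty A/C/G/T strings: {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical: {self.ref!r}")


@dataclasses.dataclass(slots=True)
class SiteGenotype:
    """One sample's call at one site.

    ``ad_ref``/``ad_alt`` are the per-allele read depths (RR and AR at
    hom-alt sites); ``ABSENT`` (-1) marks a FORMAT field missing from the
    record. ``multiallelic`` marks records with >1 ALT allele, which are
    never split -- the filter layer drops them.
    """

    key: SiteKey
    sample_id: str
    gt: int
    ad_ref: int
    ad_alt: int
    dp: int
    gq: int
    multiallelic: bool = False


@dataclasses.dataclass
class AlleleFrequencyMap:
    """Lookup from :class:`SiteKey` to alternate-allele frequency q.

    The reference allele frequency is always derived as ``p = 1 - q`` and
    never stored, since standard annotations store alt AF. Lookup misses
    return ``None`` and are counted by the caller, never raised.
    """

    entries: dict[SiteKey, float] = dataclasses.field(default_factory=dict)
    source_label: str = ""
    n_duplicates: int = 0

    def alt_af(self, key: SiteKey) -> Optional[float]:
        return self.entries.get(key)

    def ref_af(self, key: SiteKey) -> Optional[float]:
        q = self.entries.get(key)
        return None if q is None else 1.0 - q

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: SiteKey) -> bool:
        return key in self.entries


def _int_or_absent(value) -> int:
    """Map cyvcf2 missing-int sentinels (large negatives) to ABSENT."""
    v = int(value)
    return v if v >= 0 else ABSENT


def read_genotypes(
    vcf_path: str | Path,
    samples: Optional[Sequence[str]] = None,
) -> Iterator[SiteGenotype]:
    """Yield one :class:`SiteGenotype` per (site, sample) from a VCF.

    Parameters
    ----------
    vcf_path
        Plain or bgzipped VCF with GT in FORMAT; AD/DP/GQ may be absent
        per-record and come through as ``ABSENT``.
    samples
        Restrict to these sample ids (all samples if ``None``).

    Raises
    ------
    FileNotFoundError
        Unreadable path.
    VcfSchemaError
        FORMAT lacks GT entirely.
    KeyError
        A requested sample is not in the VCF.
    """
    import cyvcf2

    path = Path(vcf_path)
    if not path.exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    vcf = cyvcf2.VCF(str(path), gts012=True)
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise VcfSchemaError(f"{path}: FORMAT does not declare GT")
    if samples is not None:
        absent = [s for s in samples if s not in vcf.samples]
        if absent:
            raise KeyError(f"sample(s) not in {path}: {', '.join(absent)}")
        vcf.set_samples(list(samples))
    sample_ids = list(vcf.samples)
    n_skipped_alleles = 0

    for var in vcf:
        alts = var.ALT
        if not alts:
            n_skipped_alleles += 1
            continue
        multiallelic = len(alts) > 1
        ref, alt = var.REF.upper(), alts[0].upper()
        if not (_ALLELE_RE.match(ref) and _ALLELE_RE.match(alt)) or ref == alt:
            # symbolic / breakend / spanning-deletion alleles carry no AD
            # semantics usable here
            n_skipped_alleles += 1
            continue
        key = SiteKey(var.CHROM, var.POS, ref, alt)
        gt_types = var.gt_types  # gts012: 0 hom_ref, 1 het, 2 hom_alt, 3 unknown
        ad = var.format("AD")
        dp = var.format("DP")
        gq = var.format("GQ")
        for i, sid in enumerate(sample_ids):
            g = int(gt_types[i])
            gt = MISSING if g == 3 else g
            ad_ref = _int_or_absent(ad[i, 0]) if ad is not None and ad.shape[1] >= 1 else ABSENT
            ad_alt = _int_or_absent(ad[i, 1]) if ad is not None and ad.shape[1] >= 2 else ABSENT
            dp_i = _int_or_absent(dp[i, 0]) if dp is not None else ABSENT
            gq_i = _int_or_absent(gq[i][0] if getattr(gq[i], "ndim", 0) else gq[i]) if gq is not None else ABSENT
            yield SiteGenotype(key, sid, gt, ad_ref, ad_alt, dp_i, gq_i, multiallelic)

    if n_skipped_alleles:
        logger.warning("%s: skipped %d records with symbolic/degenerate alleles", path, n_skipped_alleles)


SITES_TABLE_COLUMNS = ("contig", "pos", "ref", "alt", "af")


def load_af_map(source: str | Path, mode: str = "sites_table") -> AlleleFrequencyMap:
    """Load alternate-allele frequencies keyed by normalized site.

    ``mode='sites_table'`` reads a TSV with header columns
    ``contig pos ref alt af``; ``mode='info_af'`` reads INFO/AF from
    biallelic records of a VCF. Duplicate keys are last-wins with a
    warning count; an ``af`` outside [0, 1] is fatal and names the
    offending line/record.
    """
    if mode == "sites_table":
        return _load_sites_table(Path(source))
    if mode == "info_af":
        return _load_info_af(Path(source))
    raise ValueError(f"unknown AF mode: {mode!r}")


def _load_sites_table(path: Path) -> AlleleFrequencyMap:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    missing = [c for c in SITES_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise VcfSchemaError(f"{path}: sites table missing column(s) {missing}")
    amap = AlleleFrequencyMap(source_label=str(path))
    for row_idx, (contig, pos, ref, alt, af) in enumerate(
        zip(df["contig"], df["pos"], df["ref"], df["alt"], df["af"])
    ):
        af = float(af)
        if not (0.0 <= af <= 1.0) or math.isnan(af):
            # +2: one for the header line, one for 1-based line numbers
            raise ValueError(f"{path} line {row_idx + 2}: af={af} outside [0, 1]")
        key = SiteKey(str(contig), int(pos), str(ref), str(alt))
        if key in amap.entries:
            amap.n_duplicates += 1
        amap.entries[key] = af
    if amap.n_duplicates:
        logger.warning("%s: %d duplicate site keys (last wins)", path, amap.n_duplicates)
    return amap


def _load_info_af(path: Path) -> AlleleFrequencyMap:
    import cyvcf2

    if not path.exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    amap = AlleleFrequencyMap(source_label=f"INFO/AF:{path}")
    for var in cyvcf2.VCF(str(path)):
        if not var.ALT or len(var.ALT) != 1:
            continue
        af = var.INFO.get("AF")
        if af is None:
            continue
        if isinstance(af, (tuple, list)):
            af = af[0]
        af = float(af)
        if not (0.0 <= af <= 1.0):
            raise ValueError(f"{path} at {var.CHROM}:{var.POS}: AF={af} outside [0, 1]")
        ref, alt = var.REF.upper(), var.ALT[0].upper()
        if not (_ALLELE_RE.match(ref) and _ALLELE_RE.match(alt)) or ref == alt:
            continue
        key = SiteKey(var.CHROM, var.POS, ref, alt)
        if key in amap.entries:
            amap.n_duplicates += 1
        amap.entries[key] = af
    if amap.n_duplicates:
        logger.warning("%s: %d duplicate site keys (last wins)", path, amap.n_duplicates)
    return amap


RESULT_COLUMNS = (
    "sample_id",
    "charr",
    "n_hom_alt_used",
    "mean_dp",
    "het_hom_ratio",
    "insufficient_sites_flag",
)


def _fmt_float(x: float) -> str:
    if math.isnan(x):
        return "nan"
    if math.isinf(x):
        return "inf"
    return f"{x:.6f}"


def write_results(results: Iterable["CharrResult"], out_path: str | Path) -> None:
    """Write per-sample estimates as a TSV (header always present)."""
    path = Path(out_path)
    with path.open("w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    (
                        r.sample_id,
                        _fmt_float(r.charr),
                        str(r.n_sites),
                        _fmt_float(r.mean_dp),
                        _fmt_float(r.het_hom_ratio),
                        "true" if r.insufficient else "false",
                    )
                )
                + "\n"
            )
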