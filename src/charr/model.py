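"""Model/Results interface over the filter, estimator and MLE layers.

`ContaminationModel` holds one cohort's genotype records together with an
allele-frequency source and a filter configuration; `fit()` runs the
selection chain and both estimators for every sample and returns a
`ContaminationResults` carrying the per-sample estimates, the grid-MLE
cross-check, the het/hom QC ratio and the filter audit, with a
``summary()`` table in the statsmodels style.

Typical use::

    model = ContaminationModel.from_vcf("cohort.vcf", af="sites.tsv")
    results = model.fit()
    print(results.summary())
    results.save("charr.tsv")
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .estimator import CharrResult, MleResult, charr, grid_mle
from .filtering import FilterConfig, FilterReport, het_hom_ratio, select_informative
from .io import (
    AlleleFrequencyMap,
    SiteGenotype,
    load_af_map,
    read_genotypes,
    write_results,
)


def _resolve_af(af, vcf_path: Optional[Path] = None) -> AlleleFrequencyMap:
    if isinstance(af, AlleleFrequencyMap):
        return af
    if af == "info":
        if vcf_path is None:
            raise ValueError("af='info' requires a VCF path")
        return load_af_map(vcf_path, mode="info_af")
    return load_af_map(af, mode="sites_table")


class ContaminationModel:
    """Per-sample contamination model for a cohort of genotype records.

    Parameters
    ----------
    genotypes
        Iterable of :class:`~charr.io.SiteGenotype` (one or many samples);
        records are grouped by ``sample_id``.
    af
        Allele-frequency source: an :class:`~charr.io.AlleleFrequencyMap`,
        or a path to a sites table (TSV with contig/pos/ref/alt/af).
    filter_config
        Selection thresholds; defaults to the recommended configuration.
    """

    def __init__(
        self,
        genotypes: Iterable[SiteGenotype],
        af,
        filter_config: Optional[FilterConfig] = None,
    ):
        self.af = _resolve_af(af)
        self.config = filter_config or FilterConfig()
        self._by_sample: dict[str, list[SiteGenotype]] = {}
        for rec in genotypes:
            self._by_sample.setdefault(rec.sample_id, []).append(rec)

    @classmethod
    def from_vcf(
        cls,
        vcf_path: str | Path,
        af="info",
        samples: Optional[Sequence[str]] = None,
        filter_config: Optional[FilterConfig] = None,
    ) -> "ContaminationModel":
        """Build from a VCF; ``af='info'`` uses the VCF's own INFO/AF."""
        vcf_path = Path(vcf_path)
        af_map = _resolve_af(af, vcf_path)
        return cls(read_genotypes(vcf_path, samples), af_map, filter_config)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._by_sample)

    def fit(
        self,
        grid_start: float = 0.0,
        grid_stop: float = 0.1,
        grid_step: float = 0.001,
        mle: bool = True,
    ) -> "ContaminationResults":
        """Filter, estimate and (optionally) grid-maximize per sample."""
        results: list[CharrResult] = []
        mles: dict[str, Optional[MleResult]] = {}
        reports: dict[str, FilterReport] = {}
        for sid, recs in self._by_sample.items():
            retained, report = select_informative(recs, self.af, self.config)
            hh = het_hom_ratio(recs, self.config)
            res = charr(retained, sid, self.config.min_sites, hh)
            results.append(res)
            reports[sid] = report
            mles[sid] = (
                grid_mle(retained, grid_start, grid_stop, grid_step)
                if mle and retained
                else None
            )
        return ContaminationResults(self, results, mles, reports)


class ContaminationResults:
    """Fitted per-sample contamination estimates and diagnostics."""

    def __init__(
        self,
        model: ContaminationModel,
        results: list[CharrResult],
        mles: Mapping[str, Optional[MleResult]],
        reports: Mapping[str, FilterReport],
    ):
        self.model = model
        self.results = results
        self.mles = dict(mles)
        self.reports = dict(reports)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            m = self.mles.get(r.sample_id)
            rows.append(
                {
                    "sample_id": r.sample_id,
                    "charr": r.charr,
                    "n_hom_alt_used": r.n_sites,
                    "mean_dp": r.mean_dp,
                    "het_hom_ratio": r.het_hom_ratio,
                    "insufficient": r.insufficient,
                    "c_mle": m.c_mle if m else np.nan,
                    "c_closed_form": m.c_closed_form if m else np.nan,
                    "loglik_at_max": m.loglik_at_max if m else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable per-sample table plus the configuration used."""
        cfg = self.model.config
        df = self.to_frame()
        lines = [
            f"Contamination estimates (charr {__version__})",
            "=" * 64,
            f"filters: GQ >= {cfg.min_gq}, {cfg.min_dp} <= DP <= {cfg.max_dp}, "
            f"{cfg.min_ref_af} < ref AF < {cfg.max_ref_af}, "
            f"types={cfg.variant_types}, autosomes_only={cfg.autosomes_only}",
            f"AF source: {self.model.af.source_label or 'in-memory map'}; "
            f"sufficiency threshold: {cfg.min_sites} sites",
            "-" * 64,
            df.to_string(index=False, float_format=lambda x: f"{x:.6f}"),
        ]
        flagged = [r.sample_id for r in self.results if r.insufficient]
        if flagged:
            lines.append("-" * 64)
            lines.append(f"insufficient sites (< {cfg.min_sites}): {', '.join(flagged)}")
        return "\n".join(lines)

    def save(self, out_path: str | Path) -> None:
        """Write the per-sample results TSV."""
        write_results(self.results, out_path)

    def save_mle(self, out_path: str | Path) -> None:
        """Write the per-sample grid-MLE table."""
        df = self.to_frame()[["sample_id", "c_mle", "c_closed_form", "loglik_at_max"]]
        df.to_csv(out_path, sep="\t", index=False, float_format="%.6f")

    def plot_estimates(self, ax=None):
        """Bar plot of per-sample estimates (matplotlib, optional)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(max(4, 0.3 * len(self.results)), 3))
        df = self.to_frame()
        ax.bar(df["sample_id"], df["charr"], color="#d95f02")
        ax.set_ylabel("estimated contamination")
        ax.tick_params(axis="x", rotation=90)
        return ax
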