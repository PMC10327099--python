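"""Synthetic cohorts with known contamination rates.

Genotype-level re-implementation of the two mixing experiments used to
benchmark the estimator, without any read-level (CRAM/BAM) machinery:

1. Site alternate-allele frequencies q_j are drawn from a Beta
   distribution truncated to [0.05, 0.95] (a stand-in for the local AF
   spectrum of a small diverse cohort).
2. True genotypes follow Hardy-Weinberg: dosage ~ Binomial(2, q_j).
3. Reads are simulated per (sample, site): DP ~ Poisson(mean_depth); each
   read originates from a contaminant with probability c (``two_way``: a
   fixed partner from a different stratum; ``n_way``: a fresh uniform
   choice among all other samples, i.e. a pool), carries an allele drawn
   from the origin's true genotype, and is flipped to the other allele
   with probability ``seq_error``.
4. A flat-prior maximum-likelihood diploid caller turns (AD_ref, AD_alt)
   into GT and GQ, so the hom-alt -> het conversion that deflates the
   estimator at high contamination emerges mechanistically.

The per-read Bernoulli/uniform draws are collapsed into binomials with the
exact marginal allele probability -- identical in distribution because
read origins and alleles are i.i.d. given the genotypes.

All randomness flows through one ``numpy`` Generator seeded from
``SimScenario.seed``; draws happen in the documented order (AFs, site
keys, truth genotypes, pairing, then reads per rate in listed order), so
every output is reproducible from (scenario, seed).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .estimator import charr, grid_mle
from .filtering import FilterConfig, het_hom_ratio, select_informative
from .io import GT_LABELS, HET, HOM_ALT, MISSING, AlleleFrequencyMap, SiteGenotype, SiteKey

MIXING_MODES = ("two_way", "n_way")

#: Truncation window for simulated alt AFs, ensuring hom-alt sites exist
#: across the estimator's reference-AF window.
AF_TRUNCATION = (0.05, 0.95)


@dataclasses.dataclass
class SimScenario:
    """Configuration of one simulated cohort.

    Defaults mirror the benchmark conditions: 30 samples in 6 strata of 5,
    contamination rates 0.5/1/2/5/10%, depth ~ Poisson(30), per-read
    error 0.001. ``af_beta_shape=(0.2, 0.2)`` gives a U-shaped allele
    frequency spectrum resembling segregating sites in a small cohort.
    """

    n_sites: int
    n_samples: int = 30
    contamination_rates: tuple[float, ...] = (0.005, 0.01, 0.02, 0.05, 0.10)
    mixing: str = "n_way"
    mean_depth: float = 30.0
    seq_error: float = 0.001
    af_beta_shape: tuple[float, float] = (0.2, 0.2)
    n_strata: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        self.contamination_rates = tuple(float(r) for r in self.contamination_rates)
        if self.n_sites < 1:
            raise ValueError(f"n_sites must be >= 1, got {self.n_sites}")
        if self.n_samples < 2:
            raise ValueError(f"n_samples must be >= 2, got {self.n_samples}")
        if any(not (0.0 <= r < 1.0) for r in self.contamination_rates):
            raise ValueError(f"contamination rates must lie in [0, 1): {self.contamination_rates}")
        if self.mixing not in MIXING_MODES:
            raise ValueError(f"mixing must be one of {MIXING_MODES}, got {self.mixing!r}")
        if self.mean_depth <= 0:
            raise ValueError(f"mean_depth must be > 0, got {self.mean_depth}")
        if not (0.0 <= self.seq_error < 0.5):
            raise ValueError(f"seq_error must lie in [0, 0.5), got {self.seq_error}")
        if any(a <= 0 for a in self.af_beta_shape):
            raise ValueError(f"af_beta_shape must be positive, got {self.af_beta_shape}")
        if not (1 <= self.n_strata <= self.n_samples):
            raise ValueError(f"n_strata must lie in [1, n_samples], got {self.n_strata}")


def simulate_site_afs(
    n_sites: int, af_beta_shape: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Draw alt AFs i.i.d. Beta(a, b), resampling until inside [0.05, 0.95]."""
    a, b = af_beta_shape
    q = rng.beta(a, b, size=n_sites)
    lo, hi = AF_TRUNCATION
    bad = (q < lo) | (q > hi)
    while np.any(bad):
        q[bad] = rng.beta(a, b, size=int(bad.sum()))
        bad = (q < lo) | (q > hi)
    return q


_BASES = np.array(list("ACGT"))


def make_site_keys(n_sites: int, rng: np.random.Generator) -> list[SiteKey]:
    """Synthetic autosomal biallelic SNV keys: contiguous blocks over
    contigs 1..22, strictly increasing positions, random ref/alt pair."""
    block = -(-n_sites // 22)  # ceil
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    return [
        SiteKey(str(j // block + 1), j + 1, _BASES[ref_idx[j]], _BASES[alt_idx[j]])
        for j in range(n_sites)
    ]


def simulate_truth_genotypes(
    q: np.ndarray, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Hardy-Weinberg truth: dosage ~ Binomial(2, q_j), shape (n_samples, n_sites)."""
    n_sites = len(q)
    return rng.binomial(2, np.broadcast_to(q, (n_samples, n_sites))).astype(np.int8)


def make_strata(n_samples: int, n_strata: int) -> np.ndarray:
    """Balanced contiguous stratum labels 0..n_strata-1."""
    return np.array([i * n_strata // n_samples for i in range(n_samples)])


def assign_contaminants(
    n_samples: int,
    mixing: str,
    strata: Sequence[int],
    rng: np.random.Generator,
) -> Optional[np.ndarray]:
    """Contaminant assignment per original sample.

    ``n_way`` returns None (the pool is all other samples; the choice is
    made per read). ``two_way`` returns a permutation ``partner`` with
    ``partner[i] != i`` and cross-stratum partners only, in which every
    sample is original exactly once and contaminant exactly once. Built by
    rotating a shuffled stratum-blocked ordering by a random valid offset,
    which is guaranteed to exist whenever no stratum holds more than half
    the cohort.
    """
    if mixing == "n_way":
        return None
    strata = np.asarray(strata)
    if len(strata) != n_samples:
        raise ValueError("strata length must equal n_samples")
    labels, counts = np.unique(strata, return_counts=True)
    if len(labels) < 2:
        raise ValueError("two_way mixing requires at least 2 strata")
    max_g = int(counts.max())
    if 2 * max_g > n_samples:
        raise ValueError(
            f"two_way pairing impossible: largest stratum holds {max_g} of {n_samples} samples"
        )
    # shuffled members within shuffled stratum blocks -> contiguous blocks
    order: list[int] = []
    for lab in rng.permutation(labels):
        members = np.flatnonzero(strata == lab)
        order.extend(rng.permutation(members).tolist())
    valid_ks = [k for k in range(1, n_samples) if k >= max_g and n_samples - k >= max_g]
    k = int(rng.choice(valid_ks))
    partner = np.empty(n_samples, dtype=int)
    for pos, i in enumerate(order):
        partner[i] = order[(pos + k) % n_samples]
    return partner


@dataclasses.dataclass
class CalledCohort:
    """Simulated and genotype-called data for one contamination rate."""

    true_c: float
    ad_ref: np.ndarray  # (n_samples, n_sites)
    ad_alt: np.ndarray
    dp: np.ndarray
    gt: np.ndarray
    gq: np.ndarray


def simulate_reads(
    truth: np.ndarray,
    assignment: Optional[np.ndarray],
    true_c: float,
    scenario: SimScenario,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Allele-count read simulation for one contamination rate.

    Returns (ad_ref, ad_alt, dp), each (n_samples, n_sites), with
    ad_ref + ad_alt == dp (errors only flip between the two alleles).
    """
    n_samples, n_sites = truth.shape
    e = scenario.seq_error
    dp = rng.poisson(scenario.mean_depth, size=truth.shape)
    n_contam = rng.binomial(dp, true_c)
    n_orig = dp - n_contam

    def p_alt(dosage_half: np.ndarray) -> np.ndarray:
        return dosage_half * (1.0 - e) + (1.0 - dosage_half) * e

    alt_orig = rng.binomial(n_orig, p_alt(truth / 2.0))
    if true_c == 0.0:
        alt_contam = np.zeros_like(alt_orig)
    elif assignment is not None:  # two_way: the fixed partner
        alt_contam = rng.binomial(n_contam, p_alt(truth[assignment] / 2.0))
    else:  # n_way: fresh uniform choice among the other samples per read
        pool = (truth.sum(axis=0)[None, :] - truth) / (2.0 * (n_samples - 1))
        alt_contam = rng.binomial(n_contam, p_alt(pool))
    ad_alt = alt_orig + alt_contam
    return dp - ad_alt, ad_alt, dp


def call_genotypes(
    ad_ref: np.ndarray | int, ad_alt: np.ndarray | int, seq_error: float
) -> tuple[np.ndarray, np.ndarray]:
    """Flat-prior maximum-likelihood diploid genotype caller.

    Per-read likelihood of a reference read is 1-e, 1/2, e under hom-ref,
    het, hom-alt respectively (symmetric for alt reads). GT is the argmax;
    GQ = min(99, round(10 log10(L_best / L_second))). Zero total depth
    gives gt = missing, gq = 0.
    """
    ad_ref = np.asarray(ad_ref)
    ad_alt = np.asarray(ad_alt)
    scalar = ad_ref.ndim == 0
    ad_ref = np.atleast_1d(ad_ref).astype(float)
    ad_alt = np.atleast_1d(ad_alt).astype(float)
    e = float(seq_error)
    total = ad_ref + ad_alt
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.stack(
            [
                xlogy(ad_ref, 1.0 - e) + xlogy(ad_alt, e),  # hom_ref
                total * np.log(0.5),  # het
                xlogy(ad_ref, e) + xlogy(ad_alt, 1.0 - e),  # hom_alt
            ]
        )
    gt = np.argmax(ll, axis=0).astype(np.int8)
    ll_sorted = np.sort(ll, axis=0)
    margin = ll_sorted[-1] - ll_sorted[-2]
    with np.errstate(invalid="ignore"):
        gq = np.where(
            np.isfinite(margin),
            np.clip(np.rint(10.0 * margin / np.log(10.0)), 0, 99),
            99,
        ).astype(np.int32)
    empty = total == 0
    gt = np.where(empty, np.int8(MISSING), gt)
    gq = np.where(empty, 0, gq)
    if scalar:
        return gt[0], gq[0]
    return gt, gq


class CohortSim:
    """A simulated cohort: shared truth plus per-rate read/call layers.

    Constructing the object draws the site AFs, site keys, truth genotypes
    and (for two-way) the contaminant pairing; :meth:`simulate_rate` then
    draws reads and calls genotypes for one contamination rate. Calling
    rates in the scenario's listed order reproduces the cohort exactly.
    """

    def __init__(self, scenario: SimScenario):
        self.scenario = scenario
        self._rng = np.random.default_rng(scenario.seed)
        self.q = simulate_site_afs(scenario.n_sites, scenario.af_beta_shape, self._rng)
        self.keys = make_site_keys(scenario.n_sites, self._rng)
        self.strata = make_strata(scenario.n_samples, scenario.n_strata)
        self.truth = simulate_truth_genotypes(self.q, scenario.n_samples, self._rng)
        self.assignment = assign_contaminants(
            scenario.n_samples, scenario.mixing, self.strata, self._rng
        )
        self.sample_ids = [f"sample_{i:03d}" for i in range(scenario.n_samples)]

    def af_map(self) -> AlleleFrequencyMap:
        """The true simulated alt AFs, keyed by site ('local' frequencies)."""
        return AlleleFrequencyMap(
            entries=dict(zip(self.keys, self.q.tolist())), source_label="simulated"
        )

    def simulate_rate(self, true_c: float) -> CalledCohort:
        ad_ref, ad_alt, dp = simulate_reads(
            self.truth, self.assignment, true_c, self.scenario, self._rng
        )
        gt, gq = call_genotypes(ad_ref, ad_alt, self.scenario.seq_error)
        return CalledCohort(true_c, ad_ref, ad_alt, dp, gt, gq)

    def iter_records(self, called: CalledCohort, sample_idx: int):
        """Yield one SiteGenotype per site for one sample of a called cohort."""
        sid = self.sample_ids[sample_idx]
        gt = called.gt[sample_idx].tolist()
        gq = called.gq[sample_idx].tolist()
        ad_ref = called.ad_ref[sample_idx].tolist()
        ad_alt = called.ad_alt[sample_idx].tolist()
        dp = called.dp[sample_idx].tolist()
        for j, key in enumerate(self.keys):
            yield SiteGenotype(key, sid, gt[j], ad_ref[j], ad_alt[j], dp[j], gq[j])


_GT_STRINGS = {HOM_ALT: "1/1", HET: "0/1", 0: "0/0", MISSING: "./."}


def write_vcf(
    path: Path,
    keys: Sequence[SiteKey],
    q: np.ndarray,
    sample_ids: Sequence[str],
    called: CalledCohort,
) -> None:
    """Write a multi-sample VCF v4.2 with GT:AD:DP:GQ and INFO/AF."""
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for contig in dict.fromkeys(k.contig for k in keys):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids) + "\n")
        gt, ad_ref, ad_alt = called.gt, called.ad_ref, called.ad_alt
        dp, gq = called.dp, called.gq
        for j, key in enumerate(keys):
            cells = [
                f"{_GT_STRINGS[int(gt[i, j])]}:{ad_ref[i, j]},{ad_alt[i, j]}:{dp[i, j]}:{gq[i, j]}"
                for i in range(len(sample_ids))
            ]
            fh.write(
                f"{key.contig}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t.\t.\t"
                f"AF={q[j]:.6f}\tGT:AD:DP:GQ\t" + "\t".join(cells) + "\n"
            )


def _rate_tag(rate: float) -> str:
    return f"{rate:g}"


def emit_cohort(scenario: SimScenario, outdir: str | Path) -> dict[str, Path]:
    """Simulate a cohort and write one VCF per contamination rate, the AF
    sites table, truth tables, and a scenario echo.

    Returns a dict of output paths: ``vcf:<rate>`` per rate, plus
    ``sites``, ``truth``, ``truth_genotypes`` and ``scenario``.
    """
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = CohortSim(scenario)
    paths: dict[str, Path] = {}

    truth_rows = []
    for rate in scenario.contamination_rates:
        called = sim.simulate_rate(rate)
        vcf_path = outdir / f"cohort_c{_rate_tag(rate)}.vcf"
        write_vcf(vcf_path, sim.keys, sim.q, sim.sample_ids, called)
        paths[f"vcf:{_rate_tag(rate)}"] = vcf_path
        for i, sid in enumerate(sim.sample_ids):
            contaminant = (
                sim.sample_ids[sim.assignment[i]] if sim.assignment is not None else "pool"
            )
            truth_rows.append(
                {
                    "rate": rate,
                    "sample_id": sid,
                    "true_c": rate,
                    "mixing": scenario.mixing,
                    "contaminant_ids": contaminant,
                }
            )

    sites_path = outdir / "sites_af.tsv"
    pd.DataFrame(
        {
            "contig": [k.contig for k in sim.keys],
            "pos": [k.pos for k in sim.keys],
            "ref": [k.ref for k in sim.keys],
            "alt": [k.alt for k in sim.keys],
            "af": np.round(sim.q, 6),
        }
    ).to_csv(sites_path, sep="\t", index=False)
    paths["sites"] = sites_path

    truth_path = outdir / "truth.tsv"
    pd.DataFrame(truth_rows).to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path

    tg_path = outdir / "truth_genotypes.tsv"
    tg = pd.DataFrame(
        sim.truth.T, columns=sim.sample_ids
    ).replace({c: GT_LABELS for c in sim.sample_ids})
    tg.insert(0, "pos", [k.pos for k in sim.keys])
    tg.insert(0, "contig", [k.contig for k in sim.keys])
    tg.to_csv(tg_path, sep="\t", index=False)
    paths["truth_genotypes"] = tg_path

    scen_path = outdir / "scenario.yaml"
    with scen_path.open("w") as fh:
        yaml.safe_dump(dataclasses.asdict(scenario), fh, sort_keys=False)
    paths["scenario"] = scen_path
    return paths


def run_simulation_study(
    scenario: SimScenario,
    cfg: FilterConfig | None = None,
    outdir: str | Path | None = None,
    mle: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate, call, filter and estimate for every contamination rate.

    Returns (summary, per_sample): the summary has one row per rate with
    the mean estimate, relative bias (mean - true)/true (nan at true 0),
    and mean retained site count; per_sample has one row per simulated
    sample. Uses the true simulated allele frequencies for the AF
    adjustment. With ``mle=True`` the grid MLE is added per sample.
    """
    cfg = cfg or FilterConfig()
    sim = CohortSim(scenario)
    af = sim.af_map()
    sample_rows = []
    for rate in scenario.contamination_rates:
        called = sim.simulate_rate(rate)
        for i, sid in enumerate(sim.sample_ids):
            recs = list(sim.iter_records(called, i))
            retained, _report = select_informative(recs, af, cfg)
            hh = het_hom_ratio(recs, cfg)
            res = charr(retained, sid, cfg.min_sites, hh)
            row = {
                "true_c": rate,
                "sample_id": sid,
                "charr": res.charr,
                "n_sites": res.n_sites,
                "mean_dp": res.mean_dp,
                "het_hom_ratio": res.het_hom_ratio,
                "insufficient": res.insufficient,
            }
            if mle and retained:
                m = grid_mle(retained)
                row["c_mle"] = m.c_mle
                row["c_closed_form"] = m.c_closed_form
            sample_rows.append(row)
    per_sample = pd.DataFrame(sample_rows)
    grouped = per_sample.groupby("true_c", sort=True)
    summary = grouped.agg(mean_charr=("charr", "mean"), mean_n_sites=("n_sites", "mean")).reset_index()
    with np.errstate(divide="ignore", invalid="ignore"):
        summary["relative_bias"] = np.where(
            summary["true_c"] > 0,
            (summary["mean_charr"] - summary["true_c"]) / summary["true_c"],
            np.nan,
        )
    summary = summary[["true_c", "mean_charr", "relative_bias", "mean_n_sites"]]
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(outdir / "study_summary.tsv", sep="\t", index=False)
        per_sample.to_csv(outdir / "study_samples.tsv", sep="\t", index=False)
    return summary, per_sample
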