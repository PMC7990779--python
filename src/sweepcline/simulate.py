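"""Synthetic-data generators matched to each pipeline stage.

Every generator takes an explicit seed and is bit-reproducible given
(parameters, seed).  The four generators emulate, at desk scale, the
statistical structure each analysis stage assumes:

* :func:`simulate_sweep` — a forward Wright–Fisher population with single
  crossover recombination and infinite-sites-style mutation on a fixed site
  grid, optionally with additive selection at a central core site.  Derived
  orientation is known by construction, so iHS truth is exact.
* :func:`simulate_balding_nichols` — per-population allele frequencies drawn
  Beta(p(1-F)/F, (1-p)(1-F)/F) around an ancestral frequency p, the standard
  generator for populations differentiated at a target F_ST.
* :func:`simulate_climate_gradient` — per-population derived allele
  frequencies whose Pearson correlation with a climate covariate is set by
  construction.
* :func:`simulate_case_control` — genotypes at a specified allelic odds
  ratio, Hardy–Weinberg within each group.

:func:`simulate_pipeline_bundle` wires the four together into an on-disk
dataset (haplotypes + panel + climate + genotypes + truth JSON) with one
planted SNP that is simultaneously swept, differentiated, clinal and
risk-associated — or a matched null bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ALL_COVARIATES, HaplotypeMatrix, SnpRecord
from . import io as scio

MAX_SWEEP_RETRIES = 1000


# ---------------------------------------------------------------------------
# forward Wright-Fisher sweep simulator
# ---------------------------------------------------------------------------

@dataclass
class SweepSimParams:
    """Forward-simulation parameters (desk scale: N <= 500, L <= 200).

    ``generations`` is the neutral burn-in length; with selection the sweep
    phase then runs until the core derived allele reaches a frequency drawn
    uniformly from ``sweep_freq_range`` (bounded rejection on allele loss).
    Defaults keep the expected sweep footprint (roughly s/r divided by the
    log factor of the sweep duration) well inside half the region, so the
    derived-class decay curve of a sweep resolves without hitting the region
    edge, while mutation keeps the marker grid dense enough that haplotype
    identity is observable marker by marker.
    """

    pop_size: int = 500           # diploids
    selection_coefficient: float = 0.0
    n_sites: int = 200
    region_length: int = 100_000  # bp
    recombination_rate: float = 2e-6   # per bp per generation
    mutation_rate: float = 6e-7        # per bp per generation
    generations: int = 3000           # neutral burn-in (~6N)
    sample_haplotypes: int = 100
    seed: int = 0
    sweep_freq_range: tuple[float, float] = (0.4, 0.8)
    max_retries: int = MAX_SWEEP_RETRIES

    def __post_init__(self) -> None:
        if self.selection_coefficient < 0:
            raise ValueError("selection coefficient must be >= 0")
        if min(self.recombination_rate, self.mutation_rate) < 0:
            raise ValueError("rates must be >= 0")
        if self.sample_haplotypes > 2 * self.pop_size:
            raise ValueError("cannot sample more haplotypes than 2N")
        if not (0 < self.sweep_freq_range[0] <= self.sweep_freq_range[1] < 1):
            raise ValueError("sweep_freq_range must satisfy 0 < lo <= hi < 1")


class _WrightFisher:
    """Mutable forward-in-time population of 2N haplotypes over L sites."""

    def __init__(self, params: SweepSimParams, rng: np.random.Generator):
        self.p = params
        self.rng = rng
        self.two_n = 2 * params.pop_size
        self.L = params.n_sites
        self.core = params.n_sites // 2
        self.pop = np.zeros((self.two_n, self.L), dtype=np.int8)
        self.rho = params.recombination_rate * params.region_length  # per meiosis
        self.mu_total = self.two_n * params.mutation_rate * params.region_length
        self._col = np.arange(self.L)

    def core_freq(self) -> float:
        return float(self.pop[:, self.core].sum()) / self.two_n

    def step(self, s: float) -> None:
        rng = self.rng
        n = self.p.pop_size
        if s > 0:
            g = self.pop[0::2, self.core].astype(np.int32) + self.pop[1::2, self.core]
            w = 1.0 + s * g  # fitness 1 : 1+s : 1+2s by derived count
            parent = rng.choice(n, size=self.two_n, p=w / w.sum())
        else:
            parent = rng.integers(0, n, size=self.two_n)
        which = rng.integers(0, 2, size=self.two_n)
        base = 2 * parent + which
        child = self.pop[base].copy()
        # single-crossover recombination at rate rho per meiosis
        rec = np.flatnonzero(rng.random(self.two_n) < self.rho)
        if rec.size:
            other = 2 * parent[rec] + (1 - which[rec])
            cuts = rng.integers(1, self.L, size=rec.size)
            mask = self._col[None, :] >= cuts[:, None]
            child[rec] = np.where(mask, self.pop[other], child[rec])
        # infinite-sites-style mutation on the grid (core site reserved)
        n_mut = rng.poisson(self.mu_total)
        if n_mut:
            freq = child.sum(axis=0)
            avail = np.flatnonzero((freq == 0) & (self._col != self.core))
            if avail.size:
                sites = rng.choice(avail, size=min(n_mut, avail.size), replace=False)
                haps = rng.integers(0, self.two_n, size=sites.size)
                child[haps, sites] = 1
        # recode derived fixations as the new ancestral background
        freq = child.sum(axis=0)
        fixed = np.flatnonzero(freq == self.two_n)
        fixed = fixed[fixed != self.core]
        if fixed.size:
            child[:, fixed] = 0
        self.pop = child


def _grid_snps(params: SweepSimParams, chrom: str = "1") -> list[SnpRecord]:
    spacing = max(params.region_length // params.n_sites, 1)
    return [SnpRecord(f"s{i:04d}", chrom, (i + 1) * spacing, "A", "G")
            for i in range(params.n_sites)]


def simulate_sweep(
    params: SweepSimParams, population: str = "pop1"
) -> tuple[HaplotypeMatrix, dict]:
    """Simulate one population sample forward in time; returns (matrix, truth).

    With ``selection_coefficient == 0`` the sample is neutral and the core
    site is monomorphic ancestral.  With selection, a single derived copy is
    introduced at the core after burn-in and the population is resampled
    (bounded retries) until the sweep survives to the target frequency; the
    truth dict records the core SNP id, realized frequency and retry count.
    """
    rng = np.random.default_rng(params.seed)
    wf = _WrightFisher(params, rng)
    for _ in range(params.generations):
        wf.step(0.0)

    s = params.selection_coefficient
    truth: dict = {"core_snp_id": f"s{wf.core:04d}", "core_index": wf.core,
                   "selection_coefficient": s, "seed": params.seed,
                   "retries": 0, "sweep_generations": 0}
    if s > 0:
        lo, hi = params.sweep_freq_range
        target = rng.uniform(lo, hi)
        snapshot = wf.pop.copy()
        for attempt in range(params.max_retries):
            wf.pop = snapshot.copy()
            wf.pop[rng.integers(0, wf.two_n), wf.core] = 1
            gens = 0
            while 0.0 < wf.core_freq() < target:
                wf.step(s)
                gens += 1
            if wf.core_freq() >= target:
                truth["retries"] = attempt
                truth["sweep_generations"] = gens
                truth["target_freq"] = target
                break
        else:
            raise RuntimeError(
                f"sweep lost in all {params.max_retries} attempts (s={s}, N={params.pop_size})")

    rows = rng.choice(wf.two_n, size=params.sample_haplotypes, replace=False)
    sample = wf.pop[np.sort(rows)]
    hap_ids = [f"{population}_h{i:04d}" for i in range(params.sample_haplotypes)]
    matrix = HaplotypeMatrix(
        snps=_grid_snps(params),
        haplotype_ids=hap_ids,
        alleles=sample,
        sample_to_population={h: population for h in hap_ids},
    )
    truth["core_daf_sample"] = float((sample[:, wf.core] == 1).mean())
    return matrix, truth


# ---------------------------------------------------------------------------
# Balding-Nichols differentiated populations
# ---------------------------------------------------------------------------

@dataclass
class BaldingNicholsParams:
    fst: float = 0.2
    ancestral_freq_low: float = 0.1
    ancestral_freq_high: float = 0.9
    n_pops: int = 2
    n_snps: int = 2000
    alleles_per_pop: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fst < 1):
            raise ValueError("F must lie in (0, 1)")
        if not (0 <= self.ancestral_freq_low < self.ancestral_freq_high <= 1):
            raise ValueError("invalid ancestral frequency range")


@dataclass
class BaldingNicholsSample:
    """Per-population derived-allele counts on a shared SNP set."""

    derived_counts: np.ndarray    # (n_pops, n_snps)
    alleles_per_pop: int
    ancestral_freqs: np.ndarray   # (n_snps,)
    pop_freqs: np.ndarray         # (n_pops, n_snps) latent frequencies

    @property
    def sample_freqs(self) -> np.ndarray:
        return self.derived_counts / self.alleles_per_pop


def simulate_balding_nichols(params: BaldingNicholsParams) -> BaldingNicholsSample:
    """Draw differentiated per-population allele counts.

    Per SNP: ancestral p ~ Uniform(low, high); per population
    p_i ~ Beta(p(1-F)/F, (1-p)(1-F)/F); counts ~ Binomial(alleles_per_pop,
    p_i).  E[p_i] = p and Var(p_i) = F p(1-p), so the Hudson
    ratio-of-averages over many SNPs recovers F.
    """
    rng = np.random.default_rng(params.seed)
    p = rng.uniform(params.ancestral_freq_low, params.ancestral_freq_high, params.n_snps)
    scale = (1 - params.fst) / params.fst
    pop_freqs = rng.beta(p * scale, (1 - p) * scale, size=(params.n_pops, params.n_snps))
    counts = rng.binomial(params.alleles_per_pop, pop_freqs)
    return BaldingNicholsSample(
        derived_counts=counts, alleles_per_pop=params.alleles_per_pop,
        ancestral_freqs=p, pop_freqs=pop_freqs)


# ---------------------------------------------------------------------------
# climate cline
# ---------------------------------------------------------------------------

def _cline_arrays(rho: float, n_pops: int, n_replicates: int,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    z1 = rng.standard_normal((n_replicates, n_pops))
    z2 = rho * z1 + np.sqrt(1 - rho ** 2) * rng.standard_normal((n_replicates, n_pops))
    daf = np.clip(0.5 + 0.15 * z2, 0.02, 0.98)
    return daf, z1


def simulate_climate_gradient(
    rho: float, n_pops: int, seed: int
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-population DAF and covariate with generating correlation ``rho``.

    (z1, z2) are bivariate standard normal with correlation rho; the
    covariate is z1 and DAF = 0.5 + 0.15 z2 clipped to [0.02, 0.98].  At
    these settings clipping is a ~1-in-1500 event per population, so the
    induced correlation bias is below 0.005.
    """
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    if n_pops < 3:
        raise ValueError("need at least 3 populations")
    rng = np.random.default_rng(seed)
    daf, cov = _cline_arrays(rho, n_pops, 1, rng)
    pops = [f"pop{i:02d}" for i in range(n_pops)]
    return (dict(zip(pops, daf[0])), dict(zip(pops, cov[0])))


def simulate_climate_gradient_replicates(
    rho: float, n_pops: int, n_replicates: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized replicate draws: (daf, covariate) arrays of shape (R, n)."""
    rng = np.random.default_rng(seed)
    return _cline_arrays(rho, n_pops, n_replicates, rng)


# ---------------------------------------------------------------------------
# case-control genotypes
# ---------------------------------------------------------------------------

def case_raf(control_raf: float, odds_ratio: float) -> float:
    """Case-group risk allele frequency implied by an allelic odds ratio."""
    odds0 = control_raf / (1 - control_raf)
    return odds_ratio * odds0 / (1 + odds_ratio * odds0)


def simulate_case_control(
    control_raf: float, odds_ratio: float,
    n_cases: int, n_controls: int, seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype vectors (risk-allele counts) at a specified allelic OR.

    Within each group genotypes are Binomial(2, p) — Hardy–Weinberg — with
    the case frequency solved from the odds ratio:
    p1 = OR*o0 / (1 + OR*o0), o0 = p0/(1-p0).
    """
    if not (0 < control_raf < 1):
        raise ValueError("control risk-allele frequency must be in (0, 1)")
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    rng = np.random.default_rng(seed)
    p1 = case_raf(control_raf, odds_ratio)
    cases = rng.binomial(2, p1, size=n_cases)
    controls = rng.binomial(2, control_raf, size=n_controls)
    return cases, controls


# ---------------------------------------------------------------------------
# full pipeline bundle
# ---------------------------------------------------------------------------

def simulate_pipeline_bundle(
    out_dir: str | Path,
    seed: int,
    *,
    planted: bool = True,
    selection_coefficient: float = 0.05,
    rho: float = 0.431,
    odds_ratio: float = 1.23,
    control_raf: float = 0.5,
    n_cases: int = 1016,
    n_controls: int = 1016,
    n_cline_pops: int = 40,
    cline_haplotypes_per_pop: int = 60,
    sweep_params: SweepSimParams | None = None,
) -> dict:
    """Write a complete synthetic input set for the four-stage pipeline.

    ``planted=True``: scan group A carries a sweep at the core SNP
    (s = ``selection_coefficient``), group B is an independent neutral
    population (so the core is strongly differentiated), the core DAF runs
    along a precipitation cline with correlation ``rho`` across
    ``n_cline_pops`` extra populations, and case-control genotypes at the
    core follow ``odds_ratio``.

    ``planted=False`` (null): groups A and B are two halves of one neutral
    sample (no differentiation), the cline correlation is 0 and the
    genotype OR is 1.

    Files written: haplotypes.tsv, panel.tsv, climate.csv, genotypes.tsv,
    truth.json.  Returns the truth dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    base = sweep_params or SweepSimParams()

    if planted:
        params_a = SweepSimParams(**{**asdict(base),
                                     "selection_coefficient": selection_coefficient,
                                     "seed": int(rng.integers(2 ** 31))})
        params_b = SweepSimParams(**{**asdict(base), "selection_coefficient": 0.0,
                                     "seed": int(rng.integers(2 ** 31))})
        mat_a, truth = simulate_sweep(params_a, population="popA")
        mat_b, _ = simulate_sweep(params_b, population="popB")
        cline_rho, cc_or = rho, odds_ratio
    else:
        params = SweepSimParams(**{**asdict(base), "selection_coefficient": 0.0,
                                   "sample_haplotypes": 2 * base.sample_haplotypes,
                                   "seed": int(rng.integers(2 ** 31))})
        mat, truth = simulate_sweep(params, population="popA")
        half = base.sample_haplotypes
        mat_a = mat.subset_haplotypes(np.arange(half))
        mat_b = mat.subset_haplotypes(np.arange(half, 2 * half))
        mat_b.haplotype_ids = [f"popB_h{i:04d}" for i in range(half)]
        mat_b.sample_to_population = {h: "popB" for h in mat_b.haplotype_ids}
        cline_rho, cc_or = 0.0, 1.0

    core_id = truth["core_snp_id"]
    snps = mat_a.snps

    # cline populations: planted SNP follows the gradient, background SNPs
    # fluctuate around the scan-group frequencies with no climate structure
    daf_by_pop, cov_by_pop = simulate_climate_gradient(
        cline_rho, n_cline_pops, seed=int(rng.integers(2 ** 31)))
    cline_pops = list(daf_by_pop)
    der_a, tot_a = mat_a.derived_counts()
    base_freq = np.clip(der_a / np.maximum(tot_a, 1), 0.02, 0.98)
    core_idx = truth["core_index"]

    blocks, hap_ids, s2p = [], [], {}
    for pop in cline_pops:
        freqs = np.clip(base_freq + rng.normal(0, 0.03, size=len(snps)), 0.0, 1.0)
        freqs[core_idx] = daf_by_pop[pop]
        block = (rng.random((cline_haplotypes_per_pop, len(snps))) < freqs).astype(np.int8)
        ids = [f"{pop}_h{i:04d}" for i in range(cline_haplotypes_per_pop)]
        blocks.append(block)
        hap_ids.extend(ids)
        s2p.update({h: pop for h in ids})

    alleles = np.vstack([mat_a.alleles, mat_b.alleles] + blocks)
    hap_ids = mat_a.haplotype_ids + mat_b.haplotype_ids + hap_ids
    s2p = {**mat_a.sample_to_population, **mat_b.sample_to_population, **s2p}
    combined = HaplotypeMatrix(snps=list(snps), haplotype_ids=hap_ids,
                               alleles=alleles, sample_to_population=s2p)
    scio.write_haplotype_tsv(combined, out / "haplotypes.tsv")

    # panel: scan groups A and B; each cline population is its own group
    panel = pd.DataFrame({
        "sample": hap_ids,
        "population": [s2p[h] for h in hap_ids],
        "group": ["A" if s2p[h] == "popA" else "B" if s2p[h] == "popB" else s2p[h]
                  for h in hap_ids],
    })
    panel.to_csv(out / "panel.tsv", sep="\t", index=False)

    # climate table: precipitation carries the gradient, everything else noise
    clim = pd.DataFrame(index=pd.Index(cline_pops, name="population"))
    for cov in ALL_COVARIATES:
        clim[cov] = rng.normal(0, 1, size=n_cline_pops)
    clim["precipitation"] = [cov_by_pop[p] for p in cline_pops]
    clim.reset_index().to_csv(out / "climate.csv", index=False)

    # case-control genotypes at the planted SNP (risk allele = coded allele)
    cases, controls = simulate_case_control(
        control_raf, cc_or, n_cases, n_controls, seed=int(rng.integers(2 ** 31)))
    geno = pd.DataFrame({
        "snp_id": core_id,
        "sample_id": [f"case{i:05d}" for i in range(n_cases)]
                     + [f"ctrl{i:05d}" for i in range(n_controls)],
        "status": ["case"] * n_cases + ["control"] * n_controls,
        "genotype": np.concatenate([cases, controls]),
    })
    geno.to_csv(out / "genotypes.tsv", sep="\t", index=False)

    truth.update({
        "planted": planted, "rho": cline_rho, "odds_ratio": cc_or,
        "control_raf": control_raf, "scan_groups": ["A", "B"],
        "n_cline_pops": n_cline_pops,
    })
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth
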