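"""Core domain containers shared by every stage of the pipeline.

Allele coding convention: ``0`` = ancestral, ``1`` = derived, ``MISSING`` (-1)
= unknown.  Orientation to ancestral/derived state happens exactly once, at
I/O time; everything downstream trusts the coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel for an unobserved allele in a haplotype matrix
MISSING: int = -1

#: canonical climate/geography covariate names, in reporting order
CLIMATE_COVARIATES = ("sunshine", "temperature", "uv", "precipitation")
GEO_COVARIATES = ("longitude", "latitude", "altitude")
ALL_COVARIATES = CLIMATE_COVARIATES + GEO_COVARIATES


@dataclass(frozen=True, slots=True)
class SnpRecord:
    """A biallelic SNP with a known ancestral/derived orientation.

    ``pos`` is 1-based (VCF convention).  The ancestral allele is taken as
    given (outgroup assignment is upstream of this package); alleles are
    compared as strings with no strand complementing.
    """

    snp_id: str
    chrom: str
    pos: int
    ancestral_allele: str
    derived_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: pos must be >= 1, got {self.pos}")
        if self.ancestral_allele == self.derived_allele:
            raise ValueError(
                f"{self.snp_id}: ancestral and derived alleles are both "
                f"{self.ancestral_allele!r}"
            )


def _sample_of(haplotype_id: str) -> str:
    """Sample id of a haplotype: the part before the final '|', if any."""
    sample, _, _ = haplotype_id.rpartition("|")
    return sample or haplotype_id


@dataclass
class HaplotypeMatrix:
    """Phased haplotypes over an ordered set of oriented SNPs.

    ``alleles`` is ``(n_haplotypes, n_snps)`` int8 with entries in
    {0, 1, MISSING}.  Haplotype ids of the form ``"<sample>|<k>"`` tie the two
    haplotypes of a diploid sample together; ``sample_to_population`` maps the
    sample part to a population label.
    """

    snps: list[SnpRecord]
    haplotype_ids: list[str]
    alleles: np.ndarray
    sample_to_population: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        n_h, n_s = self.alleles.shape if self.alleles.ndim == 2 else (-1, -1)
        if n_h != len(self.haplotype_ids) or n_s != len(self.snps):
            raise ValueError(
                f"allele matrix shape {self.alleles.shape} does not match "
                f"{len(self.haplotype_ids)} haplotypes x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise ValueError("allele matrix contains codes outside {0, 1, MISSING}")
        # positions strictly increasing within each chromosome
        last: dict[str, int] = {}
        for s in self.snps:
            if s.chrom in last and s.pos <= last[s.chrom]:
                raise ValueError(
                    f"SNP positions not strictly increasing on {s.chrom} "
                    f"at {s.snp_id} (pos {s.pos})"
                )
            last[s.chrom] = s.pos

    # -- basic geometry ----------------------------------------------------

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.snps], dtype=np.int64)

    def snp_index(self, snp_id: str) -> int:
        for i, s in enumerate(self.snps):
            if s.snp_id == snp_id:
                return i
        raise KeyError(f"SNP {snp_id!r} not in matrix")

    # -- population bookkeeping -------------------------------------------

    def haplotype_samples(self) -> list[str]:
        return [_sample_of(h) for h in self.haplotype_ids]

    def haplotype_populations(self) -> np.ndarray:
        """Population label per haplotype row (raises on unmapped samples)."""
        pops = []
        for hid, sample in zip(self.haplotype_ids, self.haplotype_samples()):
            pop = self.sample_to_population.get(sample)
            if pop is None:
                pop = self.sample_to_population.get(hid)
            if pop is None:
                raise KeyError(f"haplotype {hid!r}: sample {sample!r} has no population")
            pops.append(pop)
        return np.asarray(pops, dtype=object)

    def populations(self) -> list[str]:
        """Distinct population labels, in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.haplotype_populations():
            seen.setdefault(p, None)
        return list(seen)

    def subset_haplotypes(self, row_index: np.ndarray) -> "HaplotypeMatrix":
        ids = [self.haplotype_ids[i] for i in np.atleast_1d(row_index)]
        return HaplotypeMatrix(
            snps=list(self.snps),
            haplotype_ids=ids,
            alleles=self.alleles[np.atleast_1d(row_index)].copy(),
            sample_to_population=dict(self.sample_to_population),
        )

    def derived_counts(self, rows: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(derived count, non-missing count) per SNP over ``rows``."""
        block = self.alleles if rows is None else self.alleles[rows]
        ok = block != MISSING
        return (block == 1).sum(axis=0), ok.sum(axis=0)


@dataclass
class PopulationPanel:
    """sample -> population, population -> group (e.g. ASN / YRI / CEU)."""

    sample_to_population: dict[str, str]
    population_to_group: dict[str, str] = field(default_factory=dict)

    def group_of_sample(self, sample: str) -> str:
        pop = self.sample_to_population[sample]
        return self.population_to_group.get(pop, pop)

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.sample_to_population.values():
            seen.setdefault(self.population_to_group.get(pop, pop), None)
        return list(seen)


class ClimateTable:
    """Per-population climate and geography covariates.

    Thin wrapper over a :class:`pandas.DataFrame` indexed by population label
    with the seven canonical covariate columns (see ``ALL_COVARIATES``).
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            dups = sorted(frame.index[frame.index.duplicated()].unique())
            raise ValueError(f"duplicate population labels: {dups}")
        missing = [c for c in ALL_COVARIATES if c not in frame.columns]
        if missing:
            raise ValueError(f"climate table missing columns: {missing}")
        frame = frame[list(ALL_COVARIATES)].astype(float)
        if not np.isfinite(frame.to_numpy()).all():
            raise ValueError("climate covariates must be finite")
        self.frame = frame

    @property
    def populations(self) -> list[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)

    def covariate(self, name: str) -> pd.Series:
        if name not in ALL_COVARIATES:
            raise KeyError(f"unknown covariate {name!r}")
        return self.frame[name]
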