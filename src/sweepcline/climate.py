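"""Climate/geography association of derived allele frequencies ("driving
force" analysis).

For a candidate SNP, the per-population derived allele frequency (DAF) is
(1) correlated (Pearson) with each climate covariate — daily sunshine
duration, temperature, UV radiation, precipitation — with a two-sided t test
on n-2 degrees of freedom and Bonferroni adjustment across the four climate
hypotheses, and (2) regressed jointly on climate plus geography (longitude,
latitude, altitude) by ordinary least squares.  Geography enters as
adjustment, not as a hypothesis, so it is not counted in the Bonferroni
factor.

The response is the DAF itself (no logit/arcsine transform by default; both
are available via ``transform``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import ALL_COVARIATES, CLIMATE_COVARIATES, MISSING, ClimateTable, HaplotypeMatrix, SnpRecord

logger = logging.getLogger(__name__)

F_ZERO_VARIANCE = "zero_variance"
F_RANK_DEFICIENT = "rank_deficient"


def derived_allele_frequency(
    matrix: HaplotypeMatrix, snp: str | SnpRecord, population: str
) -> tuple[float, int]:
    """DAF and non-missing allele count for one SNP in one population."""
    j = matrix.snp_index(snp if isinstance(snp, str) else snp.snp_id)
    pops = matrix.haplotype_populations()
    rows = np.flatnonzero(pops == population)
    if rows.size == 0:
        raise ValueError(f"population {population!r} has no haplotypes")
    col = matrix.alleles[rows, j]
    ok = col != MISSING
    n = int(ok.sum())
    if n == 0:
        raise ValueError(
            f"all alleles missing at {matrix.snps[j].snp_id} in population {population!r}")
    return float((col[ok] == 1).sum() / n), n


def daf_table(matrix: HaplotypeMatrix, snp_ids: list[str] | None = None) -> pd.DataFrame:
    """DAF per population (rows) per SNP (columns) for a whole matrix."""
    pops = matrix.populations()
    ids = snp_ids or [s.snp_id for s in matrix.snps]
    data = {sid: [derived_allele_frequency(matrix, sid, p)[0] for p in pops]
            for sid in ids}
    return pd.DataFrame(data, index=pops)


@dataclass
class CorrelationResult:
    covariate: str
    n: int
    r: float = float("nan")
    p: float = float("nan")
    p_adjusted: float = float("nan")
    snp: SnpRecord | None = None
    flags: set[str] = field(default_factory=set)


@dataclass
class RegressionResult:
    covariate_names: list[str]  # "intercept" first
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    r_squared: float
    n: int
    condition_number: float = float("nan")
    snp: SnpRecord | None = None
    flags: set[str] = field(default_factory=set)

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.covariate_names.index(name)])


def _apply_transform(daf: np.ndarray, transform: str | None) -> np.ndarray:
    if transform is None:
        return daf
    if transform == "logit":
        clipped = np.clip(daf, 1e-6, 1 - 1e-6)
        return np.log(clipped / (1 - clipped))
    if transform == "arcsine":
        return np.arcsin(np.sqrt(np.clip(daf, 0.0, 1.0)))
    raise ValueError(f"unknown transform {transform!r}")


def _aligned(daf_by_pop: Mapping[str, float], climate: ClimateTable) -> tuple[list[str], np.ndarray]:
    common = [p for p in climate.populations if p in daf_by_pop]
    dropped = (len(daf_by_pop) - len(common)) + (len(climate) - len(common))
    if dropped:
        logger.info("climate association: %d population(s) dropped from the "
                    "DAF/climate intersection", dropped)
    return common, np.array([daf_by_pop[p] for p in common], dtype=float)


def correlate_climate(
    daf_by_pop: Mapping[str, float],
    climate: ClimateTable,
    covariate: str,
    n_tests: int = len(CLIMATE_COVARIATES),
    transform: str | None = None,
    snp: SnpRecord | None = None,
) -> CorrelationResult:
    """Pearson correlation of per-population DAF with one climate covariate.

    Two-sided p from t = r sqrt((n-2)/(1-r^2)) on n-2 df; ``p_adjusted`` is
    Bonferroni over ``n_tests`` covariates.  Populations absent from either
    input are dropped.
    """
    common, y = _aligned(daf_by_pop, climate)
    if len(common) < 3:
        raise ValueError(f"need >= 3 populations shared with climate table, have {len(common)}")
    x = climate.covariate(covariate).loc[common].to_numpy(float)
    y = _apply_transform(y, transform)
    res = CorrelationResult(covariate=covariate, n=len(common), snp=snp)
    if np.std(x) == 0 or np.std(y) == 0:
        res.flags.add(F_ZERO_VARIANCE)
        return res
    r, p = stats.pearsonr(x, y)
    res.r, res.p = float(r), float(p)
    res.p_adjusted = min(1.0, res.p * n_tests)
    return res


def fit_multiple_regression(
    daf_by_pop: Mapping[str, float],
    climate: ClimateTable,
    covariates: tuple[str, ...] = ALL_COVARIATES,
    transform: str | None = None,
    snp: SnpRecord | None = None,
) -> RegressionResult:
    """OLS of per-population DAF on climate and geography covariates."""
    common, y = _aligned(daf_by_pop, climate)
    if len(common) <= len(covariates) + 1:
        raise ValueError(
            f"need more populations ({len(common)}) than covariates + 1 ({len(covariates) + 1})")
    y = _apply_transform(y, transform)
    x = climate.frame.loc[common, list(covariates)]
    design = sm.add_constant(x.to_numpy(float), has_constant="add")
    fit = sm.OLS(y, design).fit()
    names = ["intercept"] + list(covariates)
    res = RegressionResult(
        covariate_names=names,
        coefficients=np.asarray(fit.params, dtype=float),
        standard_errors=np.asarray(fit.bse, dtype=float),
        t_values=np.asarray(fit.tvalues, dtype=float),
        p_values=np.asarray(fit.pvalues, dtype=float),
        r_squared=float(fit.rsquared),
        n=len(common),
        condition_number=float(np.linalg.cond(design)),
        snp=snp,
    )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        res.flags.add(F_RANK_DEFICIENT)
    return res


class ClineAssociation:
    """Climate-cline model for one SNP's per-population DAF.

    ``daf_by_pop`` maps population label to derived allele frequency (use
    :func:`derived_allele_frequency` or :func:`daf_table` to build it from a
    haplotype matrix).  ``fit`` runs the per-covariate Pearson screen and the
    joint OLS adjustment model.
    """

    def __init__(
        self,
        daf_by_pop: Mapping[str, float],
        climate: ClimateTable,
        *,
        climate_covariates: tuple[str, ...] = CLIMATE_COVARIATES,
        regression_covariates: tuple[str, ...] = ALL_COVARIATES,
        transform: str | None = None,
        snp: SnpRecord | None = None,
    ):
        self.daf_by_pop = dict(daf_by_pop)
        self.climate = climate
        self.climate_covariates = tuple(climate_covariates)
        self.regression_covariates = tuple(regression_covariates)
        self.transform = transform
        self.snp = snp

    @classmethod
    def from_matrix(cls, matrix: HaplotypeMatrix, snp: str | SnpRecord,
                    climate: ClimateTable, **kwargs) -> "ClineAssociation":
        sid = snp if isinstance(snp, str) else snp.snp_id
        daf = {}
        for pop in matrix.populations():
            daf[pop], _ = derived_allele_frequency(matrix, sid, pop)
        rec = matrix.snps[matrix.snp_index(sid)]
        return cls(daf, climate, snp=rec, **kwargs)

    def fit(self, joint_regression: bool = True) -> "ClineAssociationResults":
        correlations = [
            correlate_climate(self.daf_by_pop, self.climate, cov,
                              n_tests=len(self.climate_covariates),
                              transform=self.transform, snp=self.snp)
            for cov in self.climate_covariates
        ]
        regression = None
        if joint_regression:
            regression = fit_multiple_regression(
                self.daf_by_pop, self.climate, covariates=self.regression_covariates,
                transform=self.transform, snp=self.snp)
        return ClineAssociationResults(self, correlations, regression)

    def fit_per_covariate(self) -> dict[str, RegressionResult]:
        """One single-covariate OLS per climate variable (alternative to the
        joint model when populations are few)."""
        return {cov: fit_multiple_regression(self.daf_by_pop, self.climate,
                                             covariates=(cov,), transform=self.transform,
                                             snp=self.snp)
                for cov in self.climate_covariates}


class ClineAssociationResults:
    def __init__(self, model: ClineAssociation,
                 correlations: list[CorrelationResult],
                 regression: RegressionResult | None):
        self.model = model
        self.correlations = correlations
        self.regression = regression

    @property
    def frame(self) -> pd.DataFrame:
        sid = self.model.snp.snp_id if self.model.snp else ""
        rows = [{
            "snp_id": sid, "covariate": c.covariate, "n": c.n,
            "r": c.r, "p": c.p, "p_adjusted": c.p_adjusted,
            "flags": ",".join(sorted(c.flags)),
        } for c in self.correlations]
        return pd.DataFrame(rows, columns=["snp_id", "covariate", "n", "r", "p",
                                           "p_adjusted", "flags"])

    def best_covariate(self) -> CorrelationResult:
        scored = [c for c in self.correlations if np.isfinite(c.p)]
        if not scored:
            raise ValueError("no covariate could be tested")
        return min(scored, key=lambda c: c.p)

    def significant(self, alpha: float = 0.05, adjusted: bool = True) -> list[CorrelationResult]:
        key = (lambda c: c.p_adjusted) if adjusted else (lambda c: c.p)
        return [c for c in self.correlations if np.isfinite(key(c)) and key(c) < alpha]

    def summary(self) -> str:
        sid = self.model.snp.snp_id if self.model.snp else "(unnamed SNP)"
        lines = [f"Climate-cline association for {sid}", "=" * 40,
                 f"{'covariate':<14}{'n':>4}{'r':>9}{'P':>10}{'P(Bonf.)':>10}"]
        for c in self.correlations:
            lines.append(f"{c.covariate:<14}{c.n:>4}{c.r:>9.3f}{c.p:>10.4g}{c.p_adjusted:>10.4g}")
        if self.regression is not None:
            rg = self.regression
            lines.append("")
            lines.append(f"Joint OLS (n={rg.n}, R^2={rg.r_squared:.3f})")
            lines.append(f"{'term':<14}{'coef':>10}{'SE':>10}{'t':>8}{'P':>10}")
            for i, name in enumerate(rg.covariate_names):
                lines.append(f"{name:<14}{rg.coefficients[i]:>10.4g}"
                             f"{rg.standard_errors[i]:>10.4g}{rg.t_values[i]:>8.2f}"
                             f"{rg.p_values[i]:>10.4g}")
        return "\n".join(lines)

    def plot(self, covariate: str = "precipitation", path: str | None = None):
        """Scatter of per-population DAF against one covariate with the
        least-squares line; returns the matplotlib Axes."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        common, y = _aligned(self.model.daf_by_pop, self.model.climate)
        x = self.model.climate.covariate(covariate).loc[common].to_numpy(float)
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(x, y, s=18, alpha=0.8)
        if np.std(x) > 0:
            b, a = np.polyfit(x, y, 1)
            grid = np.linspace(x.min(), x.max(), 50)
            ax.plot(grid, a + b * grid, color="firebrick")
        ax.set_xlabel(covariate)
        ax.set_ylabel("derived allele frequency")
        sid = self.model.snp.snp_id if self.model.snp else ""
        ax.set_title(f"{sid} DAF vs {covariate}".strip())
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return ax
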