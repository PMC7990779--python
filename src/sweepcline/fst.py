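"""Per-SNP pairwise F_ST estimators and the multi-SNP ratio-of-averages.

Three estimators of Wright's fixation index are provided:

* ``hudson`` — sample-size-corrected numerator/denominator form,
  [(p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)] / [p1(1-p2) + p2(1-p1)].
  Unbiased in the sense that the ratio of averaged numerators to averaged
  denominators converges to the Balding–Nichols differentiation parameter F.
* ``nei_gst`` — 1 - H_S/H_T with population-level heterozygosities; for two
  populations its expectation is F/(2-F), i.e. it compresses high F.
* ``weir_cockerham`` — the ANOVA (variance-components) estimator applied to
  allele counts.

Single-SNP Hudson and Weir–Cockerham estimates can be negative; they are
reported as-is (clipping would bias multi-SNP averages).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .core import HaplotypeMatrix, PopulationPanel, SnpRecord

ESTIMATORS = ("hudson", "nei_gst", "weir_cockerham")

F_MONOMORPHIC = "monomorphic"


@dataclass
class FstResult:
    pop_pair: tuple[str, str]
    estimator: str
    p1: float
    p2: float
    n1: int
    n2: int
    fst: float = float("nan")
    numerator: float = float("nan")
    denominator: float = float("nan")
    snp: SnpRecord | None = None
    flags: set[str] = field(default_factory=set)


def _hudson(p1, n1, p2, n2):
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def _nei_gst(p1, n1, p2, n2):
    pbar = 0.5 * (p1 + p2)
    h_t = 2 * pbar * (1 - pbar)
    h_s = p1 * (1 - p1) + p2 * (1 - p2)  # mean of 2 p_i (1 - p_i)
    return h_t - h_s, h_t


def _weir_cockerham(p1, n1, p2, n2):
    # two-population ANOVA estimator on allele counts
    n_tot = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / n_tot
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # r - 1 = 1
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n_tot - 2)
    nc = n_tot - (n1 ** 2 + n2 ** 2) / n_tot
    return msp - msg, msp + (nc - 1) * msg


_FORMS = {"hudson": _hudson, "nei_gst": _nei_gst, "weir_cockerham": _weir_cockerham}


def compute_fst(
    p1: float, n1: int, p2: float, n2: int,
    estimator: str = "hudson",
    pop_pair: tuple[str, str] = ("pop1", "pop2"),
    snp: SnpRecord | None = None,
) -> FstResult:
    """Single-SNP F_ST from allele frequencies and allele sample sizes.

    ``n1``/``n2`` count allele copies (2x diploid individuals).  A site
    monomorphic for the same allele in both populations has no information
    about differentiation and comes back flagged with no estimate.
    """
    if estimator not in _FORMS:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("allele frequencies must lie in [0, 1]")
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 allele copies per population")
    num, den = _FORMS[estimator](float(p1), int(n1), float(p2), int(n2))
    res = FstResult(pop_pair=pop_pair, estimator=estimator,
                    p1=float(p1), p2=float(p2), n1=int(n1), n2=int(n2),
                    numerator=float(num), denominator=float(den), snp=snp)
    if den == 0:
        res.flags.add(F_MONOMORPHIC)
    else:
        res.fst = float(num / den)
    return res


def fst_ratio_of_averages(per_snp: list[FstResult]) -> float:
    """Multi-SNP F_ST as sum(numerators) / sum(denominators).

    Averaging numerator and denominator separately before dividing (rather
    than averaging per-SNP ratios) is the standard way to combine noisy
    single-SNP estimates; monomorphic-flagged SNPs contribute zero to both.
    """
    if not per_snp:
        raise ValueError("no F_ST results to combine")
    estimators = {r.estimator for r in per_snp}
    if len(estimators) > 1:
        raise ValueError(f"mixed estimators: {sorted(estimators)}")
    num = sum(r.numerator for r in per_snp if np.isfinite(r.numerator))
    den = sum(r.denominator for r in per_snp if np.isfinite(r.denominator))
    if den == 0:
        raise ValueError("total denominator is zero (all sites monomorphic?)")
    return float(num / den)


class FstScan:
    """Per-SNP pairwise F_ST across population groups of a haplotype matrix."""

    def __init__(
        self,
        matrix: HaplotypeMatrix,
        panel: PopulationPanel | None = None,
        *,
        estimator: str = "hudson",
        pairs: list[tuple[str, str]] | None = None,
    ):
        if estimator not in _FORMS:
            raise ValueError(f"unknown estimator {estimator!r}")
        self.matrix = matrix
        self.panel = panel
        self.estimator = estimator
        self.pairs = pairs

    def _group_rows(self) -> dict[str, np.ndarray]:
        m = self.matrix
        if self.panel is not None:
            labels = np.asarray([self.panel.group_of_sample(s)
                                 for s in m.haplotype_samples()], dtype=object)
        else:
            labels = m.haplotype_populations()
        seen: dict[str, None] = {}
        for lab in labels:
            seen.setdefault(lab, None)
        return {lab: np.flatnonzero(labels == lab) for lab in seen}

    def fit(self, snp_ids: list[str] | None = None) -> "FstScanResults":
        groups = self._group_rows()
        pairs = self.pairs or list(combinations(groups, 2))
        m = self.matrix
        snp_idx = (range(m.n_snps) if snp_ids is None
                   else [m.snp_index(s) for s in snp_ids])
        freqs = {}
        for g, rows in groups.items():
            der, tot = m.derived_counts(rows)
            freqs[g] = (der, tot)
        results: list[FstResult] = []
        for g1, g2 in pairs:
            d1, t1 = freqs[g1]
            d2, t2 = freqs[g2]
            for j in snp_idx:
                if t1[j] < 2 or t2[j] < 2:
                    continue
                results.append(compute_fst(
                    d1[j] / t1[j], t1[j], d2[j] / t2[j], t2[j],
                    estimator=self.estimator, pop_pair=(g1, g2), snp=m.snps[j]))
        return FstScanResults(self, results)


class FstScanResults:
    def __init__(self, model: FstScan, results: list[FstResult]):
        self.model = model
        self.results = results

    @property
    def frame(self) -> pd.DataFrame:
        rows = [{
            "snp_id": r.snp.snp_id if r.snp else "",
            "pop1": r.pop_pair[0], "pop2": r.pop_pair[1],
            "estimator": r.estimator, "p1": r.p1, "p2": r.p2,
            "n1": r.n1, "n2": r.n2, "fst": r.fst,
            "flags": ",".join(sorted(r.flags)),
        } for r in self.results]
        return pd.DataFrame(rows, columns=["snp_id", "pop1", "pop2", "estimator",
                                           "p1", "p2", "n1", "n2", "fst", "flags"])

    def ratio_of_averages(self, pair: tuple[str, str] | None = None) -> float:
        sel = self.results if pair is None else [
            r for r in self.results if set(r.pop_pair) == set(pair)]
        return fst_ratio_of_averages(sel)

    def summary(self) -> str:
        df = self.frame
        lines = ["Pairwise F_ST scan", "=" * 18,
                 f"estimator: {self.model.estimator}"]
        for (g1, g2), grp in df.groupby(["pop1", "pop2"], sort=False):
            roa = self.ratio_of_averages((g1, g2))
            lines.append(f"{g1} vs {g2}: {len(grp)} SNPs, "
                         f"ratio-of-averages F_ST = {roa:.4f}, "
                         f"max single-SNP = {grp['fst'].max():.4f}")
        return "\n".join(lines)
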