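"""Case-control allelic association: 2x2 allele table, odds ratio with Wald
confidence interval, Pearson chi-square test.

The allelic (per-allele) model treats each of the 2N allele copies as an
independent Bernoulli draw, the usual first-line replication statistic when
no genetic model is specified.  Risk-allele orientation is fixed by
configuration, never inferred from the data, so an over-fitted "protective"
flip cannot sneak in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, SnpRecord

Z_95 = 1.959964  # two-sided 95% normal quantile

F_HALDANE = "haldane_corrected"
F_DEGENERATE = "degenerate_margin"


def genotypes_to_allele_table(
    case_genotypes: Sequence[int],
    control_genotypes: Sequence[int],
    risk_allele: str = "coded",
) -> tuple[int, int, int, int]:
    """Collapse genotype counts into the 2x2 allele table (a, b, c, d).

    Genotypes are risk-allele counts in {0, 1, 2}; MISSING entries are
    excluded from both numerator and denominator.  ``risk_allele="other"``
    flips the coding (g -> 2 - g) when the table should count the allele the
    genotypes were *not* coded on.
    """
    if risk_allele not in ("coded", "other"):
        raise ValueError(f"risk_allele must be 'coded' or 'other', got {risk_allele!r}")

    def _count(genotypes: Sequence[int], label: str) -> tuple[int, int]:
        g = np.asarray(list(genotypes))
        g = g[g != MISSING]
        if g.size == 0:
            raise ValueError(f"no non-missing genotypes in the {label} group")
        if not np.isin(g, (0, 1, 2)).all():
            raise ValueError(f"{label} genotypes must be counts in {{0,1,2}} or MISSING")
        if risk_allele == "other":
            g = 2 - g
        risk = int(g.sum())
        return risk, 2 * g.size - risk

    a, b = _count(case_genotypes, "case")
    c, d = _count(control_genotypes, "control")
    return a, b, c, d


@dataclass
class AssociationResult:
    """2x2 allelic association result.

    ``a``..``d`` are the observed counts (risk/non-risk x case/control);
    the odds ratio and its Wald CI come from the Haldane–Anscombe corrected
    cells whenever any observed cell is zero (flagged).
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    chi2: float = float("nan")
    p: float = float("nan")
    snp: SnpRecord | None = None
    flags: set[str] = field(default_factory=set)

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "snp_id": self.snp.snp_id if self.snp else "",
            "a": self.a, "b": self.b, "c": self.c, "d": self.d,
            "odds_ratio": self.odds_ratio, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "chi2": self.chi2, "p": self.p,
            "flags": ",".join(sorted(self.flags)),
        }])

    def summary(self) -> str:
        sid = self.snp.snp_id if self.snp else "(unnamed SNP)"
        lines = [
            f"Allelic association for {sid}",
            "=" * 40,
            f"            risk  non-risk",
            f"  cases     {self.a:>5} {self.b:>8}",
            f"  controls  {self.c:>5} {self.d:>8}",
            f"OR = {self.odds_ratio:.3f}  (95% CI {self.ci_low:.3f}-{self.ci_high:.3f})",
            f"chi-square = {self.chi2:.3f} (1 df), P = {self.p:.4g}",
        ]
        if self.flags:
            lines.append(f"flags: {', '.join(sorted(self.flags))}")
        return "\n".join(lines)


def allelic_association(
    a: int, b: int, c: int, d: int,
    continuity: bool = False,
    snp: SnpRecord | None = None,
) -> AssociationResult:
    """OR, 95% Wald CI and chi-square P for a 2x2 allele-count table.

    OR = ad/bc with CI exp(ln OR +/- 1.959964 * sqrt(1/a+1/b+1/c+1/d)); cells
    get the Haldane–Anscombe +0.5 iff any cell is zero (result flagged).  The
    chi-square is Pearson's on the observed table, without continuity
    correction unless ``continuity=True`` (Yates).  A zero row or column
    margin leaves the result flagged with no test.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("cell counts must be non-negative")
    if cells.sum() == 0:
        raise ValueError("empty 2x2 table")
    res = AssociationResult(a=int(a), b=int(b), c=int(c), d=int(d), snp=snp)
    table = cells.reshape(2, 2)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        res.flags.add(F_DEGENERATE)
        return res
    work = cells.copy()
    if (work == 0).any():
        work = work + 0.5
        res.flags.add(F_HALDANE)
    aw, bw, cw, dw = work
    log_or = np.log(aw * dw / (bw * cw))
    se = np.sqrt(1 / aw + 1 / bw + 1 / cw + 1 / dw)
    res.odds_ratio = float(np.exp(log_or))
    res.ci_low = float(np.exp(log_or - Z_95 * se))
    res.ci_high = float(np.exp(log_or + Z_95 * se))
    chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity)
    res.chi2, res.p = float(chi2), float(p)
    return res


class AllelicAssociation:
    """Case-control allelic association model for one SNP.

    Construct from a 2x2 table or from per-individual genotype vectors;
    ``fit`` returns the :class:`AssociationResult`.
    """

    def __init__(self, a: int, b: int, c: int, d: int,
                 *, continuity: bool = False, snp: SnpRecord | None = None):
        self.a, self.b, self.c, self.d = a, b, c, d
        self.continuity = continuity
        self.snp = snp

    @classmethod
    def from_genotypes(cls, case_genotypes: Sequence[int],
                       control_genotypes: Sequence[int],
                       risk_allele: str = "coded",
                       **kwargs) -> "AllelicAssociation":
        a, b, c, d = genotypes_to_allele_table(case_genotypes, control_genotypes,
                                               risk_allele=risk_allele)
        return cls(a, b, c, d, **kwargs)

    @classmethod
    def from_frame(cls, genotypes: pd.DataFrame, snp_id: str | None = None,
                   **kwargs) -> "AllelicAssociation":
        """Build from a genotype table as read by ``read_genotype_tsv``."""
        df = genotypes
        if snp_id is not None:
            df = df[df["snp_id"] == snp_id]
            if df.empty:
                raise KeyError(f"SNP {snp_id!r} not in genotype table")
        cases = df.loc[df["status"] == "case", "genotype"].tolist()
        controls = df.loc[df["status"] == "control", "genotype"].tolist()
        return cls.from_genotypes(cases, controls, **kwargs)

    def fit(self) -> AssociationResult:
        return allelic_association(self.a, self.b, self.c, self.d,
                                   continuity=self.continuity, snp=self.snp)
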