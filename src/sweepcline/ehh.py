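"""Extended haplotype homozygosity (EHH), integrated haplotype homozygosity
(iHH) and the integrated haplotype score (iHS).

EHH at a flanking marker t is the probability that two randomly drawn
haplotypes carrying the core allele are identical at every site from the core
through t:

    EHH(t) = sum_h C(c_h, 2) / C(n, 2)

where c_h counts carriers sharing extended haplotype h and n is the number of
carriers still evaluable at t.  iHH is the trapezoidal area under the EHH
decay curve on each side of the core, summed; the unstandardized score is
ln(iHH_A / iHH_D) (ancestral over derived), and iHS standardizes that
ln-ratio to zero mean / unit variance within derived-allele-frequency bins so
scores are comparable across frequencies.  Large |iHS| — conventionally
|iHS| > 2 — marks unusually long haplotypes around one allele class, the
footprint of recent positive selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING, HaplotypeMatrix, PopulationPanel, SnpRecord
from .io import GeneticMap

DEFAULT_EHH_CUTOFF = 0.05
DEFAULT_IHS_THRESHOLD = 2.0
DEFAULT_MIN_DAF = 0.05

# flags attached to per-SNP results
F_EDGE = "edge_truncated"
F_INSUFFICIENT = "insufficient_carriers"
F_ZERO_IHH = "zero_ihh"
F_SMALL_BIN = "small_bin"
F_NO_BIN = "no_bin"


@dataclass
class EhhCurve:
    """One side of an EHH decay curve for one allele class at a core SNP.

    ``marker_positions[0]`` is the core position with ``ehh_values[0] == 1``;
    subsequent entries move outward.  ``truncated_missing`` records that the
    walk stopped early because fewer than two carriers remained evaluable.
    """

    core_snp: SnpRecord
    allele_class: str  # "ancestral" | "derived"
    side: str  # "left" | "right"
    marker_positions: np.ndarray
    ehh_values: np.ndarray
    n_carriers: int
    truncated_missing: bool = False
    flags: set[str] = field(default_factory=set)

    @property
    def distances(self) -> np.ndarray:
        return np.abs(self.marker_positions - self.core_snp.pos)


def compute_ehh(
    matrix: HaplotypeMatrix,
    core: SnpRecord | str | int,
    allele_class: str,
    side: str,
    rows: np.ndarray | None = None,
) -> EhhCurve:
    """EHH decay curve for carriers of one allele at the core SNP.

    A carrier haplotype that is MISSING at some marker is dropped from both
    numerator and denominator at that marker and at all markers further out
    on the same side.  With fewer than two carriers the result is flagged and
    carries no curve.

    ``rows`` restricts the computation to a subset of haplotypes (e.g. one
    population).
    """
    if allele_class not in ("ancestral", "derived"):
        raise ValueError(f"allele_class must be 'ancestral' or 'derived', got {allele_class!r}")
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")

    if isinstance(core, SnpRecord):
        j = matrix.snp_index(core.snp_id)
    elif isinstance(core, str):
        j = matrix.snp_index(core)
    else:
        j = int(core)
    core_snp = matrix.snps[j]

    block = matrix.alleles if rows is None else matrix.alleles[rows]
    target = 1 if allele_class == "derived" else 0
    carriers = np.flatnonzero(block[:, j] == target)
    n0 = carriers.size
    if n0 < 2:
        return EhhCurve(core_snp, allele_class, side,
                        np.array([core_snp.pos]), np.array([], dtype=float),
                        n_carriers=n0, flags={F_INSUFFICIENT})

    marker_idx = range(j - 1, -1, -1) if side == "left" else range(j + 1, matrix.n_snps)

    sub = block[carriers]
    group = np.zeros(n0, dtype=np.int64)  # identical by construction at the core
    alive = np.ones(n0, dtype=bool)
    positions = [core_snp.pos]
    ehh = [1.0]
    truncated_missing = False

    for m in marker_idx:
        col = sub[:, m]
        alive &= col != MISSING
        n = int(alive.sum())
        if n < 2:
            truncated_missing = True
            break
        key = group[alive] * 2 + col[alive]
        _, inv = np.unique(key, return_inverse=True)
        group[alive] = inv
        counts = np.bincount(inv)
        ehh_t = float((counts * (counts - 1)).sum() / (n * (n - 1)))
        positions.append(matrix.snps[m].pos)
        ehh.append(ehh_t)
        if ehh_t == 0.0:
            break  # identity cannot recover further out

    return EhhCurve(core_snp, allele_class, side,
                    np.asarray(positions, dtype=np.int64), np.asarray(ehh, dtype=float),
                    n_carriers=n0, truncated_missing=truncated_missing)


def _side_area(curve: EhhCurve, cutoff: float, genetic_map: GeneticMap | None) -> tuple[float, set[str]]:
    """Trapezoidal area of one EHH side, stopping at the cutoff crossing."""
    e = curve.ehh_values
    if e.size == 0:
        return 0.0, set(curve.flags)
    if genetic_map is not None:
        d = np.abs(genetic_map(curve.marker_positions) - genetic_map(np.array([curve.core_snp.pos]))[0])
    else:
        d = curve.distances.astype(float)
    area = 0.0
    for i in range(1, e.size):
        if e[i] < cutoff:
            # linear interpolation to the point where EHH crosses the cutoff
            t = d[i - 1] + (d[i] - d[i - 1]) * (e[i - 1] - cutoff) / (e[i - 1] - e[i])
            area += 0.5 * (e[i - 1] + cutoff) * (t - d[i - 1])
            return area, set()
        area += 0.5 * (e[i - 1] + e[i]) * (d[i] - d[i - 1])
        if e[i] == cutoff:
            return area, set()  # decayed exactly to the cutoff: complete
    # curve ended (region edge or missing-data truncation) above the cutoff
    return area, {F_EDGE}


def integrate_ihh(
    left: EhhCurve,
    right: EhhCurve,
    cutoff: float = DEFAULT_EHH_CUTOFF,
    genetic_map: GeneticMap | None = None,
) -> tuple[float, set[str]]:
    """Integrated EHH (area under both sides of the decay curve).

    Integration runs outward and stops at the first marker where EHH drops
    below ``cutoff``; the sliver up to the linearly interpolated crossing is
    included.  If a side never reaches the cutoff before the curve ends, its
    area is truncated there and the result is flagged ``edge_truncated``.
    Distances are physical bp unless a genetic map is supplied (then cM).
    """
    if left.core_snp.snp_id != right.core_snp.snp_id or left.allele_class != right.allele_class:
        raise ValueError("left/right curves must share core SNP and allele class")
    if left.ehh_values.size == 0 and right.ehh_values.size == 0:
        raise ValueError("cannot integrate an empty EHH curve")
    a_l, f_l = _side_area(left, cutoff, genetic_map)
    a_r, f_r = _side_area(right, cutoff, genetic_map)
    return a_l + a_r, f_l | f_r


def unstandardized_ihs(ihh_a: float, ihh_d: float) -> float:
    """ln(iHH_ancestral / iHH_derived); NaN when either area is zero."""
    if ihh_a <= 0.0 or ihh_d <= 0.0:
        return float("nan")
    return float(np.log(ihh_a / ihh_d))


@dataclass
class IhsResult:
    """Per-SNP, per-population iHS bookkeeping."""

    snp: SnpRecord
    population: str
    daf: float
    ihh_a: float = float("nan")
    ihh_d: float = float("nan")
    ln_ratio: float = float("nan")
    ihs: float = float("nan")
    bin_index: int = -1
    flags: set[str] = field(default_factory=set)


class BinTable:
    """Derived-allele-frequency bin means/SDs of the unstandardized ln-ratio.

    Built from a background set of scores (ideally genome-wide, since a small
    candidate region cannot self-calibrate) and applied to standardize new
    scans.  Bins are stored as half-open intervals on daf covering (0, 1].
    """

    def __init__(self, edges: np.ndarray, means: np.ndarray, sds: np.ndarray,
                 counts: np.ndarray | None = None):
        edges = np.asarray(edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing, length >= 2")
        if not (len(means) == len(sds) == edges.size - 1):
            raise ValueError("means/sds must have one entry per bin")
        self.edges = edges
        self.means = np.asarray(means, dtype=float)
        self.sds = np.asarray(sds, dtype=float)
        self.counts = (np.asarray(counts, dtype=int) if counts is not None
                       else np.zeros(edges.size - 1, dtype=int))

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    def bin_of(self, daf: float) -> int:
        """Index of the bin containing ``daf``; -1 when outside the table."""
        if not (self.edges[0] <= daf <= self.edges[-1]):
            return -1
        i = int(np.searchsorted(self.edges, daf, side="right")) - 1
        return min(max(i, 0), self.n_bins - 1)

    @classmethod
    def from_scores(cls, dafs: np.ndarray, ln_ratios: np.ndarray,
                    n_bins: int = 20, min_bin_size: int = 5) -> "BinTable":
        """Equal-count (quantile) bins over daf; bins below ``min_bin_size``
        get NaN statistics so their members stay unscored."""
        dafs = np.asarray(dafs, dtype=float)
        ln_ratios = np.asarray(ln_ratios, dtype=float)
        if dafs.size == 0:
            raise ValueError("no scores to bin")
        q = np.quantile(dafs, np.linspace(0.0, 1.0, n_bins + 1))
        q[0], q[-1] = 0.0, 1.0
        edges = np.unique(q)
        if edges.size < 2:
            edges = np.array([0.0, 1.0])
        idx = np.clip(np.searchsorted(edges, dafs, side="right") - 1, 0, edges.size - 2)
        means = np.full(edges.size - 1, np.nan)
        sds = np.full(edges.size - 1, np.nan)
        counts = np.zeros(edges.size - 1, dtype=int)
        for b in range(edges.size - 1):
            sel = idx == b
            counts[b] = int(sel.sum())
            if counts[b] >= max(min_bin_size, 2):
                means[b] = float(ln_ratios[sel].mean())
                sds[b] = float(ln_ratios[sel].std(ddof=1))
        return cls(edges, means, sds, counts)

    @classmethod
    def from_results(cls, results: list["IhsResult"], n_bins: int = 20,
                     min_bin_size: int = 5,
                     exclude_flags: tuple[str, ...] = (F_EDGE,)) -> "BinTable":
        """Calibration table from a background scan's unstandardized results."""
        keep = [r for r in results
                if np.isfinite(r.ln_ratio) and not (r.flags & set(exclude_flags))]
        if not keep:
            raise ValueError("no eligible background results")
        return cls.from_scores(np.array([r.daf for r in keep]),
                               np.array([r.ln_ratio for r in keep]),
                               n_bins=n_bins, min_bin_size=min_bin_size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "daf_low": self.edges[:-1], "daf_high": self.edges[1:],
            "mean": self.means, "sd": self.sds, "count": self.counts,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BinTable":
        edges = np.append(df["daf_low"].to_numpy(float), df["daf_high"].to_numpy(float)[-1])
        return cls(edges, df["mean"].to_numpy(float), df["sd"].to_numpy(float),
                   df.get("count", pd.Series(np.zeros(len(df)))).to_numpy(int))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BinTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def standardize_ihs(
    results: list[IhsResult],
    n_bins: int = 20,
    min_bin_size: int = 5,
    external_bin_table: BinTable | None = None,
    exclude_flags: tuple[str, ...] = (F_EDGE,),
) -> list[IhsResult]:
    """Standardize ln-ratios to iHS within daf bins.

    Entries whose flags intersect ``exclude_flags`` (edge-truncated curves by
    default) or whose ln-ratio is not finite are passed through unscored.
    With an external bin table its means/SDs are used; otherwise quantile
    bins are fit to the eligible entries themselves.
    """
    out = [replace(r, flags=set(r.flags)) for r in results]
    eligible = [r for r in out
                if np.isfinite(r.ln_ratio) and np.isfinite(r.daf)
                and not (r.flags & set(exclude_flags))]
    if not eligible:
        return out
    table = external_bin_table
    if table is None:
        table = BinTable.from_scores(
            np.array([r.daf for r in eligible]),
            np.array([r.ln_ratio for r in eligible]),
            n_bins=n_bins, min_bin_size=min_bin_size,
        )
    for r in eligible:
        b = table.bin_of(r.daf)
        r.bin_index = b
        if b < 0:
            r.flags.add(F_NO_BIN)
            continue
        mu, sd = table.means[b], table.sds[b]
        if not (np.isfinite(mu) and np.isfinite(sd)) or sd <= 0:
            r.flags.add(F_SMALL_BIN)
            continue
        r.ihs = (r.ln_ratio - mu) / sd
    return out


def screen_candidates(
    results: list[IhsResult], threshold: float = DEFAULT_IHS_THRESHOLD
) -> list[tuple[SnpRecord, str, float]]:
    """SNPs with |iHS| strictly greater than ``threshold``, per population."""
    return [(r.snp, r.population, r.ihs) for r in results
            if np.isfinite(r.ihs) and abs(r.ihs) > threshold]


# ---------------------------------------------------------------------------
# model / results layer
# ---------------------------------------------------------------------------

class IhsScan:
    """iHS selection scan over one haplotype matrix.

    Parameters
    ----------
    matrix
        Phased, ancestral/derived-oriented haplotypes.
    panel
        Optional population panel; when given, haplotypes are scanned per
        *group* (e.g. ASN / YRI / CEU).  Without a panel the matrix's own
        population labels are used, or a single pooled population when the
        matrix carries none.
    min_daf
        Core SNPs with derived allele frequency below this (or above
        1 - min_daf) are not scored; iHS is unstable near fixation.
    ehh_cutoff
        EHH level at which iHH integration stops (0.05 by convention).
    bin_table
        External daf-bin calibration (e.g. genome-wide background).  Without
        it, quantile bins are fit within each population.
    """

    def __init__(
        self,
        matrix: HaplotypeMatrix,
        panel: PopulationPanel | None = None,
        *,
        min_daf: float = DEFAULT_MIN_DAF,
        ehh_cutoff: float = DEFAULT_EHH_CUTOFF,
        n_bins: int = 20,
        min_bin_size: int = 5,
        bin_table: BinTable | None = None,
        genetic_map: GeneticMap | None = None,
        exclude_flags: tuple[str, ...] = (F_EDGE,),
    ):
        self.matrix = matrix
        self.panel = panel
        self.min_daf = min_daf
        self.ehh_cutoff = ehh_cutoff
        self.n_bins = n_bins
        self.min_bin_size = min_bin_size
        self.bin_table = bin_table
        self.genetic_map = genetic_map
        self.exclude_flags = exclude_flags

    def _population_rows(self) -> dict[str, np.ndarray]:
        m = self.matrix
        if self.panel is not None:
            labels = [self.panel.group_of_sample(s) for s in m.haplotype_samples()]
        elif m.sample_to_population:
            labels = list(m.haplotype_populations())
        else:
            labels = ["all"] * m.n_haplotypes
        labels = np.asarray(labels, dtype=object)
        seen: dict[str, None] = {}
        for lab in labels:
            seen.setdefault(lab, None)
        return {lab: np.flatnonzero(labels == lab) for lab in seen}

    def score_snp(self, core, rows: np.ndarray | None = None,
                  population: str = "all") -> IhsResult:
        """Unstandardized iHS bookkeeping for one core SNP."""
        m = self.matrix
        j = m.snp_index(core) if isinstance(core, str) else (
            m.snp_index(core.snp_id) if isinstance(core, SnpRecord) else int(core))
        snp = m.snps[j]
        der, tot = m.derived_counts(rows)
        daf = der[j] / tot[j] if tot[j] > 0 else float("nan")
        res = IhsResult(snp=snp, population=population, daf=float(daf))
        areas = {}
        for allele_class in ("ancestral", "derived"):
            curves = [compute_ehh(m, j, allele_class, side, rows=rows)
                      for side in ("left", "right")]
            if any(F_INSUFFICIENT in c.flags for c in curves):
                res.flags.add(F_INSUFFICIENT)
                return res
            area, flags = integrate_ihh(curves[0], curves[1], cutoff=self.ehh_cutoff,
                                        genetic_map=self.genetic_map)
            res.flags |= flags
            areas[allele_class] = area
        res.ihh_a, res.ihh_d = areas["ancestral"], areas["derived"]
        res.ln_ratio = unstandardized_ihs(res.ihh_a, res.ihh_d)
        if not np.isfinite(res.ln_ratio):
            res.flags.add(F_ZERO_IHH)
        return res

    def _raw_for_population(self, pop: str, rows: np.ndarray) -> list[IhsResult]:
        der, tot = self.matrix.derived_counts(rows)
        with np.errstate(invalid="ignore"):
            daf = np.where(tot > 0, der / np.maximum(tot, 1), np.nan)
        scored = [j for j in range(self.matrix.n_snps)
                  if np.isfinite(daf[j]) and self.min_daf <= daf[j] <= 1 - self.min_daf]
        return [self.score_snp(j, rows=rows, population=pop) for j in scored]

    def raw_results(self) -> list[IhsResult]:
        """Unstandardized per-SNP results (for building background bin tables)."""
        return [r for pop, rows in self._population_rows().items()
                for r in self._raw_for_population(pop, rows)]

    def fit(self) -> "IhsScanResults":
        all_results: list[IhsResult] = []
        for pop, rows in self._population_rows().items():
            raw = self._raw_for_population(pop, rows)
            all_results.extend(standardize_ihs(
                raw, n_bins=self.n_bins, min_bin_size=self.min_bin_size,
                external_bin_table=self.bin_table, exclude_flags=self.exclude_flags))
        return IhsScanResults(self, all_results)


class IhsScanResults:
    """Fitted iHS scan: per-SNP scores, candidate screen, summary table."""

    def __init__(self, model: IhsScan, results: list[IhsResult]):
        self.model = model
        self.results = results

    @property
    def frame(self) -> pd.DataFrame:
        rows = [{
            "snp_id": r.snp.snp_id, "chrom": r.snp.chrom, "pos": r.snp.pos,
            "population": r.population, "daf": r.daf,
            "ihh_a": r.ihh_a, "ihh_d": r.ihh_d, "ln_ratio": r.ln_ratio,
            "ihs": r.ihs, "bin_index": r.bin_index,
            "flags": ",".join(sorted(r.flags)),
        } for r in self.results]
        return pd.DataFrame(rows, columns=[
            "snp_id", "chrom", "pos", "population", "daf", "ihh_a", "ihh_d",
            "ln_ratio", "ihs", "bin_index", "flags"])

    def candidates(self, threshold: float = DEFAULT_IHS_THRESHOLD) -> pd.DataFrame:
        hits = screen_candidates(self.results, threshold)
        return pd.DataFrame(
            [{"snp_id": s.snp_id, "population": p, "ihs": v} for s, p, v in hits],
            columns=["snp_id", "population", "ihs"])

    def summary(self, threshold: float = DEFAULT_IHS_THRESHOLD) -> str:
        df = self.frame
        lines = ["iHS selection scan", "=" * 19]
        for pop, grp in df.groupby("population", sort=False):
            scored = int(np.isfinite(grp["ihs"]).sum())
            hits = int((np.abs(grp["ihs"]) > threshold).sum())
            lines.append(f"population {pop}: {len(grp)} SNPs evaluated, "
                         f"{scored} scored, {hits} with |iHS| > {threshold:g}")
        return "\n".join(lines)
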