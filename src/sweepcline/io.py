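"""Readers and writers for the pipeline's file formats.

This module is the single place where coordinate and allele conventions are
enforced: VCF positions stay 1-based externally, array indices are 0-based
internally, and alleles are recoded to 0=ancestral / 1=derived exactly once,
here.  Alleles are compared as given — no strand flipping or complementing,
because a silent strand "fix" corrupts A/T and C/G SNPs.

Missing data is carried through as a distinct state (``"."`` on disk,
:data:`~sweepcline.core.MISSING` in memory) and never imputed at I/O time.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ALL_COVARIATES, MISSING, ClimateTable, HaplotypeMatrix, PopulationPanel, SnpRecord

logger = logging.getLogger(__name__)

# Header-name aliases accepted by read_climate_csv, extendable per call.
DEFAULT_CLIMATE_ALIASES: dict[str, str] = {
    "population": "population",
    "pop": "population",
    "longitude": "longitude",
    "lon": "longitude",
    "latitude": "latitude",
    "lat": "latitude",
    "altitude": "altitude",
    "alt": "altitude",
    "elevation_m": "altitude",
    "sunshine": "sunshine",
    "sunshine_h": "sunshine",
    "daily_sunshine": "sunshine",
    "temperature": "temperature",
    "temp": "temperature",
    "temp_c": "temperature",
    "uv": "uv",
    "uv_radiation": "uv",
    "precipitation": "precipitation",
    "precip": "precipitation",
    "precip_mm": "precipitation",
}


# ---------------------------------------------------------------------------
# phased VCF
# ---------------------------------------------------------------------------

def read_phased_vcf(
    path: str | Path,
    ancestral_source: str | Mapping[str, str] | Sequence[SnpRecord] = "AA",
    sample_to_population: Mapping[str, str] | None = None,
    stats: dict | None = None,
) -> HaplotypeMatrix:
    """Read phased biallelic genotypes into a HaplotypeMatrix.

    ``ancestral_source`` is either the name of an INFO tag carrying the
    ancestral allele (default ``"AA"``), a mapping ``snp_id -> ancestral
    base``, or a sequence of :class:`SnpRecord` (the sidecar table, which
    takes priority over any INFO tag because ancestral calls usually ship
    separately from the genotypes).

    Sites are dropped (and counted in ``stats`` / the log) when multiallelic,
    when no ancestral allele is assigned, or when the assigned ancestral
    allele matches neither REF nor ALT.  An unphased genotype is an error
    naming the sample and site.
    """
    from cyvcf2 import VCF

    sidecar: dict[str, str] = {}
    if isinstance(ancestral_source, str):
        aa_tag: str | None = ancestral_source
    else:
        aa_tag = None
        for rec in ancestral_source if not isinstance(ancestral_source, Mapping) else []:
            sidecar[rec.snp_id] = rec.ancestral_allele
        if isinstance(ancestral_source, Mapping):
            sidecar = dict(ancestral_source)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snps: list[SnpRecord] = []
    columns: list[np.ndarray] = []
    counts = {"sites": 0, "kept": 0, "multiallelic": 0, "no_ancestral": 0, "ancestral_mismatch": 0}

    for v in vcf:
        counts["sites"] += 1
        if len(v.ALT) != 1:
            counts["multiallelic"] += 1
            logger.warning("skipping multiallelic site %s:%s", v.CHROM, v.POS)
            continue
        snp_id = v.ID or f"{v.CHROM}:{v.POS}"
        ref, alt = v.REF, v.ALT[0]
        aa = sidecar.get(snp_id)
        if aa is None and aa_tag is not None:
            raw = v.INFO.get(aa_tag)
            if raw is not None:
                aa = str(raw).upper()
        if aa is None or aa == "." or aa == "":
            counts["no_ancestral"] += 1
            continue
        if aa == ref:
            derived = alt
        elif aa == alt:
            derived = ref
        else:
            counts["ancestral_mismatch"] += 1
            logger.warning("site %s: ancestral %r is neither REF nor ALT", snp_id, aa)
            continue

        col = np.full(2 * len(samples), MISSING, dtype=np.int8)
        for si, gt in enumerate(v.genotypes):  # [a0, a1, phased]
            a0, a1, phased = gt[0], gt[1], gt[-1]
            alleles_present = [a for a in (a0, a1) if a >= 0]
            if alleles_present and not phased and a0 != a1:
                raise ValueError(
                    f"unphased heterozygote for sample {samples[si]!r} at {snp_id}"
                )
            for k, a in enumerate((a0, a1)):
                if a < 0:
                    continue
                base = ref if a == 0 else alt
                col[2 * si + k] = 0 if base == aa else 1
        snps.append(SnpRecord(snp_id, v.CHROM, v.POS, aa, derived))
        columns.append(col)
        counts["kept"] += 1

    if stats is not None:
        stats.update(counts)
    logger.info("read %s: %d sites, kept %d (%d multiallelic, %d without ancestral call)",
                path, counts["sites"], counts["kept"], counts["multiallelic"], counts["no_ancestral"])

    hap_ids = [f"{s}|{k}" for s in samples for k in (0, 1)]
    alleles = (np.column_stack(columns) if columns
               else np.empty((2 * len(samples), 0), dtype=np.int8))
    return HaplotypeMatrix(
        snps=snps,
        haplotype_ids=hap_ids,
        alleles=alleles,
        sample_to_population=dict(sample_to_population or {}),
    )


# ---------------------------------------------------------------------------
# haplotype matrix TSV
# ---------------------------------------------------------------------------

def write_haplotype_tsv(matrix: HaplotypeMatrix, path: str | Path) -> None:
    """Write a HaplotypeMatrix as TSV (rows = haplotypes, '.' = missing).

    SNP metadata travels in ``##snp`` comment lines so the file round-trips
    without a sidecar.
    """
    with open(path, "w") as fh:
        for s in matrix.snps:
            fh.write(f"##snp\t{s.snp_id}\t{s.chrom}\t{s.pos}\t{s.ancestral_allele}\t{s.derived_allele}\n")
        for sample, pop in matrix.sample_to_population.items():
            fh.write(f"##population\t{sample}\t{pop}\n")
        fh.write("haplotype_id\t" + "\t".join(s.snp_id for s in matrix.snps) + "\n")
        for hid, row in zip(matrix.haplotype_ids, matrix.alleles):
            cells = [("." if a == MISSING else str(int(a))) for a in row]
            fh.write(hid + "\t" + "\t".join(cells) + "\n")


def read_haplotype_tsv(path: str | Path) -> HaplotypeMatrix:
    """Inverse of :func:`write_haplotype_tsv`.

    Files without ``##snp`` metadata get placeholder SNP records (chrom "1",
    positions 1..n, alleles A/G) so that plain 0/1 matrices remain readable.
    Ragged rows are an error naming the offending line number.
    """
    snp_meta: dict[str, SnpRecord] = {}
    pops: dict[str, str] = {}
    header: list[str] | None = None
    hap_ids: list[str] = []
    rows: list[list[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##snp\t"):
                _, sid, chrom, pos, anc, der = line.split("\t")
                snp_meta[sid] = SnpRecord(sid, chrom, int(pos), anc, der)
                continue
            if line.startswith("##population\t"):
                _, sample, pop = line.split("\t")
                pops[sample] = pop
                continue
            fields = line.split("\t")
            if header is None:
                header = fields[1:]
                continue
            if len(fields) != len(header) + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header) + 1} fields, got {len(fields)}"
                )
            hap_ids.append(fields[0])
            rows.append([MISSING if c == "." else int(c) for c in fields[1:]])
    if header is None:
        raise ValueError(f"{path}: no header row")
    if snp_meta:
        snps = [snp_meta[sid] for sid in header]
    else:
        snps = [SnpRecord(sid, "1", i + 1, "A", "G") for i, sid in enumerate(header)]
    alleles = (np.asarray(rows, dtype=np.int8) if rows
               else np.empty((0, len(header)), dtype=np.int8))
    return HaplotypeMatrix(snps=snps, haplotype_ids=hap_ids, alleles=alleles,
                           sample_to_population=pops)


# ---------------------------------------------------------------------------
# generic result tables, panel, SNP sidecar, genotypes, climate, map
# ---------------------------------------------------------------------------

def write_results_tsv(records: pd.DataFrame, path: str | Path) -> None:
    """Write a result table (any Results ``.frame``) as TSV."""
    records.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def read_panel_tsv(path: str | Path) -> PopulationPanel:
    """Panel TSV with columns ``sample``, ``population`` and optional ``group``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns or "population" not in df.columns:
        raise ValueError(f"{path}: panel needs 'sample' and 'population' columns")
    s2p = dict(zip(df["sample"], df["population"]))
    p2g: dict[str, str] = {}
    if "group" in df.columns:
        p2g = dict(zip(df["population"], df["group"]))
    return PopulationPanel(sample_to_population=s2p, population_to_group=p2g)


def read_snp_table(path: str | Path) -> list[SnpRecord]:
    """Sidecar SNP table: snp_id, chrom, pos, ancestral_allele, derived_allele."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    return [
        SnpRecord(r.snp_id, str(r.chrom), int(r.pos), r.ancestral_allele, r.derived_allele)
        for r in df.itertuples()
    ]


def read_genotype_tsv(path: str | Path) -> pd.DataFrame:
    """Case-control genotype TSV: snp_id, sample_id, status, genotype.

    ``genotype`` is the risk-allele count in {0, 1, 2} or '.' for missing;
    ``status`` must be 'case' or 'control'.  A file without a ``snp_id``
    column is treated as a single unnamed SNP.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "status", "genotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = ~df["status"].isin(["case", "control"])
    if bad.any():
        raise ValueError(f"{path}: invalid status values {sorted(df.loc[bad, 'status'].unique())}")
    df["genotype"] = df["genotype"].map(lambda g: MISSING if g == "." else int(g))
    if not df["genotype"].isin([0, 1, 2, MISSING]).all():
        raise ValueError(f"{path}: genotypes must be 0/1/2 or '.'")
    if "snp_id" not in df.columns:
        df["snp_id"] = "snp"
    return df[["snp_id", "sample_id", "status", "genotype"]]


def read_climate_csv(path: str | Path, aliases: Mapping[str, str] | None = None) -> ClimateTable:
    """Read a per-population climate/geography CSV.

    Header names are matched case-insensitively against
    :data:`DEFAULT_CLIMATE_ALIASES`, extended/overridden by ``aliases``
    (raw header -> canonical covariate name).
    """
    alias_map = dict(DEFAULT_CLIMATE_ALIASES)
    for k, v in (aliases or {}).items():
        alias_map[k.lower()] = v
    raw = pd.read_csv(path, dtype=str)
    renames = {}
    for col in raw.columns:
        canon = alias_map.get(col.strip().lower())
        if canon is not None:
            renames[col] = canon
    df = raw.rename(columns=renames)
    if "population" not in df.columns:
        raise ValueError(f"{path}: no population column (or alias) found")
    missing = [c for c in ALL_COVARIATES if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing covariate column(s): {missing}")
    dup = df["population"][df["population"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate population(s): {sorted(dup.unique())}")
    for col in ALL_COVARIATES:
        for i, cell in enumerate(df[col]):
            try:
                float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} in column {col!r}, row {i + 2}"
                ) from None
    out = df.set_index("population")[list(ALL_COVARIATES)].astype(float)
    return ClimateTable(out)


def read_genetic_map(path: str | Path) -> "GeneticMap":
    """PLINK-style .map (chrom, id, cM, bp) or HapMap-format (pos, rate, cM).

    Returns an interpolator from bp position to cM.
    """
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first and first.split("\t")[2].replace(".", "", 1).lstrip("-").isdigit() \
            and len(first.split("\t")) == 4:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "snp_id", "cm", "pos"])
        pos, cm = df["pos"].to_numpy(float), df["cm"].to_numpy(float)
    else:
        df = pd.read_csv(path, sep=None, engine="python")
        cols = [c.lower() for c in df.columns]
        df.columns = cols
        pos_col = next(c for c in cols if "pos" in c)
        cm_col = next(c for c in cols if "cm" in c or "map" in c)
        pos, cm = df[pos_col].to_numpy(float), df[cm_col].to_numpy(float)
    order = np.argsort(pos)
    return GeneticMap(pos[order], cm[order])


class GeneticMap:
    """Monotone bp -> cM interpolation (linear, flat extrapolation)."""

    def __init__(self, positions_bp: np.ndarray, cm: np.ndarray):
        if np.any(np.diff(cm) < 0):
            raise ValueError("genetic map cM values must be non-decreasing")
        self.positions_bp = positions_bp
        self.cm = cm

    def __call__(self, pos_bp: np.ndarray) -> np.ndarray:
        return np.interp(pos_bp, self.positions_bp, self.cm)


def write_run_summary(summary: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
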