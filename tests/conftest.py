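import numpy as np
import pytest

from sweepcline.core import HaplotypeMatrix, SnpRecord


def make_matrix(alleles, positions=None, pops=None, chrom="1"):
    """Build a HaplotypeMatrix from a nested list / array of allele codes."""
    alleles = np.asarray(alleles, dtype=np.int8)
    n_h, n_s = alleles.shape
    positions = positions or [(j + 1) * 1000 for j in range(n_s)]
    snps = [SnpRecord(f"rs{j}", chrom, positions[j], "A", "G") for j in range(n_s)]
    hap_ids = [f"h{i}" for i in range(n_h)]
    s2p = {h: (pops[i] if pops else "pop1") for i, h in enumerate(hap_ids)}
    return HaplotypeMatrix(snps=snps, haplotype_ids=hap_ids, alleles=alleles,
                           sample_to_population=s2p)


@pytest.fixture
def small_matrix():
    """8 haplotypes x 5 SNPs, core at index 2 with 4 derived carriers."""
    return make_matrix([
        [0, 0, 1, 0, 0],
        [0, 0, 1, 0, 0],
        [0, 1, 1, 1, 0],
        [1, 1, 1, 1, 1],
        [0, 0, 0, 0, 0],
        [0, 1, 0, 1, 0],
        [1, 0, 0, 0, 1],
        [1, 1, 0, 1, 1],
    ])


def brute_force_ehh(alleles, positions, core_j, allele_class, side):
    """Independent EHH oracle: enumerate all carrier pairs and check segment
    identity from the core through each flanking marker.

    Missing-data policy mirrors the implementation contract: a carrier is
    dropped at the first marker (moving outward) where it is missing, and
    beyond.  Returns (positions, ehh_values) including the core point.
    """
    from sweepcline.core import MISSING

    alleles = np.asarray(alleles)
    target = 1 if allele_class == "derived" else 0
    carriers = [i for i in range(alleles.shape[0]) if alleles[i, core_j] == target]
    if len(carriers) < 2:
        return None
    if side == "left":
        markers = list(range(core_j - 1, -1, -1))
    else:
        markers = list(range(core_j + 1, alleles.shape[1]))
    out_pos, out_ehh = [positions[core_j]], [1.0]
    sub = alleles[carriers]
    k = len(carriers)
    ident = np.ones((k, k), dtype=bool)  # pairwise identity core..current marker
    alive = np.ones(k, dtype=bool)
    for m in markers:
        col = sub[:, m]
        alive &= col != MISSING
        n = int(alive.sum())
        if n < 2:
            break
        ident &= col[:, None] == col[None, :]
        sel = ident[np.ix_(alive, alive)]
        n_pairs_identical = (sel.sum() - n) // 2
        ehh = n_pairs_identical / (n * (n - 1) / 2)
        out_pos.append(positions[m])
        out_ehh.append(ehh)
        if ehh == 0.0:
            break
    return np.array(out_pos), np.array(out_ehh)
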