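import numpy as np
import pandas as pd
import pytest

from vertebramark.io_core import GenotypeMatrix, SampleManifest


def make_matrix(loci, samples, calls, gq=None, pl=None):
    """Build a GenotypeMatrix from genotype strings like "0/1", "1|1", "./.".

    ``loci``: list of (chrom, pos, ref, alt); ``calls``: loci x samples grid.
    ``gq``/``pl`` optional parallel grids (ints / int triples), -1 = absent.
    """
    L, S = len(loci), len(samples)
    alleles = np.full((L, S, 2), -1, dtype=np.int8)
    phased = np.zeros((L, S), dtype=bool)
    gq_arr = np.full((L, S), -1, dtype=np.int16)
    pl_arr = np.full((L, S, 3), -1, dtype=np.int32)
    for i in range(L):
        for j in range(S):
            gt = calls[i][j]
            sep = "|" if "|" in gt else "/"
            a1, a2 = gt.split(sep)
            alleles[i, j, 0] = -1 if a1 == "." else int(a1)
            alleles[i, j, 1] = -1 if a2 == "." else int(a2)
            phased[i, j] = sep == "|"
            if gq is not None:
                gq_arr[i, j] = gq[i][j]
            if pl is not None:
                pl_arr[i, j] = pl[i][j]
    frame = pd.DataFrame(loci, columns=["chrom", "pos", "ref", "alt"])
    frame["locus_id"] = frame["chrom"] + ":" + frame["pos"].astype(str)
    return GenotypeMatrix(
        loci=frame, samples=list(samples), alleles=alleles,
        phased=phased, gq=gq_arr, pl=pl_arr,
    )


def make_manifest(rows):
    """rows: list of (sample_id, population, thoracic, lumbar)."""
    return SampleManifest(
        table=pd.DataFrame(
            rows, columns=["sample_id", "population", "thoracic", "lumbar"]
        )
    )


@pytest.fixture
def tiny_cohort():
    """3 populations x 2 samples, 4 loci with a clean fixed difference."""
    loci = [
        ("chr1", 100, "A", "C"),
        ("chr1", 200, "G", "T"),
        ("chr1", 300, "A", "G"),
        ("chr2", 150, "C", "T"),
    ]
    samples = ["YC1", "YC2", "ZC1", "ZC2", "GY1", "GY2"]
    calls = [
        ["1/1", "1/1", "0/0", "0/0", "0/0", "0/0"],  # differential fixed
        ["0/1", "0/1", "0/1", "0/1", "0/1", "0/1"],  # fixed het everywhere
        ["0/0", "0/1", "0/0", "0/0", "1/1", "1/1"],  # not fixed in YC
        ["0/0", "./.", "1/1", "1/1", "0/0", "0/0"],  # missing kills YC fixation
    ]
    matrix = make_matrix(loci, samples, calls)
    manifest = make_manifest(
        [("YC1", "YC", 15, 5), ("YC2", "YC", 15, 5),
         ("ZC1", "ZC", 14, 5), ("ZC2", "ZC", 14, 5),
         ("GY1", "GY", 14, 5), ("GY2", "GY", 14, 5)]
    )
    return matrix, manifest
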