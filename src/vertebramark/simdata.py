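"""Synthetic phased diploid cohorts with planted differential markers.

The generator emulates the study design the analysis layer expects: three
small yak populations (a 5-animal T15L5 case population and two 5-animal
T14L5 control populations), genome-wide biallelic SNVs whose between-
population differentiation comes from Balding-Nichols drift around shared
ancestral frequencies, local linkage disequilibrium from per-population
haplotype pools with a per-locus copying-switch process, a causal region
whose loci are fixed for alternative genotypes in the case population and
reference genotypes in the controls, per-call genotype qualities and
missingness, and a larger validation cohort with known phenotypes.

Everything is deterministic under the seed; the returned
:class:`TruthTable` records the planted loci, true phenotypes, haplotype
pools and phase so every downstream stage can be checked against ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import (
    GeneInterval,
    GenotypeMatrix,
    SampleManifest,
    write_gene_bed,
    write_manifest,
    write_vcf,
)


@dataclass
class CausalRegion:
    chrom: str = "chr1"
    start: int = 400_000  # 0-based
    end: int = 410_000
    n_loci: int = 20


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the resequencing design: populations YC (case, 5
    diploids, T15L5), ZC and GY (controls, 5 each, T14L5); drift F = 0.03
    per population (windowed F_ST on the 0.02-0.06 scale); ancestral
    frequencies Uniform(0.05, 0.95); per-population haplotype pools with
    the case pool smallest (highest LD); GQ = 30 + rounded Exponential
    (floor 3) with PL derived as (0, GQ, GQ+30) around the called
    genotype; 1% missing calls; a 51-animal validation cohort of which 10
    carry the case phenotype.
    """

    seed: int = 0
    populations: tuple[tuple[str, int], ...] = (("YC", 5), ("ZC", 5), ("GY", 5))
    case_population: str = "YC"
    case_formula: tuple[int, int] = (15, 5)  # thoracic, lumbar -> T15L5
    control_formula: tuple[int, int] = (14, 5)  # T14L5
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    n_loci_per_chrom: int = 1000
    freq_low: float = 0.05
    freq_high: float = 0.95
    drift_f: float = 0.03
    pool_sizes: dict = field(default_factory=lambda: {"YC": 6, "ZC": 10, "GY": 10})
    default_pool_size: int = 10
    shared_pool: bool = False  # one common pool for all populations (no structure)
    switch_rate: float = 0.05  # per-locus pool-switch probability while copying
    causal: CausalRegion = field(default_factory=CausalRegion)
    sweep_halo: int = 0  # bp around the causal span where the case pool is
    # homogenized to one haplotype, emulating a hard sweep (controls stay
    # polymorphic); 0 disables
    penetrance: float = 1.0  # P(case-population animal truly shows the case formula)
    gq_scale: float = 15.0
    gq_floor: int = 3
    missing_rate: float = 0.01
    n_validation: int = 51
    n_validation_case: int = 10
    n_genes: int = 8

    def __post_init__(self) -> None:
        if self.causal.n_loci < 1:
            raise ValueError("need at least one planted causal locus")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing rate must be in [0, 1]")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must be in [0, 1]")
        if self.causal.chrom not in self.chrom_lengths:
            raise ValueError(f"causal chrom {self.causal.chrom!r} not simulated")
        if self.causal.end > self.chrom_lengths[self.causal.chrom]:
            raise ValueError("causal region exceeds chromosome length")
        if any(n < 2 for n in self.pool_sizes.values()) or self.default_pool_size < 2:
            raise ValueError("haplotype pools need >=2 haplotypes")


@dataclass
class TruthTable:
    planted_locus_ids: list[str]
    phenotypes: dict[str, str]  # sample -> formula (e.g. "T15L5")
    pools: dict[str, np.ndarray] = field(repr=False)  # pop -> (pool, L) haplotypes
    haplotypes: dict[str, np.ndarray] = field(repr=False)  # sample -> (L, 2)


@dataclass
class SimulatedCohort:
    matrix: GenotypeMatrix
    manifest: SampleManifest
    genes: list[GeneInterval]
    truth: TruthTable
    config: SimConfig


def _draw_loci(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sorted distinct SNV positions per chromosome, causal loci included."""
    bases = np.array(list("ACGT"))
    frames = []
    for chrom in sorted(cfg.chrom_lengths):
        length = cfg.chrom_lengths[chrom]
        if chrom == cfg.causal.chrom:
            # keep the causal span free of background loci so it holds
            # exactly the K planted positions
            lo, hi = cfg.causal.start + 1, cfg.causal.end  # 1-based inclusive
            causal_pos = np.unique(np.linspace(lo, hi, cfg.causal.n_loci).astype(int))
            allowed = np.concatenate(
                [np.arange(1, lo), np.arange(hi + 1, length)]
            )
            pos = rng.choice(allowed, size=cfg.n_loci_per_chrom - len(causal_pos),
                             replace=False)
            pos = np.union1d(pos, causal_pos)
        else:
            pos = rng.choice(length - 1, size=cfg.n_loci_per_chrom, replace=False) + 1
        pos = np.sort(pos)
        ref_idx = rng.integers(0, 4, size=len(pos))
        alt_idx = (ref_idx + rng.integers(1, 4, size=len(pos))) % 4
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": bases[ref_idx],
                    "alt": bases[alt_idx],
                }
            )
        )
    loci = pd.concat(frames, ignore_index=True)
    loci["locus_id"] = loci["chrom"] + ":" + loci["pos"].astype(str)
    return loci


def _causal_rows(cfg: SimConfig, loci: pd.DataFrame) -> np.ndarray:
    pos0 = loci["pos"].to_numpy() - 1
    mask = (
        (loci["chrom"] == cfg.causal.chrom).to_numpy()
        & (pos0 >= cfg.causal.start)
        & (pos0 < cfg.causal.end)
    )
    return np.flatnonzero(mask)


def _balding_nichols(
    ancestral: np.ndarray, F: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-population allele frequencies drifted around ancestral ones."""
    if F <= 0:
        return ancestral.copy()
    a = ancestral * (1.0 - F) / F
    b = (1.0 - ancestral) * (1.0 - F) / F
    return rng.beta(a, b)


def _copy_gamete(
    pool: np.ndarray, switch_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """One gamete copied from the pool with per-locus template switching."""
    n_pool, L = pool.shape
    template = np.empty(L, dtype=np.intp)
    template[0] = rng.integers(n_pool)
    switches = rng.random(L) < switch_rate
    current = template[0]
    for i in range(1, L):
        if switches[i]:
            current = rng.integers(n_pool)
        template[i] = current
    return pool[template, np.arange(L)]


def simulate_cohort(config: SimConfig | None = None) -> SimulatedCohort:
    """Generate the phased reference cohort with ground truth."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)

    loci = _draw_loci(cfg, rng)
    L = len(loci)
    causal_rows = _causal_rows(cfg, loci)
    ancestral = rng.uniform(cfg.freq_low, cfg.freq_high, size=L)

    pools: dict[str, np.ndarray] = {}
    if cfg.shared_pool:
        size = cfg.default_pool_size
        freqs = _balding_nichols(ancestral, cfg.drift_f, rng)
        common = (rng.random((size, L)) < freqs).astype(np.int8)
        for pop, _ in cfg.populations:
            pools[pop] = common.copy()  # planting must not leak across groups
    else:
        for pop, _ in cfg.populations:
            size = cfg.pool_sizes.get(pop, cfg.default_pool_size)
            freqs = _balding_nichols(ancestral, cfg.drift_f, rng)
            pools[pop] = (rng.random((size, L)) < freqs).astype(np.int8)

    # plant the causal region: case pool fixed alt, control pools fixed ref
    for pop, _ in cfg.populations:
        planted = 1 if pop == cfg.case_population else 0
        pools[pop][:, causal_rows] = planted

    if cfg.sweep_halo > 0:
        pos0 = loci["pos"].to_numpy() - 1
        halo = np.flatnonzero(
            (loci["chrom"] == cfg.causal.chrom).to_numpy()
            & (pos0 >= cfg.causal.start - cfg.sweep_halo)
            & (pos0 < cfg.causal.end + cfg.sweep_halo)
        )
        case_pool = pools[cfg.case_population]
        case_pool[:, halo] = case_pool[0, halo]  # one swept haplotype

    samples: list[str] = []
    rows_manifest = []
    haplotypes: dict[str, np.ndarray] = {}
    phenotypes: dict[str, str] = {}
    for pop, n in cfg.populations:
        for k in range(1, n + 1):
            sid = f"{pop}{k}"
            samples.append(sid)
            hap = np.stack(
                [
                    _copy_gamete(pools[pop], cfg.switch_rate, rng),
                    _copy_gamete(pools[pop], cfg.switch_rate, rng),
                ],
                axis=1,
            )  # (L, 2)
            haplotypes[sid] = hap
            if pop == cfg.case_population and rng.random() < cfg.penetrance:
                t, l = cfg.case_formula
            else:
                t, l = cfg.control_formula
            phenotypes[sid] = f"T{t}L{l}"
            rows_manifest.append(
                {"sample_id": sid, "population": pop, "thoracic": t, "lumbar": l}
            )

    matrix = _assemble_matrix(cfg, loci, samples, haplotypes, rng)
    manifest = SampleManifest(table=pd.DataFrame(rows_manifest))
    genes = _make_genes(cfg, rng)
    truth = TruthTable(
        planted_locus_ids=list(loci["locus_id"].iloc[causal_rows]),
        phenotypes=phenotypes,
        pools=pools,
        haplotypes=haplotypes,
    )
    return SimulatedCohort(matrix, manifest, genes, truth, cfg)


def _assemble_matrix(
    cfg: SimConfig,
    loci: pd.DataFrame,
    samples: list[str],
    haplotypes: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> GenotypeMatrix:
    L, S = len(loci), len(samples)
    alleles = np.stack([haplotypes[s] for s in samples], axis=1).astype(np.int8)
    phased = np.ones((L, S), dtype=bool)

    gq_raw = 30 + np.round(rng.exponential(cfg.gq_scale, size=(L, S)))
    gq = np.maximum(cfg.gq_floor, gq_raw).astype(np.int16)

    # PL convention: 0 at the called genotype, GQ at the nearer alternative,
    # GQ + 30 at the farther one
    g = alleles.sum(axis=2)  # 0, 1, 2
    pl = np.zeros((L, S, 3), dtype=np.int32)
    gq32 = gq.astype(np.int32)
    for called in (0, 1, 2):
        m = g == called
        order = {0: (0, 1, 2), 1: (1, 0, 2), 2: (2, 1, 0)}[called]
        pl[m, order[0]] = 0
        pl[m, order[1]] = gq32[m]
        pl[m, order[2]] = gq32[m] + 30

    if cfg.missing_rate > 0:
        drop = rng.random((L, S)) < cfg.missing_rate
        alleles[drop] = -1
        gq[drop] = -1
        pl[drop] = -1

    return GenotypeMatrix(
        loci=loci.reset_index(drop=True),
        samples=samples,
        alleles=alleles,
        phased=phased,
        gq=gq,
        pl=pl,
    )


def _make_genes(cfg: SimConfig, rng: np.random.Generator) -> list[GeneInterval]:
    """Gene intervals, one overlapping the causal region, rest spaced out."""
    genes = [
        GeneInterval(
            cfg.causal.chrom,
            max(0, cfg.causal.start - 2_000),
            cfg.causal.end + 2_000,
            "geneCAUSAL",
        )
    ]
    n = 1
    for chrom in sorted(cfg.chrom_lengths):
        length = cfg.chrom_lengths[chrom]
        for start in range(50_000, length - 30_000, length // max(cfg.n_genes // 2, 1)):
            if chrom == cfg.causal.chrom and not (
                start + 20_000 <= cfg.causal.start or start >= cfg.causal.end
            ):
                continue
            genes.append(GeneInterval(chrom, start, start + 20_000, f"gene{n:03d}"))
            n += 1
            if len(genes) >= cfg.n_genes:
                return genes
    return genes


def emit_validation_cohort(
    cohort: SimulatedCohort,
    n_total: int | None = None,
    n_case: int | None = None,
    loci_subset: Sequence[str] | None = None,
    seed_offset: int = 1,
) -> tuple[GenotypeMatrix, SampleManifest]:
    """Draw an independent validation cohort from the same haplotype pools.

    ``n_case`` animals carry the case phenotype (and case-pool genomes),
    the rest draw from the control pools.  ``loci_subset`` restricts the
    emitted matrix to given locus ids (e.g. the shortlisted markers).
    """
    cfg = cohort.config
    n_total = cfg.n_validation if n_total is None else n_total
    n_case = cfg.n_validation_case if n_case is None else n_case
    if n_case > n_total:
        raise ValueError("validation case count exceeds cohort size")
    rng = np.random.default_rng(cfg.seed + seed_offset)

    control_pops = [p for p, _ in cfg.populations if p != cfg.case_population]
    loci = cohort.matrix.loci
    samples, rows_manifest, haps = [], [], {}
    for k in range(1, n_total + 1):
        sid = f"V{k:03d}"
        samples.append(sid)
        if k <= n_case:
            pop = cfg.case_population
            t, l = cfg.case_formula
        else:
            pop = control_pops[rng.integers(len(control_pops))]
            t, l = cfg.control_formula
        hap = np.stack(
            [
                _copy_gamete(cohort.truth.pools[pop], cfg.switch_rate, rng),
                _copy_gamete(cohort.truth.pools[pop], cfg.switch_rate, rng),
            ],
            axis=1,
        )
        haps[sid] = hap
        rows_manifest.append(
            {"sample_id": sid, "population": "validation", "thoracic": t, "lumbar": l}
        )

    matrix = _assemble_matrix(cfg, loci, samples, haps, rng)
    if loci_subset is not None:
        wanted = set(loci_subset)
        idx = np.flatnonzero(matrix.loci["locus_id"].isin(wanted).to_numpy())
        matrix = matrix.subset_loci(idx)
    manifest = SampleManifest(table=pd.DataFrame(rows_manifest))
    return matrix, manifest


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path,
                 validation: tuple[GenotypeMatrix, SampleManifest] | None = None) -> dict:
    """Write VCF/manifest/BED/truth files; returns the path map."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "manifest": out / "manifest.tsv",
        "genes": out / "genes.bed",
        "truth": out / "truth.json",
    }
    write_vcf(cohort.matrix, paths["vcf"], contig_lengths=cohort.config.chrom_lengths)
    write_manifest(cohort.manifest, paths["manifest"])
    write_gene_bed(cohort.genes, paths["genes"])
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "planted_locus_ids": cohort.truth.planted_locus_ids,
                "phenotypes": cohort.truth.phenotypes,
                "seed": cohort.config.seed,
            },
            fh,
            indent=1,
        )
    if validation is not None:
        vm, vman = validation
        paths["validation_vcf"] = out / "validation.vcf"
        paths["validation_manifest"] = out / "validation_manifest.tsv"
        write_vcf(vm, paths["validation_vcf"], contig_lengths=cohort.config.chrom_lengths)
        write_manifest(vman, paths["validation_manifest"])
    return {k: str(v) for k, v in paths.items()}
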