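"""Synthetic study generator with planted ground truth.

Emulates a two-compartment (epithelium/fiber), two-stage (E14.5/P0.5),
three-replicate WGBS design together with ATAC peaks and DARs, H3.3-style
ChIP peaks in two replicates per compartment, TF peaks, and a DEG table --
everything the integration pipeline consumes, at desk scale.

Genome model
------------
CpG positions follow a two-state process: sparse background (geometric
spacing, mean ~100 bp) punctuated by CpG islands (mean spacing ~10 bp)
placed at gene promoters and at extra sites reserved for planting. The
methylation landscape is high (~0.85) in background and low (~0.10) in
constitutive islands; planted condition-specific UMRs, LMRs and path DMRs
modify the per-condition mean level of selected islands. Read counts are
beta-binomial: coverage ~ Poisson(mean_coverage), methylated reads ~
BetaBinomial(coverage, mu, dispersion), with a small replicate-level jitter
on mu, so replicate overdispersion is realistic and differential calling is
non-trivial. The whole dataset is a pure function of the seed and config.

A separate :func:`dmr_benchmark` builds a focused two-group scenario (uniform
CpG spacing, 200 planted DMRs of known extent) for scoring DMR recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from .core import GeneModel, GenomicInterval, ValidationError
from . import intervalops
from .annotation import FeatureMap, build_feature_map
from .dmr import DMR, PATHS
from .io import DEGRecord
from .methylome import ChromSites, CpGMethylome
from .segmentation import MethylRegion

CONDITIONS: Tuple[Tuple[str, str], ...] = (
    ("epithelium", "E14.5"),
    ("epithelium", "P0.5"),
    ("fiber", "E14.5"),
    ("fiber", "P0.5"),
)


@dataclass
class SimulationConfig:
    n_chroms: int = 3
    chrom_size: int = 2_000_000
    background_spacing: int = 100      # mean bp between background CpGs
    island_spacing: int = 10           # mean bp between island CpGs
    n_genes: int = 150
    n_replicates: int = 3
    mean_coverage: float = 20.0
    dispersion: float = 0.05           # beta-binomial rho in (0, 1)
    replicate_jitter_sd: float = 0.02  # SD of replicate-level shift on mu
    baseline_meth: float = 0.85
    island_meth: float = 0.10
    umr_meth: float = 0.05
    lmr_meth: float = 0.35
    dmr_delta: float = 0.40
    n_umrs_per_condition: int = 30
    n_lmrs_per_condition: int = 20
    n_dmrs_per_path: int = 25
    n_promoter_dmrs_per_path: int = 12
    n_fiber_lineage_dmrs: int = 15
    deg_correlation: float = 1.0       # P(promoter hypo-opening DMAR gene is "up")
    dar_fraction: float = 0.8          # fraction of planted DMRs with a matched DAR

    def __post_init__(self) -> None:
        if not (0.0 < self.dispersion < 1.0):
            raise ValidationError("dispersion must lie in (0, 1)")


@dataclass
class SyntheticGenome:
    chrom_sizes: Dict[str, int]
    cpg_positions: Dict[str, np.ndarray]
    genes: List[GeneModel]
    promoter_islands: List[GenomicInterval]
    extra_islands: List[GenomicInterval]

    def n_cpgs(self) -> int:
        return sum(len(p) for p in self.cpg_positions.values())


@dataclass
class SyntheticTruth:
    """Planted ground truth sufficient to score every pipeline stage."""

    genome: SyntheticGenome
    planted_umrs: Dict[Tuple[str, str], List[MethylRegion]]
    planted_lmrs: Dict[Tuple[str, str], List[MethylRegion]]
    planted_dmrs: Dict[str, List[DMR]]
    atac_peaks: Dict[Tuple[str, str], List[GenomicInterval]] = field(default_factory=dict)
    dars: Dict[str, Dict[str, List[GenomicInterval]]] = field(default_factory=dict)
    h33_peaks: Dict[str, List[List[GenomicInterval]]] = field(default_factory=dict)
    tf_peaks: List[GenomicInterval] = field(default_factory=list)
    deg_records: List[DEGRecord] = field(default_factory=list)
    seed: int = 0


def _geometric_positions(rng, size: int, mean_spacing: float, start: int, end: int):
    n_expect = int((end - start) / mean_spacing * 1.3) + 10
    gaps = rng.geometric(1.0 / mean_spacing, size=n_expect)
    pos = start + np.cumsum(gaps)
    return pos[pos < end]


def generate_genome(
    n_chroms: int = 3,
    chrom_size: int = 2_000_000,
    background_spacing: int = 100,
    island_spacing: int = 10,
    n_genes: int = 150,
    n_extra_islands: int = 260,
    seed: int = 0,
) -> SyntheticGenome:
    """Chromosome sizes, two-state CpG positions, and non-overlapping gene models."""
    if min(n_chroms, chrom_size, background_spacing, island_spacing, n_genes) <= 0:
        raise ValidationError("genome parameters must be positive")
    rng = np.random.default_rng(seed)
    chrom_sizes = {f"chr{i + 1}": chrom_size for i in range(n_chroms)}
    chroms = list(chrom_sizes)

    genes: List[GeneModel] = []
    per_chrom = n_genes // n_chroms + (n_genes % n_chroms > 0)
    gid = 0
    for chrom in chroms:
        slot = chrom_size // (per_chrom + 1)
        for k in range(per_chrom):
            if gid >= n_genes:
                break
            anchor = slot * (k + 1) + int(rng.integers(-slot // 6, slot // 6))
            length = int(rng.integers(5_000, 20_000))
            tx_start = max(6_000, min(anchor, chrom_size - length - 6_000))
            tx_end = tx_start + length
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(3, 9))
            cuts = np.sort(rng.choice(np.arange(200, length - 200, 50), size=2 * n_exons, replace=False))
            exon_starts = tuple(int(tx_start + cuts[2 * i]) for i in range(n_exons))
            exon_ends = tuple(int(tx_start + cuts[2 * i + 1]) for i in range(n_exons))
            coding = rng.random() < 0.8
            if coding and n_exons >= 2:
                cds_start = exon_starts[0] + (exon_ends[0] - exon_starts[0]) // 2
                cds_end = exon_starts[-1] + (exon_ends[-1] - exon_starts[-1]) // 2
                cds = (cds_start, max(cds_end, cds_start + 50))
            else:
                cds = (None, None)
            genes.append(
                GeneModel(f"gene{gid:04d}", chrom, strand, tx_start, tx_end,
                          cds[0], cds[1], exon_starts, exon_ends)
            )
            gid += 1

    promoter_islands = []
    for g in genes:
        tss = g.tx_start if g.strand == "+" else g.tx_end
        promoter_islands.append(
            GenomicInterval(g.chrom, max(0, tss - 300), min(chrom_size, tss + 700))
        )

    occupied = intervalops.merge(
        promoter_islands
        + [GenomicInterval(g.chrom, g.tx_start, g.tx_end) for g in genes]
    )
    extra_islands: List[GenomicInterval] = []
    tries = 0
    while len(extra_islands) < n_extra_islands and tries < 50 * n_extra_islands:
        tries += 1
        chrom = chroms[int(rng.integers(0, n_chroms))]
        length = int(rng.integers(200, 1200))
        start = int(rng.integers(1000, chrom_size - length - 1000))
        cand = GenomicInterval(chrom, start, start + length)
        if not any(cand.overlaps(iv) for iv in occupied if iv.chrom == chrom) and not any(
            cand.overlaps(iv) for iv in extra_islands if iv.chrom == chrom
        ):
            extra_islands.append(cand)

    island_by_chrom = intervalops.by_chrom(promoter_islands + extra_islands)
    cpg_positions: Dict[str, np.ndarray] = {}
    for chrom in chroms:
        bg = _geometric_positions(rng, 0, background_spacing, 0, chrom_size)
        island_pos = [
            _geometric_positions(rng, 0, island_spacing, iv.start, iv.end)
            for _, iv in island_by_chrom.get(chrom, [])
        ]
        allpos = np.unique(np.concatenate([bg] + island_pos)) if island_pos else np.unique(bg)
        if len(allpos) == 0:
            raise ValidationError("CpG density parameters produced zero CpGs")
        cpg_positions[chrom] = allpos.astype(np.int64)
    return SyntheticGenome(chrom_sizes, cpg_positions, genes, promoter_islands, extra_islands)


def _region_cpg_count(genome: SyntheticGenome, iv: GenomicInterval) -> int:
    pos = genome.cpg_positions[iv.chrom]
    return int(np.searchsorted(pos, iv.end) - np.searchsorted(pos, iv.start))


def _mu_matrix(
    genome: SyntheticGenome, cfg: SimulationConfig, rng
) -> Tuple[Dict[Tuple[str, str], Dict[str, np.ndarray]], SyntheticTruth]:
    """Per-condition true methylation level per CpG, plus the planted truth."""
    mu: Dict[Tuple[str, str], Dict[str, np.ndarray]] = {
        cond: {
            chrom: np.full(len(pos), cfg.baseline_meth)
            for chrom, pos in genome.cpg_positions.items()
        }
        for cond in CONDITIONS
    }

    def set_region(cond, iv: GenomicInterval, level: float) -> None:
        pos = genome.cpg_positions[iv.chrom]
        lo, hi = np.searchsorted(pos, (iv.start, iv.end))
        mu[cond][iv.chrom][lo:hi] = level

    # constitutive unmethylated promoters (all conditions)
    for iv in genome.promoter_islands:
        for cond in CONDITIONS:
            set_region(cond, iv, cfg.island_meth)

    primary_paths = ["Epi(dif)", "EpiFiber(dif)", "Fiber(dif)"]
    planted_dmrs: Dict[str, List[DMR]] = {p: [] for p in PATHS}
    high = cfg.baseline_meth - 0.20       # 0.65: early level at DMR regions
    low = high - cfg.dmr_delta            # advanced level for hypo DMRs

    # promoters that demethylate along a path: methylated early, hypo advanced
    n_prom = cfg.n_promoter_dmrs_per_path * len(primary_paths)
    prom_idx = rng.choice(len(genome.genes), size=min(n_prom, len(genome.genes)), replace=False)
    for j, gi in enumerate(prom_idx):
        path = primary_paths[j % len(primary_paths)]
        _early, advanced = PATHS[path]
        iv = genome.promoter_islands[gi]
        for cond in CONDITIONS:
            set_region(cond, iv, low if cond == advanced else high)
        planted_dmrs[path].append(
            DMR(iv, path, "hypo", _region_cpg_count(genome, iv), -cfg.dmr_delta, 0.0)
        )

    pool = [iv for iv in genome.extra_islands]
    rng.shuffle(pool)
    big = [iv for iv in pool if _region_cpg_count(genome, iv) > 40]
    small = [iv for iv in pool if 8 <= _region_cpg_count(genome, iv) < 30]

    def take(lst, n):
        out = lst[:n]
        del lst[:n]
        return out

    planted_umrs: Dict[Tuple[str, str], List[MethylRegion]] = {c: [] for c in CONDITIONS}
    planted_lmrs: Dict[Tuple[str, str], List[MethylRegion]] = {c: [] for c in CONDITIONS}
    for cond in CONDITIONS:
        for iv in take(big, cfg.n_umrs_per_condition):
            set_region(cond, iv, cfg.umr_meth)
            planted_umrs[cond].append(
                MethylRegion(iv, _region_cpg_count(genome, iv), cfg.umr_meth, "UMR")
            )
        for iv in take(small, cfg.n_lmrs_per_condition):
            set_region(cond, iv, cfg.lmr_meth)
            planted_lmrs[cond].append(
                MethylRegion(iv, _region_cpg_count(genome, iv), cfg.lmr_meth, "LMR")
            )

    for path in primary_paths:
        early, advanced = PATHS[path]
        for i, iv in enumerate(take(big, cfg.n_dmrs_per_path)):
            hyper = i % 5 == 4  # one in five planted DMRs gains methylation
            lv_early, lv_adv = (low, high) if hyper else (high, low)
            for cond in CONDITIONS:
                set_region(cond, iv, lv_adv if cond == advanced else lv_early)
            n = _region_cpg_count(genome, iv)
            delta = lv_adv - lv_early
            planted_dmrs[path].append(
                DMR(iv, path, "hyper" if delta > 0 else "hypo", n, delta, 0.0)
            )
    # fiber-lineage regions losing methylation at both steps: DMRs in
    # EpiFiber(dif), Fiber(dif) and the direct E14.5-epi -> P0.5-fiber contrast
    direct = "Epi(E14.5)->Fiber(P0.5)"
    for iv in take(big, cfg.n_fiber_lineage_dmrs):
        levels = {
            ("epithelium", "E14.5"): 0.75,
            ("epithelium", "P0.5"): 0.75,
            ("fiber", "E14.5"): 0.40,
            ("fiber", "P0.5"): 0.05,
        }
        for cond, lv in levels.items():
            set_region(cond, iv, lv)
        n = _region_cpg_count(genome, iv)
        planted_dmrs["EpiFiber(dif)"].append(DMR(iv, "EpiFiber(dif)", "hypo", n, -0.35, 0.0))
        planted_dmrs["Fiber(dif)"].append(DMR(iv, "Fiber(dif)", "hypo", n, -0.35, 0.0))
        planted_dmrs[direct].append(DMR(iv, direct, "hypo", n, -0.70, 0.0))

    truth = SyntheticTruth(genome, planted_umrs, planted_lmrs, planted_dmrs)
    return mu, truth


def _beta_binomial(rng, coverage: np.ndarray, mu: np.ndarray, rho: float) -> np.ndarray:
    m = np.clip(mu, 1e-3, 1 - 1e-3)
    a = m * (1.0 - rho) / rho
    b = (1.0 - m) * (1.0 - rho) / rho
    p = rng.beta(a, b)
    return rng.binomial(coverage, p)


def generate_methylomes(
    genome: SyntheticGenome, cfg: SimulationConfig, seed: int
) -> Tuple[Dict[Tuple[str, str], List[CpGMethylome]], SyntheticTruth]:
    """Beta-binomial replicate methylomes for the four conditions, plus truth."""
    rng = np.random.default_rng(seed)
    mu, truth = _mu_matrix(genome, cfg, rng)
    truth.seed = seed
    methylomes: Dict[Tuple[str, str], List[CpGMethylome]] = {}
    for cond in CONDITIONS:
        comp, stage = cond
        reps = []
        for r in range(1, cfg.n_replicates + 1):
            chroms = {}
            for chrom, pos in genome.cpg_positions.items():
                base = mu[cond][chrom]
                jitter = rng.normal(0.0, cfg.replicate_jitter_sd, size=len(pos))
                level = np.clip(base + jitter, 0.0, 1.0)
                cov = rng.poisson(cfg.mean_coverage, size=len(pos))
                n_meth = _beta_binomial(rng, cov, level, cfg.dispersion)
                chroms[chrom] = ChromSites(pos.copy(), n_meth.astype(np.int64),
                                           (cov - n_meth).astype(np.int64))
            reps.append(
                CpGMethylome(f"{comp}_{stage}_rep{r}", f"{comp}:{stage}", r, chroms)
            )
        methylomes[cond] = reps
    return methylomes, truth


def generate_peaks_dars_degs(
    truth: SyntheticTruth, cfg: SimulationConfig, seed: int
) -> SyntheticTruth:
    """ATAC peaks, DARs, replicate ChIP peaks, TF peaks and a DEG table.

    DARs mirror a configurable fraction of planted DMRs (hypomethylation
    pairs with opening chromatin, hypermethylation with closing); the DEG
    direction of genes whose promoters carry a hypo-opening DMAR follows the
    ``deg_correlation`` knob: probability ``k`` of being upregulated, else an
    independent random assignment.
    """
    rng = np.random.default_rng(seed)
    genome = truth.genome
    fmap = build_feature_map(genome.genes, genome.chrom_sizes)

    expressed = {
        g.gene_id: rng.random() < 0.7 for g in genome.genes
    }  # expressed in every condition; the rest are condition-variable
    atac: Dict[Tuple[str, str], List[GenomicInterval]] = {c: [] for c in CONDITIONS}
    for g in genome.genes:
        tss = g.tx_start if g.strand == "+" else g.tx_end
        peak = GenomicInterval(
            g.chrom,
            max(0, tss - 400),
            min(genome.chrom_sizes[g.chrom], tss + 400),
        )
        conds = (
            list(CONDITIONS)
            if expressed[g.gene_id]
            else [CONDITIONS[int(rng.integers(0, 4))]]
        )
        for cond in conds:
            atac[cond].append(peak)
    for cond in CONDITIONS:
        for _ in range(40):  # distal accessible sites
            chrom = list(genome.chrom_sizes)[int(rng.integers(0, len(genome.chrom_sizes)))]
            start = int(rng.integers(0, genome.chrom_sizes[chrom] - 600))
            atac[cond].append(GenomicInterval(chrom, start, start + 600))

    dars: Dict[str, Dict[str, List[GenomicInterval]]] = {}
    for path, dmrs in truth.planted_dmrs.items():
        opening, closing = [], []
        early, advanced = PATHS[path]
        for d in dmrs:
            if rng.random() > cfg.dar_fraction:
                continue
            dar = GenomicInterval(
                d.interval.chrom,
                max(0, d.interval.start - 100),
                min(genome.chrom_sizes[d.interval.chrom], d.interval.end + 100),
            )
            if d.direction == "hypo":
                opening.append(dar)
                atac[advanced].append(dar)
            else:
                closing.append(dar)
                atac[early].append(dar)
        dars[path] = {"opening": opening, "closing": closing}

    for cond in CONDITIONS:
        atac[cond] = intervalops.merge(atac[cond])

    h33: Dict[str, List[List[GenomicInterval]]] = {"epithelium": [], "fiber": []}
    for comp in ("epithelium", "fiber"):
        body_peaks = []
        for g in genome.genes:
            keep = expressed[g.gene_id] or rng.random() < (0.6 if comp == "fiber" else 0.3)
            if keep:
                body_peaks.append(g)
        for _rep in range(2):
            peaks = []
            for g in body_peaks:
                jit = int(rng.integers(-50, 51))
                peaks.append(
                    GenomicInterval(
                        g.chrom,
                        max(0, g.tx_start + jit),
                        min(genome.chrom_sizes[g.chrom], g.tx_end + int(rng.integers(-50, 51))),
                    )
                )
            h33[comp].append(intervalops.merge(peaks))

    merged_atac = intervalops.merge(
        [iv for cond in CONDITIONS for iv in atac[cond]]
    )
    tf_peaks: List[GenomicInterval] = []
    open_sites = [iv for iv in merged_atac if len(iv) >= 300]
    rng.shuffle(open_sites)
    for iv in open_sites[:90]:
        mid = (iv.start + iv.end) // 2
        tf_peaks.append(GenomicInterval(iv.chrom, max(0, mid - 150), mid + 150))
    closed_space = intervalops.complement(merged_atac, genome.chrom_sizes)
    deserts = [iv for iv in closed_space if len(iv) > 2000]
    rng.shuffle(deserts)
    for iv in deserts[:60]:
        mid = (iv.start + iv.end) // 2
        tf_peaks.append(GenomicInterval(iv.chrom, mid - 150, mid + 150))

    # DEG directions correlated with promoter hypomethylation + opening
    from .integration import call_dmars  # local import to avoid a cycle

    linked_up: Dict[str, set] = {}
    for path, dmrs in truth.planted_dmrs.items():
        for dmar in call_dmars(dmrs, dars[path], fmap):
            if (
                dmar.dmr.direction == "hypo"
                and dmar.dar_direction == "opening"
                and "proximal_promoter" in dmar.features
            ):
                linked_up.setdefault(path, set()).update(dmar.genes)
    all_linked = set().union(*linked_up.values()) if linked_up else set()
    degs: List[DEGRecord] = []
    for g in genome.genes:
        if g.gene_id in all_linked and rng.random() < cfg.deg_correlation:
            lfc, padj = float(rng.normal(2.5, 0.5)), 1e-5
        elif rng.random() < 0.10:
            lfc, padj = float(rng.normal(0, 2.0)), 1e-3
        else:
            lfc, padj = float(rng.normal(0, 0.3)), float(rng.uniform(0.2, 1.0))
        direction = "up" if (padj < 0.05 and lfc > 0) else "down" if (padj < 0.05 and lfc < 0) else "none"
        degs.append(DEGRecord(g.gene_id, lfc, padj, direction))

    truth.atac_peaks = atac
    truth.dars = dars
    truth.h33_peaks = h33
    truth.tf_peaks = tf_peaks
    truth.deg_records = degs
    return truth


@dataclass
class SyntheticStudy:
    """A full synthetic dataset: truth, methylomes, peaks, DEGs."""

    truth: SyntheticTruth
    methylomes: Dict[Tuple[str, str], List[CpGMethylome]]
    config: SimulationConfig

    @property
    def genome(self) -> SyntheticGenome:
        return self.truth.genome

    def feature_map(self) -> FeatureMap:
        return build_feature_map(self.genome.genes, self.genome.chrom_sizes)


def generate_study(seed: int, config: Optional[SimulationConfig] = None) -> SyntheticStudy:
    """The full synthetic study: genome, 4 x 3 methylomes, peaks, DARs, DEGs."""
    cfg = config or SimulationConfig()
    genome = generate_genome(
        cfg.n_chroms, cfg.chrom_size, cfg.background_spacing,
        cfg.island_spacing, cfg.n_genes, seed=seed,
    )
    methylomes, truth = generate_methylomes(genome, cfg, seed + 1)
    truth = generate_peaks_dars_degs(truth, cfg, seed + 2)
    return SyntheticStudy(truth, methylomes, cfg)


def write_study(study: "SyntheticStudy", outdir) -> None:
    """Write a study as standard on-disk formats plus ground-truth files.

    Layout: ``chrom.sizes``, ``genes.bed12``, per-sample
    ``calls/<sample>.bedgraph``, per-condition ``atac_*.bed``, per-path
    ``dars_<path>_<direction>.bed``, per-compartment/replicate ``h33_*.bed``,
    ``tf_peaks.bed``, ``deg.tsv`` and ``truth/`` BEDs of planted regions.
    """
    from pathlib import Path

    from . import io as _io

    out = Path(outdir)
    (out / "calls").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    genome = study.genome
    _io.write_chrom_sizes(genome.chrom_sizes, out / "chrom.sizes")
    _io.write_gene_models(genome.genes, out / "genes.bed12")
    for cond, reps in study.methylomes.items():
        for m in reps:
            calls = [
                (chrom, int(p), "+", int(nm), int(nu))
                for chrom, s in m.chroms.items()
                for p, nm, nu in zip(s.pos, s.n_meth, s.n_unmeth)
            ]
            _io.write_cpg_calls(calls, out / "calls" / f"{m.sample_id}.bedgraph")
    for cond, peaks in study.truth.atac_peaks.items():
        _io.write_bed(peaks, out / f"atac_{cond[0]}_{cond[1]}.bed")
    safe = {p: p.replace("(", "").replace(")", "").replace("->", "_to_").replace(".", "") for p in study.truth.dars}
    for path, dd in study.truth.dars.items():
        for direction, ivs in dd.items():
            _io.write_bed(ivs, out / f"dars_{safe[path]}_{direction}.bed")
    for comp, reps in study.truth.h33_peaks.items():
        for i, peaks in enumerate(reps, 1):
            _io.write_bed(peaks, out / f"h33_{comp}_rep{i}.bed")
    _io.write_bed(study.truth.tf_peaks, out / "tf_peaks.bed")
    _io.write_deg_table(study.truth.deg_records, out / "deg.tsv")
    for cond in CONDITIONS:
        for label, regions in (("umrs", study.truth.planted_umrs[cond]),
                               ("lmrs", study.truth.planted_lmrs[cond])):
            _io.write_bed(
                [r.interval for r in regions],
                out / "truth" / f"{label}_{cond[0]}_{cond[1]}.bed",
            )
    for path, dmrs in study.truth.planted_dmrs.items():
        _io.write_bed(
            [
                GenomicInterval(d.interval.chrom, d.interval.start, d.interval.end,
                                name=d.direction, score=d.mean_diff)
                for d in dmrs
            ],
            out / "truth" / f"dmrs_{safe[path]}.bed",
        )


def dmr_benchmark(
    seed: int,
    n_dmrs: int = 200,
    delta: float = 0.40,
    dmr_span_bp: int = 3_000,
    spacing: int = 30,
    n_chroms: int = 4,
    chrom_size: int = 3_500_000,
    n_replicates: int = 3,
    mean_coverage: float = 20.0,
    dispersion: float = 0.05,
    replicate_jitter_sd: float = 0.02,
    planted: bool = True,
) -> Tuple[List[CpGMethylome], List[CpGMethylome], List[DMR]]:
    """A focused two-group scenario for scoring DMR recovery.

    CpGs are uniformly dense (mean spacing ``spacing`` bp) so planted regions
    are wider than the smoothing window and their boundaries are resolvable.
    Half the planted DMRs lose methylation from group A to group B, half
    gain. With ``planted=False`` the same genome is generated with no
    methylation differences (the matched null).

    Returns ``(group_a, group_b, truth_dmrs)`` with truth oriented A -> B.
    """
    rng = np.random.default_rng(seed)
    chrom_sizes = {f"chr{i + 1}": chrom_size for i in range(n_chroms)}
    positions = {
        chrom: _geometric_positions(rng, 0, spacing, 0, chrom_size)
        for chrom in chrom_sizes
    }
    mu_a = {c: np.full(len(p), 0.65) for c, p in positions.items()}
    mu_b = {c: np.full(len(p), 0.65) for c, p in positions.items()}

    truth: List[DMR] = []
    slots_per_chrom = n_dmrs // n_chroms + 1
    slot = chrom_size // (slots_per_chrom + 1)
    k = 0
    for chrom in chrom_sizes:
        for j in range(slots_per_chrom):
            if k >= n_dmrs:
                break
            start = slot * (j + 1) + int(rng.integers(-slot // 8, slot // 8))
            iv = GenomicInterval(chrom, start, start + dmr_span_bp)
            lo, hi = np.searchsorted(positions[chrom], (iv.start, iv.end))
            if hi - lo < 10:
                continue
            hyper = k % 2 == 1
            if planted:
                if hyper:
                    mu_a[chrom][lo:hi] = 0.65 - delta
                else:
                    mu_b[chrom][lo:hi] = 0.65 - delta
            truth.append(
                DMR(iv, "benchmark", "hyper" if hyper else "hypo",
                    int(hi - lo), delta if hyper else -delta, 0.0)
            )
            k += 1

    def make_group(mu: Mapping[str, np.ndarray], label: str) -> List[CpGMethylome]:
        group = []
        for r in range(1, n_replicates + 1):
            chroms = {}
            for chrom, pos in positions.items():
                level = np.clip(
                    mu[chrom] + rng.normal(0.0, replicate_jitter_sd, size=len(pos)),
                    0.0, 1.0,
                )
                cov = rng.poisson(mean_coverage, size=len(pos))
                n_meth = _beta_binomial(rng, cov, level, dispersion)
                chroms[chrom] = ChromSites(
                    pos.copy(), n_meth.astype(np.int64), (cov - n_meth).astype(np.int64)
                )
            group.append(CpGMethylome(f"{label}_rep{r}", label, r, chroms))
        return group

    return make_group(mu_a, "groupA"), make_group(mu_b, "groupB"), truth
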