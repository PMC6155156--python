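"""Self-consistent synthetic genomes, annotations, peaks, coverage,
methylation and expression tables, plus a two-population contamination
mixer.

Everything is planted constructively (not rejection-sampled), so the truth
record scores every downstream estimate exactly: the planted fraction of
peaks in promoter windows is hit exactly, H/PH/TS gene labels are chosen up
front and drive both peak placement and coverage, CGI sequences are built
token-by-token to realize a prescribed o/e ratio, high-expression genes are
suppressed after the configured stage, and peak-bearing CGIs receive low
methylation. All randomness flows through one seeded generator.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals_io import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    Peak,
    PeakSet,
    StructuralError,
    write_bed,
    write_bedgraph,
    write_genes,
    write_totals,
)
from .cgi_analysis import CpGIsland, write_cgis
from .integrative_epigenomics import MethylationRecord, write_methylation, write_expression
from .mixture_model import MixtureSpec

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "CapacityError",
    "generate_dataset",
    "mix_total_sperm",
]

DEFAULT_STAGES = ("oocyte", "zygote", "2cell", "4cell", "8cell", "morula", "ICM")


class CapacityError(ValueError):
    """Requested peaks/genes do not fit in the configured genome."""


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_chromosomes: int = 3          # last chromosome is chrX at half gene density
    chrom_length: int = 600_000
    n_genes: int = 60
    promoter_peak_fraction: float = 0.65
    cgi_oe_high_mean: float = 1.2
    cgi_oe_low_mean: float = 0.55
    hrcs_peak_count: int = 40
    total_peak_count: int = 60
    hruncs_fraction: float = 0.10
    histone_ratio_un_vs_c: float = 41.0
    stages: tuple[str, ...] = DEFAULT_STAGES
    fpkm_threshold: float = 10.0
    # layout / signal knobs
    bin_width: int = 50
    promoter_flank: int = 1000
    flank_extent: int = 5000
    sex_gene_density: float = 0.5
    background_lam: float = 2.0
    hrcs_peak_height: float = 30.0
    ph_multiple: float = 5.0        # PH promoter coverage = ph_multiple * background
    ph_fraction: float = 0.5        # of total-only target genes planted as PH
    hruncs_block_halfwidth: int = 1500  # breadth of contaminant blocks (unquantified upstream; exposed)
    cgi_length: int = 400
    fpkm_sigma: float = 0.4
    suppress_after_stage: str = "4cell"
    meth_site_fraction: float = 0.05  # subsampling of CG sites outside CGIs
    repeats_per_chrom: int = 8

    def validate(self) -> None:
        for name in ("promoter_peak_fraction", "hruncs_fraction", "sex_gene_density",
                     "ph_fraction", "meth_site_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.hrcs_peak_count < 0 or self.total_peak_count < 0:
            raise ValueError("peak counts must be non-negative")
        if self.total_peak_count < self.hrcs_peak_count:
            raise ValueError("total_peak_count must be >= hrcs_peak_count")
        if self.n_chromosomes < 1 or self.n_genes < 1:
            raise ValueError("need at least one chromosome and one gene")
        if self.chrom_length % self.bin_width:
            raise ValueError("chrom_length must be a multiple of bin_width")
        if self.chrom_length <= 2 * (self.flank_extent + self.promoter_flank) + 20_000:
            raise ValueError("chrom_length too small for the window sizes used")
        if self.histone_ratio_un_vs_c < 0:
            raise ValueError("histone_ratio_un_vs_c must be non-negative")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("stage labels must be unique")


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    repeats: list[GenomicInterval]
    cgis: list[CpGIsland]
    peaks: dict[str, PeakSet]
    coverage: dict[str, CoverageTrack]
    methylation: dict[str, list[MethylationRecord]]
    expression: pd.DataFrame
    truth: dict = field(default_factory=dict)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Serialize every component as plain text; deterministic byte-wise."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        fasta = outdir / "genome.fa"
        with open(fasta, "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        paths["genome"] = fasta

        write_genes(self.genes, outdir / "genes.tsv")
        paths["genes"] = outdir / "genes.tsv"
        write_bed(self.repeats, outdir / "repeats.bed")
        paths["repeats"] = outdir / "repeats.bed"

        cgi_path = outdir / "cgis.bed"
        write_cgis(self.cgis, cgi_path)
        paths["cgis"] = cgi_path

        for label, ps in sorted(self.peaks.items()):
            p = outdir / f"peaks_{label}.bed"
            write_bed(ps, p)
            paths[f"peaks_{label}"] = p
        totals = {}
        for label, track in sorted(self.coverage.items()):
            p = outdir / f"coverage_{label}.bedGraph"
            write_bedgraph(track, p)
            paths[f"coverage_{label}"] = p
            totals[label] = track.total_mapped_reads
        write_totals(totals, outdir / "totals.tsv")
        paths["totals"] = outdir / "totals.tsv"

        for label, records in sorted(self.methylation.items()):
            p = outdir / f"methylation_{label}.tsv"
            write_methylation(records, p)
            paths[f"methylation_{label}"] = p

        write_expression(self.expression, outdir / "expression.tsv")
        paths["expression"] = outdir / "expression.tsv"

        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
        paths["truth"] = outdir / "truth.json"
        return paths


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _chrom_names(n: int) -> list[str]:
    if n == 1:
        return ["chr1"]
    return [f"chr{i}" for i in range(1, n)] + ["chrX"]


def _allocate_genes(cfg: GeneratorConfig) -> dict[str, int]:
    """Largest-remainder allocation; chrX gets ``sex_gene_density`` weight."""
    names = _chrom_names(cfg.n_chromosomes)
    weights = np.ones(len(names))
    if names[-1] == "chrX":
        weights[-1] = cfg.sex_gene_density
    raw = cfg.n_genes * weights / weights.sum()
    counts = np.floor(raw).astype(int)
    remainder = cfg.n_genes - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    return dict(zip(names, (int(c) for c in counts)))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _cgi_sequence(target_oe: float, length: int, gc: float, rng: np.random.Generator) -> str:
    """Build a sequence realizing approximately ``target_oe``.

    Tokens are assembled so no CpG arises at token junctions: "CG" tokens
    carry the dinucleotides, lone C's are padded with an A/T tail, lone G's
    and A/T filler are junction-safe. The realized o/e is then exactly
    n_cpg * L / (n_c * n_g) for the planted counts.
    """
    n_c = n_g = max(2, int(gc * length / 2))
    n_cpg = int(round(target_oe * n_c * n_g / length))
    n_cpg = max(0, min(n_cpg, n_c, n_g))
    core = 2 * n_c + n_g - n_cpg  # CG pairs + padded C's + lone G's
    if core > length:  # very high o/e at high GC; shed lone bases first
        n_c = n_g = max(2, (length + n_cpg) // 3)
        n_cpg = min(n_cpg, n_c)
        core = 2 * n_c + n_g - n_cpg
    at = "AT"
    tokens = (
        ["CG"] * n_cpg
        + ["C" + at[int(rng.integers(2))] for _ in range(n_c - n_cpg)]
        + ["G"] * (n_g - n_cpg)
        + [at[int(rng.integers(2))] for _ in range(length - core)]
    )
    rng.shuffle(tokens)
    seq = "".join(tokens)[:length]
    return seq


def _stage_means(cfg: GeneratorConfig) -> dict[str, dict[str, float]]:
    stages = list(cfg.stages)
    if cfg.suppress_after_stage in stages:
        cut = stages.index(cfg.suppress_after_stage)
    else:
        cut = len(stages) // 2
    means: dict[str, dict[str, float]] = {"H": {}, "PH": {}, "TS": {}, "none": {}}
    for i, stage in enumerate(stages):
        if i <= cut:
            hot = 30.0 - (30.0 - 12.0) * (i / max(1, cut))
        else:
            hot = 1.0
        means["H"][stage] = hot
        means["PH"][stage] = hot
        steady = 20.0 - 6.0 * i / max(1, len(stages) - 1)
        means["TS"][stage] = steady
        means["none"][stage] = steady
    return means


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_genome(length: int, rng: np.random.Generator) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate a full dataset with planted truth; deterministic under seed."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    chrom_names = _chrom_names(cfg.n_chromosomes)
    sizes = {c: cfg.chrom_length for c in chrom_names}

    # --- gene layout -------------------------------------------------------
    per_chrom = _allocate_genes(cfg)
    margin = cfg.flank_extent + cfg.promoter_flank + 4000
    tx_min, tx_max = 2000, 4000
    min_spacing = tx_max + 2 * (cfg.flank_extent + cfg.promoter_flank) + 2000

    genes: list[GeneModel] = []
    slot_starts: dict[str, list[int]] = {c: [] for c in chrom_names}
    gid = 0
    for chrom in chrom_names:
        n_on = per_chrom[chrom]
        if n_on == 0:
            continue
        usable = cfg.chrom_length - 2 * margin
        spacing = usable // n_on
        if spacing < min_spacing:
            raise CapacityError(
                f"{n_on} genes do not fit on {chrom} "
                f"({cfg.chrom_length} bp; need spacing >= {min_spacing})"
            )
        for i in range(n_on):
            anchor = margin + i * spacing
            slot_starts[chrom].append(anchor)
            jitter = int(rng.integers(0, spacing - min_spacing + 1))
            tx_len = int(rng.integers(tx_min, tx_max + 1))
            tx_start = anchor + cfg.flank_extent + cfg.promoter_flank + jitter
            tx_end = tx_start + tx_len
            strand = "+" if rng.integers(2) else "-"
            n_exons = int(rng.integers(2, 5))
            cuts = np.sort(rng.choice(np.arange(1, tx_len), size=2 * n_exons - 2, replace=False))
            bounds = np.concatenate(([0], cuts, [tx_len])) + tx_start
            exons = [(int(bounds[k]), int(bounds[k + 1])) for k in range(0, 2 * n_exons - 1, 2)]
            gid += 1
            genes.append(GeneModel.from_tx(f"gene{gid:04d}", chrom, strand, tx_start, tx_end, exons))

    # --- plant categories and peak placement -------------------------------
    n_prom_hrcs = _round_half_up(cfg.promoter_peak_fraction * cfg.hrcs_peak_count)
    n_prom_total = _round_half_up(cfg.promoter_peak_fraction * cfg.total_peak_count)
    n_prom_total = max(n_prom_total, n_prom_hrcs)
    if n_prom_total > len(genes):
        raise CapacityError(
            f"{n_prom_total} promoter peaks requested but only {len(genes)} genes available"
        )
    gene_order = rng.permutation(len(genes))
    h_genes = [genes[i] for i in gene_order[:n_prom_hrcs]]
    rest = [genes[i] for i in gene_order[n_prom_hrcs:n_prom_total]]
    n_ph = _round_half_up(cfg.ph_fraction * len(rest))
    ph_genes, ts_genes = rest[:n_ph], rest[n_ph:]
    categories = {g.gene_id: "none" for g in genes}
    categories.update({g.gene_id: "H" for g in h_genes})
    categories.update({g.gene_id: "PH" for g in ph_genes})
    categories.update({g.gene_id: "TS" for g in ts_genes})

    def promoter_peak(g: GeneModel, label: str, idx: int) -> Peak:
        a = int(rng.integers(100, 801))
        b = int(rng.integers(100, 801))
        return Peak(g.chrom, g.tss - a, g.tss + b, name=f"{label}_p{idx}",
                    score=10.0, fold_change=10.0, fdr=1e-6)

    # intergenic slots: one near the start of each gene slot (upstream of any
    # promoter window by construction) plus two per chromosome in the margins
    free_slots: list[tuple[str, int]] = []
    for chrom in chrom_names:
        for anchor in slot_starts[chrom]:
            free_slots.append((chrom, anchor + 100))
        free_slots.append((chrom, 2000))
        free_slots.append((chrom, cfg.chrom_length - 3000))

    n_free_hrcs = cfg.hrcs_peak_count - n_prom_hrcs
    n_free_total = cfg.total_peak_count - n_prom_total
    if max(n_free_hrcs, n_free_total) > len(free_slots):
        raise CapacityError(
            f"{max(n_free_hrcs, n_free_total)} non-promoter peaks requested but only "
            f"{len(free_slots)} intergenic slots available"
        )
    slot_perm = rng.permutation(len(free_slots))

    hrcs_peaks: list[Peak] = []
    hrcs_in_promoter: dict[str, bool] = {}
    for i, g in enumerate(h_genes):
        p = promoter_peak(g, "hrcs", i + 1)
        hrcs_peaks.append(p)
        hrcs_in_promoter[p.name] = True
    for j in range(n_free_hrcs):
        chrom, pos = free_slots[slot_perm[j]]
        p = Peak(chrom, pos, pos + 400, name=f"hrcs_d{j + 1}",
                 score=8.0, fold_change=8.0, fdr=1e-4)
        hrcs_peaks.append(p)
        hrcs_in_promoter[p.name] = False

    total_peaks: list[Peak] = []
    total_in_promoter: dict[str, bool] = {}
    total_promoter_peak_by_gene: dict[str, Peak] = {}
    for i, g in enumerate(h_genes + ph_genes + ts_genes):
        p = promoter_peak(g, "total", i + 1)
        total_peaks.append(p)
        total_in_promoter[p.name] = True
        total_promoter_peak_by_gene[g.gene_id] = p
    for j in range(n_free_total):
        chrom, pos = free_slots[slot_perm[j]]  # reuse HRCS slots first -> overlap
        p = Peak(chrom, pos + 50, pos + 450, name=f"total_d{j + 1}",
                 score=8.0, fold_change=8.0, fdr=1e-4)
        total_peaks.append(p)
        total_in_promoter[p.name] = False

    peaks = {
        "hrcs": PeakSet("hrcs", hrcs_peaks),
        "total": PeakSet("total", total_peaks),
    }

    # --- genome sequence and CGIs ------------------------------------------
    genome_arrays = {c: _random_genome(cfg.chrom_length, rng) for c in chrom_names}
    cgis: list[CpGIsland] = []
    cgi_oe_truth: dict[str, float] = {}
    half_cgi = cfg.cgi_length // 2
    for g in genes:
        target = (
            cfg.cgi_oe_high_mean if categories[g.gene_id] == "H" else cfg.cgi_oe_low_mean
        )
        target = float(np.clip(rng.normal(target, 0.08), 0.2, 1.8))
        seq = _cgi_sequence(target, cfg.cgi_length, 0.6, rng)
        start = g.tss - half_cgi
        genome_arrays[g.chrom][start : start + cfg.cgi_length] = np.frombuffer(
            seq.encode(), dtype=np.uint8
        )
        iv = GenomicInterval(g.chrom, start, start + cfg.cgi_length,
                             name=f"cgi_{g.gene_id}")
        cgi = CpGIsland.from_sequence(iv, seq)
        cgis.append(cgi)
        cgi_oe_truth[g.gene_id] = cgi.oe_ratio
    genome = {c: arr.tobytes().decode("ascii") for c, arr in genome_arrays.items()}

    # --- repeats ------------------------------------------------------------
    repeats: list[GenomicInterval] = []
    for chrom in chrom_names:
        for j in range(cfg.repeats_per_chrom):
            pos = int(rng.integers(0, cfg.chrom_length - 2000))
            length = int(rng.integers(500, 2001))
            repeats.append(GenomicInterval(chrom, pos, pos + length,
                                           name=f"rep_{chrom}_{j + 1}"))

    # --- coverage tracks ----------------------------------------------------
    n_bins = cfg.chrom_length // cfg.bin_width

    def _background() -> dict[str, np.ndarray]:
        return {c: rng.poisson(cfg.background_lam, size=n_bins).astype(float)
                for c in chrom_names}

    def _add_signal(counts: dict[str, np.ndarray], iv: GenomicInterval, height: float) -> None:
        lo = iv.start // cfg.bin_width
        hi = -(-iv.end // cfg.bin_width)
        arr = counts[iv.chrom]
        arr[max(0, lo) : min(len(arr), hi)] += height

    hrcs_counts = _background()
    for p in hrcs_peaks:
        _add_signal(hrcs_counts, p, cfg.hrcs_peak_height)
    for g in ph_genes:  # moderate signal, no peak: drives the PH call
        _add_signal(hrcs_counts, total_promoter_peak_by_gene[g.gene_id],
                    (cfg.ph_multiple - 1.0) * cfg.background_lam)
    hrcs_track = CoverageTrack(cfg.bin_width, hrcs_counts,
                               sum(v.sum() for v in hrcs_counts.values()))

    input_counts = _background()
    input_track = CoverageTrack(cfg.bin_width, input_counts,
                                sum(v.sum() for v in input_counts.values()))

    hruncs_counts = _background()
    for _ in range(3 * len(chrom_names)):  # broad distal contaminant blocks
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        pos = int(rng.integers(0, cfg.chrom_length - 2 * cfg.hruncs_block_halfwidth))
        block = GenomicInterval(chrom, pos, pos + 2 * cfg.hruncs_block_halfwidth)
        _add_signal(hruncs_counts, block, 8.0)
    # per-unit-histone shape track: normalize total mass to the purified
    # track's so the mixture's bulk ratio is exactly (1-f) + f*h_un/h_c
    scale = (sum(v.sum() for v in hrcs_counts.values())
             / sum(v.sum() for v in hruncs_counts.values()))
    hruncs_counts = {c: v * scale for c, v in hruncs_counts.items()}
    hruncs_track = CoverageTrack(cfg.bin_width, hruncs_counts,
                                 sum(v.sum() for v in hruncs_counts.values()))

    mspec = MixtureSpec(f=cfg.hruncs_fraction, h_c=1.0, h_un=cfg.histone_ratio_un_vs_c)
    total_track = mix_total_sperm(hrcs_track, hruncs_track, mspec)

    coverage = {
        "hrcs": hrcs_track,
        "input": input_track,
        "hruncs": hruncs_track,
        "total": total_track,
    }

    # --- methylation --------------------------------------------------------
    peak_cgi_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    target_ids = {g.gene_id for g in h_genes + ph_genes + ts_genes}
    for cgi in cgis:
        if cgi.interval.name.removeprefix("cgi_") in target_ids:
            peak_cgi_spans[cgi.interval.chrom].append((cgi.interval.start, cgi.interval.end))
    cgi_spans_all: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    for cgi in cgis:
        cgi_spans_all[cgi.interval.chrom].append((cgi.interval.start, cgi.interval.end))

    def _in_spans(positions: np.ndarray, spans: list[tuple[int, int]]) -> np.ndarray:
        if not spans:
            return np.zeros(len(positions), dtype=bool)
        spans = sorted(spans)
        starts = np.array([s for s, _ in spans])
        ends = np.array([e for _, e in spans])
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(positions), dtype=bool)
        out[ok] = positions[ok] < ends[idx[ok]]
        return out

    methylation: dict[str, list[MethylationRecord]] = {"hrcs": [], "swimup": []}
    for chrom in chrom_names:
        arr = genome_arrays[chrom]
        cg_pos = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        in_cgi = _in_spans(cg_pos, cgi_spans_all[chrom])
        keep = in_cgi | (rng.random(len(cg_pos)) < cfg.meth_site_fraction)
        cg_pos = cg_pos[keep]
        low = _in_spans(cg_pos, peak_cgi_spans[chrom])
        levels = np.where(low, rng.beta(0.5, 5.0, size=len(cg_pos)),
                          rng.beta(5.0, 1.5, size=len(cg_pos)))
        for sample in ("hrcs", "swimup"):
            depth = rng.integers(5, 31, size=len(cg_pos))
            meth = rng.binomial(depth, levels)
            methylation[sample].extend(
                MethylationRecord(chrom, int(p), int(m), int(t))
                for p, m, t in zip(cg_pos, meth, depth)
            )

    # --- expression ---------------------------------------------------------
    means = _stage_means(cfg)
    stages = list(cfg.stages)
    expr = np.empty((len(genes), len(stages)))
    for i, g in enumerate(genes):
        mu = means[categories[g.gene_id]]
        for j, stage in enumerate(stages):
            expr[i, j] = rng.lognormal(np.log(mu[stage]), cfg.fpkm_sigma)
    expression = pd.DataFrame(expr, index=[g.gene_id for g in genes], columns=stages)

    truth = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "promoter_peak_fraction": cfg.promoter_peak_fraction,
        "n_promoter_peaks": {"hrcs": n_prom_hrcs, "total": n_prom_total},
        "realized_promoter_fraction": {
            "hrcs": n_prom_hrcs / cfg.hrcs_peak_count if cfg.hrcs_peak_count else None,
            "total": n_prom_total / cfg.total_peak_count if cfg.total_peak_count else None,
        },
        "gene_categories": dict(sorted(categories.items())),
        "peak_in_promoter": {
            "hrcs": hrcs_in_promoter,
            "total": total_in_promoter,
        },
        "mixture": {
            "f": cfg.hruncs_fraction,
            "h_un_over_h_c": cfg.histone_ratio_un_vs_c,
            "bulk_ratio": mspec.bulk_ratio,
        },
        "cgi_oe": dict(sorted(cgi_oe_truth.items())),
        "stage_means": means,
    }

    return SyntheticDataset(
        config=cfg,
        genome=genome,
        genes=genes,
        repeats=repeats,
        cgis=cgis,
        peaks=peaks,
        coverage=coverage,
        methylation=methylation,
        expression=expression,
        truth=truth,
    )


def mix_total_sperm(
    hrcs_track: CoverageTrack,
    hruncs_track: CoverageTrack,
    spec: MixtureSpec,
    total_mapped_reads: float | None = None,
) -> CoverageTrack:
    """Per-bin two-population mixture: ``(1-f)*h_c*hrcs + f*h_un*hruncs``.

    The declared depth of the output defaults to the purified track's, i.e.
    both samples are read at equal cell numbers, so the mixed track's bulk
    signal exceeds the purified track's by the model's bulk ratio.
    """
    if not hrcs_track.same_grid(hruncs_track):
        raise StructuralError("mixture inputs are not on the same bin grid")
    f = spec.f
    mixed = {
        chrom: (1.0 - f) * spec.h_c * hrcs_track.counts[chrom]
        + f * spec.h_un * hruncs_track.counts[chrom]
        for chrom in hrcs_track.counts
    }
    declared = total_mapped_reads if total_mapped_reads is not None else hrcs_track.total_mapped_reads
    return CoverageTrack(hrcs_track.bin_width, mixed, declared)
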