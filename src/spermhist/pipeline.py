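"""End-to-end orchestration: simulate -> screen -> annotate -> cgi ->
categorize -> matrix -> methyl -> dynamics -> mixture, from one config.

The run report collects every summary statistic and a content hash of
every file written; re-running with the same config and seed reproduces
every output byte for byte (no timestamps anywhere).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import cgi_analysis, compartments, signal_profiles, synthetic_data
from .integrative_epigenomics import (
    expression_dynamics,
    methylation_correlation,
    read_expression,
    read_methylation,
    region_methylation,
)
from .intervals_io import (
    CoverageTrack,
    PeakSet,
    enrichment_screen,
    read_bed,
    read_bedgraph,
    read_fasta,
    read_genes,
    read_totals,
    write_bed,
)
from .mixture_model import invert_ratio
from .signal_profiles import Anchor, build_tss_matrix, export_heatmap_matrix, profile_curve
from .target_categories import categorize, overlap_summary, peaks_to_genes, write_catalog

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("spermhist")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


_SECTION_KEYS: dict[str, set[str]] = {
    "": {"seed", "outdir", "simulate", "data_dir", "generator", "screen",
         "compartments", "categorize", "profiles", "methylation", "dynamics",
         "verbosity"},
    "screen": {"fdr_max", "fc_min", "pseudocount"},
    "compartments": {"promoter_flank", "flank_extent", "assignment"},
    "categorize": {"k_background", "method", "signal_quantile"},
    "profiles": {"window", "bin_width"},
    "methylation": {"min_coverage"},
    "dynamics": {"threshold", "condition_stage", "condition_all_genes"},
}
_GENERATOR_KEYS = {f.name for f in synthetic_data.GeneratorConfig.__dataclass_fields__.values()}


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    simulate: bool = True
    data_dir: str | None = None
    generator: dict = field(default_factory=dict)
    screen: dict = field(default_factory=dict)
    compartments: dict = field(default_factory=dict)
    categorize: dict = field(default_factory=dict)
    profiles: dict = field(default_factory=dict)
    methylation: dict = field(default_factory=dict)
    dynamics: dict = field(default_factory=dict)
    verbosity: int = 1

    def __post_init__(self) -> None:
        for section in ("screen", "compartments", "categorize", "profiles",
                        "methylation", "dynamics"):
            unknown = set(getattr(self, section)) - _SECTION_KEYS[section]
            if unknown:
                raise ValueError(f"unknown keys in '{section}': {sorted(unknown)}")
        unknown = set(self.generator) - (_GENERATOR_KEYS - {"seed"})
        if unknown:
            raise ValueError(f"unknown keys in 'generator': {sorted(unknown)}")
        if not self.simulate and not self.data_dir:
            raise ValueError("simulate is disabled but no data_dir was given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(raw) - _SECTION_KEYS[""]
        if unknown:
            raise ValueError(f"{path}: unknown top-level keys: {sorted(unknown)}")
        if "outdir" not in raw:
            raise ValueError(f"{path}: 'outdir' is required")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_dataset_like(data_dir: Path) -> dict:
    """Load pre-existing inputs written in the generator's layout."""
    required = ["genome.fa", "genes.tsv", "repeats.bed", "cgis.bed",
                "peaks_hrcs.bed", "peaks_total.bed", "totals.tsv",
                "expression.tsv"]
    for name in required:
        if not (data_dir / name).exists():
            raise FileNotFoundError(f"missing input file: {data_dir / name}")
    genome = read_fasta(data_dir / "genome.fa")
    totals = read_totals(data_dir / "totals.tsv")
    coverage: dict[str, CoverageTrack] = {}
    for label, total in totals.items():
        bg = data_dir / f"coverage_{label}.bedGraph"
        if not bg.exists():
            raise FileNotFoundError(f"missing input file: {bg}")
        coverage[label] = read_bedgraph(bg, total)
    methylation = {}
    for p in sorted(data_dir.glob("methylation_*.tsv")):
        methylation[p.stem.removeprefix("methylation_")] = read_methylation(p)
    return {
        "genome": genome,
        "chrom_sizes": {c: len(s) for c, s in genome.items()},
        "genes": read_genes(data_dir / "genes.tsv"),
        "repeats": read_bed(data_dir / "repeats.bed"),
        "cgis": cgi_analysis.read_cgis(data_dir / "cgis.bed"),
        "peaks": {
            "hrcs": PeakSet("hrcs", read_bed(data_dir / "peaks_hrcs.bed")),
            "total": PeakSet("total", read_bed(data_dir / "peaks_total.bed")),
        },
        "coverage": coverage,
        "methylation": methylation,
        "expression": read_expression(data_dir / "expression.tsv"),
        "truth": None,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run report (also written as JSON)."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO if config.verbosity else logging.WARNING,
                        format="%(name)s %(levelname)s %(message)s")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": [], "files": {}}

    def _record(name: str, path: Path) -> None:
        report["files"][name] = {"path": str(path), "sha256": _sha256(path)}

    def _stage(name: str):
        log.info("stage %s", name)
        report["stages"].append(name)

    # --- simulate / load ---------------------------------------------------
    try:
        _stage("simulate" if config.simulate else "load")
        if config.simulate:
            gcfg = synthetic_data.GeneratorConfig(seed=config.seed, **config.generator)
            dataset = synthetic_data.generate_dataset(gcfg)
            data_dir = outdir / "data"
            for name, path in dataset.write(data_dir).items():
                _record(f"data/{name}", path)
            data = {
                "genome": dataset.genome,
                "chrom_sizes": dataset.chrom_sizes,
                "genes": dataset.genes,
                "repeats": dataset.repeats,
                "cgis": dataset.cgis,
                "peaks": dataset.peaks,
                "coverage": dataset.coverage,
                "methylation": dataset.methylation,
                "expression": dataset.expression,
                "truth": dataset.truth,
            }
        else:
            data = _load_dataset_like(Path(config.data_dir))
    except Exception as exc:
        raise PipelineError(f"stage 'simulate/load': {exc}") from exc

    genes = data["genes"]
    peaks_hrcs, peaks_total = data["peaks"]["hrcs"], data["peaks"]["total"]
    promoter_flank = int(config.compartments.get("promoter_flank", 1000))

    # --- enrichment screen -------------------------------------------------
    try:
        _stage("screen")
        if "hrcs" in data["coverage"] and "input" in data["coverage"]:
            screened = enrichment_screen(
                data["coverage"]["hrcs"],
                data["coverage"]["input"],
                fdr_max=float(config.screen.get("fdr_max", 0.01)),
                fc_min=float(config.screen.get("fc_min", 5.0)),
                pseudocount=float(config.screen.get("pseudocount", 1.0)),
                sample_label="hrcs_screen",
            )
            path = outdir / "screened_peaks.bed"
            write_bed(screened, path)
            _record("screened_peaks", path)
            report["screen"] = {"n_peaks": len(screened)}
        else:
            report["screen"] = {"skipped": "no hrcs/input coverage pair"}
    except Exception as exc:
        raise PipelineError(f"stage 'screen': {exc}") from exc

    # --- compartments ------------------------------------------------------
    try:
        _stage("annotate")
        ann = compartments.build_annotation(
            genes, data["repeats"], data["chrom_sizes"],
            promoter_flank=promoter_flank,
            flank_extent=int(config.compartments.get("flank_extent", 5000)),
        )
        mode = config.compartments.get("assignment", "midpoint")
        report["compartments"] = {}
        for label, ps in (("total", peaks_total), ("hrcs", peaks_hrcs)):
            table = compartments.peak_compartment_table(ps, ann, mode=mode)
            path = outdir / f"compartments_{label}.tsv"
            table.to_csv(path, sep="\t", float_format="%.6g")
            _record(f"compartments_{label}", path)
            report["compartments"][label] = {
                "fractions": {k: float(v) for k, v in table["fraction"].items()},
                "promoter_fraction": float(table.loc["promoter", "fraction"]),
            }
    except Exception as exc:
        raise PipelineError(f"stage 'annotate': {exc}") from exc

    # --- CGI analysis ------------------------------------------------------
    try:
        _stage("cgi")
        comparison = cgi_analysis.cgi_peak_oe_comparison(
            data["cgis"], peaks_total, peaks_hrcs
        )
        density = cgi_analysis.chromosome_density(
            peaks_hrcs, data["cgis"], data["chrom_sizes"]
        )
        path = outdir / "chromosome_density.tsv"
        density.to_csv(path, sep="\t", float_format="%.6g")
        _record("chromosome_density", path)
        report["cgi"] = {
            "medians": {k: v["median"] for k, v in comparison["boxplots"].items()},
            "pvalues": comparison["pvalues"],
            "counts": comparison["counts"],
        }
    except Exception as exc:
        raise PipelineError(f"stage 'cgi': {exc}") from exc

    # --- overlap + categorization -----------------------------------------
    try:
        _stage("categorize")
        summary = overlap_summary(
            {"total": peaks_total, "hrcs": peaks_hrcs}, genes, promoter_flank
        )
        report["overlap"] = summary
        genes_total = peaks_to_genes(peaks_total, genes, promoter_flank)
        genes_hrcs = peaks_to_genes(peaks_hrcs, genes, promoter_flank)
        catalog = categorize(
            genes_total, genes_hrcs, data["coverage"]["hrcs"], peaks_total, genes,
            k_background=float(config.categorize.get("k_background", 2.0)),
            promoter_flank=promoter_flank,
            method=config.categorize.get("method", "background"),
            signal_quantile=float(config.categorize.get("signal_quantile", 0.75)),
        )
        path = outdir / "catalog.tsv"
        write_catalog(catalog, path)
        _record("catalog", path)
        report["categories"] = catalog.category_sizes()
        report["categories"]["n_target_genes"] = len(catalog.table)
    except Exception as exc:
        raise PipelineError(f"stage 'categorize': {exc}") from exc

    # --- TSS matrices ------------------------------------------------------
    try:
        _stage("matrix")
        anchors = [Anchor(g.gene_id, g.chrom, g.tss, g.strand) for g in genes]
        window = int(config.profiles.get("window", 3000))
        bin_width = int(config.profiles.get("bin_width", 50))
        report["profiles"] = {}
        for label in ("hrcs", "total"):
            if label not in data["coverage"]:
                continue
            m = build_tss_matrix(data["coverage"][label], anchors, window, bin_width,
                                 sample_label=label)
            path = outdir / f"tss_matrix_{label}.tsv"
            export_heatmap_matrix(m, "mean_desc", path)
            _record(f"tss_matrix_{label}", path)
            curve = profile_curve(m)
            cpath = outdir / f"profile_{label}.tsv"
            curve.to_csv(cpath, sep="\t", index_label="offset_bp", float_format="%.6g")
            _record(f"profile_{label}", cpath)
            report["profiles"][label] = {
                "center_mean_rpm": float(curve.iloc[len(curve) // 2]),
                "edge_mean_rpm": float(curve.iloc[0]),
            }
    except Exception as exc:
        raise PipelineError(f"stage 'matrix': {exc}") from exc

    # --- methylation -------------------------------------------------------
    try:
        _stage("methyl")
        meth = data["methylation"]
        if len(meth) >= 1:
            min_cov = int(config.methylation.get("min_coverage", 1))
            regions = list(peaks_hrcs)
            levels = {}
            for label, records in sorted(meth.items()):
                table = region_methylation(records, regions, min_coverage=min_cov)
                path = outdir / f"region_methylation_{label}.tsv"
                table.to_csv(path, sep="\t", index=False, float_format="%.6g")
                _record(f"region_methylation_{label}", path)
                levels[label] = table["mean_level"].to_numpy()
                report.setdefault("methylation", {})[label] = {
                    "mean_peak_region_level": float(table["mean_level"].mean()),
                    "n_regions_missing": int(table["mean_level"].isna().sum()),
                }
            if len(levels) >= 2:
                labels = sorted(levels)
                r, n = methylation_correlation(levels[labels[0]], levels[labels[1]])
                report["methylation"]["pearson_r"] = {"samples": labels[:2], "r": r, "n": n}
        else:
            report["methylation"] = {"skipped": "no methylation tables"}
    except Exception as exc:
        raise PipelineError(f"stage 'methyl': {exc}") from exc

    # --- expression dynamics ----------------------------------------------
    try:
        _stage("dynamics")
        dyn = expression_dynamics(
            data["expression"], catalog,
            threshold=float(config.dynamics.get("threshold", 10.0)),
            condition_stage=config.dynamics.get("condition_stage", "oocyte"),
            condition_all_genes=bool(config.dynamics.get("condition_all_genes", True)),
        )
        path = outdir / "expression_dynamics.tsv"
        dyn.to_csv(path, sep="\t", float_format="%.6g")
        _record("expression_dynamics", path)
        report["dynamics"] = {
            cat: {stage: (None if dyn.isna().loc[cat, stage] else float(dyn.loc[cat, stage]))
                  for stage in dyn.columns if stage != "n"}
            for cat in dyn.index
        }
    except Exception as exc:
        raise PipelineError(f"stage 'dynamics': {exc}") from exc

    # --- mixture inversion -------------------------------------------------
    try:
        _stage("mixture")
        cov = data["coverage"]
        if "total" in cov and "hrcs" in cov:
            R = cov["total"].total_signal() / cov["hrcs"].total_signal()
            f = (data["truth"] or {}).get("mixture", {}).get(
                "f", config.generator.get("hruncs_fraction", 0.10)
            )
            ratio, share = invert_ratio(f, R)
            report["mixture"] = {
                "bulk_ratio_R": R,
                "f": f,
                "h_un_over_h_c": ratio,
                "contamination_share": share,
            }
        else:
            report["mixture"] = {"skipped": "need total and hrcs coverage"}
    except Exception as exc:
        raise PipelineError(f"stage 'mixture': {exc}") from exc

    if data["truth"] is not None:
        report["truth_check"] = {
            "planted_promoter_fraction": data["truth"]["realized_promoter_fraction"],
            "recovered_promoter_fraction": {
                label: report["compartments"][label]["promoter_fraction"]
                for label in ("total", "hrcs")
            },
        }

    report_path = outdir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    log.info("report written to %s", report_path)
    return report
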