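"""End-to-end orchestration: simulate -> quantify -> rank -> compare -> report.

A run is a plain directory of text artifacts (library, sample sheet, FASTQ,
counts, QC, fold changes, ranks, comparison report) plus a JSON manifest
recording the config hash, seed and a checksum per artifact.  Identical
configs reproduce byte-identical outputs; all joins are by identifier, never
by position.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import library as lib
from . import quantify as quant
from . import rank as rk
from . import simulate as sim
from .library import ParameterError

__all__ = ["RunConfig", "run_pipeline", "report", "PipelineError"]

log = logging.getLogger("dropscreen")


class PipelineError(RuntimeError):
    """A stage failed; message names the stage and cause."""


@dataclass
class RunConfig:
    """All pipeline parameters; defaults mirror the screen protocol.

    ``coverage`` is reads per library barcode (the protocol mandates
    200-1000x representation); selection lasts ``days`` (default 9); samples
    outside the transduction-efficiency window [qc_low, qc_high] are excluded.
    """

    name: str = "run"
    seed: int = 0
    # library
    n_reliable_genes: int = 1000
    n_total_shrnas: int | None = None  # default: 5-6 per gene, no auxiliaries
    barcode_length: int = 18
    n_reliable_shrnas: int | None = None
    # planted effects
    fraction_essential: float = 0.05
    fraction_condition_specific: float = 0.10
    s_mean: float = 0.5
    s_sd: float = 0.15
    effective_fraction: float = 0.8
    # simulation
    settings: list[str] = field(default_factory=lambda: ["setting1", "setting2", "setting3"])
    replicates: int = 2
    days: float = 9.0
    coverage: float = 500.0
    error_rate: float = 0.005
    dispersion: float = 0.3
    te_low_sim: float = 0.15
    te_high_sim: float = 0.35
    # quantification
    max_mismatch: int = 1
    barcode_offset: int = len(sim.DEFAULT_FLANK_5)
    # ranking
    pseudocount: float = 0.5
    top_fraction: float = 0.01
    # QC window
    qc_low: float = 0.10
    qc_high: float = 0.40

    def __post_init__(self):
        if self.n_total_shrnas is None:
            self.n_total_shrnas = 5 * self.n_reliable_genes
        if self.seed is None:
            raise ParameterError("seed is mandatory")
        if not self.settings:
            raise ParameterError("at least one selection setting is required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute every stage and write all artifacts under ``outdir``.

    Returns the run directory.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    artifacts: list[Path] = []
    try:
        stage = "library"
        design = lib.generate_library(
            config.n_reliable_genes, config.n_total_shrnas,
            config.barcode_length, seed=config.seed,
            n_reliable_shrnas=config.n_reliable_shrnas)
        lib.write_library(design, outdir / "library.tsv")
        artifacts.append(outdir / "library.tsv")
        log.info("stage=library complexity=%d reliable_genes=%d",
                 design.complexity, len(design.reliable_genes))

        stage = "plant_effects"
        cond_label = config.settings[-1]
        effects = sim.plant_effects(
            design, config.fraction_essential, config.fraction_condition_specific,
            (config.s_mean, config.s_sd), config.effective_fraction,
            condition_specific_label=cond_label, seed=config.seed + 1)
        truth = {
            "essential_genes": sorted(effects.essential_genes),
            "condition_specific_genes": sorted(effects.condition_specific_genes()),
            "condition_specific_label": cond_label,
        }
        _dump_json(truth, outdir / "truth.json")
        artifacts.append(outdir / "truth.json")
        log.info("stage=plant_effects essential=%d condition_specific=%d",
                 len(effects.essential_genes), len(truth["condition_specific_genes"]))

        stage = "simulate"
        n_reads = int(round(config.coverage * design.complexity))
        samples, _ = sim.simulate_screen(
            design, effects, config.settings, config.replicates, config.days,
            n_reads, config.error_rate, config.dispersion,
            (config.te_low_sim, config.te_high_sim),
            seed=config.seed + 2, outdir=outdir / "fastq")
        artifacts.append(outdir / "fastq" / "samples.tsv")
        log.info("stage=simulate samples=%d reads_per_sample=%d", len(samples), n_reads)

        stage = "qc_filter"
        retained, excluded = quant.qc_filter_samples(samples, config.qc_low, config.qc_high)
        qc_report = {
            "retained": [s.sample_id for s in retained],
            "excluded": [{"sample_id": s.sample_id, "reason": why} for s, why in excluded],
        }
        _dump_json(qc_report, outdir / "sample_qc.json")
        artifacts.append(outdir / "sample_qc.json")
        log.info("stage=qc_filter retained=%d excluded=%d", len(retained), len(excluded))
        if not any(not s.is_baseline for s in retained):
            raise PipelineError(
                "qc_filter: all non-baseline samples excluded by the "
                "transduction-efficiency window; see sample_qc.json")

        stage = "quantify"
        index = quant.build_barcode_index(design, config.max_mismatch)
        per_sample, qcs = {}, {}
        for s in retained:
            counts, qc = quant.quantify_fastq(
                s.fastq_path, index, config.barcode_offset)
            per_sample[s.sample_id] = counts
            qcs[s.sample_id] = asdict(qc)
            log.info("stage=quantify sample=%s assigned=%d recovery=%.4f",
                     s.sample_id, qc.assigned_reads, qc.barcode_recovery)
        matrix = quant.assemble_count_matrix(per_sample, retained, design)
        matrix.to_tsv(outdir / "counts.tsv")
        _dump_json(qcs, outdir / "quant_qc.json")
        artifacts += [outdir / "counts.tsv", outdir / "quant_qc.json"]

        stage = "rank"
        norm = rk.normalize_counts(matrix, config.pseudocount)
        retained_ids = {s.sample_id for s in retained}
        top_sets: dict[str, dict[int, list[str]]] = {}
        concordance: dict[str, dict] = {}
        fc_by_exp: dict[str, rk.FoldChangeTable] = {}
        for setting in config.settings:
            per_rep_fc = {}
            for rep in range(1, config.replicates + 1):
                b, f = f"baseline_rep{rep}", f"{setting}_rep{rep}"
                if b not in retained_ids or f not in retained_ids:
                    continue
                fc = rk.fold_changes(norm, b, f, design, config.pseudocount)
                fc.to_tsv(outdir / f"fc_{setting}_rep{rep}.tsv")
                artifacts.append(outdir / f"fc_{setting}_rep{rep}.tsv")
                ranks = rk.gene_scores_second_best(fc, design)
                ranks.to_tsv(outdir / f"ranks_{setting}_rep{rep}.tsv")
                artifacts.append(outdir / f"ranks_{setting}_rep{rep}.tsv")
                top_sets.setdefault(setting, {})[rep] = sorted(
                    rk.top_fraction_set(ranks, config.top_fraction))
                per_rep_fc[rep] = fc
                fc_by_exp[f"{setting}_rep{rep}"] = fc
            if len(per_rep_fc) >= 2:
                reps = sorted(per_rep_fc)
                rho, r = rk.replicate_concordance(per_rep_fc[reps[0]], per_rep_fc[reps[1]])
                concordance[setting] = {"spearman": rho, "pearson_log2": r,
                                        "replicates": reps[:2]}
                log.info("stage=rank setting=%s spearman=%.3f", setting, rho)

        stage = "compare"
        comparison = {"top_fraction": config.top_fraction,
                      "top_sets": top_sets, "concordance": concordance}
        target = config.settings[-1]
        others = [set(v) for s in config.settings[:-1]
                  for v in top_sets.get(s, {}).values()]
        targets = [set(v) for v in top_sets.get(target, {}).values()]
        if targets and others:
            specific = rk.setting_specific_genes(targets, others)
            comparison["setting_specific"] = {
                "target_setting": target, "genes": sorted(specific)}
        _dump_json(comparison, outdir / "comparison.json")
        artifacts.append(outdir / "comparison.json")

        stage = "manifest"
        manifest = {
            "config": asdict(config),
            "config_sha256": config.digest(),
            "seed": config.seed,
            "artifacts": {str(p.relative_to(outdir)): _sha256(p)
                          for p in sorted(artifacts)},
        }
        _dump_json(manifest, outdir / "manifest.json")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"{stage}: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir


def report(run_dir, with_plots: bool = True) -> str:
    """Human-readable run summary; verifies artifact checksums first.

    Covers per-sample barcode recovery, replicate concordance, top-fraction
    gene sets per setting, setting-specific genes, and (when the run stored
    ground truth) recovery of planted essentials.  Writes ``report.txt`` and,
    optionally, a replicate fold-change scatter per setting.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise PipelineError("report: run has no manifest.json (incomplete run)")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    missing, tampered = [], []
    for rel, digest in manifest["artifacts"].items():
        p = run_dir / rel
        if not p.exists():
            missing.append(rel)
        elif _sha256(p) != digest:
            tampered.append(rel)
    if missing or tampered:
        raise PipelineError(
            f"report: artifact check failed (missing={missing}, checksum mismatch={tampered})")

    with open(run_dir / "quant_qc.json") as fh:
        qcs = json.load(fh)
    with open(run_dir / "comparison.json") as fh:
        comparison = json.load(fh)

    lines = [f"dropscreen run: {manifest['config']['name']} (seed {manifest['seed']})", ""]
    lines.append("Barcode recovery per sample:")
    for sid in sorted(qcs):
        q = qcs[sid]
        lines.append(f"  {sid}: {q['barcode_recovery']:.4f} "
                     f"({q['assigned_reads']}/{q['total_reads']} reads assigned)")
    lines.append("")
    lines.append("Replicate concordance (Spearman of depletion fold changes):")
    for setting, c in comparison.get("concordance", {}).items():
        lines.append(f"  {setting}: rho={c['spearman']:.3f} "
                     f"(Pearson on log2: {c['pearson_log2']:.3f})")
    lines.append("")
    frac = comparison.get("top_fraction", 0.01)
    lines.append(f"Top {100 * frac:g}% gene sets:")
    for setting, reps in comparison.get("top_sets", {}).items():
        for rep, genes in sorted(reps.items()):
            lines.append(f"  {setting} rep{rep}: {len(genes)} genes")
    if "setting_specific" in comparison:
        ss = comparison["setting_specific"]
        lines.append("")
        lines.append(f"Genes specific to {ss['target_setting']} "
                     f"(in every replicate's top set, absent from all others):")
        lines.append(f"  {', '.join(ss['genes']) if ss['genes'] else '(none)'}")

    truth_path = run_dir / "truth.json"
    if truth_path.exists():
        with open(truth_path) as fh:
            truth = json.load(fh)
        planted = set(truth["essential_genes"])
        lines.append("")
        lines.append("Recovery of planted essentials in top sets:")
        for setting, reps in comparison.get("top_sets", {}).items():
            for rep, genes in sorted(reps.items()):
                hit = len(planted & set(genes))
                lines.append(f"  {setting} rep{rep}: {hit}/{len(genes)} of top set planted")

    if with_plots:
        _plot_concordance(run_dir, comparison)

    text = "\n".join(lines) + "\n"
    with open(run_dir / "report.txt", "w") as fh:
        fh.write(text)
    return text


def _plot_concordance(run_dir: Path, comparison: dict) -> None:
    """Replicate log2 fold-change scatter per setting (best-effort)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    for setting, c in comparison.get("concordance", {}).items():
        r1, r2 = c["replicates"]
        try:
            t1 = pd.read_csv(run_dir / f"fc_{setting}_rep{r1}.tsv", sep="\t",
                             index_col="shrna_id")
            t2 = pd.read_csv(run_dir / f"fc_{setting}_rep{r2}.tsv", sep="\t",
                             index_col="shrna_id")
        except FileNotFoundError:
            continue
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(t1["log2_fc"], t2["log2_fc"].reindex(t1.index), s=2, alpha=0.3)
        ax.set_xlabel(f"log2 depletion FC, rep {r1}")
        ax.set_ylabel(f"log2 depletion FC, rep {r2}")
        ax.set_title(f"{setting}: Spearman rho = {c['spearman']:.3f}")
        fig.tight_layout()
        fig.savefig(run_dir / f"concordance_{setting}.png", dpi=100)
        plt.close(fig)
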