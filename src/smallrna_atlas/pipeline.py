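"""End-to-end run orchestration.

One config drives simulate -> signatures -> contigs -> classify ->
count -> differential expression -> report, writing every stage output
under a run directory in documented plain-text formats (FASTA, BED6,
TSV, Newick, JSON) plus a manifest with parameters, seeds and file
checksums.  Reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, diffexp, intervals, io, reporting, signatures, simdata

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration; defaults reproduce the study conditions
    (12 normal vs 10 tumor samples, 1e5 expected reads per sample,
    global piRNA loss at log2FC -5, 23 up-regulated miRNAs at +11)."""

    seed: int = 0
    simulate: bool = True
    reads_dir: str | None = None       # used when simulate is off
    tracks_dir: str | None = None
    n_normal: int = 12
    n_tumor: int = 10
    n_cis: int = 0
    depth: float = 100_000.0
    genome: dict = field(default_factory=dict)      # GenomeSpec overrides
    group: dict = field(default_factory=dict)       # GroupParams overrides
    contig: dict = field(default_factory=dict)      # ContigParams overrides
    mirna_window: tuple[int, int] = (18, 24)
    fit_type_contigs: str = "local"
    fit_type_mirna: str = "parametric"
    alpha: float = 1e-6                # significance threshold on padj
    volcano_padj: float = 1e-8
    volcano_lfc: float = 5.0
    top_n_contigs: int = 2000
    top_n_mirna: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "mirna_window" in data:
            data["mirna_window"] = tuple(data["mirna_window"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mirna_window"] = list(self.mirna_window)
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class PipelineResult:
    """In-memory handles on the main stage outputs (everything is also
    on disk under ``outdir``)."""

    outdir: Path
    design: pd.DataFrame
    truth: pd.DataFrame | None
    contigs: pd.DataFrame
    contig_summary: dict
    contig_de: pd.DataFrame
    mirna_de: pd.DataFrame
    contig_dendrogram: reporting.Dendrogram
    mirna_dendrogram: reporting.Dendrogram
    recovery: dict | None
    manifest: dict


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"pipeline stage {stage!r} failed: {detail}")
        self.stage = stage


def _write_de(df: pd.DataFrame, path: Path) -> None:
    """DE table TSV with Inf/-Inf literals for infinite fold changes."""
    out = df.copy()
    lfc = out["log2FoldChange"]
    out["log2FoldChange"] = [
        "Inf" if v == np.inf else "-Inf" if v == -np.inf else repr(float(v))
        for v in lfc
    ]
    out.to_csv(path, sep="\t")


def run_pipeline(config: RunConfig, outdir: str | Path) -> PipelineResult:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    def emit(path: Path) -> Path:
        files.append(path)
        return path

    # ---- stage: simulate (or load user reads) ---------------------------
    design = simdata.default_design(config.n_normal, config.n_tumor,
                                    config.n_cis)
    truth = None
    try:
        if config.simulate:
            spec = simdata.GenomeSpec(seed=config.seed, **config.genome)
            genome, tracks = simdata.make_genome(spec)
            base = simdata.normal_params(depth=config.depth, **config.group)
            params_by_group = simdata.default_params_by_group(
                design["group"].unique(), base)
            reads_by_sample, truth = simdata.simulate_experiment(
                genome, tracks, design, params_by_group, seed=config.seed)
            io.write_fasta(genome, emit(outdir / "genome.fasta"))
            tracks_dir = outdir / "tracks"
            tracks_dir.mkdir(exist_ok=True)
            for name in simdata.ANNOTATION_TRACKS:
                io.write_bed(tracks[name], emit(tracks_dir / f"{name}.bed"))
            reads_dir = outdir / "reads"
            reads_dir.mkdir(exist_ok=True)
            for sample, reads in reads_by_sample.items():
                io.write_reads(reads, emit(reads_dir / f"{sample}.tsv"))
            io.write_table(truth, emit(outdir / "truth.tsv"))
        else:
            if not config.reads_dir or not config.tracks_dir:
                raise ValueError("simulate=false requires reads_dir and "
                                 "tracks_dir")
            tracks = {p.stem: io.read_bed(p)
                      for p in sorted(Path(config.tracks_dir).glob("*.bed"))}
            reads_by_sample = {
                s: io.read_reads(Path(config.reads_dir) / f"{s}.tsv")
                for s in design["sample_id"]}
    except Exception as exc:
        raise StageError("simulate", str(exc)) from exc

    # ---- stage: signatures ---------------------------------------------
    try:
        group_of = dict(zip(design["sample_id"], design["group"]))
        reads_by_group: dict[str, list] = {}
        for sample, reads in reads_by_sample.items():
            reads_by_group.setdefault(group_of[sample], []).extend(
                reads["seq"].tolist())
        io.write_table(signatures.histogram_table(reads_by_sample),
                       emit(outdir / "length_histogram.tsv"))
        io.write_table(signatures.signature_table(reads_by_group),
                       emit(outdir / "signature_fractions.tsv"))
        io.write_table(signatures.logo_table(reads_by_group),
                       emit(outdir / "logo_matrices.tsv"))
    except Exception as exc:
        raise StageError("signatures", str(exc)) from exc

    # ---- stage: contigs -------------------------------------------------
    try:
        pooled = pd.concat(reads_by_sample.values(), ignore_index=True)
        cparams = intervals.ContigParams(**config.contig)
        contigs = intervals.build_contigs(pooled, cparams)
        summary = intervals.contig_summary(contigs)
        io.write_bed(contigs, emit(outdir / "contigs.bed"))
        io.write_table(pd.DataFrame([summary]),
                       emit(outdir / "contig_summary.tsv"))
        pirna_overlap = intervals.overlap_report(
            contigs, tracks.get("pirna_cluster", pd.DataFrame(
                columns=io.BED6_COLUMNS)))
        with open(emit(outdir / "pirna_overlap.json"), "w") as fh:
            json.dump(pirna_overlap, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise StageError("contigs", str(exc)) from exc

    # ---- stage: classify ------------------------------------------------
    try:
        composition = classify.class_composition(reads_by_sample, design,
                                                 tracks)
        io.write_table(composition, emit(outdir / "class_composition.tsv"))
        trna_types = classify.type_trna_reads(
            pooled.head(200_000), tracks.get("trna", pd.DataFrame(
                columns=io.BED6_COLUMNS)))
        type_summary = (trna_types.groupby(["fragment_type", "origin_end"])
                        .size().rename("n").reset_index())
        io.write_table(type_summary, emit(outdir / "trna_fragment_types.tsv"))
    except Exception as exc:
        raise StageError("classify", str(exc)) from exc

    # ---- stage: counting + differential expression ----------------------
    try:
        contig_cm = diffexp.count_matrix(contigs, reads_by_sample, design,
                                         strandedness="same")
        contig_de = diffexp.nbinom_de(contig_cm,
                                      fit_type=config.fit_type_contigs)
        _write_de(contig_de, emit(outdir / "contig_de.tsv"))

        lo, hi = config.mirna_window
        mirna_reads = {
            s: r[(r["end"] - r["start"]).between(lo, hi)]
            for s, r in reads_by_sample.items()}
        mirna_cm = diffexp.count_matrix(tracks["mirna"], mirna_reads, design)
        mirna_de = diffexp.nbinom_de(mirna_cm, fit_type=config.fit_type_mirna)
        _write_de(mirna_de, emit(outdir / "mirna_de.tsv"))

        contig_sf = diffexp.size_factors(contig_cm.counts)
        contig_model = diffexp.estimate_dispersions(
            contig_cm.counts, contig_sf, contig_cm.conditions,
            fit_type=config.fit_type_contigs)
        contig_vst = diffexp.vst(contig_cm.counts, contig_sf, contig_model)
        io.write_table(contig_vst, emit(outdir / "contig_vst.tsv"),
                       index=True)
        mirna_sf = diffexp.size_factors(mirna_cm.counts)
        mirna_model = diffexp.estimate_dispersions(
            mirna_cm.counts, mirna_sf, mirna_cm.conditions,
            fit_type=config.fit_type_mirna)
        mirna_vst = diffexp.vst(mirna_cm.counts, mirna_sf, mirna_model)
        io.write_table(mirna_vst, emit(outdir / "mirna_vst.tsv"), index=True)
    except Exception as exc:
        raise StageError("diffexp", str(exc)) from exc

    # ---- stage: report --------------------------------------------------
    try:
        top_contigs = reporting.top_n_features(contig_vst,
                                               config.top_n_contigs).index
        contig_dendro = reporting.cluster_samples(contig_vst, top_contigs)
        (outdir / "contig_dendrogram.nwk").write_text(
            contig_dendro.to_newick() + "\n")
        files.append(outdir / "contig_dendrogram.nwk")
        io.write_table(reporting.heatmap_table(contig_vst, top_contigs,
                                               contig_dendro),
                       emit(outdir / "contig_heatmap.tsv"), index=True)
        io.write_table(reporting.volcano_table(contig_de, config.volcano_padj,
                                               config.volcano_lfc),
                       emit(outdir / "contig_volcano.tsv"), index=True)

        top_mirna = reporting.top_n_features(mirna_vst,
                                             config.top_n_mirna).index
        mirna_dendro = reporting.cluster_samples(mirna_vst, top_mirna)
        (outdir / "mirna_dendrogram.nwk").write_text(
            mirna_dendro.to_newick() + "\n")
        files.append(outdir / "mirna_dendrogram.nwk")
        io.write_table(reporting.volcano_table(mirna_de, config.volcano_padj,
                                               config.volcano_lfc),
                       emit(outdir / "mirna_volcano.tsv"), index=True)
    except Exception as exc:
        raise StageError("report", str(exc)) from exc

    # ---- stage: truth recovery ------------------------------------------
    recovery = None
    if truth is not None:
        try:
            recovery = recovery_report(truth, contigs, contig_de, mirna_de,
                                       contig_dendro, design, config.alpha)
            with open(emit(outdir / "recovery.json"), "w") as fh:
                json.dump(recovery, fh, indent=2, sort_keys=True)
        except Exception as exc:
            raise StageError("recovery", str(exc)) from exc

    manifest = {
        "config": config.to_dict(),
        "n_samples": int(len(design)),
        "n_reads_total": int(sum(len(r) for r in reads_by_sample.values())),
        "n_contigs": summary["n_contigs"],
        "files": {str(p.relative_to(outdir)): io.sha256_of(p)
                  for p in sorted(files)},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        outdir=outdir, design=design, truth=truth, contigs=contigs,
        contig_summary=summary, contig_de=contig_de, mirna_de=mirna_de,
        contig_dendrogram=contig_dendro, mirna_dendrogram=mirna_dendro,
        recovery=recovery, manifest=manifest)


def recovery_report(truth: pd.DataFrame, contigs: pd.DataFrame,
                    contig_de: pd.DataFrame, mirna_de: pd.DataFrame,
                    contig_dendro: reporting.Dendrogram,
                    design: pd.DataFrame, alpha: float = 1e-6) -> dict:
    """Compare pipeline output with the simulation ground truth.

    Reports the mean measured log2FC of contigs matched to truth piRNA
    clusters, the sensitivity/false-positive tally for the injected
    up-regulated miRNA subset at the significance threshold, the
    fraction of expressed truth piRNA clusters recovered by a contig,
    volcano skew counts, and the purity of the 2-way dendrogram cut
    against the case/control labels.
    """
    from . import intervals as iv

    pirna_truth = truth[truth["klass"] == "piRNA"]
    pairs = iv.intersect(contigs, pirna_truth, strandedness="same")
    matched = contigs.iloc[sorted(pairs["query_idx"].unique())]["name"]
    pirna_lfc = contig_de.loc[contig_de.index.intersection(matched),
                              "log2FoldChange"]
    pirna_lfc = pirna_lfc[np.isfinite(pirna_lfc)]

    expressed = pirna_truth[pirna_truth["mean_normal"] > 1.0]
    exp_pairs = iv.intersect(expressed, contigs, strandedness="same")
    frac_clusters_recovered = (exp_pairs["query_idx"].nunique()
                               / len(expressed)) if len(expressed) else np.nan

    up_names = set(truth.loc[truth["is_up_mirna"], "name"])
    sig = diffexp.filter_significant(mirna_de, alpha)
    sig_up = sig[sig["log2FoldChange"] > 0]
    tp = len(set(sig_up.index) & up_names)
    fp = len(set(sig.index) - up_names)
    up_lfc = mirna_de.loc[mirna_de.index.isin(up_names), "log2FoldChange"]
    up_lfc = up_lfc[np.isfinite(up_lfc)]

    sig_contigs = diffexp.filter_significant(contig_de, alpha)
    n_down = int((sig_contigs["log2FoldChange"] < 0).sum())
    n_up = int((sig_contigs["log2FoldChange"] > 0).sum())

    cut = contig_dendro.cut(2)
    cond = design.set_index("sample_id")["condition"].reindex(cut.index)
    purity = max(
        ((cut == c) == (cond == "case").to_numpy()).mean()
        for c in (1, 2))

    return {
        "mean_pirna_contig_log2fc": float(pirna_lfc.mean()),
        "n_pirna_contigs": int(len(pirna_lfc)),
        "frac_truth_pirna_clusters_recovered": float(frac_clusters_recovered),
        "mirna_up_total": int(len(up_names)),
        "mirna_up_recovered": int(tp),
        "mirna_false_positives": int(fp),
        "mean_up_mirna_log2fc": float(up_lfc.mean()),
        "volcano_down": n_down,
        "volcano_up": n_up,
        "dendrogram_2cut_purity": float(purity),
    }
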