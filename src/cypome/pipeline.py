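"""End-to-end pipeline: clustering → identification → classification → GCM analyses.

Runs the four steps on a directory of per-genome protein FASTA files against a
named reference CYP FASTA and a CYP-domain alignment, writing a fixed catalog
of at most 32 output files (raw tables prefixed ``R_``/``panTable_``,
identification ``I_``, classification ``C_``, network ``N_``, plus images,
``run.log`` and a checksum manifest).  All non-image outputs are deterministic
for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import analysis, classify, cluster, gcm, identify, seqio

logger = logging.getLogger(__name__)

#: Every file the pipeline may write (excluding nothing); kept ≤ 32.
OUTPUT_CATALOG = [
    "R_centroids.faa",
    "R_clusters.uc",
    "I_cyp_hits.tsv",
    "C_classification.tsv",
    "panTable_Family_numeric.csv",
    "panTable_Subfamily_numeric.csv",
    "R_pancore_family.tsv",
    "R_pancore_subfamily.tsv",
    "R_powerlaw.tsv",
    "N_network_family.tsv",
    "N_network_subfamily.tsv",
    "N_nodes_family.tsv",
    "N_nodes_subfamily.tsv",
    "R_heatmap_family.txt",
    "R_heatmap_subfamily.txt",
    "R_cloud_family.tsv",
    "R_cloud_subfamily.tsv",
    "I_pancore_family.png",
    "I_pancore_subfamily.png",
    "I_heatmap_family.png",
    "I_heatmap_subfamily.png",
    "I_cloud_family.png",
    "I_cloud_subfamily.png",
    "run.log",
    "manifest.tsv",
]
assert len(OUTPUT_CATALOG) <= 32


@dataclass
class RunConfig:
    """All knobs of one pipeline run; thresholds are the published defaults."""

    input_dir: str
    ref_cyps: str
    ref_domains: str
    out_dir: str
    cluster_id: float = 0.55
    family_id: float = 0.40
    subfamily_id: float = 0.55
    evalue: float = 1e-5
    pan_samples: int = 300
    seed: int = 0
    plots: bool = True
    exact: bool = False
    fit_target: str = "mean"

    def __post_init__(self) -> None:
        for name in ("cluster_id", "family_id", "subfamily_id"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.evalue <= 0:
            raise ValueError("evalue cutoff must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _setup_logging(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("cypome")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    return handler


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a summary dict of per-step counts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out)
    try:
        return _run(config, out)
    finally:
        logging.getLogger("cypome").removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> dict:
    ref_path = Path(config.ref_cyps)
    dom_path = Path(config.ref_domains)
    for p in (ref_path, dom_path):
        if not p.exists():
            raise FileNotFoundError(f"missing reference file: {p}")
    fasta_files = sorted(
        p for p in Path(config.input_dir).iterdir() if p.suffix in (".fasta", ".faa")
    )
    if not fasta_files:
        raise ValueError(f"no .fasta/.faa files in {config.input_dir}")

    logger.info("run config: %s", dataclasses.asdict(config))

    # Step 1: ingest and orthologous clustering.
    genomes = [seqio.read_fasta(p) for p in fasta_files]
    genome_ids = [g.genome_id for g in genomes]
    pooled = seqio.pool_and_tag(genomes)
    logger.info("step1: %d genomes, %d pooled sequences", len(genomes), len(pooled))
    clusters = cluster.greedy_cluster(pooled, threshold=config.cluster_id, exact=config.exact)
    logger.info("step1: %d clusters at identity %.2f", len(clusters), config.cluster_id)
    centroid_records = {
        cl.centroid: cl.centroid_sequence for cl in clusters.clusters
    }
    centroid_list = [
        seqio.ProteinRecord(
            id=seqio.split_tag(cid)[1], genome_id=seqio.split_tag(cid)[0], sequence=seq
        )
        for cid, seq in centroid_records.items()
    ]
    seqio.write_fasta(centroid_list, out / "R_centroids.faa", tagged=True)
    seqio.write_uc(clusters, out / "R_clusters.uc")

    # Step 2: CYP identification by profile scan.
    from Bio import SeqIO as _SeqIO

    aligned = [str(r.seq) for r in _SeqIO.parse(str(dom_path), "fasta")]
    profile = identify.build_profile(aligned, name="CYP_domain")
    calibration = identify.calibrate(profile, seed=config.seed)
    hits = identify.identify_cyps(
        centroid_list, [profile], {profile.name: calibration}, evalue_cutoff=config.evalue
    )
    pd.DataFrame(
        [dataclasses.asdict(h) for h in hits],
        columns=["query", "profile", "score", "evalue", "start", "end"],
    ).to_csv(out / "I_cyp_hits.tsv", sep="\t", index=False)
    logger.info("step2: %d of %d centroids identified as CYPs", len(hits), len(centroid_list))

    # Step 3: classification against the named reference set.
    refs = classify.read_reference_fasta(ref_path)
    cyp_centroids = {h.query: centroid_records[h.query] for h in hits}
    assignments = classify.classify_centroids(
        cyp_centroids, refs, config.family_id, config.subfamily_id
    )
    per_sequence = classify.propagate_to_members(assignments, clusters)
    per_sequence.to_csv(out / "C_classification.tsv", sep="\t", index=False)
    logger.info(
        "step3: %d CYP centroids classified, %d sequences after propagation",
        len(assignments),
        len(per_sequence),
    )

    # Step 4: GCMs and analyses.
    summary = {
        "n_genomes": len(genomes),
        "n_sequences": len(pooled),
        "n_clusters": len(clusters),
        "n_cyp_centroids": len(hits),
        "n_cyp_sequences": len(per_sequence),
    }
    for level, pan_csv in (
        ("family", "panTable_Family_numeric.csv"),
        ("subfamily", "panTable_Subfamily_numeric.csv"),
    ):
        matrix = gcm.build_gcm(per_sequence, level, genome_ids=genome_ids)
        gcm.export_numeric_csv(matrix, out / pan_csv)
        summary[f"n_{level}"] = matrix.n_cyps
        _analyze_level(matrix, level, config, out, summary)
    logger.info("step4 summary: %s", summary)

    _write_manifest(out)
    summary["files"] = sorted(p.name for p in out.iterdir() if p.is_file())
    return summary


def _analyze_level(matrix: gcm.GCM, level: str, config: RunConfig, out: Path, summary: dict) -> None:
    if matrix.n_cyps == 0:
        logger.warning("WARN no CYPs at %s level; analyses skipped", level)
        return
    curve = analysis.pan_core_curve(matrix, samples=config.pan_samples, seed=config.seed)
    curve.to_frame().to_csv(out / f"R_pancore_{level}.tsv", sep="\t", index=False)
    fit = None
    try:
        fit = analysis.fit_power_law(curve, fit_target=config.fit_target)
        summary[f"pan_gamma_{level}"] = fit.gamma
        summary[f"pan_sigma_{level}"] = fit.sigma
    except ValueError as exc:
        logger.warning("WARN power-law fit skipped at %s level: %s", level, exc)
    mode = "a" if (out / "R_powerlaw.tsv").exists() else "w"
    with open(out / "R_powerlaw.tsv", mode) as fh:
        if mode == "w":
            fh.write("level\tfit_target\tsigma\tgamma\tn_points\n")
        if fit is not None:
            fh.write(f"{level}\t{fit.fit_target}\t{fit.sigma:.6g}\t{fit.gamma:.6g}\t{fit.n_points}\n")
    summary[f"core_size_{level}"] = int((matrix.g_ci == matrix.g_t).sum())

    net = analysis.cooccurrence(matrix)
    net.edges.to_csv(out / f"N_network_{level}.tsv", sep="\t", index=False)
    nodes = pd.DataFrame(
        {
            "cyp": net.occurrence.index,
            "occurrence": net.occurrence.to_numpy(),
            "total_count": matrix.table.sum(axis=1).to_numpy(),
        }
    )
    nodes.to_csv(out / f"N_nodes_{level}.tsv", sep="\t", index=False)

    analysis.cluster_heatmap(
        matrix,
        out_image=(out / f"I_heatmap_{level}.png") if config.plots else None,
        out_text=out / f"R_heatmap_{level}.txt",
    )
    cloud = analysis.cloud_frequencies(matrix)
    cloud.to_csv(out / f"R_cloud_{level}.tsv", sep="\t", index=False)
    if config.plots:
        analysis.render_cloud(cloud, out / f"I_cloud_{level}.png", seed=config.seed)
        analysis.plot_pan_core(curve, fit, out / f"I_pancore_{level}.png")


def _write_manifest(out: Path) -> None:
    rows = []
    for p in sorted(out.iterdir()):
        if not p.is_file() or p.name == "manifest.tsv":
            continue
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        rows.append(f"{p.name}\t{p.stat().st_size}\t{digest}")
    (out / "manifest.tsv").write_text("file\tbytes\tsha256\n" + "\n".join(rows) + "\n")
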