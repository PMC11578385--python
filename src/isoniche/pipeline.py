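"""End-to-end orchestration: QC -> normalize -> neighbor graph -> contact
frequency -> isoform classes -> differential splicing -> presence ->
enrichment -> ratio groups -> association report.

Configuration is a single declarative document (YAML on disk); the
effective config with every default resolved is echoed into the run
manifest, which also records input checksums, per-stage row counts and
wall-clock.  Identical config + seed reproduce identical tabular outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._errors import ConfigError, IsonicheError
from .coloc import MarkerPanel, call_presence_markers, enrichment_score, enrichment_summary
from .hexgrid import build_neighbor_graph, contact_frequency
from .io import QCConfig, log_normalize, qc_filter_spots, read_counts, read_positions
from .isoforms import (DSConfig, class_distribution, classify_pattern,
                       classify_spatial, differential_splicing)
from .simulate import SimConfig, generate_dataset
from .stats import assign_groups, association_report, compute_ratio

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run.

    Exactly one of ``input_dir`` (a directory in the synthetic-bundle
    layout) or ``sim`` (generate the bundle first) must be set.
    """

    output_dir: str = "isoniche_out"
    input_dir: str | None = None
    sim: SimConfig | None = None
    seed: int = 0
    qc: QCConfig = field(default_factory=lambda: QCConfig())
    ds: DSConfig = field(default_factory=DSConfig)
    panel_a: MarkerPanel = field(
        default_factory=lambda: MarkerPanel("CD8_CXCL13_Tex", ("CD8A", "CXCL13", "CD3E", "PDCD1"))
    )
    panel_b: MarkerPanel = field(
        default_factory=lambda: MarkerPanel("C1QC_TAM", ("C1QC", "LYZ", "APOE", "CSF1R"))
    )
    ratio_pair: tuple = ("CD74-202", "CD74-201")
    ratio_high: float = 15.0
    ratio_low: float = 1.0
    fraction_cutoff: float = 0.6

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = self.sim.to_dict() if self.sim else None
        d["ratio_pair"] = list(self.ratio_pair)
        d["panel_a"]["markers"] = list(self.panel_a.markers)
        d["panel_b"]["markers"] = list(self.panel_b.markers)
        return d


def default_synthetic_config(output_dir: str = "isoniche_out", seed: int = 0) -> PipelineConfig:
    """Synthetic-mode defaults: the generator's conditions plus a QC gene
    floor scaled to the synthetic transcriptome (500 genes, so the
    whole-transcriptome floor of 1000 would empty the dataset)."""
    return PipelineConfig(
        output_dir=output_dir,
        sim=SimConfig(seed=seed),
        seed=seed,
        qc=QCConfig(min_genes_per_spot=100),
    )


def load_config(path) -> PipelineConfig:
    """Parse a YAML pipeline config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    kwargs = dict(raw)
    if kwargs.get("sim") is not None:
        sim = dict(kwargs["sim"])
        if "isoforms_per_gene" in sim:
            sim["isoforms_per_gene"] = {int(k): float(v)
                                        for k, v in sim["isoforms_per_gene"].items()}
        for key in ("tex_markers", "tam_markers", "ratio_pair"):
            if key in sim:
                sim[key] = tuple(sim[key])
        kwargs["sim"] = SimConfig(**sim)
    if "qc" in kwargs:
        kwargs["qc"] = QCConfig(**kwargs["qc"])
    if "ds" in kwargs:
        kwargs["ds"] = DSConfig(**kwargs["ds"])
    for key in ("panel_a", "panel_b"):
        if key in kwargs:
            p = dict(kwargs[key])
            p["markers"] = tuple(p["markers"])
            kwargs[key] = MarkerPanel(**p)
    if "ratio_pair" in kwargs:
        kwargs["ratio_pair"] = tuple(kwargs["ratio_pair"])
    return PipelineConfig(**kwargs)


def validate_config(cfg: PipelineConfig) -> list:
    """Return every invariant violation (empty list = valid)."""
    violations = []
    if (cfg.input_dir is None) == (cfg.sim is None):
        violations.append("exactly one of input_dir and sim must be set")
    if not (cfg.ratio_high > cfg.ratio_low > 0):
        violations.append(
            f"ratio thresholds must satisfy high > low > 0 "
            f"(got high={cfg.ratio_high}, low={cfg.ratio_low})"
        )
    if not (0.0 <= cfg.fraction_cutoff <= 1.0):
        violations.append(f"fraction_cutoff {cfg.fraction_cutoff} outside [0, 1]")
    if len(cfg.ratio_pair) != 2 or cfg.ratio_pair[0] == cfg.ratio_pair[1]:
        violations.append("ratio_pair must name two distinct isoforms")
    if cfg.seed < 0:
        violations.append("seed must be non-negative")
    return violations


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    from .stats import TestResult

    if isinstance(obj, TestResult):
        return {"statistic": obj.statistic, "df": obj.df, "pvalue": obj.pvalue}
    if isinstance(obj, pd.DataFrame):
        return {str(k): {str(kk): _jsonable(vv) for kk, vv in v.items()}
                for k, v in obj.to_dict(orient="index").items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage in order and return the run manifest."""
    problems = validate_config(cfg)
    if problems:
        raise ConfigError("invalid config: " + "; ".join(problems))
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": cfg.to_dict(),
        "stages": {},
        "outputs": [],
        "inputs": {},
    }
    t_all = time.perf_counter()
    current = "setup"

    def _stage(name):
        nonlocal current
        current = name
        return time.perf_counter()

    def _done(name, t0, n_rows):
        manifest["stages"][name] = {
            "rows": int(n_rows),
            "seconds": round(time.perf_counter() - t0, 3),
        }

    def _emit(df: pd.DataFrame, name: str, index: bool = True):
        path = outdir / name
        df.to_csv(path, sep="\t", index=index, float_format="%.10g")
        manifest["outputs"].append(name)

    def _emit_json(obj, name: str):
        with open(outdir / name, "w") as fh:
            json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest["outputs"].append(name)

    try:
        if cfg.sim is not None:
            t0 = _stage("simulate")
            data_dir = outdir / "data"
            truth = generate_dataset(cfg.sim, data_dir)
            _done("simulate", t0, len(truth.spatial_class))
        else:
            data_dir = Path(cfg.input_dir)
            truth = None

        t0 = _stage("load")
        lattice = read_positions(data_dir / "tissue_positions.csv")
        gene_m = read_counts(data_dir / "gene_matrix.mtx", data_dir / "gene_features.tsv",
                             data_dir / "barcodes.tsv", level="gene")
        iso_m = read_counts(data_dir / "iso_matrix.mtx", data_dir / "iso_features.tsv",
                            data_dir / "iso_barcodes.tsv", level="isoform",
                            iso2gene=data_dir / "iso2gene.tsv")
        for f in ("tissue_positions.csv", "gene_matrix.mtx", "iso_matrix.mtx"):
            manifest["inputs"][f] = _sha256(data_dir / f)
        niche_path = data_dir / "truth_spots.tsv"
        niches = None
        if niche_path.exists():
            spot_truth = pd.read_csv(niche_path, sep="\t", index_col=0)
            niches = spot_truth["niche"].to_dict()
        _done("load", t0, gene_m.shape[0])

        t0 = _stage("qc")
        gene_m, removal_log = qc_filter_spots(gene_m, cfg.qc)
        _emit(removal_log, "qc_removal_log.tsv", index=False)
        kept = gene_m.spots
        iso_m = iso_m.subset_spots(kept)
        lattice = lattice.subset(kept)
        if niches is not None:
            niches = {s: niches[s] for s in kept}
        _done("qc", t0, len(kept))

        if niches is None:
            raise ConfigError(
                "no niche labels found (truth_spots.tsv); external labels are required "
                "for real-input runs"
            )

        t0 = _stage("normalize")
        gene_norm = log_normalize(gene_m)
        _done("normalize", t0, gene_norm.shape[0])

        t0 = _stage("neighbor_graph")
        graph = build_neighbor_graph(lattice)
        _emit(graph.to_edge_frame(), "neighbor_graph.tsv", index=False)
        _done("neighbor_graph", t0, len(graph.spot_ids))

        t0 = _stage("contact_frequency")
        cf = contact_frequency(graph, niches)
        _emit(cf.rename_axis("spot_id").to_frame(), "contact_frequency.tsv")
        _done("contact_frequency", t0, len(cf))

        t0 = _stage("isoform_classes")
        classes = classify_spatial(iso_m, niches, cfg.ds.detection_min_spots)
        out_classes = classes.copy()
        out_classes["support"] = [",".join(map(str, s)) for s in out_classes["support"]]
        _emit(out_classes, "spatial_classes.tsv")
        _emit_json(class_distribution(classes), "class_distribution.json")
        _done("isoform_classes", t0, len(classes))

        if (data_dir / "before").exists() and (data_dir / "after_ln").exists():
            t0 = _stage("expression_patterns")
            trio = {"after": iso_m}
            for key, sub in (("before", "before"), ("after_ln", "after_ln")):
                d = data_dir / sub
                trio[key] = read_counts(d / "iso_matrix.mtx", d / "iso_features.tsv",
                                        d / "iso_barcodes.tsv", level="isoform",
                                        iso2gene=data_dir / "iso2gene.tsv")
                trio[key] = trio[key].subset_spots(
                    [s for s in kept if s in set(trio[key].spots)])
            patterns = classify_pattern(trio, cfg.ds)
            out_pat = patterns.copy()
            out_pat["labels"] = [",".join(t) for t in out_pat["labels"]]
            _emit(out_pat, "expression_patterns.tsv")
            _done("expression_patterns", t0, len(patterns))

        t0 = _stage("differential_splicing")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds_res = differential_splicing(iso_m, niches, cfg.ds)
        _emit(ds_res, "differential_splicing.tsv", index=False)
        _done("differential_splicing", t0, len(ds_res))

        t0 = _stage("presence")
        presence = call_presence_markers(gene_m, cfg.panel_a, cfg.panel_b)
        _emit(presence, "presence.tsv")
        _done("presence", t0, len(presence))

        t0 = _stage("enrichment")
        enr = enrichment_score(graph, presence)
        _emit(enr, "enrichment.tsv")
        _done("enrichment", t0, len(enr))

        t0 = _stage("ratio_groups")
        ratios = compute_ratio(iso_m, cfg.ratio_pair[0], cfg.ratio_pair[1])
        grouping = assign_groups(ratios, high=cfg.ratio_high, low=cfg.ratio_low)
        _emit(grouping, "ratio_groups.tsv")
        _emit_json(enrichment_summary(enr, grouping["group"]), "enrichment_summary.json")
        _done("ratio_groups", t0, len(grouping))

        t0 = _stage("association")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = association_report(grouping, enr)
        _emit_json(report, "association_report.json")
        _done("association", t0, report["n_spots"])

    except IsonicheError:
        (outdir / "FAILED").write_text(f"failed at stage: {current}\n")
        raise
    except Exception as exc:
        (outdir / "FAILED").write_text(f"failed at stage: {current}\n")
        raise IsonicheError(f"stage {current!r} failed: {exc}") from exc

    manifest["total_seconds"] = round(time.perf_counter() - t_all, 3)
    tmp = outdir / "manifest.json.tmp"
    with open(tmp, "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)
        fh.write("\n")
    tmp.replace(outdir / "manifest.json")
    return manifest
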