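"""End-to-end orchestration: simulate/ingest -> curate orthologs ->
deconvolve -> quantify -> analyze -> compare, with a JSON run manifest.

The manifest records, per stage, the parameters used, the in/out item
counts, and a sha256 checksum of every file written (paths relative to
the output directory, no timestamps), so a rerun with the same config
and seed is byte-identical and a molecule-conservation audit can be
replayed from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import de as de_mod
from . import deconvolve as dc
from . import identity, io, orthologs, quantify
from .simulate import SimulationConfig, make_homology_records, simulate_chimera

logger = logging.getLogger(__name__)

STAGES = ["input", "ortholog", "deconvolve", "quantify", "analyze", "compare"]


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    mode: str = "synthetic"  # synthetic | read_table | sam
    outdir: str = "chimeraseq_run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    deconvolution: dc.DeconvolutionParams = field(
        default_factory=dc.DeconvolutionParams
    )
    scale_factor: float = 1e4
    n_clusters: int = 2
    labels_path: str | None = None
    alpha: float = 0.05
    fold_cutoff: float = 2.0
    test: str = "ranksum"
    pseudocount: float = 0.01
    de_scale: str = "linear"  # scale of the DE fold ratio (linear | log)
    panels: dict = field(default_factory=dict)  # name -> TSV path
    read_table_path: str | None = None
    sam_path: str | None = None
    sam_score_tag: str = "AS"
    ortholog_path: str | None = None
    ortholog_precurated: bool = False
    write_read_table: bool = False
    write_molecules: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        dec = dc.DeconvolutionParams(**raw.pop("deconvolution", {}))
        return cls(simulation=sim, deconvolution=dec, **raw)

    def to_manifest_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        d["deconvolution"] = self.deconvolution.to_dict()
        d.pop("outdir", None)  # keep the manifest location-independent
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config: RunConfig):
        self.outdir = outdir
        self.data: dict = {
            "config": config.to_manifest_dict(),
            "stages": [],
            "conservation": {},
        }

    def add_stage(self, name: str, params: dict, counts: dict,
                  outputs: list[Path]) -> None:
        self.data["stages"].append(
            {
                "name": name,
                "parameters": params,
                "counts": counts,
                "outputs": {
                    str(p.relative_to(self.outdir)): _sha256(p) for p in outputs
                },
            }
        )

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in fixed order and return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config)
    state: dict = {}

    def stage(name: str, fn) -> None:
        try:
            fn()
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001 - attribute failure to the stage
            manifest.data["failure"] = {"stage": name, "cause": str(e)}
            manifest.write()
            raise PipelineError(name, e) from e

    # ---- input ------------------------------------------------------
    def _input() -> None:
        outputs = []
        if config.mode == "synthetic":
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            reads, truth = simulate_chimera(sim)
            state["reads"], state["truth"], state["sim"] = reads, truth, sim
            if config.write_read_table:
                p = outdir / "read_table.tsv"
                io.write_read_table(reads, p)
                outputs.append(p)
                io.write_truth(truth, outdir / "truth")
                outputs += sorted((outdir / "truth").glob("*.tsv"))
        elif config.mode == "read_table":
            if not config.read_table_path:
                raise FileNotFoundError("read_table_path is required")
            state["reads"] = io.read_read_table(config.read_table_path)
        elif config.mode == "sam":
            if not config.sam_path:
                raise FileNotFoundError("sam_path is required")
            state["reads"] = io.read_sam_records(
                config.sam_path, score_tag=config.sam_score_tag
            )
        else:
            raise ValueError(f"unknown input mode {config.mode!r}")
        manifest.add_stage(
            "input",
            {"mode": config.mode, "seed": config.seed},
            {"n_reads": len(state["reads"])},
            outputs,
        )

    # ---- ortholog table ---------------------------------------------
    def _ortholog() -> None:
        if config.mode == "synthetic":
            records = make_homology_records(state["sim"])
            table = orthologs.build_ortholog_table(records)
        else:
            if not config.ortholog_path:
                raise FileNotFoundError("ortholog_path is required")
            if config.ortholog_precurated:
                table = orthologs.OrthologTable.read_tsv(config.ortholog_path)
            else:
                records = orthologs.read_homology_report(config.ortholog_path)
                table = orthologs.build_ortholog_table(records)
        state["table"] = table
        p = outdir / "ortholog_table.tsv"
        table.write_tsv(p)
        pd_ = outdir / "ortholog_dropped.tsv"
        table.dropped_classes.to_csv(pd_, sep="\t", index=False)
        manifest.add_stage(
            "ortholog",
            {"precurated": config.ortholog_precurated},
            {"n_entries": len(table), "n_dropped": len(table.dropped_classes)},
            [p, pd_],
        )

    # ---- deconvolution ----------------------------------------------
    def _deconvolve() -> None:
        reads = state["reads"]
        params = config.deconvolution
        calls_r = dc.assign_reads(reads)
        n_groups = reads.groupby(["barcode", "umi"]).ngroups
        molecules = dc.collapse_umis(reads, params, calls=calls_r)
        read_calls = pd.DataFrame(
            {"barcode": reads["barcode"], "call": calls_r.to_numpy()}
        )
        barcode_calls = dc.classify_barcodes(molecules, params, read_calls=read_calls)
        called = molecules["barcode"].isin(barcode_calls["barcode"])
        n_uncalled = int((~called).sum())
        split = dc.split_by_species(molecules[called], barcode_calls)
        summary = dc.classification_summary(barcode_calls)

        state.update(molecules=molecules, calls=barcode_calls, split=split)
        p = outdir / "barcode_calls.tsv"
        barcode_calls.to_csv(p, sep="\t", index=False, float_format="%.6g")
        outputs = [p]
        if config.write_molecules:
            for name, df in (
                ("molecules_human.tsv", split.human),
                ("molecules_mouse.tsv", split.mouse),
                ("molecules_excluded.tsv", split.excluded),
            ):
                q = outdir / name
                df.to_csv(q, sep="\t", index=False)
                outputs.append(q)
        manifest.add_stage(
            "deconvolve",
            params.to_dict(),
            {
                "n_reads": len(reads),
                "n_umi_groups": int(n_groups),
                "n_molecules": len(molecules),
                "n_dropped_min_reads": int(n_groups - len(molecules)),
                "n_molecules_uncalled_barcode": n_uncalled,
                "n_molecules_human": len(split.human),
                "n_molecules_mouse": len(split.mouse),
                "n_molecules_excluded": len(split.excluded),
                **summary,
            },
            outputs,
        )

    # ---- quantification ---------------------------------------------
    def _quantify() -> None:
        split = state["split"]
        cm_h = quantify.count_molecules(split.human, "human")
        cm_m = quantify.count_molecules(split.mouse, "mouse")
        merged_raw, report = quantify.merge_species_matrices(
            cm_h, cm_m, state["table"]
        )
        merged = quantify.log_normalize(merged_raw, config.scale_factor)
        state.update(cm_h=cm_h, cm_m=cm_m, merged=merged)
        outputs = []
        for name, cm in (("human_counts", cm_h), ("mouse_counts", cm_m),
                         ("merged_lognorm", merged)):
            d = outdir / name
            cm.save_mtx(d)
            outputs += sorted(d.iterdir())
        manifest.add_stage(
            "quantify",
            {"scale_factor": config.scale_factor},
            {
                "human_matrix_total": cm_h.total(),
                "mouse_matrix_total": cm_m.total(),
                "n_shared_genes": len(merged.genes),
                "n_human_unmapped_genes": len(report.human_unmapped),
                "n_mouse_not_shared": len(report.mouse_not_shared),
                "n_merged_barcodes": len(merged.barcodes),
            },
            outputs,
        )

    # ---- identity analysis ------------------------------------------
    def _analyze() -> None:
        merged = state["merged"]
        provided = None
        if config.labels_path:
            lab = pd.read_csv(config.labels_path, sep="\t")
            provided = pd.Series(
                lab.iloc[:, 1].to_numpy(), index=lab.iloc[:, 0].to_numpy()
            )
        labels = identity.cluster_cells(
            merged, k=config.n_clusters, seed=config.seed, provided=provided
        )
        profiles, n_cells = identity.cluster_mean_profiles(merged, labels)
        corr = identity.cross_correlate_clusters(profiles)
        state.update(labels=labels, profiles=profiles)
        p1 = outdir / "cluster_labels.tsv"
        labels.labels.rename_axis("barcode").reset_index().to_csv(
            p1, sep="\t", index=False
        )
        p2 = outdir / "cluster_correlation.tsv"
        corr.to_csv(p2, sep="\t", float_format="%.6g")
        manifest.add_stage(
            "analyze",
            {
                "k": config.n_clusters,
                "provenance": labels.provenance,
            },
            {"n_clusters": int(profiles.shape[0]),
             "cluster_sizes": {str(k): int(v) for k, v in n_cells.items()}},
            [p1, p2],
        )

    # ---- cross-species comparison -----------------------------------
    def _compare() -> None:
        merged = state["merged"]
        human_cells = [b for b in merged.barcodes if b.endswith("_human")]
        mouse_cells = [b for b in merged.barcodes if b.endswith("_mouse")]
        pairs = de_mod.ortholog_pair_means(
            merged, human_cells, mouse_cells, config.pseudocount
        )
        conc = de_mod.concordance(pairs)
        det = de_mod.differential_orthologs(
            merged,
            human_cells,
            mouse_cells,
            alpha=config.alpha,
            fold_cutoff=config.fold_cutoff,
            test=config.test,
            pseudocount=config.pseudocount,
            scale=config.de_scale,
        )
        outputs = []
        p1 = outdir / "ortholog_pair_means.tsv"
        pairs.to_csv(p1, sep="\t", float_format="%.6g")
        p2 = outdir / "de_table.tsv"
        det.to_csv(p2, sep="\t", float_format="%.6g")
        p3 = outdir / "concordance.tsv"
        pd.DataFrame([dataclasses.asdict(conc)]).to_csv(p3, sep="\t", index=False)
        outputs += [p1, p2, p3]
        panel_rows = []
        for name, path in sorted(config.panels.items()):
            genes = pd.read_csv(path, sep="\t")["gene"].astype(str).tolist()
            s = de_mod.panel_summary(pairs, genes, name, table=state.get("table"))
            panel_rows.append(s.to_dict())
        if panel_rows:
            p4 = outdir / "panel_summaries.tsv"
            pd.DataFrame(panel_rows).to_csv(p4, sep="\t", index=False)
            outputs.append(p4)
        cls_counts = det["class"].value_counts()
        manifest.add_stage(
            "compare",
            {
                "alpha": config.alpha,
                "fold_cutoff": config.fold_cutoff,
                "test": config.test,
                "pseudocount": config.pseudocount,
            },
            {
                "n_pairs": conc.n_pairs,
                "fraction_within_twofold": conc.fraction_within_twofold,
                "r_squared": conc.r_squared,
                "n_human_enriched": int(cls_counts.get(de_mod.HUMAN_ENRICHED, 0)),
                "n_mouse_enriched": int(cls_counts.get(de_mod.MOUSE_ENRICHED, 0)),
            },
            outputs,
        )

    for name, fn in zip(
        STAGES, [_input, _ortholog, _deconvolve, _quantify, _analyze, _compare]
    ):
        stage(name, fn)

    audit = _conservation(manifest.data)
    manifest.data["conservation"] = audit
    manifest.write()
    logger.info(
        "pipeline complete: %d reads -> %d molecules -> %d counted UMIs",
        audit["n_reads"], audit["n_molecules"], audit["n_counted"],
    )
    return manifest.data


def _conservation(manifest: dict) -> dict:
    stages = {s["name"]: s for s in manifest["stages"]}
    d = stages["deconvolve"]["counts"]
    q = stages["quantify"]["counts"]
    n_counted = int(q["human_matrix_total"] + q["mouse_matrix_total"])
    checks = {
        "umi_groups_accounted": d["n_umi_groups"]
        == d["n_molecules"] + d["n_dropped_min_reads"],
        "molecules_accounted": d["n_molecules"]
        == d["n_molecules_human"]
        + d["n_molecules_mouse"]
        + d["n_molecules_excluded"]
        + d["n_molecules_uncalled_barcode"],
        "counts_match_molecules": n_counted
        == d["n_molecules_human"] + d["n_molecules_mouse"],
    }
    return {
        "n_reads": d["n_reads"],
        "n_umi_groups": d["n_umi_groups"],
        "n_molecules": d["n_molecules"],
        "n_counted": n_counted,
        "checks": checks,
        "reconciled": all(checks.values()),
    }


def verify_conservation(manifest: dict) -> bool:
    """True when every molecule in the manifest is accounted for."""
    return bool(manifest["conservation"]["reconciled"])
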