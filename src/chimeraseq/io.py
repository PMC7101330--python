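"""On-disk formats: the read-table TSV dialect, ground-truth tables,
and a SAM/BAM ingest adapter for pooled-reference alignments.

The read-table contract is a TSV with columns read_id, barcode, umi,
gene_human, score_human, gene_mouse, score_mouse; a missing alignment
is an empty gene plus an empty score field.  The SAM adapter extracts
the same records from a pooled-reference alignment whose contig names
carry species prefixes, taking the best numeric alignment score per
species per read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import READ_TABLE_COLUMNS, GroundTruth

_SCORE_FMT = "%.4f"


def write_read_table(reads: pd.DataFrame, path) -> None:
    df = reads[READ_TABLE_COLUMNS]
    df.to_csv(path, sep="\t", index=False, float_format=_SCORE_FMT)


def read_read_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "read_id": str,
            "barcode": str,
            "umi": str,
            "gene_human": str,
            "gene_mouse": str,
            "score_human": float,
            "score_mouse": float,
        },
        keep_default_na=False,
        na_values={"score_human": [""], "score_mouse": [""]},
    )
    missing = set(READ_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"read table lacks columns: {sorted(missing)}")
    return df[READ_TABLE_COLUMNS]


def write_truth(truth: GroundTruth, outdir) -> None:
    """Barcode table, per-gene fold table, and read-origin table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.barcode_species.rename_axis("barcode").reset_index().to_csv(
        outdir / "truth_barcodes.tsv", sep="\t", index=False
    )
    folds = truth.gene_log2_fold.rename("planted_log2_fold").rename_axis(
        "human_symbol"
    )
    folds.reset_index().to_csv(outdir / "truth_gene_folds.tsv", sep="\t", index=False)
    truth.molecule_counts.to_csv(
        outdir / "truth_molecule_counts.tsv", sep="\t", index=False
    )


DEFAULT_PREFIX_MAP = {"hg": "human", "GRCh": "human", "mm": "mouse", "GRCm": "mouse"}


def read_sam_records(
    path,
    score_tag: str = "AS",
    barcode_tag: str = "CB",
    umi_tag: str = "UB",
    gene_tag: str = "GX",
    prefix_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Build a read table from a pooled-reference SAM/BAM.

    The reference must name contigs with species prefixes (configurable
    ``prefix_map``, e.g. ``hg19_chr1``); the species of each alignment
    is taken from its contig, the score from ``score_tag``, and the
    gene from ``gene_tag`` when present, else the unprefixed contig
    name.  For each read the best-scoring alignment per species is
    retained.
    """
    import pysam

    prefix_map = prefix_map or DEFAULT_PREFIX_MAP
    best: dict[str, dict] = {}
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            contig = aln.reference_name or ""
            species = None
            for prefix, sp in prefix_map.items():
                if contig.startswith(prefix):
                    species = sp
                    break
            if species is None:
                continue
            try:
                score = float(aln.get_tag(score_tag))
            except KeyError:
                continue
            gene = (
                str(aln.get_tag(gene_tag))
                if aln.has_tag(gene_tag)
                else contig.split("_", 1)[-1]
            )
            barcode = str(aln.get_tag(barcode_tag)) if aln.has_tag(barcode_tag) else ""
            umi = str(aln.get_tag(umi_tag)) if aln.has_tag(umi_tag) else ""
            rec = best.setdefault(
                aln.query_name,
                {
                    "read_id": aln.query_name,
                    "barcode": barcode,
                    "umi": umi,
                    "gene_human": "",
                    "score_human": np.nan,
                    "gene_mouse": "",
                    "score_mouse": np.nan,
                },
            )
            cur = rec[f"score_{species}"]
            if np.isnan(cur) or score > cur:
                rec[f"score_{species}"] = score
                rec[f"gene_{species}"] = gene
    if not best:
        return pd.DataFrame(columns=READ_TABLE_COLUMNS)
    return pd.DataFrame(list(best.values()))[READ_TABLE_COLUMNS]


def builtin_panel(name: str) -> list[str]:
    """Editable disease gene panel shipped with the package.

    The panels (``ms``, ``ad``, ``pd``) are illustrative subsets of
    microglia-expressed disease-risk genes drawn from public reports;
    they are plain inputs with no provenance claim and are meant to be
    replaced by a user-supplied TSV for real analyses.
    """
    path = Path(__file__).parent / "data" / "panels" / f"{name}.tsv"
    if not path.exists():
        raise FileNotFoundError(f"no builtin panel {name!r}")
    return pd.read_csv(path, sep="\t")["gene"].astype(str).tolist()
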