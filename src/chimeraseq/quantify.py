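"""UMI count matrices: construction from molecules, log normalization,
and cross-species merging into a shared ortholog namespace.

A :class:`CountMatrix` is barcodes x genes with sparse storage; raw
matrices hold integer UMI counts, normalized matrices hold
ln(1 + count / cell_total * scale_factor) values (the standard droplet
counts-per-10k convention).  Merging translates human gene symbols to
mouse symbols through the 1:1 ortholog table and restricts to the
shared namespace, since cross-species comparisons are defined only on
genes with unique orthologs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .orthologs import HUMAN_TO_MOUSE, OrthologTable, translate_symbols

logger = logging.getLogger(__name__)

RAW = "raw"
LOG_NORMALIZED = "log_normalized"


@dataclass
class CountMatrix:
    barcodes: np.ndarray  # ordered, unique
    genes: np.ndarray  # ordered, unique
    counts: sp.csr_matrix  # barcodes x genes
    species: str  # human | mouse | merged
    normalization: str = RAW

    def __post_init__(self) -> None:
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.genes = np.asarray(self.genes, dtype=object)
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes")
        if self.counts.shape != (len(self.barcodes), len(self.genes)):
            raise ValueError("counts shape does not match labels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def total(self) -> float:
        return float(self.counts.sum())

    def to_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.toarray(), index=self.barcodes, columns=self.genes
        )

    def to_anndata(self):
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.copy(),
            obs=pd.DataFrame(index=pd.Index(self.barcodes, name="barcode")),
            var=pd.DataFrame(index=pd.Index(self.genes, name="gene")),
        )
        adata.uns["species"] = self.species
        adata.uns["normalization"] = self.normalization
        return adata

    def save_mtx(self, outdir) -> None:
        """10x-style directory: matrix.mtx + barcodes.tsv + features.tsv
        + a sidecar metadata.tsv recording species and normalization."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mmwrite(outdir / "matrix.mtx", self.counts.T.tocoo())  # genes x barcodes
        pd.Series(self.barcodes).to_csv(
            outdir / "barcodes.tsv", sep="\t", index=False, header=False
        )
        pd.Series(self.genes).to_csv(
            outdir / "features.tsv", sep="\t", index=False, header=False
        )
        meta = pd.DataFrame(
            {"key": ["species", "normalization"],
             "value": [self.species, self.normalization]}
        )
        meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)

    @classmethod
    def load_mtx(cls, indir) -> "CountMatrix":
        from pathlib import Path

        indir = Path(indir)
        mat = sp.csr_matrix(mmread(indir / "matrix.mtx").T)
        barcodes = pd.read_csv(
            indir / "barcodes.tsv", sep="\t", header=None
        )[0].to_numpy(dtype=object)
        genes = pd.read_csv(
            indir / "features.tsv", sep="\t", header=None
        )[0].to_numpy(dtype=object)
        meta = pd.read_csv(indir / "metadata.tsv", sep="\t").set_index("key")["value"]
        return cls(
            barcodes=barcodes,
            genes=genes,
            counts=mat,
            species=str(meta.get("species", "merged")),
            normalization=str(meta.get("normalization", RAW)),
        )


def count_molecules(molecules: pd.DataFrame, species: str) -> CountMatrix:
    """Raw UMI matrix: entry (b, g) = distinct UMIs of gene g in barcode b.

    ``molecules`` must come from the per-species split (one row per
    molecule); duplicate (barcode, umi, gene) rows indicate a broken
    upstream collapse and are rejected.
    """
    if len(molecules) == 0:
        warnings.warn("empty molecule set: returning 0x0 matrix")
        return CountMatrix(
            barcodes=np.array([], dtype=object),
            genes=np.array([], dtype=object),
            counts=sp.csr_matrix((0, 0), dtype=np.int64),
            species=species,
        )
    if molecules.duplicated(["barcode", "umi", "gene"]).any():
        raise ValueError("duplicate (barcode, umi, gene) molecules: collapse broken")
    b = pd.Categorical(molecules["barcode"])
    g = pd.Categorical(molecules["gene"])
    mat = sp.coo_matrix(
        (np.ones(len(molecules), dtype=np.int64), (b.codes, g.codes)),
        shape=(len(b.categories), len(g.categories)),
    ).tocsr()
    return CountMatrix(
        barcodes=b.categories.to_numpy(dtype=object),
        genes=g.categories.to_numpy(dtype=object),
        counts=mat,
        species=species,
    )


def log_normalize(matrix: CountMatrix, scale_factor: float = 1e4) -> CountMatrix:
    """ln(1 + count / cell_total * scale_factor) per entry.

    Zero-total barcodes are dropped (logged).  Strictly monotone in the
    raw count at fixed cell total.
    """
    if matrix.normalization != RAW:
        raise ValueError("matrix is already normalized")
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = np.asarray(matrix.counts.sum(axis=1)).ravel()
    keep = totals > 0
    if not keep.all():
        logger.info("dropping %d zero-total barcodes", int((~keep).sum()))
    X = matrix.counts[keep].tocoo().astype(np.float64)
    t = totals[keep]
    X.data = np.log1p(X.data / t[X.row] * scale_factor)
    return CountMatrix(
        barcodes=matrix.barcodes[keep],
        genes=matrix.genes.copy(),
        counts=X.tocsr(),
        species=matrix.species,
        normalization=LOG_NORMALIZED,
    )


@dataclass
class MergeReport:
    """Genes that could not enter the shared namespace."""

    human_unmapped: list[str] = field(default_factory=list)  # no table entry
    human_not_in_mouse: list[str] = field(default_factory=list)
    mouse_not_shared: list[str] = field(default_factory=list)


def merge_species_matrices(
    human: CountMatrix,
    mouse: CountMatrix,
    table: OrthologTable,
) -> tuple[CountMatrix, MergeReport]:
    """Merge per-species matrices into the shared mouse-symbol namespace.

    Human symbols are translated human -> mouse; the merged gene set is
    the intersection of translated human genes with the mouse genes
    (order follows the mouse matrix).  Barcodes get a ``_human`` /
    ``_mouse`` suffix; untranslatable genes are reported, never silently
    dropped.
    """
    if human.normalization != mouse.normalization:
        raise ValueError("matrices must share a normalization state")
    translated, unmapped = translate_symbols(
        list(human.genes), table, HUMAN_TO_MOUSE
    )
    mapping = table.mapping(HUMAN_TO_MOUSE)
    human_in_mouse_ns = {mapping[g]: g for g in human.genes if g in mapping}
    shared = [g for g in mouse.genes if g in human_in_mouse_ns]
    report = MergeReport(
        human_unmapped=unmapped,
        human_not_in_mouse=sorted(set(translated) - set(mouse.genes)),
        mouse_not_shared=[g for g in mouse.genes if g not in human_in_mouse_ns],
    )

    h_order = [human_in_mouse_ns[g] for g in shared]
    h_pos = pd.Series(range(len(human.genes)), index=human.genes)
    m_pos = pd.Series(range(len(mouse.genes)), index=mouse.genes)
    Xh = human.counts[:, h_pos[h_order].to_numpy()]
    Xm = mouse.counts[:, m_pos[shared].to_numpy()]

    new_barcodes = np.concatenate(
        [
            np.char.add(human.barcodes.astype(str), "_human"),
            np.char.add(mouse.barcodes.astype(str), "_mouse"),
        ]
    ).astype(object)
    if len(set(new_barcodes)) != len(new_barcodes):
        raise ValueError("barcode collision after species suffixing")
    merged = CountMatrix(
        barcodes=new_barcodes,
        genes=np.array(shared, dtype=object),
        counts=sp.vstack([Xh, Xm]).tocsr(),
        species="merged",
        normalization=human.normalization,
    )
    return merged, report
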