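"""Synthetic mixed-species ("barnyard") droplet scRNA-seq generator.

Emulates the read-level structure produced by aligning a chimeric
human/mouse brain sample against a pooled two-species reference:
every read carries a cell barcode, a UMI, and a best alignment
(gene, score) per species.  Expression is negative-binomial per gene
per cell with a lognormal library-size factor; interspecies doublets
are built by pooling one human and one mouse cell's molecules under a
fresh barcode.  Full ground truth (barcode species, per-gene molecule
counts, read origins, planted fold-changes) is returned alongside the
read table so downstream stages can be scored exactly.

Alignment scores are modelled as one draw near the own-species score
level and one near the (lower) cross-species level; the two draws are
order-enforced so that with ``misassignment_rate = 0`` every read's
own-species score strictly exceeds its other-species score, and a read
is misassigned exactly when the generator swaps the pair.  Only reads
from orthologous genes receive a cross-species alignment;
species-exclusive genes align to their own genome alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

HUMAN = "human"
MOUSE = "mouse"
DOUBLET = "doublet"

#: column order of the read table contract
READ_TABLE_COLUMNS = [
    "read_id",
    "barcode",
    "umi",
    "gene_human",
    "score_human",
    "gene_mouse",
    "score_mouse",
]


def _ortholog_symbols(n: int) -> tuple[list[str], list[str]]:
    """Paired symbols: upper-case human form, capitalized mouse form."""
    human = [f"GENE{i:05d}" for i in range(n)]
    mouse = [f"Gene{i:05d}" for i in range(n)]
    return human, mouse


@dataclass
class SimulationConfig:
    """Parameters of one synthetic chimeric dataset.

    Counts are desk-scale by default: a few hundred cells per species
    and ~1,200 genes, with per-cell molecule depth far below a real 10x
    run so that whole pipelines execute in seconds.  The doublet rate
    default (0.8%) matches the order of cross-species barcode
    contamination observed in chimeric-brain data.
    """

    n_cells_human: int = 300
    n_cells_mouse: int = 300
    doublet_rate: float = 0.008
    n_ortholog_genes: int = 1000
    n_human_only_genes: int = 100
    n_mouse_only_genes: int = 100
    reads_per_molecule: float = 3.0
    molecules_per_cell: float = 300.0
    nb_dispersion: float = 2.0
    library_sigma: float = 0.3
    score_own_mean: float = 90.0
    score_other_mean: float = 60.0
    score_sd: float = 8.0
    misassignment_rate: float = 0.002
    planted_fold_changes: Mapping[str, float] = field(default_factory=dict)
    # extra homology classes emitted only in the homology report, to
    # stress the curation stage (they carry no expression)
    n_many_to_one_classes: int = 0
    n_collision_classes: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells_human == 0 and self.n_cells_mouse == 0:
            raise ValueError("at least one species must have cells")
        for name in ("doublet_rate", "misassignment_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_cells_human",
            "n_cells_mouse",
            "n_ortholog_genes",
            "n_human_only_genes",
            "n_mouse_only_genes",
            "n_many_to_one_classes",
            "n_collision_classes",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.score_own_mean <= self.score_other_mean:
            raise ValueError("score_own_mean must exceed score_other_mean")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.reads_per_molecule < 1:
            raise ValueError("reads_per_molecule must be >= 1")
        if self.molecules_per_cell <= 0:
            raise ValueError("molecules_per_cell must be positive")
        human_orth = set(_ortholog_symbols(self.n_ortholog_genes)[0])
        bad = sorted(set(self.planted_fold_changes) - human_orth)
        if bad:
            raise ValueError(
                "planted fold-changes must target ortholog genes (human "
                f"symbols); not orthologs: {bad[:5]}"
            )

    @property
    def n_doublets(self) -> int:
        return int(round(self.doublet_rate * (self.n_cells_human + self.n_cells_mouse)))

    def gene_symbols(self, species: str) -> list[str]:
        """Own-namespace gene list for one species (orthologs first)."""
        h_orth, m_orth = _ortholog_symbols(self.n_ortholog_genes)
        if species == HUMAN:
            return h_orth + [f"HONLY{i:04d}" for i in range(self.n_human_only_genes)]
        if species == MOUSE:
            return m_orth + [f"Monly{i:04d}" for i in range(self.n_mouse_only_genes)]
        raise ValueError(f"unknown species {species!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted_fold_changes"] = dict(self.planted_fold_changes)
        return d


@dataclass
class GroundTruth:
    """Exact generative record of one simulated dataset."""

    barcode_species: pd.Series  # barcode -> human | mouse | doublet
    molecule_counts: pd.DataFrame  # barcode, species, gene, count
    gene_log2_fold: pd.Series  # human ortholog symbol -> planted log2 fold
    read_species: pd.Series  # read_id -> true species of origin
    config: SimulationConfig

    def n_molecules(self, species: str) -> int:
        sel = self.molecule_counts["species"] == species
        return int(self.molecule_counts.loc[sel, "count"].sum())


@dataclass
class TruthSummary:
    n_human_cells: int
    n_mouse_cells: int
    n_doublets: int
    gene_table: pd.DataFrame  # per ortholog pair: mean counts + realized fold


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """NB with mean mu and variance mu + mu^2/theta."""
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p)


def simulate_chimera(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a pooled-alignment read table plus its ground truth.

    Returns a DataFrame with :data:`READ_TABLE_COLUMNS` (absent
    alignments encoded as empty gene and NaN score) and the matching
    :class:`GroundTruth`.  Identical config and seed give byte-identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_h, n_m, n_d = config.n_cells_human, config.n_cells_mouse, config.n_doublets
    genes_h = np.array(config.gene_symbols(HUMAN))
    genes_m = np.array(config.gene_symbols(MOUSE))
    n_orth = config.n_ortholog_genes

    # shared base expression weights for orthologs; independent weights
    # for species-exclusive genes
    w_orth = rng.lognormal(0.0, 1.0, n_orth)
    w_honly = rng.lognormal(0.0, 1.0, config.n_human_only_genes)
    w_monly = rng.lognormal(0.0, 1.0, config.n_mouse_only_genes)
    mu_h = np.concatenate([w_orth, w_honly])
    mu_m = np.concatenate([w_orth, w_monly])
    mu_h = mu_h / mu_h.sum() * config.molecules_per_cell if mu_h.size else mu_h
    mu_m = mu_m / mu_m.sum() * config.molecules_per_cell if mu_m.size else mu_m

    # planted log2 folds (human over mouse) applied on the human side
    fold = pd.Series(0.0, index=_ortholog_symbols(n_orth)[0])
    for g, lf in config.planted_fold_changes.items():
        fold[g] = float(lf)
    if n_orth:
        mu_h = mu_h.copy()
        mu_h[:n_orth] *= 2.0 ** fold.to_numpy()

    # barcode layout: singlets first, then doublet barcodes; each doublet
    # pools one extra hidden cell of each species
    n_barcodes = n_h + n_m + n_d
    barcodes = np.array([f"BC{i:05d}" for i in range(n_barcodes)])
    species_label = np.array([HUMAN] * n_h + [MOUSE] * n_m + [DOUBLET] * n_d)

    def simulate_cells(n_cells: int, mu: np.ndarray) -> np.ndarray:
        if n_cells == 0 or mu.size == 0:
            return np.zeros((n_cells, mu.size), dtype=np.int64)
        lib = rng.lognormal(0.0, config.library_sigma, n_cells)
        return _nb_counts(rng, np.outer(lib, mu), config.nb_dispersion)

    counts_h = simulate_cells(n_h + n_d, mu_h)  # hidden doublet halves last
    counts_m = simulate_cells(n_m + n_d, mu_m)

    # map cells to barcode indices
    bidx_h = np.concatenate([np.arange(n_h), n_h + n_m + np.arange(n_d)])
    bidx_m = np.concatenate([n_h + np.arange(n_m), n_h + n_m + np.arange(n_d)])

    def molecule_frame(counts: np.ndarray, bidx: np.ndarray, genes: np.ndarray,
                       species: str) -> pd.DataFrame:
        cell, gene = np.nonzero(counts)
        n = counts[cell, gene]
        return pd.DataFrame(
            {
                "barcode_idx": np.repeat(bidx[cell], n),
                "species": species,
                "gene_idx": np.repeat(gene, n),
            }
        )

    mol = pd.concat(
        [
            molecule_frame(counts_h, bidx_h, genes_h, HUMAN),
            molecule_frame(counts_m, bidx_m, genes_m, MOUSE),
        ],
        ignore_index=True,
    )
    mol = mol.sort_values(["barcode_idx", "species", "gene_idx"], kind="stable")
    mol = mol.reset_index(drop=True)
    # UMIs unique within a barcode
    umi_rank = mol.groupby("barcode_idx").cumcount()
    mol["umi"] = np.char.add("UMI", umi_rank.to_numpy().astype("U8"))

    n_mol = len(mol)
    reads_per = 1 + rng.poisson(config.reads_per_molecule - 1.0, n_mol)
    ridx = np.repeat(np.arange(n_mol), reads_per)
    n_reads = len(ridx)

    r_species = mol["species"].to_numpy()[ridx]
    r_gene_idx = mol["gene_idx"].to_numpy()[ridx]
    r_barcode = barcodes[mol["barcode_idx"].to_numpy()[ridx]]
    r_umi = mol["umi"].to_numpy()[ridx]
    is_human = r_species == HUMAN
    is_orth = r_gene_idx < n_orth  # orthologs lead both gene lists

    own_gene = np.where(is_human, genes_h[r_gene_idx], genes_m[r_gene_idx])
    if n_orth:
        pidx = np.minimum(r_gene_idx, n_orth - 1)
        partner = np.where(is_human, genes_m[pidx], genes_h[pidx])
    else:
        partner = np.full(n_reads, "", dtype=object)

    # order-enforced score pair; swap == misassignment
    a = rng.normal(config.score_own_mean, config.score_sd, n_reads)
    b = rng.normal(config.score_other_mean, config.score_sd, n_reads)
    hi, lo = np.maximum(a, b), np.minimum(a, b)
    swap = (rng.random(n_reads) < config.misassignment_rate) & is_orth
    own_score = np.where(swap, lo, hi)
    other_score = np.where(swap, hi, lo)

    gene_human = np.where(is_human, own_gene, np.where(is_orth, partner, ""))
    gene_mouse = np.where(~is_human, own_gene, np.where(is_orth, partner, ""))
    score_human = np.where(is_human, own_score, np.where(is_orth, other_score, np.nan))
    score_mouse = np.where(~is_human, own_score, np.where(is_orth, other_score, np.nan))

    read_ids = np.char.add("R", np.arange(n_reads).astype("U9"))
    reads = pd.DataFrame(
        {
            "read_id": read_ids,
            "barcode": r_barcode,
            "umi": r_umi,
            "gene_human": gene_human,
            "score_human": np.round(score_human, 4),
            "gene_mouse": gene_mouse,
            "score_mouse": np.round(score_mouse, 4),
        }
    )

    mol_out = pd.DataFrame(
        {
            "barcode": barcodes[mol["barcode_idx"].to_numpy()],
            "species": mol["species"].to_numpy(),
            "gene": np.where(
                mol["species"].to_numpy() == HUMAN,
                genes_h[mol["gene_idx"].to_numpy()] if genes_h.size else "",
                genes_m[mol["gene_idx"].to_numpy()] if genes_m.size else "",
            ),
        }
    )
    mol_counts = (
        mol_out.groupby(["barcode", "species", "gene"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )

    truth = GroundTruth(
        barcode_species=pd.Series(species_label, index=barcodes, name="species"),
        molecule_counts=mol_counts,
        gene_log2_fold=fold,
        read_species=pd.Series(r_species, index=read_ids, name="species"),
        config=config,
    )
    return reads, truth


def truth_summary(truth: GroundTruth) -> TruthSummary:
    """Tally the ground truth: cell counts and realized per-gene folds.

    Realized fold is log2 of the ratio of per-cell mean molecule counts
    (human over mouse) for each ortholog pair, NaN where either species
    mean is zero.  Hidden doublet halves count toward their species'
    per-cell means.
    """
    if len(truth.barcode_species) == 0:
        raise ValueError("empty ground truth")
    cfg = truth.config
    labels = truth.barcode_species.value_counts()
    n_h_cells = cfg.n_cells_human + cfg.n_doublets
    n_m_cells = cfg.n_cells_mouse + cfg.n_doublets

    per_gene = (
        truth.molecule_counts.groupby(["species", "gene"])["count"].sum().unstack(0)
    )
    h_orth, m_orth = _ortholog_symbols(cfg.n_ortholog_genes)
    mean_h = pd.Series(0.0, index=h_orth)
    mean_m = pd.Series(0.0, index=h_orth)
    if HUMAN in per_gene:
        got = per_gene[HUMAN].reindex(h_orth).fillna(0.0)
        mean_h = got / max(n_h_cells, 1)
    if MOUSE in per_gene:
        got = per_gene[MOUSE].reindex(m_orth).fillna(0.0)
        mean_m = pd.Series(got.to_numpy(), index=h_orth) / max(n_m_cells, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        realized = np.log2(mean_h.to_numpy() / mean_m.to_numpy())
    realized[~np.isfinite(realized)] = np.nan

    gene_table = pd.DataFrame(
        {
            "human_symbol": h_orth,
            "mouse_symbol": m_orth,
            "mean_count_human": mean_h.to_numpy(),
            "mean_count_mouse": mean_m.to_numpy(),
            "planted_log2_fold": truth.gene_log2_fold.reindex(h_orth).to_numpy(),
            "realized_log2_fold": realized,
        }
    )
    return TruthSummary(
        n_human_cells=int(labels.get(HUMAN, 0)),
        n_mouse_cells=int(labels.get(MOUSE, 0)),
        n_doublets=int(labels.get(DOUBLET, 0)),
        gene_table=gene_table,
    )


def make_homology_records(config: SimulationConfig) -> pd.DataFrame:
    """Homology-report rows matching the simulated gene universe.

    One clean 1:1 class per ortholog pair, a missing-partner class per
    species-exclusive gene, plus optional many-to-one and
    symbol-collision stress classes that carry no expression.
    """
    h_orth, m_orth = _ortholog_symbols(config.n_ortholog_genes)
    rows: list[tuple[str, str, str]] = []
    cls = 0
    for h, m in zip(h_orth, m_orth):
        rows.append((f"C{cls:06d}", HUMAN, h))
        rows.append((f"C{cls:06d}", MOUSE, m))
        cls += 1
    for g in config.gene_symbols(HUMAN)[config.n_ortholog_genes:]:
        rows.append((f"C{cls:06d}", HUMAN, g))
        cls += 1
    for g in config.gene_symbols(MOUSE)[config.n_ortholog_genes:]:
        rows.append((f"C{cls:06d}", MOUSE, g))
        cls += 1
    for i in range(config.n_many_to_one_classes):
        rows.append((f"C{cls:06d}", HUMAN, f"MULTI{i:04d}"))
        rows.append((f"C{cls:06d}", MOUSE, f"Multi{i:04d}a"))
        rows.append((f"C{cls:06d}", MOUSE, f"Multi{i:04d}b"))
        cls += 1
    for i in range(config.n_collision_classes):
        # two classes claiming the same mouse symbol
        rows.append((f"C{cls:06d}", HUMAN, f"COLL{i:04d}A"))
        rows.append((f"C{cls:06d}", MOUSE, f"Coll{i:04d}"))
        cls += 1
        rows.append((f"C{cls:06d}", HUMAN, f"COLL{i:04d}B"))
        rows.append((f"C{cls:06d}", MOUSE, f"Coll{i:04d}"))
        cls += 1
    return pd.DataFrame(rows, columns=["class_id", "species", "symbol"])
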