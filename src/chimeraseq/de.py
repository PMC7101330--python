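"""Cross-species comparison of orthologous gene expression between a
human microglia cluster and its coresident mouse microglia cluster.

Works on the merged (shared mouse-symbol namespace) log-normalized
matrix.  Provides:

* per-ortholog mean expression in each species and the pseudocounted
  log2 ratio (human over mouse);
* a concordance summary — the fraction of ortholog pairs within a
  twofold range (|log2 ratio| < 1) and the squared Pearson correlation
  of the two mean vectors;
* differential calls at a fold cutoff and Benjamini-Hochberg FDR,
  using a two-sided rank-sum test per gene (Welch t as an option);
* disease-gene-panel tallies of the direction of the mean difference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .orthologs import HUMAN_TO_MOUSE, OrthologTable
from .quantify import LOG_NORMALIZED, CountMatrix

logger = logging.getLogger(__name__)

HUMAN_ENRICHED = "human_enriched"
MOUSE_ENRICHED = "mouse_enriched"
SHARED = "shared"


def _cell_split(
    matrix: CountMatrix, human_cells: list[str], mouse_cells: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    if matrix.normalization != LOG_NORMALIZED:
        raise ValueError("expected a log-normalized merged matrix")
    if not human_cells or not mouse_cells:
        raise ValueError("both cell sets must be nonempty")
    if set(human_cells) & set(mouse_cells):
        raise ValueError("cell sets must be disjoint")
    pos = pd.Series(range(len(matrix.barcodes)), index=matrix.barcodes)
    try:
        hi = pos[human_cells].to_numpy()
        mi = pos[mouse_cells].to_numpy()
    except KeyError as e:
        raise ValueError(f"cells absent from matrix: {e}") from None
    X = matrix.counts
    return X[hi].toarray(), X[mi].toarray()


def _ratio_means(Xh: np.ndarray, Xm: np.ndarray, scale: str) -> tuple[np.ndarray, np.ndarray]:
    """Cluster means on the requested scale for the fold ratio.

    ``log``: arithmetic means of the log-normalized values themselves.
    ``linear``: means of the de-logged (expm1) values — the convention
    of standard droplet toolkits for fold changes, and the one under
    which a planted raw fold survives undistorted (log1p compresses
    large values, roughly halving apparent folds on the log scale).
    """
    if scale == "log":
        return Xh.mean(axis=0), Xm.mean(axis=0)
    if scale == "linear":
        return np.expm1(Xh).mean(axis=0), np.expm1(Xm).mean(axis=0)
    raise ValueError(f"unknown scale {scale!r}")


def ortholog_pair_means(
    matrix: CountMatrix,
    human_cells: list[str],
    mouse_cells: list[str],
    pseudocount: float = 0.01,
    scale: str = "log",
) -> pd.DataFrame:
    """Mean log-normalized expression per ortholog in each cluster.

    One row per shared-namespace gene with ``mean_human``,
    ``mean_mouse`` and ``log2_ratio`` = log2((mean_h + eps)/(mean_m + eps)),
    where the means entering the ratio follow ``scale`` (default: means
    of the log-normalized values, matching the scatter-of-means
    presentation; ``"linear"`` uses de-logged means).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    Xh, Xm = _cell_split(matrix, human_cells, mouse_cells)
    mh = Xh.mean(axis=0)
    mm = Xm.mean(axis=0)
    rh, rm = _ratio_means(Xh, Xm, scale)
    return pd.DataFrame(
        {
            "gene": matrix.genes,
            "mean_human": mh,
            "mean_mouse": mm,
            "log2_ratio": np.log2((rh + pseudocount) / (rm + pseudocount)),
        }
    ).set_index("gene")


def within_twofold_percent(n_within: int, n_pairs: int) -> float:
    """Within-twofold fraction as a percentage, one decimal.

    14,488 of 15,058 reports 96.2.
    """
    if n_pairs <= 0:
        raise ValueError("need at least one pair")
    return round(100.0 * n_within / n_pairs, 1)


@dataclass
class ConcordanceSummary:
    n_pairs: int
    n_within_twofold: int
    fraction_within_twofold: float  # percent, one decimal
    r_squared: float | None  # None when a mean vector has zero variance
    p_value: float | None


def concordance(pairs: pd.DataFrame) -> ConcordanceSummary:
    """Ortholog-pair concordance: twofold fraction and r^2 of the means.

    "Within twofold" means |log2 ratio| < 1; r^2 is the squared Pearson
    correlation between the human and mouse mean vectors (undefined —
    reported as missing — when either vector has zero variance).
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 ortholog pairs")
    within = int((pairs["log2_ratio"].abs() < 1.0).sum())
    mh = pairs["mean_human"].to_numpy()
    mm = pairs["mean_mouse"].to_numpy()
    if np.std(mh) == 0 or np.std(mm) == 0:
        r2, p = None, None
    else:
        r, p = stats.pearsonr(mh, mm)
        r2, p = float(r * r), float(p)
    return ConcordanceSummary(
        n_pairs=len(pairs),
        n_within_twofold=within,
        fraction_within_twofold=within_twofold_percent(within, len(pairs)),
        r_squared=r2,
        p_value=p,
    )


def differential_orthologs(
    matrix: CountMatrix,
    human_cells: list[str],
    mouse_cells: list[str],
    alpha: float = 0.05,
    fold_cutoff: float = 2.0,
    test: str = "ranksum",
    pseudocount: float = 0.01,
    scale: str = "linear",
) -> pd.DataFrame:
    """Per-gene cross-species differential expression calls.

    A two-sided rank-sum (Wilcoxon/Mann-Whitney) test — or Welch t with
    ``test="ttest"`` — compares log-normalized per-cell values between
    the two clusters; Benjamini-Hochberg FDR is computed across all
    tested genes.  A gene is ``human_enriched`` when its log2 mean
    ratio is at least log2(fold_cutoff) and FDR < alpha
    (``mouse_enriched`` symmetric), otherwise ``shared``.  Genes with
    all-zero values in both sets are excluded and logged.

    The ratio is computed on de-logged (linear) cluster means by
    default so that a twofold cutoff means a twofold expression
    difference; ``scale="log"`` switches to means of the log-normalized
    values (which compress real folds).  ``mean_human``/``mean_mouse``
    columns always report mean log-normalized expression.
    """
    if len(human_cells) < 3 or len(mouse_cells) < 3:
        raise ValueError("need at least 3 cells per cluster")
    if fold_cutoff < 1:
        raise ValueError("fold_cutoff must be >= 1")
    Xh, Xm = _cell_split(matrix, human_cells, mouse_cells)
    nonzero = (Xh.sum(axis=0) + Xm.sum(axis=0)) > 0
    if not nonzero.all():
        logger.info(
            "excluding %d genes with all-zero values in both clusters",
            int((~nonzero).sum()),
        )
    genes = np.asarray(matrix.genes)[nonzero]
    Xh, Xm = Xh[:, nonzero], Xm[:, nonzero]

    mh = Xh.mean(axis=0)
    mm = Xm.mean(axis=0)
    rh, rm = _ratio_means(Xh, Xm, scale)
    log2_ratio = np.log2((rh + pseudocount) / (rm + pseudocount))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant genes give exact-tie warnings
        if test == "ranksum":
            res = stats.mannwhitneyu(Xh, Xm, axis=0, alternative="two-sided")
        elif test == "ttest":
            res = stats.ttest_ind(Xh, Xm, axis=0, equal_var=False)
        else:
            raise ValueError(f"unknown test {test!r}")
    p = np.nan_to_num(np.asarray(res.pvalue, dtype=float), nan=1.0)
    fdr = multipletests(p, method="fdr_bh")[1]

    cut = np.log2(fold_cutoff)
    cls = np.where(
        (log2_ratio >= cut) & (fdr < alpha),
        HUMAN_ENRICHED,
        np.where((log2_ratio <= -cut) & (fdr < alpha), MOUSE_ENRICHED, SHARED),
    )
    return pd.DataFrame(
        {
            "gene": genes,
            "mean_human": mh,
            "mean_mouse": mm,
            "log2_ratio": log2_ratio,
            "p_value": p,
            "fdr": fdr,
            "class": cls,
        }
    ).set_index("gene")


@dataclass
class DiseasePanelSummary:
    """Direction-of-means tallies for one disease gene panel."""

    name: str
    genes: list[str]
    n_found: int
    n_human_higher: int
    n_mouse_higher: int
    n_ties: int
    missing: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "panel": self.name,
            "n_genes": len(self.genes),
            "n_found": self.n_found,
            "n_human_higher": self.n_human_higher,
            "n_mouse_higher": self.n_mouse_higher,
            "n_ties": self.n_ties,
            "missing": ",".join(self.missing),
        }


def panel_summary(
    pairs: pd.DataFrame,
    panel_genes: list[str],
    name: str,
    table: OrthologTable | None = None,
    de_table: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> DiseasePanelSummary:
    """Tally which species expresses each panel gene more.

    Panel symbols are expected in the mouse namespace; symbols not
    found directly are translated human -> mouse when an ortholog table
    is given.  "Higher" is a direction-of-means comparison with no
    significance filter; pass ``de_table`` to restrict the tallies to
    FDR-significant genes.
    """
    if not panel_genes:
        raise ValueError("empty panel")
    mapping = table.mapping(HUMAN_TO_MOUSE) if table is not None else {}
    resolved = [g if g in pairs.index else mapping.get(g, g) for g in panel_genes]
    found = [g for g in resolved if g in pairs.index]
    missing = [orig for orig, g in zip(panel_genes, resolved) if g not in pairs.index]
    if not found:
        warnings.warn(f"panel {name!r}: no genes found in the pair table")
    sub = pairs.loc[found]
    if de_table is not None:
        sig = de_table.index[de_table["fdr"] < alpha]
        sub = sub.loc[sub.index.isin(sig)]
    higher_h = int((sub["mean_human"] > sub["mean_mouse"]).sum())
    higher_m = int((sub["mean_human"] < sub["mean_mouse"]).sum())
    ties = len(sub) - higher_h - higher_m
    return DiseasePanelSummary(
        name=name,
        genes=list(panel_genes),
        n_found=len(found),
        n_human_higher=higher_h,
        n_mouse_higher=higher_m,
        n_ties=ties,
        missing=missing,
    )
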