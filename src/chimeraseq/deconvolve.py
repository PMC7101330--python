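"""Read-level species assignment, UMI collapse, barcode classification
and per-species splitting for pooled-reference alignments.

The stage consumes a read table (one row per read: barcode, UMI, best
human alignment, best mouse alignment) and produces, in order:

1. a species call per read — the species with the strictly greater
   alignment score (ties are ambiguous, a single present alignment wins);
2. one molecule per (barcode, UMI) by majority vote of its read calls;
3. a verdict per barcode — its majority species, or ``cross_species``
   when the minor species contributes at least ``min_minor_molecules``
   molecules *and* at least a ``minor_fraction_threshold`` share of its
   unambiguous molecules;
4. per-species molecule sets, with cross-species barcodes eliminated
   and every discarded molecule attributed to a named filter.

Barcode classification operates on molecules (UMIs), not raw reads, so
that PCR amplification depth cannot bias the species tallies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HUMAN = "human"
MOUSE = "mouse"
AMBIGUOUS = "ambiguous"
CROSS_SPECIES = "cross_species"

MOLECULE_COLUMNS = ["barcode", "umi", "species", "gene", "supporting_reads"]


@dataclass
class DeconvolutionParams:
    """Thresholds of the barcode-elimination rule.

    ``minor_fraction_threshold`` (tau) and ``min_minor_molecules``
    jointly define "optimally aligning with both species": a literal
    any-read rule would flag nearly every barcode under realistic
    misassignment noise, so both a minimum minor-species molecule count
    and a minimum minor fraction are required.
    """

    minor_fraction_threshold: float = 0.10
    min_minor_molecules: int = 2
    min_reads_per_molecule: int = 1

    def validate(self) -> None:
        if not 0.0 <= self.minor_fraction_threshold <= 0.5:
            raise ValueError("minor_fraction_threshold must be in [0, 0.5]")
        if self.min_minor_molecules < 0 or self.min_reads_per_molecule < 1:
            raise ValueError("invalid molecule-count thresholds")

    def to_dict(self) -> dict:
        return {
            "minor_fraction_threshold": self.minor_fraction_threshold,
            "min_minor_molecules": self.min_minor_molecules,
            "min_reads_per_molecule": self.min_reads_per_molecule,
        }


def assign_read_species(record) -> str:
    """Species call for one read: strictly greater score wins.

    ``record`` is any mapping with ``score_human`` / ``score_mouse``
    (NaN or None meaning no alignment).  Equal present scores are
    ambiguous; a single present alignment wins by default; two absent
    alignments violate the read-record contract.
    """
    sh = record["score_human"]
    sm = record["score_mouse"]
    h = sh is not None and not (isinstance(sh, float) and math.isnan(sh))
    m = sm is not None and not (isinstance(sm, float) and math.isnan(sm))
    if not h and not m:
        raise ValueError("read has no alignment in either species")
    if h and not m:
        return HUMAN
    if m and not h:
        return MOUSE
    if sh > sm:
        return HUMAN
    if sm > sh:
        return MOUSE
    return AMBIGUOUS


def assign_reads(reads: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`assign_read_species` over a read table."""
    sh = reads["score_human"].to_numpy(dtype=float)
    sm = reads["score_mouse"].to_numpy(dtype=float)
    if np.any(np.isnan(sh) & np.isnan(sm)):
        raise ValueError("read with no alignment in either species")
    sh_f = np.where(np.isnan(sh), -np.inf, sh)
    sm_f = np.where(np.isnan(sm), -np.inf, sm)
    call = np.where(sh_f > sm_f, HUMAN, np.where(sm_f > sh_f, MOUSE, AMBIGUOUS))
    return pd.Series(call, index=reads.index, name="call")


def collapse_umis(reads: pd.DataFrame, params: DeconvolutionParams | None = None,
                  calls: pd.Series | None = None) -> pd.DataFrame:
    """Collapse reads into one molecule per (barcode, UMI).

    Molecule species is the majority of its read calls (human-vs-mouse
    ties are ambiguous); the gene is the majority gene among reads
    voting the winning species, ties broken lexicographically (logged).
    ``supporting_reads`` counts the reads agreeing with the winning
    species (all reads, for ambiguous molecules); molecules with fewer
    than ``min_reads_per_molecule`` supporting reads are dropped.
    """
    params = params or DeconvolutionParams()
    params.validate()
    if calls is None:
        calls = assign_reads(reads)
    df = reads[["barcode", "umi", "gene_human", "gene_mouse"]].copy()
    df["call"] = calls.to_numpy()

    votes = (
        df.groupby(["barcode", "umi"])["call"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=[HUMAN, MOUSE, AMBIGUOUS], fill_value=0)
    )
    n_h = votes[HUMAN].to_numpy()
    n_m = votes[MOUSE].to_numpy()
    n_a = votes[AMBIGUOUS].to_numpy()
    species = np.where(n_h > n_m, HUMAN, np.where(n_m > n_h, MOUSE, AMBIGUOUS))
    supporting = np.where(
        species == AMBIGUOUS, n_h + n_m + n_a, np.maximum(n_h, n_m)
    )
    mol = pd.DataFrame(
        {"species": species, "supporting_reads": supporting}, index=votes.index
    )

    # majority gene among the winning species' reads, lexicographic ties
    n_ties = 0
    gene = pd.Series("", index=votes.index, dtype=object)
    for sp, col in ((HUMAN, "gene_human"), (MOUSE, "gene_mouse")):
        sub = df[df["call"] == sp]
        if sub.empty:
            continue
        sizes = (
            sub.groupby(["barcode", "umi", col])
            .size()
            .rename("n")
            .reset_index()
            .sort_values(["barcode", "umi", "n", col],
                         ascending=[True, True, False, True], kind="stable")
        )
        top = sizes.drop_duplicates(["barcode", "umi"])
        tie = (
            sizes.groupby(["barcode", "umi"])["n"].transform("max") == sizes["n"]
        )
        n_ties += int(
            (sizes[tie].groupby(["barcode", "umi"]).size() > 1).sum()
        )
        idx = pd.MultiIndex.from_frame(top[["barcode", "umi"]])
        winner = pd.Series(top[col].to_numpy(), index=idx)
        mask = mol["species"] == sp
        gene[mask] = winner.reindex(mol.index[mask]).to_numpy()
    if n_ties:
        logger.info("broke %d gene-vote ties lexicographically", n_ties)
    mol["gene"] = gene

    mol = mol[mol["supporting_reads"] >= params.min_reads_per_molecule]
    out = mol.reset_index()
    return out[MOLECULE_COLUMNS]


def flagged_percentage(n_flagged: int, n_total: int) -> float:
    """Cross-species barcode percentage reported to two decimals.

    The trailing remainder is truncated, not rounded (integer
    arithmetic, so the report is exact): 147 of 19,154 reports 0.76.
    """
    if n_total <= 0:
        raise ValueError("total barcode count must be positive")
    return (10000 * n_flagged // n_total) / 100


def classify_barcodes(
    molecules: pd.DataFrame,
    params: DeconvolutionParams | None = None,
    read_calls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-barcode species tallies and verdicts.

    Ambiguous molecules are excluded from the species tallies (they are
    counted in ``n_ambiguous``).  A barcode is ``cross_species`` when
    the minor species has at least ``min_minor_molecules`` molecules and
    a minor fraction of at least tau; otherwise the verdict is the
    majority species.  Barcodes with no unambiguous molecules (or an
    exact non-cross tie) fall back to read-level majority when
    ``read_calls`` (columns barcode, call) is supplied, else they are
    dropped with a log entry.
    """
    params = params or DeconvolutionParams()
    params.validate()
    tallies = (
        molecules.groupby("barcode")["species"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=[HUMAN, MOUSE, AMBIGUOUS], fill_value=0)
    )
    h = tallies[HUMAN].to_numpy()
    m = tallies[MOUSE].to_numpy()
    tot = h + m
    minor = np.minimum(h, m)
    with np.errstate(invalid="ignore", divide="ignore"):
        minor_frac = np.where(tot > 0, minor / np.maximum(tot, 1), 0.0)
    cross = (minor >= params.min_minor_molecules) & (
        minor_frac >= params.minor_fraction_threshold
    ) & (minor > 0)
    verdict = np.where(
        cross, CROSS_SPECIES, np.where(h > m, HUMAN, np.where(m > h, MOUSE, ""))
    )

    calls = pd.DataFrame(
        {
            "barcode": tallies.index,
            "n_molecules_human": h,
            "n_molecules_mouse": m,
            "n_ambiguous": tallies[AMBIGUOUS].to_numpy(),
            "minor_fraction": minor_frac,
            "verdict": verdict,
        }
    ).reset_index(drop=True)

    unresolved = calls["verdict"] == ""
    if unresolved.any():
        if read_calls is not None:
            rc = (
                read_calls.groupby("barcode")["call"]
                .value_counts()
                .unstack(fill_value=0)
                .reindex(columns=[HUMAN, MOUSE], fill_value=0)
            )
            for i in calls.index[unresolved]:
                bc = calls.at[i, "barcode"]
                if bc in rc.index:
                    nh, nm = rc.at[bc, HUMAN], rc.at[bc, MOUSE]
                    if nh > nm:
                        calls.at[i, "verdict"] = HUMAN
                    elif nm > nh:
                        calls.at[i, "verdict"] = MOUSE
        still = calls["verdict"] == ""
        if still.any():
            logger.warning(
                "dropping %d barcodes with unresolvable species", int(still.sum())
            )
            calls = calls[~still].reset_index(drop=True)
    return calls


def classification_summary(calls: pd.DataFrame) -> dict:
    """Flagged count / total and the two-decimal reported percentage."""
    n_total = len(calls)
    n_flagged = int((calls["verdict"] == CROSS_SPECIES).sum())
    return {
        "n_barcodes": n_total,
        "n_cross_species": n_flagged,
        "percent_cross_species": flagged_percentage(n_flagged, n_total),
    }


@dataclass
class SplitResult:
    """Per-species molecule sets after cross-species elimination."""

    human: pd.DataFrame
    mouse: pd.DataFrame
    excluded: pd.DataFrame  # molecules + an ``excluded_reason`` column

    def conservation_holds(self, n_input_molecules: int) -> bool:
        return len(self.human) + len(self.mouse) + len(self.excluded) == (
            n_input_molecules
        )


def split_by_species(molecules: pd.DataFrame, calls: pd.DataFrame) -> SplitResult:
    """Split molecules by their barcode's verdict.

    The human set holds exactly the human molecules of human-verdict
    barcodes (mouse symmetric).  Everything else is excluded with a
    reason: molecules of cross-species barcodes, ambiguous molecules,
    and minor-species molecules of a called barcode.  A molecule whose
    barcode has no call is an error.
    """
    verdicts = calls.set_index("barcode")["verdict"]
    v = molecules["barcode"].map(verdicts)
    if v.isna().any():
        missing = molecules.loc[v.isna(), "barcode"].iloc[0]
        raise ValueError(f"molecule with uncalled barcode {missing!r}")
    v = v.to_numpy()
    sp = molecules["species"].to_numpy()

    human = molecules[(v == HUMAN) & (sp == HUMAN)].reset_index(drop=True)
    mouse = molecules[(v == MOUSE) & (sp == MOUSE)].reset_index(drop=True)
    reason = np.where(
        v == CROSS_SPECIES,
        "cross_species_barcode",
        np.where(sp == AMBIGUOUS, "ambiguous_molecule", "minor_species"),
    )
    keep = ((v == HUMAN) & (sp == HUMAN)) | ((v == MOUSE) & (sp == MOUSE))
    excluded = molecules[~keep].copy()
    excluded["excluded_reason"] = reason[~keep]
    return SplitResult(human=human, mouse=mouse, excluded=excluded.reset_index(drop=True))
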