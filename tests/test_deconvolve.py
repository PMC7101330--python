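"""Species deconvolution: read calls, UMI-collapse votes, barcode
verdicts and splitting — checked against an independent brute-force
enumeration and against simulator ground truth."""

import math

import numpy as np
import pandas as pd
import pytest

from chimeraseq import (
    DeconvolutionParams,
    assign_read_species,
    assign_reads,
    classification_summary,
    classify_barcodes,
    collapse_umis,
    flagged_percentage,
    simulate_chimera,
    split_by_species,
)
from chimeraseq.simulate import SimulationConfig

from conftest import make_reads


# ---------------------------------------------------------------------
# independent brute-force oracle (pure-python re-derivation of the
# vote/tally chain; shares no code with the implementation)
# ---------------------------------------------------------------------

def _oracle_read_call(sh, sm):
    h = sh is not None and not math.isnan(sh)
    m = sm is not None and not math.isnan(sm)
    if h and not m:
        return "human"
    if m and not h:
        return "mouse"
    if sh > sm:
        return "human"
    if sm > sh:
        return "mouse"
    return "ambiguous"


def oracle_chain(reads: pd.DataFrame, params: DeconvolutionParams):
    groups: dict = {}
    for row in reads.itertuples(index=False):
        call = _oracle_read_call(row.score_human, row.score_mouse)
        groups.setdefault((row.barcode, row.umi), []).append(
            (call, row.gene_human, row.gene_mouse)
        )
    molecules = []
    for (bc, umi), items in groups.items():
        nh = sum(1 for c, _, _ in items if c == "human")
        nm = sum(1 for c, _, _ in items if c == "mouse")
        if nh > nm:
            sp = "human"
            genes = [gh for c, gh, _ in items if c == "human"]
            support = nh
        elif nm > nh:
            sp = "mouse"
            genes = [gm for c, _, gm in items if c == "mouse"]
            support = nm
        else:
            sp, genes, support = "ambiguous", [], len(items)
        gene = ""
        if genes:
            tally: dict = {}
            for g in genes:
                tally[g] = tally.get(g, 0) + 1
            top = max(tally.values())
            gene = min(g for g, n in tally.items() if n == top)
        if support >= params.min_reads_per_molecule:
            molecules.append((bc, umi, sp, gene, support))
    barcodes: dict = {}
    for bc, _, sp, _, _ in molecules:
        d = barcodes.setdefault(bc, {"human": 0, "mouse": 0, "ambiguous": 0})
        d[sp] += 1
    verdicts = {}
    for bc, d in barcodes.items():
        h, m = d["human"], d["mouse"]
        minor = min(h, m)
        frac = minor / (h + m) if h + m else 0.0
        if (
            minor >= params.min_minor_molecules
            and minor > 0
            and frac >= params.minor_fraction_threshold
        ):
            verdicts[bc] = "cross_species"
        elif h > m:
            verdicts[bc] = "human"
        elif m > h:
            verdicts[bc] = "mouse"
        else:
            verdicts[bc] = None  # unresolved
    return molecules, verdicts


# ---------------------------------------------------------------------
# read-level assignment
# ---------------------------------------------------------------------

def test_assign_strict_score_order():
    assert assign_read_species({"score_human": 50.0, "score_mouse": 30.0}) == "human"
    assert assign_read_species({"score_human": 30.0, "score_mouse": 50.0}) == "mouse"


def test_assign_tie_is_ambiguous():
    assert assign_read_species({"score_human": 42.0, "score_mouse": 42.0}) == (
        "ambiguous"
    )


def test_assign_single_alignment_wins():
    assert assign_read_species(
        {"score_human": float("nan"), "score_mouse": 20.0}
    ) == "mouse"


def test_assign_rejects_fully_unaligned_read():
    with pytest.raises(ValueError):
        assign_read_species({"score_human": float("nan"), "score_mouse": float("nan")})
    with pytest.raises(ValueError):
        assign_reads(
            make_reads([("r1", "b", "u", "", float("nan"), "", float("nan"))])
        )


# ---------------------------------------------------------------------
# UMI collapse
# ---------------------------------------------------------------------

def test_unanimous_reads_collapse_to_one_molecule():
    reads = make_reads(
        [
            ("r1", "b1", "u1", "AAA", 50, "Aaa", 20),
            ("r2", "b1", "u1", "AAA", 55, "Aaa", 25),
            ("r3", "b1", "u1", "AAA", 60, "Aaa", 30),
        ]
    )
    mol = collapse_umis(reads)
    assert len(mol) == 1
    row = mol.iloc[0]
    assert (row["species"], row["gene"], row["supporting_reads"]) == ("human", "AAA", 3)


def test_split_vote_is_ambiguous():
    reads = make_reads(
        [
            ("r1", "b1", "u1", "AAA", 50, "Aaa", 20),
            ("r2", "b1", "u1", "AAA", 10, "Aaa", 40),
        ]
    )
    mol = collapse_umis(reads)
    assert mol.iloc[0]["species"] == "ambiguous"


def test_five_group_fixture_matches_hand_enumeration():
    nan = float("nan")
    reads = make_reads(
        [
            # g1: 2 human vs 1 mouse -> human, gene AAA
            ("r1", "b1", "u1", "AAA", 50, "Aaa", 20),
            ("r2", "b1", "u1", "AAA", 50, "Aaa", 20),
            ("r3", "b1", "u1", "AAA", 10, "Aaa", 40),
            # g2: 1v1 tie -> ambiguous
            ("r4", "b1", "u2", "BBB", 50, "Bbb", 20),
            ("r5", "b1", "u2", "BBB", 10, "Bbb", 40),
            # g3: gene vote tie XXX vs YYY -> lexicographic XXX
            ("r6", "b2", "u1", "XXX", 50, "Xxx", 20),
            ("r7", "b2", "u1", "YYY", 50, "Yyy", 20),
            # g4: mouse-only alignments
            ("r8", "b2", "u2", "", nan, "Ccc", 30),
            # g5: 3 mouse reads, gene majority Ddd over Eee
            ("r9", "b3", "u1", "", nan, "Ddd", 30),
            ("r10", "b3", "u1", "", nan, "Ddd", 35),
            ("r11", "b3", "u1", "", nan, "Eee", 32),
        ]
    )
    mol = collapse_umis(reads).set_index(["barcode", "umi"])
    expected = {
        ("b1", "u1"): ("human", "AAA", 2),
        ("b1", "u2"): ("ambiguous", "", 2),
        ("b2", "u1"): ("human", "XXX", 2),
        ("b2", "u2"): ("mouse", "Ccc", 1),
        ("b3", "u1"): ("mouse", "Ddd", 3),
    }
    assert len(mol) == len(expected)
    for key, (sp, gene, n) in expected.items():
        row = mol.loc[key]
        assert (row["species"], row["gene"], row["supporting_reads"]) == (sp, gene, n)


def test_min_reads_filter_drops_singleton_molecules():
    reads = make_reads(
        [
            ("r1", "b1", "u1", "AAA", 50, "Aaa", 20),
            ("r2", "b1", "u2", "BBB", 50, "Bbb", 20),
            ("r3", "b1", "u2", "BBB", 55, "Bbb", 25),
        ]
    )
    mol = collapse_umis(reads, DeconvolutionParams(min_reads_per_molecule=2))
    assert mol["umi"].tolist() == ["u2"]


# ---------------------------------------------------------------------
# barcode classification
# ---------------------------------------------------------------------

def _mol(bc, umi, sp, gene="G"):
    return {"barcode": bc, "umi": umi, "species": sp, "gene": gene,
            "supporting_reads": 1}


def test_pure_barcode_gets_species_verdict():
    mols = pd.DataFrame([_mol("b1", f"u{i}", "human") for i in range(100)])
    calls = classify_barcodes(mols)
    assert calls.iloc[0]["verdict"] == "human"
    assert calls.iloc[0]["minor_fraction"] == 0.0


def test_maximally_mixed_barcode_is_cross_species():
    mols = pd.DataFrame(
        [_mol("b1", f"u{i}", "human") for i in range(50)]
        + [_mol("b1", f"v{i}", "mouse") for i in range(50)]
    )
    calls = classify_barcodes(mols)
    assert calls.iloc[0]["verdict"] == "cross_species"
    assert calls.iloc[0]["minor_fraction"] == 0.5


def test_flagged_percentage_printed_worked_example():
    assert flagged_percentage(147, 19154) == 0.76


def test_raising_tau_never_increases_flags(small_dataset):
    reads, _ = small_dataset
    mols = collapse_umis(reads)
    flagged = []
    for tau in (0.0, 0.05, 0.1, 0.2, 0.5):
        calls = classify_barcodes(
            mols, DeconvolutionParams(minor_fraction_threshold=tau)
        )
        flagged.append((calls["verdict"] == "cross_species").sum())
    assert flagged == sorted(flagged, reverse=True)


# ---------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------

def test_all_human_barcodes_give_empty_mouse_set():
    mols = pd.DataFrame([_mol("b1", "u1", "human"), _mol("b2", "u1", "human")])
    calls = classify_barcodes(mols)
    split = split_by_species(mols, calls)
    assert len(split.mouse) == 0
    assert len(split.human) == 2


def test_cross_species_barcode_is_fully_excluded():
    mols = pd.DataFrame(
        [_mol("pure", f"u{i}", "human") for i in range(10)]
        + [_mol("mix", f"u{i}", "human") for i in range(5)]
        + [_mol("mix", f"v{i}", "mouse") for i in range(5)]
    )
    calls = classify_barcodes(mols)
    split = split_by_species(mols, calls)
    assert (split.excluded["barcode"] == "mix").all()
    assert len(split.excluded) == 10
    assert set(split.excluded["excluded_reason"]) == {"cross_species_barcode"}


def test_uncalled_barcode_rejected():
    mols = pd.DataFrame([_mol("b1", "u1", "human"), _mol("ghost", "u1", "human")])
    calls = classify_barcodes(mols[mols["barcode"] == "b1"])
    with pytest.raises(ValueError, match="ghost"):
        split_by_species(mols, calls)


def test_split_totals_match_ground_truth_exactly():
    cfg = SimulationConfig(
        n_cells_human=40,
        n_cells_mouse=40,
        doublet_rate=0.0,
        misassignment_rate=0.0,
        n_ortholog_genes=60,
        n_human_only_genes=5,
        n_mouse_only_genes=5,
        molecules_per_cell=40.0,
        seed=17,
    )
    reads, truth = simulate_chimera(cfg)
    mols = collapse_umis(reads)
    calls = classify_barcodes(mols)
    split = split_by_species(mols, calls)
    assert len(split.human) == truth.n_molecules("human")
    assert len(split.mouse) == truth.n_molecules("mouse")
    assert len(split.excluded) == 0


# ---------------------------------------------------------------------
# oracle equivalence on the full chain
# ---------------------------------------------------------------------

@pytest.mark.parametrize("seed", [0, 1, 2])
def test_full_chain_matches_brute_force(seed, default_params):
    cfg = SimulationConfig(
        n_cells_human=6,
        n_cells_mouse=6,
        doublet_rate=0.15,
        misassignment_rate=0.2,
        n_ortholog_genes=15,
        n_human_only_genes=3,
        n_mouse_only_genes=3,
        molecules_per_cell=5.0,
        reads_per_molecule=2.0,
        seed=seed,
    )
    reads, _ = simulate_chimera(cfg)
    mols = collapse_umis(reads, default_params)
    got = {
        (r.barcode, r.umi): (r.species, r.gene, r.supporting_reads)
        for r in mols.itertuples(index=False)
    }
    oracle_mols, oracle_verdicts = oracle_chain(reads, default_params)
    expected = {(bc, umi): (sp, g, n) for bc, umi, sp, g, n in oracle_mols}
    assert got == expected

    calls = classify_barcodes(mols, default_params)
    got_v = dict(zip(calls["barcode"], calls["verdict"]))
    expected_v = {
        bc: v for bc, v in oracle_verdicts.items() if v is not None
    }
    # unresolved barcodes may be rescued by read-level fallback only when
    # read calls are passed; here they are simply dropped by both sides
    assert got_v == expected_v


def test_classification_summary_reports_counts(small_dataset, default_params):
    reads, truth = small_dataset
    mols = collapse_umis(reads, default_params)
    calls = classify_barcodes(mols, default_params)
    s = classification_summary(calls)
    assert s["n_barcodes"] == len(calls)
    assert s["percent_cross_species"] == flagged_percentage(
        s["n_cross_species"], s["n_barcodes"]
    )
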