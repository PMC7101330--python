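"""Curation of a two-species homology report into a strict 1:1
human/mouse gene-symbol table, and symbol translation between the two
namespaces.

The input is the symbol-level content of a homology report (e.g. the
Jackson Laboratory human/mouse report): rows of (homology class id,
species, gene symbol).  Curation retains a class only when it pairs
exactly one human with exactly one mouse symbol and neither symbol is
claimed by another retained class, yielding a bijection; every other
class is dropped with a machine-readable reason.  Symbol comparison is
case-sensitive throughout, since human (all-caps) and mouse
(capitalized) symbol conventions differ only by case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

HUMAN = "human"
MOUSE = "mouse"

HUMAN_TO_MOUSE = "human_to_mouse"
MOUSE_TO_HUMAN = "mouse_to_human"


@dataclass
class OrthologTable:
    """Strict 1:1 mapping between human and mouse gene symbols."""

    entries: pd.DataFrame  # columns human_symbol, mouse_symbol
    dropped_classes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["class_id", "reason"])
    )

    def __post_init__(self) -> None:
        e = self.entries
        if e["human_symbol"].duplicated().any() or e["mouse_symbol"].duplicated().any():
            raise ValueError("ortholog table is not a bijection")

    def __len__(self) -> int:
        return len(self.entries)

    def mapping(self, direction: str = HUMAN_TO_MOUSE) -> dict[str, str]:
        if direction == HUMAN_TO_MOUSE:
            return dict(
                zip(self.entries["human_symbol"], self.entries["mouse_symbol"])
            )
        if direction == MOUSE_TO_HUMAN:
            return dict(
                zip(self.entries["mouse_symbol"], self.entries["human_symbol"])
            )
        raise ValueError(f"unknown direction {direction!r}")

    def write_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "OrthologTable":
        """Load a pre-curated two-column table (skips curation)."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        if list(df.columns[:2]) != ["human_symbol", "mouse_symbol"]:
            df = df.iloc[:, :2]
            df.columns = ["human_symbol", "mouse_symbol"]
        return cls(entries=df.reset_index(drop=True))


def read_homology_report(
    path,
    class_col: str = "class_id",
    species_col: str = "species",
    symbol_col: str = "symbol",
) -> pd.DataFrame:
    """Read a homology report TSV into (class_id, species, symbol) rows.

    Organism names are normalized: any value containing "human" maps to
    human, any containing "mouse" to mouse (the JAX report uses
    "mouse, laboratory").  Unknown organisms raise with the offending
    line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.rename(
        columns={class_col: "class_id", species_col: "species", symbol_col: "symbol"}
    )
    missing = {"class_id", "species", "symbol"} - set(df.columns)
    if missing:
        raise ValueError(f"homology report lacks columns: {sorted(missing)}")
    out = df[["class_id", "species", "symbol"]].copy()
    norm = out["species"].str.lower()
    species = pd.Series(pd.NA, index=out.index, dtype=object)
    species[norm.str.contains("human", na=False)] = HUMAN
    species[norm.str.contains("mouse", na=False)] = MOUSE
    bad = species.isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise ValueError(
            f"unknown species token {out.loc[bad.idxmax(), 'species']!r} "
            f"at line {line}"
        )
    out["species"] = species
    return out


def build_ortholog_table(records: pd.DataFrame) -> OrthologTable:
    """Curate homology classes into a strict 1:1 table.

    A class is retained iff it contains exactly one human and exactly
    one mouse symbol ("many-to-one" or "missing species" otherwise) and
    neither symbol appears in any other retained candidate
    ("symbol collision").  Duplicate (class, species, symbol) rows are
    deduplicated silently but logged.
    """
    if len(records) == 0:
        raise ValueError("no homology records")
    bad = ~records["species"].isin([HUMAN, MOUSE])
    if bad.any():
        raise ValueError(
            f"unknown species token {records.loc[bad.idxmax(), 'species']!r} "
            f"at row {int(bad.idxmax())}"
        )
    n_before = len(records)
    records = records.drop_duplicates(["class_id", "species", "symbol"])
    if len(records) < n_before:
        logger.info("deduplicated %d repeated homology rows", n_before - len(records))

    counts = (
        records.groupby(["class_id", "species"]).size().unstack(fill_value=0)
    ).reindex(columns=[HUMAN, MOUSE], fill_value=0)

    dropped: list[tuple[str, str]] = []
    missing = counts.index[(counts[HUMAN] == 0) | (counts[MOUSE] == 0)]
    many = counts.index[
        ((counts[HUMAN] > 1) | (counts[MOUSE] > 1))
        & (counts[HUMAN] > 0)
        & (counts[MOUSE] > 0)
    ]
    dropped += [(c, "missing species") for c in missing]
    dropped += [(c, "many-to-one") for c in many]

    clean = counts.index[(counts[HUMAN] == 1) & (counts[MOUSE] == 1)]
    cand = records[records["class_id"].isin(clean)]
    wide = cand.pivot(index="class_id", columns="species", values="symbol").reindex(
        columns=[HUMAN, MOUSE]
    )

    coll_h = wide[HUMAN].duplicated(keep=False)
    coll_m = wide[MOUSE].duplicated(keep=False)
    colliding = wide.index[coll_h | coll_m]
    dropped += [(c, "symbol collision") for c in colliding]
    kept = wide.drop(index=colliding)

    entries = pd.DataFrame(
        {
            "human_symbol": kept[HUMAN].to_numpy(),
            "mouse_symbol": kept[MOUSE].to_numpy(),
        }
    ).sort_values("human_symbol", kind="stable").reset_index(drop=True)
    dropped_df = pd.DataFrame(sorted(dropped), columns=["class_id", "reason"])
    return OrthologTable(entries=entries, dropped_classes=dropped_df)


def translate_symbols(
    symbols: list[str],
    table: OrthologTable,
    direction: str = HUMAN_TO_MOUSE,
) -> tuple[list[str], list[str]]:
    """Translate an ordered gene list across species.

    Returns (translated, unmapped); order is preserved within each list
    and nothing is silently dropped.  Translating then reverse
    translating is the identity on the mapped subset.
    """
    if len(table) == 0:
        raise ValueError("empty ortholog table")
    mapping = table.mapping(direction)
    translated = [mapping[s] for s in symbols if s in mapping]
    unmapped = [s for s in symbols if s not in mapping]
    return translated, unmapped
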